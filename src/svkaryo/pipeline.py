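"""End-to-end orchestration: simulate -> filter -> ancestry -> windows ->
svscan -> xpehh -> trees, with one YAML config, per-stage derived seeds,
and a machine-readable JSON run report.

Stage seeds are derived deterministically from the master seed and the
stage name, so toggling one stage never changes another stage's draws.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc
from . import io_core, phylo, simulate, sv_karyotype, windows as win
from . import xpehh as xp

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "svkaryo_run",
    "input": {"vcf": None, "samples": None},
    "simulate": {"enabled": True},
    "stages": {"windows": True, "ancestry": True, "svscan": True,
               "xpehh": False, "tree": True},
    "maf": 0.05,
    "windows": {"size": 5000, "min_sites": 15, "method": "hudson",
                "q_low": 0.95, "q_high": 0.99, "chrom_rule": 0.025,
                "comparator": ">"},
    "ancestry": {"K": 3, "max_sites": 5000, "major": 0.80, "minor": 0.10,
                 "n_init": 10},
    "svscan": {"posterior": 0.90, "max_gap": 2, "use_local_pca": True},
    "xpehh": {"cutoff": 0.05, "max_gap_bp": 200000, "stride": 4,
              "n_chroms": 2},
    "tree": {"max_chroms": 3},
}

_POSITIVE = {("windows", "size"), ("windows", "min_sites"), ("ancestry", "K"),
             ("xpehh", "stride"), ("tree", "max_chroms")}


#: the simulate block also accepts generator-config overrides
_SIM_KEYS = {"enabled", "n_per_group", "n_chroms", "sites_per_chrom",
             "chrom_length_bp", "fst_targets", "sv_specs", "admix_concentration"}


def validate_config(cfg: dict) -> list[str]:
    """Schema-check a config dict; returns a list of error strings."""
    errors = []

    def walk(given, known, prefix=""):
        for key, val in given.items():
            if prefix == "simulate." and key in _SIM_KEYS:
                continue
            if key not in known:
                hint = difflib.get_close_matches(key, list(known), n=1)
                sug = f" (did you mean {hint[0]!r}?)" if hint else ""
                errors.append(f"unknown key {prefix}{key}{sug}")
                continue
            if isinstance(known[key], dict) and isinstance(val, dict):
                walk(val, known[key], prefix=f"{prefix}{key}.")

    walk(cfg, DEFAULT_CONFIG)
    merged = merge_config(cfg, check=False)
    for section, key in _POSITIVE:
        v = merged[section][key]
        if not (isinstance(v, (int, float)) and v > 0):
            errors.append(f"{section}.{key} must be positive, got {v!r}")
    for q in ("q_low", "q_high"):
        if not (0 < merged["windows"][q] < 1):
            errors.append(f"windows.{q} must be in (0,1)")
    if merged["windows"]["comparator"] not in (">", ">="):
        errors.append("windows.comparator must be '>' or '>='")
    return errors


def merge_config(cfg: dict, check: bool = True) -> dict:
    if check:
        errs = validate_config(cfg)
        if errs:
            raise ValueError("invalid config: " + "; ".join(errs))
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return merge_config(cfg)


def stage_seed(master: int, stage: str) -> int:
    return (int(master) + zlib.crc32(stage.encode())) % (2**31)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run(config: dict) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run report (also written to ``<outdir>/report.json``).
    Any stage failure aborts with a partial report on disk.
    """
    cfg = merge_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"config": cfg, "stages": {}, "warnings": [], "summary": {}}
    report_path = outdir / "report.json"

    def finish_stage(name, t0, outputs):
        report["stages"][name] = {
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": {str(p.name): _digest(p) for p in outputs},
        }
        report_path.write_text(json.dumps(report, indent=1, default=str))

    try:
        # ------------------------------------------------ input / simulate
        t0 = time.time()
        truth = None
        if cfg["simulate"]["enabled"]:
            sim_over = {k: v for k, v in cfg["simulate"].items() if k != "enabled"}
            sim_cfg = simulate.default_study_config(seed=stage_seed(cfg["seed"], "simulate"))
            for k, v in sim_over.items():
                setattr(sim_cfg, k, v)
            gm, truth = simulate.simulate_study(sim_cfg)
            sheet = truth.sample_sheet()
            io_core.write_vcf(gm, outdir / "sim.vcf")
            sheet.write_tsv(outdir / "samples.tsv")
            truth.to_json(outdir / "truth.json")
            finish_stage("simulate", t0, [outdir / "sim.vcf", outdir / "samples.tsv",
                                          outdir / "truth.json"])
        else:
            if not cfg["input"]["vcf"]:
                raise ValueError("stage 'simulate' disabled and no input.vcf given")
            gm = io_core.read_vcf(cfg["input"]["vcf"])
            sheet = (io_core.SampleSheet.read_tsv(cfg["input"]["samples"])
                     if cfg["input"]["samples"] else None)
            finish_stage("input", t0, [])

        gm_f = io_core.filter_maf(gm, cfg["maf"]) if cfg["maf"] else gm
        chrom_lengths = None
        if truth is not None:
            chrom_lengths = {c: sim_cfg.chrom_length_bp for c in sim_cfg.chrom_names()}

        # ------------------------------------------------ ancestry
        if not cfg["stages"]["ancestry"]:
            raise ValueError("stage 'ancestry' is required by downstream stages")
        t0 = time.time()
        a = cfg["ancestry"]
        sub = gm_f
        if sub.n_sites > a["max_sites"]:
            step = sub.n_sites / a["max_sites"]
            idx = (np.arange(a["max_sites"]) * step).astype(int)
            sub = sub.take_sites(idx)
        est = anc.AdmixtureEM(K=a["K"], n_init=a["n_init"],
                              seed=stage_seed(cfg["seed"], "ancestry")).fit(sub)
        Q = est.Q_
        if truth is not None:
            perm = anc.align_q_to_groups(Q, truth.ancestry["group"].to_numpy())
        else:
            perm = np.arange(a["K"])
        Q = Q[:, perm]
        profiles = anc.classify_profiles(Q, gm.samples, major=a["major"], minor=a["minor"])
        profiles.to_csv(outdir / "q_matrix.tsv", sep="\t", index=False)
        pca_res = anc.pca(sub, n_axes=4)
        pd.DataFrame(pca_res["coords"], index=gm.samples).to_csv(outdir / "pca_scores.tsv", sep="\t")
        if sheet is not None:
            comp = anc.class_composition_report(profiles, sheet)
            comp.to_csv(outdir / "class_composition.tsv", sep="\t")
        finish_stage("ancestry", t0, [outdir / "q_matrix.tsv", outdir / "pca_scores.tsv"])
        report["summary"]["class_counts"] = profiles["ternary_class"].value_counts().to_dict()

        # ------------------------------------------------ windows
        flagged = {}
        pops = {k: profiles.loc[profiles["ternary_class"] == k, "sample"].tolist()
                for k in ("C", "S", "M")}
        if cfg["stages"]["windows"]:
            t0 = time.time()
            w = cfg["windows"]
            outs = []
            for name, (ka, kb) in {"CM": ("C", "M"), "CS": ("C", "S"), "SM": ("S", "M")}.items():
                if len(pops[ka]) < 2 or len(pops[kb]) < 2:
                    report["warnings"].append(f"windows: too few samples for {name}")
                    continue
                tab = win.window_stats(gm, pops[ka], pops[kb], size=w["size"],
                                       min_sites=w["min_sites"], method=w["method"],
                                       chrom_lengths=chrom_lengths)
                tab = win.quantile_flags(tab, q_low=w["q_low"], q_high=w["q_high"])
                tab.to_csv(outdir / f"windows_{name}.tsv", sep="\t", index=False)
                flagged[name] = tab
                outs.append(outdir / f"windows_{name}.tsv")
            finish_stage("windows", t0, outs)

        # ------------------------------------------------ svscan
        sv_results = {}
        if cfg["stages"]["svscan"]:
            if not flagged:
                raise ValueError("stage 'svscan' needs stage 'windows' outputs")
            t0 = time.time()
            w = cfg["windows"]
            per_comp = {name: win.chromosome_sv_flag(tab, threshold=w["chrom_rule"],
                                                     comparator=w["comparator"])
                        for name, tab in flagged.items()}
            union = pd.DataFrame(per_comp).any(axis=1)
            sv_chroms = sorted(union[union].index)
            report["summary"]["flagged_chromosomes"] = sv_chroms
            s = cfg["svscan"]
            sv_results = sv_karyotype.sv_scan(
                gm, profiles, flagged, sv_chroms, posterior=s["posterior"],
                max_gap=s["max_gap"], use_local_pca=s["use_local_pca"],
                seed=stage_seed(cfg["seed"], "svscan"))
            outs = []
            for chrom, entry in sv_results.items():
                if entry.get("status") != "ok":
                    report["warnings"].append(f"svscan: {chrom}: {entry.get('status')}")
                    continue
                entry["calls"].to_csv(outdir / f"karyotypes_{chrom}.tsv", sep="\t", index=False)
                entry["freq_table"].to_csv(outdir / f"freq_{chrom}.tsv", sep="\t", index=False)
                outs.append(outdir / f"karyotypes_{chrom}.tsv")
                if not entry["polarization"]["polarized"]:
                    report["warnings"].append(f"svscan: {chrom} unpolarized")
            with open(outdir / "sv_blocks.bed", "w") as fh:
                for chrom, entry in sv_results.items():
                    for s0, e0 in entry.get("blocks", []):
                        fh.write(f"{chrom}\t{s0}\t{e0}\tSV\n")
            outs.append(outdir / "sv_blocks.bed")
            finish_stage("svscan", t0, outs)
            report["summary"]["called_svs"] = [
                c for c, e in sv_results.items() if e.get("status") == "ok"]

        # ------------------------------------------------ xpehh
        if cfg["stages"]["xpehh"]:
            t0 = time.time()
            x = cfg["xpehh"]
            sv_list = report["summary"].get("flagged_chromosomes", [])
            chroms = (sv_list[: 1] + [c for c in gm.chroms if c not in sv_list][: x["n_chroms"] - 1])
            rows = []
            for chrom in chroms:
                reg = gm.region(chrom)
                cores = list(range(0, reg.n_sites, x["stride"]))
                sc = xp.xpehh_scan(reg, pops["C"], pops["M"], cores=cores,
                                   cutoff=x["cutoff"], max_gap=x["max_gap_bp"])
                rows.append(sc)
            scores = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
            if len(scores):
                sd = scores["ln_ratio"].std(ddof=0)
                scores["z"] = (scores["ln_ratio"] - scores["ln_ratio"].mean()) / (sd or 1.0)
            scores.to_csv(outdir / "xpehh.tsv", sep="\t", index=False)
            finish_stage("xpehh", t0, [outdir / "xpehh.tsv"])

        # ------------------------------------------------ trees
        if cfg["stages"]["tree"]:
            if not sv_results:
                raise ValueError("stage 'tree' needs stage 'svscan' outputs")
            t0 = time.time()
            tdir = outdir / "trees"
            tdir.mkdir(exist_ok=True)
            outs = []
            done = 0
            for chrom, entry in sv_results.items():
                if entry.get("status") != "ok" or entry.get("block") is None:
                    continue
                if done >= cfg["tree"]["max_chroms"]:
                    break
                calls = entry["calls"]
                homo = phylo.subset_homokaryotes(gm, calls)
                if len(homo) < 4:
                    continue
                s0, e0 = entry["block"]
                dm = phylo.diff_matrix(gm, samples=homo, chrom=chrom, start=s0, end=e0)
                tree = phylo.nj(dm)
                geno = dict(zip(calls["sample"], calls["genotype"]))
                g00 = [s for s in homo if geno[s] == "00"]
                g11 = [s for s in homo if geno[s] in ("11", "22")]
                try:
                    tree = phylo.root_between_groups(tree, g00, g11)
                except ValueError as e:
                    report["warnings"].append(f"tree: {chrom}: {e}")
                phylo.write_newick(tree, tdir / f"{chrom}.nwk")
                outs.append(tdir / f"{chrom}.nwk")
                done += 1
            finish_stage("tree", t0, outs)
    except Exception as e:
        report["error"] = str(e)
        report_path.write_text(json.dumps(report, indent=1, default=str))
        raise
    report_path.write_text(json.dumps(report, indent=1, default=str))
    return report
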