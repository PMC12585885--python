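"""Synthetic three-lineage, SV-bearing genotype data with ground truth.

The generator emulates the statistical structure the downstream analyses
assume, without any coalescent machinery:

* Collinear background: per-site ancestral frequency ``p ~ U(0.05, 0.95)``
  drifts into each of three parental lineages (coastal ``C``, southern
  ``S``, marine ``M``) under the Balding-Nichols model with a per-lineage
  drift parameter ``F_k``; under this scheme the expected pairwise Hudson
  F_ST between two lineages is ``(F_a + F_b) / 2``, so pairwise F_ST
  targets translate into drift parameters by solving a linear system.
* Admixture: each individual carries an ancestry vector ``q`` (Dirichlet
  around its group's mean, groups placed along a 1-D latitude gradient);
  its genotype at a collinear site is Binomial(2, q . p_site).
* Structural variants: inside an SV block every site is determined by the
  two haplotype labels an individual draws from its ancestry-weighted
  karyotype frequencies — fixed differences between haplogroups, a small
  set of within-haplotype polymorphisms, and no recombination.

Every draw flows from a single :class:`numpy.random.Generator`, so one
(config, seed) pair yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, make_site_table, SampleSheet

LINEAGES = ("C", "S", "M")

#: group -> (mean ancestry (q_C, q_S, q_M), latitude in [0,1], habitat)
GROUP_MODEL = {
    "C": ((1.0, 0.0, 0.0), 0.15, "coastal"),
    "M": ((0.0, 0.0, 1.0), 0.20, "marine"),
    "MC": ((0.47, 0.06, 0.47), 0.35, "marine"),
    "CS": ((0.47, 0.47, 0.06), 0.50, "coastal"),
    "MCS": ((1 / 3, 1 / 3, 1 / 3), 0.60, "marine"),
    "SM": ((0.06, 0.47, 0.47), 0.75, "marine"),
    "S": ((0.0, 1.0, 0.0), 0.90, "marine"),
}


@dataclass
class SVSpec:
    """One non-recombining SV block.

    ``karyotype_freqs`` gives, per lineage, the frequency of the ``0``
    (southern-derived) haplotype; with ``n_haplotypes == 3``,
    ``third_hap_freqs`` gives the frequency of haplotype ``2`` *within*
    the ``1`` haplogroup. ``hap_divergence`` is the per-bp fixed-difference
    density between the ``0`` and ``1`` haplogroups; divergence between
    haplotypes 1 and 2 is ``third_divergence_frac`` of that, and
    within-haplotype polymorphism density is ``within_poly_frac`` of it.
    """

    chrom: str
    start: int
    end: int
    n_haplotypes: int = 2
    hap_divergence: float = 0.0018
    karyotype_freqs: dict = field(default_factory=dict)
    third_hap_freqs: dict = field(default_factory=dict)
    within_poly_frac: float = 0.10
    third_divergence_frac: float = 0.40

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("SV end must exceed start")
        if self.n_haplotypes not in (2, 3):
            raise ValueError("n_haplotypes must be 2 or 3")
        for k, v in self.karyotype_freqs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"karyotype freq out of [0,1] for {k}")


@dataclass
class SimConfig:
    n_per_group: dict
    n_chroms: int = 24
    sites_per_chrom: int = 2000
    chrom_length_bp: int = 500_000
    fst_targets: dict = field(default_factory=lambda: {"CM": 0.013, "CS": 0.075, "SM": 0.066})
    sv_specs: list = field(default_factory=list)
    seed: int = 0
    admix_concentration: float = 30.0

    def chrom_names(self):
        return [f"chr{i + 1:02d}" for i in range(self.n_chroms)]

    def validate(self):
        names = set(self.chrom_names())
        seen = {}
        for sv in self.sv_specs:
            if sv.chrom not in names:
                raise ValueError(f"SV chromosome {sv.chrom} not in config")
            if sv.end > self.chrom_length_bp:
                raise ValueError(f"SV on {sv.chrom} exceeds chromosome length")
            for (s, e) in seen.get(sv.chrom, []):
                if sv.start < e and s < sv.end:
                    raise ValueError(f"overlapping SVs on {sv.chrom}")
            seen.setdefault(sv.chrom, []).append((sv.start, sv.end))
        for g in self.n_per_group:
            if g not in GROUP_MODEL:
                raise ValueError(f"unknown group {g}")
        calibrate_drift(self.fst_targets)  # raises if infeasible
        return self


def calibrate_drift(fst_targets: dict) -> dict:
    """Solve per-lineage drift parameters from pairwise F_ST targets.

    Under per-lineage Balding-Nichols drift from a shared ancestral
    frequency, E[Hudson F_ST(a, b)] = (F_a + F_b) / 2, giving a linear
    system in (F_C, F_S, F_M). Raises if the solution leaves (0, 1).
    """
    t_cm, t_cs, t_sm = fst_targets["CM"], fst_targets["CS"], fst_targets["SM"]
    total = t_cm + t_cs + t_sm  # = F_C + F_S + F_M
    f = {"C": total - 2 * t_sm, "S": total - 2 * t_cm, "M": total - 2 * t_cs}
    for k, v in f.items():
        if not (0.0 < v < 1.0):
            raise ValueError(
                f"infeasible F_ST targets: implied drift F_{k} = {v:.4g} outside (0, 1)"
            )
    return f


@dataclass
class TruthTable:
    """Simulator ground truth for recovery tests.

    ``ancestry``: per-sample true q, group, latitude, location.
    ``karyotypes``: per SV chromosome, per sample: the drawn haplotype pair,
    the two-state karyotype (haplotype 2 counted within the ``1``
    haplogroup) and the full karyotype string.
    ``sv_regions``: per SV chromosome, breakpoints and haplotype counts.
    ``drift``: per-lineage Balding-Nichols F actually used.
    """

    ancestry: pd.DataFrame
    karyotypes: dict = field(default_factory=dict)
    sv_regions: dict = field(default_factory=dict)
    drift: dict = field(default_factory=dict)

    def q_matrix(self) -> np.ndarray:
        return self.ancestry[["q_C", "q_S", "q_M"]].to_numpy()

    def to_json(self, path):
        payload = {
            "ancestry": self.ancestry.to_dict(orient="list"),
            "karyotypes": {
                c: {k: list(v) for k, v in d.items()} for c, d in self.karyotypes.items()
            },
            "sv_regions": self.sv_regions,
            "drift": self.drift,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            ancestry=pd.DataFrame(payload["ancestry"]),
            karyotypes=payload["karyotypes"],
            sv_regions=payload["sv_regions"],
            drift=payload["drift"],
        )

    def sample_sheet(self) -> SampleSheet:
        tab = pd.DataFrame(
            {
                "sample_id": self.ancestry["sample"],
                "habitat": self.ancestry["habitat"],
                "location": self.ancestry["location"],
                "dataset": "WGS",
            }
        )
        return SampleSheet(tab)


def _draw_lineage_freqs(p: np.ndarray, F: float, rng) -> np.ndarray:
    if F < 1e-12:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def _draw_q(groups, config: SimConfig, rng) -> np.ndarray:
    q = np.zeros((len(groups), 3))
    conc = config.admix_concentration
    for i, g in enumerate(groups):
        mean = np.array(GROUP_MODEL[g][0])
        if g in LINEAGES:
            q[i] = mean  # parental individuals are unadmixed by construction
        else:
            q[i] = rng.dirichlet(mean * conc)
    return q


def simulate_collinear(config: SimConfig, rng=None):
    """Simulate the drifted, admixed collinear background.

    Returns a genotype matrix over all chromosomes (no SV blocks yet) and
    the truth table holding per-sample ancestry.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    drift = calibrate_drift(config.fst_targets)

    groups, sample_ids = [], []
    for g in sorted(config.n_per_group, key=lambda g: GROUP_MODEL[g][1]):
        for i in range(config.n_per_group[g]):
            groups.append(g)
            sample_ids.append(f"{g}_{i + 1:03d}")
    n = len(sample_ids)
    q = _draw_q(groups, config, rng)
    lat = np.array(
        [GROUP_MODEL[g][1] + rng.uniform(-0.05, 0.05) for g in groups]
    ).clip(0, 1)
    location = [f"LOC{int(np.floor(t * 5.9999)) + 1}" for t in lat]
    habitat = [GROUP_MODEL[g][2] for g in groups]

    chrom_col, pos_col = [], []
    dosage_parts = []
    for chrom in config.chrom_names():
        m = config.sites_per_chrom
        pos = np.sort(rng.choice(config.chrom_length_bp, size=m, replace=False)) + 1
        p_anc = rng.uniform(0.05, 0.95, size=m)
        p_lin = np.stack(
            [_draw_lineage_freqs(p_anc, drift[k], rng) for k in LINEAGES], axis=0
        )  # (3, m)
        p_ind = q @ p_lin  # (n, m)
        dos = rng.binomial(2, p_ind).astype(np.int8)
        chrom_col.extend([chrom] * m)
        pos_col.append(pos)
        dosage_parts.append(dos)
    pos_all = np.concatenate(pos_col)
    n_sites = len(pos_all)
    ref = rng.choice(list("ACGT"), size=n_sites)
    shift = rng.integers(1, 4, size=n_sites)
    order = np.array(list("ACGT"))
    lut = {b: i for i, b in enumerate(order)}
    alt = order[(np.array([lut[b] for b in ref]) + shift) % 4]
    sites = make_site_table(chrom_col, pos_all, ref, alt)
    gm = GenotypeMatrix(sample_ids, sites, np.concatenate(dosage_parts, axis=1))

    ancestry = pd.DataFrame(
        {
            "sample": sample_ids,
            "group": groups,
            "q_C": q[:, 0],
            "q_S": q[:, 1],
            "q_M": q[:, 2],
            "latitude": lat,
            "location": location,
            "habitat": habitat,
        }
    )
    truth = TruthTable(ancestry=ancestry, drift=drift)
    return gm, truth


def _partition_block_sites(n_block, L, spec: SVSpec, rng):
    """Split block site indices into fixed-difference / within-poly sets."""
    n_fix = int(round(spec.hap_divergence * L))
    n_third = (
        int(round(spec.third_divergence_frac * spec.hap_divergence * L))
        if spec.n_haplotypes == 3
        else 0
    )
    n_hap = spec.n_haplotypes
    n_within_each = int(round(spec.within_poly_frac * spec.hap_divergence * L))
    need = n_fix + n_third + n_hap * n_within_each
    if need > n_block:
        raise ValueError(
            f"SV block on {spec.chrom} has {n_block} sites but needs {need}; "
            "increase site density or lower hap_divergence"
        )
    perm = rng.permutation(n_block)
    out = {"fix01": perm[:n_fix], "fix12": perm[n_fix : n_fix + n_third]}
    at = n_fix + n_third
    for h in range(n_hap):
        out[f"within{h}"] = perm[at : at + n_within_each]
        at += n_within_each
    return out


def simulate_sv(gm: GenotypeMatrix, truth: TruthTable, spec: SVSpec, rng):
    """Overwrite one SV block with haplotype-determined genotypes (in place).

    Each individual draws two haplotype labels from its ancestry-weighted
    karyotype frequencies; all block sites are then deterministic given
    the labels except the within-haplotype polymorphic sites. Records the
    drawn karyotypes and the block breakpoints in the truth table.
    """
    if spec.chrom in truth.sv_regions:
        raise ValueError(f"chromosome {spec.chrom} already carries an SV")
    mask = gm.site_mask(spec.chrom, spec.start, spec.end)
    idx = np.flatnonzero(mask)
    L = spec.end - spec.start
    parts = _partition_block_sites(len(idx), L, spec, rng)

    q = truth.q_matrix()  # (n, 3) in order C, S, M
    f0 = np.array([spec.karyotype_freqs[k] for k in LINEAGES])
    f0_ind = q @ f0
    if spec.n_haplotypes == 3:
        f2 = np.array([spec.third_hap_freqs.get(k, 0.0) for k in LINEAGES])
        f2_ind = q @ f2
    else:
        f2_ind = np.zeros(len(q))

    n = gm.n_samples
    copies = np.zeros((n, 2), dtype=np.int8)
    u = rng.uniform(size=(n, 2))
    v = rng.uniform(size=(n, 2))
    in1 = u >= f0_ind[:, None]  # copy belongs to the 1 haplogroup
    copies[in1] = 1
    copies[in1 & (v < f2_ind[:, None])] = 2
    # Parental (unadmixed) groups realise their configured haplotype
    # frequencies exactly: balanced copy assignment, random pairing.
    groups = truth.ancestry["group"].to_numpy()
    for gi, k in enumerate(LINEAGES):
        rows = np.flatnonzero(groups == k)
        if len(rows) == 0:
            continue
        n_cp = 2 * len(rows)
        n0 = int(round(spec.karyotype_freqs[k] * n_cp))
        pool = np.ones(n_cp, dtype=np.int8)
        pool[:n0] = 0
        if spec.n_haplotypes == 3:
            n1g = n_cp - n0
            n2 = int(round(spec.third_hap_freqs.get(k, 0.0) * n1g))
            pool[n0 : n0 + n2] = 2
        rng.shuffle(pool)
        copies[rows] = pool.reshape(-1, 2)

    block = np.zeros((n, len(idx)), dtype=np.int8)
    n_group1 = (copies >= 1).sum(axis=1)  # dosage at 0-vs-1 fixed differences
    block[:, parts["fix01"]] = n_group1[:, None]
    n_hap2 = (copies == 2).sum(axis=1)
    block[:, parts["fix12"]] = n_hap2[:, None]
    for h in range(spec.n_haplotypes):
        cols = parts[f"within{h}"]
        if len(cols) == 0:
            continue
        freqs = rng.uniform(0.1, 0.4, size=len(cols))
        carries = (copies == h)  # (n, 2)
        draws = rng.uniform(size=(n, 2, len(cols))) < freqs[None, None, :]
        block[:, cols] += (draws & carries[:, :, None]).sum(axis=1).astype(np.int8)

    gm.dosage[:, idx] = block

    pair = np.sort(copies, axis=1)
    full = np.array([f"{a}{b}" for a, b in pair])
    grp = np.array([f"{min(a,1)}{min(b,1)}" for a, b in pair])
    truth.karyotypes[spec.chrom] = {
        "sample": list(gm.samples),
        "hap_pair": [f"{a}|{b}" for a, b in pair],
        "karyotype": list(grp),
        "karyotype_full": list(full),
    }
    truth.sv_regions[spec.chrom] = {
        "start": int(spec.start),
        "end": int(spec.end),
        "n_haplotypes": int(spec.n_haplotypes),
        "hap_divergence": float(spec.hap_divergence),
        "n_fixed_diff": int(len(parts["fix01"])),
        "karyotype_freqs": dict(spec.karyotype_freqs),
    }
    return gm, truth


def simulate_study(config: SimConfig):
    """Full generator: collinear background plus every configured SV."""
    rng = np.random.default_rng(config.seed)
    gm, truth = simulate_collinear(config, rng)
    for spec in config.sv_specs:
        simulate_sv(gm, truth, spec, rng)
    return gm, truth


def default_study_config(seed: int = 0) -> SimConfig:
    """The study-shaped default: 24 chromosomes, 13 SVs, 185 samples.

    SV karyotype-frequency profiles follow the observed qualitative
    patterns: three SVs where the southern haplotype is fixed in the
    coastal lineage, six SVs fixed 00 in the southern lineage overall,
    two SVs with a third haplotype splitting the 1 haplogroup between
    coastal and marine backgrounds, and one SV polymorphic in both
    northern lineages. Collinear drift targets pairwise F_ST
    (C-M, C-S, S-M) = (0.013, 0.075, 0.066).
    """
    svs = []

    def add(chrom, f0, n_hap=2, f2=None, div=0.0018, start=100_000, end=250_000):
        svs.append(
            SVSpec(
                chrom=chrom,
                start=start,
                end=end,
                n_haplotypes=n_hap,
                hap_divergence=div,
                karyotype_freqs=dict(zip(LINEAGES, f0)),
                third_hap_freqs=dict(zip(LINEAGES, f2)) if f2 else {},
            )
        )

    # southern haplotype shared with (fixed in) the coastal lineage
    add("chr02", (1.0, 1.0, 0.05), div=0.0019, start=120_000, end=270_000)
    add("chr05", (1.0, 1.0, 0.05), div=0.0017, start=80_000, end=230_000)
    add("chr12", (1.0, 1.0, 0.05), div=0.0018, start=200_000, end=350_000)
    # north-vs-south, fixed 00 in S
    add("chr03", (0.05, 1.0, 0.05), div=0.0018, start=150_000, end=300_000)
    add("chr08", (0.05, 1.0, 0.05), div=0.0016, start=60_000, end=210_000)
    add("chr15", (0.05, 1.0, 0.05), div=0.0019, start=250_000, end=400_000)
    add("chr07", (0.05, 1.0, 0.05), div=0.0018)
    add("chr17", (0.05, 1.0, 0.05), div=0.0017, start=300_000, end=450_000)
    add("chr21", (0.05, 1.0, 0.05), div=0.0018, start=50_000, end=200_000)
    add("chr23", (0.05, 1.0, 0.05), div=0.0019, start=180_000, end=330_000)
    # three haplotypes: 1 haplogroup split between coastal and marine
    add("chr10", (0.03, 0.95, 0.03), n_hap=3, f2=(0.95, 0.0, 0.03), div=0.0018)
    add("chr19", (0.03, 0.95, 0.03), n_hap=3, f2=(0.95, 0.0, 0.05), div=0.0018)
    # polymorphic in both northern lineages
    add("chr13", (0.5, 0.9, 0.5), div=0.0017)

    return SimConfig(
        n_per_group={"C": 40, "S": 40, "M": 40, "CS": 15, "SM": 15, "MC": 15, "MCS": 20},
        n_chroms=24,
        sites_per_chrom=2000,
        chrom_length_bp=500_000,
        fst_targets={"CM": 0.013, "CS": 0.075, "SM": 0.066},
        sv_specs=svs,
        seed=seed,
    )


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["sv_specs"] = [SVSpec(**s) for s in d.get("sv_specs", [])]
    return SimConfig(**d)


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    return d
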