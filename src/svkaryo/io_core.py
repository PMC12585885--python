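"""VCF / sample-sheet input-output and site-level filters.

Reads diploid GT calls from VCF 4.x into a :class:`~svkaryo.matrix.GenotypeMatrix`
(multiallelic and non-SNP records are skipped and counted), applies the
minor-allele-frequency filter, intersects the site sets of two matrices
(e.g. a dense and a reduced-representation call set over the same
reference), and merges samples across matrices on an identical site grid.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, SampleSheet, make_site_table

log = logging.getLogger(__name__)

_NUCS = {"A", "C", "G", "T"}


class VCFError(ValueError):
    pass


def read_vcf(path, region: str | None = None) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix.

    Multiallelic records and non-SNP alleles are skipped (logged with a
    count); dosage is taken from GT regardless of phasing; half or fully
    missing genotypes become missing.

    Parameters
    ----------
    path : str
        Path to a VCF 4.x file with GT fields.
    region : str, optional
        ``chrom`` or ``chrom:start-end`` restriction (1-based, inclusive,
        as in tabix); requires an indexed bgzipped file for random access,
        otherwise the region is filtered during the linear scan.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as e:  # pragma: no cover - cyvcf2 message passthrough
        raise VCFError(f"cannot parse VCF {path}: {e}") from e
    samples = list(vcf.samples)
    if not samples:
        raise VCFError(f"VCF {path} contains no samples")

    want_chrom = want_lo = want_hi = None
    if region:
        if ":" in region:
            want_chrom, span = region.split(":", 1)
            lo, hi = span.split("-", 1)
            want_lo, want_hi = int(lo), int(hi)
        else:
            want_chrom = region

    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if want_chrom is not None:
            if v.CHROM != want_chrom:
                continue
            if want_lo is not None and not (want_lo <= v.POS <= want_hi):
                continue
        if len(v.ALT) != 1 or v.REF not in _NUCS or v.ALT[0] not in _NUCS:
            n_skipped += 1
            continue
        gt = v.gt_types  # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        row = np.asarray(gt, dtype=np.int8)
        row[row == 3] = MISSING
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(row)
    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    sites = make_site_table(chroms, poss, refs, alts)
    dosage = (
        np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, sites, dosage)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in gm.chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        site_arr = gm.sites[["chrom", "pos", "ref", "alt"]].to_numpy()
        for j in range(gm.n_sites):
            chrom, pos, ref, alt = site_arr[j]
            gts = "\t".join(code[int(d)] for d in gm.dosage[:, j])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def filter_maf(gm: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Retain sites with minor-allele frequency strictly above ``min_maf``.

    Frequencies are computed over non-missing calls; with ``min_maf=0``
    only monomorphic sites are removed. The inequality is strict: a site
    at exactly the threshold is dropped.
    """
    if not (0 <= min_maf < 0.5):
        raise ValueError("min_maf must be in [0, 0.5)")
    maf = gm.minor_allele_freq()
    keep = np.nan_to_num(maf, nan=0.0) > min_maf
    log.info("filter_maf(%.3g): kept %d / %d sites", min_maf, int(keep.sum()), gm.n_sites)
    return gm.take_sites(keep)


def _site_keys(gm: GenotypeMatrix) -> pd.Index:
    s = gm.sites
    return pd.MultiIndex.from_arrays([s["chrom"], s["pos"], s["ref"], s["alt"]])


def intersect_sites(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix):
    """Restrict both matrices to their shared (chrom, pos, ref, alt) sites.

    Output site order follows the first matrix; raises if no site is shared.
    """
    ka, kb = _site_keys(gm_a), _site_keys(gm_b)
    shared = ka.intersection(kb, sort=False)
    if len(shared) == 0:
        raise ValueError("no shared sites between the two matrices")
    ia = np.flatnonzero(ka.isin(shared))
    pos_b = {k: i for i, k in enumerate(kb)}
    ib = np.array([pos_b[ka[i]] for i in ia], dtype=np.intp)
    return gm_a.take_sites(ia), gm_b.take_sites(ib)


def merge_samples(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix) -> GenotypeMatrix:
    """Union of samples over an identical site table.

    Site tables must match exactly (run :func:`intersect_sites` first);
    duplicate sample ids keep the first matrix's genotypes (logged).
    """
    if not gm_a.sites[["chrom", "pos", "ref", "alt"]].equals(
        gm_b.sites[["chrom", "pos", "ref", "alt"]]
    ):
        raise ValueError("site tables differ; intersect_sites first")
    seen = set(gm_a.samples)
    dup = [s for s in gm_b.samples if s in seen]
    if dup:
        log.info("merge_samples: %d duplicate ids kept from first matrix: %s", len(dup), dup[:5])
    extra = [s for s in gm_b.samples if s not in seen]
    idx_b = gm_b.sample_index(extra)
    dosage = np.concatenate([gm_a.dosage, gm_b.dosage[idx_b]], axis=0)
    return GenotypeMatrix(gm_a.samples + extra, gm_a.sites.copy(), dosage)
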