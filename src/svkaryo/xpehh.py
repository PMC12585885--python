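"""Cross-population extended haplotype homozygosity on unphased genotypes.

No phasing is attempted: individuals are grouped by the identity of
their multilocus *genotype* vector extending outward from a core site.
With ``n_g`` individuals in identity class g among n individuals,

    EHH(d) = sum_g n_g (n_g - 1) / (n (n - 1)),

which is 1 at distance zero (empty extension) and non-increasing as
sites are added. iHH integrates EHH over physical distance (trapezoid,
both directions summed), stopping at the linear-interpolated crossing of
the EHH cutoff. XP-EHH is ln(iHH_A / iHH_B), z-standardized over all
scanned cores in a single genome-wide bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class EHHCurve:
    core_site: int
    direction: str  # "left" | "right"
    distances: np.ndarray  # bp from core, starting at 0
    values: np.ndarray  # EHH, starting at 1.0


def _ehh_of_classes(class_ids: np.ndarray) -> float:
    n = len(class_ids)
    if n < 2:
        return float("nan")
    _, counts = np.unique(class_ids, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_unphased(gm: GenotypeMatrix, pop, core_site: int, direction: str,
                 cutoff: float = 0.05, max_gap: int = 200_000) -> EHHCurve:
    """EHH decay curve in one direction from a core site.

    The curve starts at (0, 1); each further point adds the next site
    (the core itself first) to the identity vector. Missing genotypes
    form their own identity symbol. Truncation happens at the chromosome
    end, at an inter-site gap above ``max_gap``, or one point after EHH
    falls below ``cutoff`` (so the crossing can be interpolated).
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    idx = gm.sample_index(pop)
    if len(idx) < 2:
        raise ValueError("need at least 2 individuals")
    chrom = gm.sites["chrom"].iloc[core_site]
    pos = gm.sites["pos"].to_numpy()
    on_chrom = np.flatnonzero((gm.sites["chrom"] == chrom).to_numpy())
    k0 = int(np.searchsorted(on_chrom, core_site))
    walk = on_chrom[k0:] if direction == "right" else on_chrom[: k0 + 1][::-1]

    core_pos = pos[core_site]
    class_ids = np.zeros(len(idx), dtype=np.int64)
    dists = [0.0]
    vals = [1.0]
    prev_pos = core_pos
    for j in walk:
        d = abs(int(pos[j]) - int(core_pos))
        if abs(int(pos[j]) - int(prev_pos)) > max_gap:
            break
        g = gm.dosage[idx, j].astype(np.int64)
        g = np.where(g < 0, 3, g)  # missing is its own symbol
        class_ids = class_ids * 4 + g
        _, class_ids = np.unique(class_ids, return_inverse=True)
        e = _ehh_of_classes(class_ids)
        if d > 0:
            dists.append(float(d))
            vals.append(e)
        else:
            vals[0] = 1.0  # core point stays at 1 by definition
            # the core genotype still refines the classes for later sites
        prev_pos = pos[j]
        if e < cutoff and d > 0:
            break
    return EHHCurve(core_site, direction, np.array(dists), np.array(vals))


def ihh(curve_left: EHHCurve, curve_right: EHHCurve, cutoff: float = 0.05) -> float:
    """Integrated EHH: trapezoid area of both directional curves.

    Integration stops at the linear-interpolated point where EHH crosses
    ``cutoff``; a curve entirely above the cutoff integrates over its
    full extent.
    """

    def one_side(c: EHHCurve) -> float:
        x, y = c.distances, c.values
        area = 0.0
        for i in range(1, len(x)):
            if y[i] >= cutoff:
                area += 0.5 * (y[i - 1] + y[i]) * (x[i] - x[i - 1])
            else:
                # interpolate crossing point within this interval
                if y[i - 1] <= cutoff:
                    break
                frac = (y[i - 1] - cutoff) / (y[i - 1] - y[i])
                xc = x[i - 1] + frac * (x[i] - x[i - 1])
                area += 0.5 * (y[i - 1] + cutoff) * (xc - x[i - 1])
                break
        return area

    return one_side(curve_left) + one_side(curve_right)


def xpehh_scan(gm: GenotypeMatrix, popA, popB, cores=None, cutoff: float = 0.05,
               max_gap: int = 200_000) -> pd.DataFrame:
    """XP-EHH scores for a set of core sites.

    Cores with an undefined or zero iHH in either population are dropped
    (logged). Returns ``chrom, pos, ihh_a, ihh_b, ln_ratio, z``.
    """
    if cores is None:
        cores = range(gm.n_sites)
    rows, dropped = [], 0
    for c in cores:
        vals = []
        for pop in (popA, popB):
            cl = ehh_unphased(gm, pop, c, "left", cutoff=cutoff, max_gap=max_gap)
            cr = ehh_unphased(gm, pop, c, "right", cutoff=cutoff, max_gap=max_gap)
            vals.append(ihh(cl, cr, cutoff=cutoff))
        ia, ib = vals
        if not (np.isfinite(ia) and np.isfinite(ib)) or ia <= 0 or ib <= 0:
            dropped += 1
            continue
        # log difference (not log of ratio) so population swap negates exactly
        rows.append((gm.sites["chrom"].iloc[c], int(gm.sites["pos"].iloc[c]),
                     ia, ib, float(np.log(ia) - np.log(ib))))
    if dropped:
        log.info("xpehh_scan: dropped %d cores with zero/undefined iHH", dropped)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ihh_a", "ihh_b", "ln_ratio"])
    if len(df):
        sd = df["ln_ratio"].std(ddof=0)
        df["z"] = (df["ln_ratio"] - df["ln_ratio"].mean()) / (sd if sd > 0 else 1.0)
    else:
        df["z"] = []
    return df
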