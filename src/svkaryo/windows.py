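"""Windowed diversity/differentiation landscapes and quantile flagging.

Statistics are computed in non-overlapping windows (default 5 kb, 0-based
half-open), with windows carrying fewer than ``min_sites`` usable sites
marked unusable and excluded from quantile thresholds. Per-bp quantities
(pi, d_XY) divide by the window's bp span. Missing genotypes are handled
pairwise-complete throughout; nothing is imputed.

F_ST comes in two flavours: Hudson (1 - mean within / mean between
heterozygosity, ratio of averages over sites — the default) and
Weir-Cockerham (variance components, ratio of sums).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    n_sites: int = 0

    @property
    def span(self) -> int:
        return self.end - self.start


def make_windows(sites: pd.DataFrame, size: int = 5000, min_sites: int = 15,
                 chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping windows.

    Returns a frame with ``chrom, start, end, n_sites, partial, usable``.
    Without ``chrom_lengths`` the last window is truncated at the last
    site (making it partial); a window is usable when it holds at least
    ``min_sites`` sites.
    """
    rows = []
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy() - 1
        length = (chrom_lengths or {}).get(chrom, int(pos0.max()) + 1 if len(pos0) else 0)
        n_win = max(1, int(np.ceil(length / size)))
        starts = np.arange(n_win) * size
        ends = np.minimum(starts + size, length)
        counts = np.histogram(pos0, bins=np.append(starts, length))[0] if len(pos0) else np.zeros(n_win, int)
        for s, e, c in zip(starts, ends, counts):
            rows.append((chrom, int(s), int(e), int(c), e - s < size, c >= min_sites))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "partial", "usable"])


# ---------------------------------------------------------------------------
# per-site building blocks

def _pop_site_stats(gm: GenotypeMatrix, idx):
    """Per-site alt frequency, unbiased heterozygosity and allele counts."""
    d = gm.dosage[idx]
    called = d >= 0
    an = 2 * called.sum(axis=0).astype(np.float64)
    ac = np.where(called, d, 0).sum(axis=0).astype(np.float64)
    ok = an >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, ac / np.maximum(an, 1), np.nan)
        het = np.where(ok, 2 * p * (1 - p) * an / np.maximum(an - 1, 1), np.nan)
    return p, het, an, ok


def pi(gm: GenotypeMatrix, pop_samples, window: Window) -> float:
    """Per-bp nucleotide diversity of one population in one window.

    Sum over sites of ``2 p (1-p) n/(n-1)`` (n = non-missing allele
    count), divided by the window's bp span; equals the mean pairwise
    difference per bp.
    """
    idx = gm.sample_index(pop_samples)
    sub = gm.region(window.chrom, window.start, window.end)
    _, het, _, ok = _pop_site_stats(sub, idx)
    return float(np.nansum(np.where(ok, het, 0.0)) / window.span)


def dxy(gm: GenotypeMatrix, popA, popB, window: Window) -> float:
    """Per-bp absolute divergence between two populations in one window."""
    ia, ib = gm.sample_index(popA), gm.sample_index(popB)
    sub = gm.region(window.chrom, window.start, window.end)
    pA, _, _, okA = _pop_site_stats(sub, ia)
    pB, _, _, okB = _pop_site_stats(sub, ib)
    ok = okA & okB
    term = pA * (1 - pB) + pB * (1 - pA)
    return float(np.nansum(np.where(ok, term, 0.0)) / window.span)


def _hudson_sums(gm: GenotypeMatrix, ia, ib):
    """Per-site Hudson numerator/denominator terms and validity mask."""
    pA, hA, _, okA = _pop_site_stats(gm, ia)
    pB, hB, _, okB = _pop_site_stats(gm, ib)
    ok = okA & okB
    hw = (hA + hB) / 2.0
    hb = pA * (1 - pB) + pB * (1 - pA)
    return hw, hb, ok


def _wc_components(gm: GenotypeMatrix, ia, ib):
    """Weir-Cockerham (1984) two-population variance components per site."""
    comps = []
    for idx in (ia, ib):
        d = gm.dosage[idx]
        called = d >= 0
        n_i = called.sum(axis=0).astype(np.float64)  # diploids
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(called, d, 0).sum(axis=0) / np.maximum(2 * n_i, 1)
            h_i = (d == 1).sum(axis=0) / np.maximum(n_i, 1)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    ok = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 3)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    return a, b, c, ok & (nbar > 1) & (nc > 0)


def fst(gm: GenotypeMatrix, popA, popB, window: Window | None = None,
        method: str = "hudson") -> float:
    """F_ST between two sample groups, optionally restricted to a window.

    Hudson: ratio of averages of within/between heterozygosity. WC:
    Weir-Cockerham ratio of sums of variance components. Returns NaN when
    no site is informative.
    """
    sub = gm if window is None else gm.region(window.chrom, window.start, window.end)
    ia, ib = sub.sample_index(popA), sub.sample_index(popB)
    if method == "hudson":
        hw, hb, ok = _hudson_sums(sub, ia, ib)
        den = np.nansum(np.where(ok, hb, 0.0))
        if den <= 0 or not ok.any():
            return float("nan")
        return float(1.0 - np.nansum(np.where(ok, hw, 0.0)) / den)
    elif method == "wc":
        a, b, c, ok = _wc_components(sub, ia, ib)
        den = np.nansum(np.where(ok, a + b + c, 0.0))
        if den == 0 or not ok.any():
            return float("nan")
        return float(np.nansum(np.where(ok, a, 0.0)) / den)
    raise ValueError(f"unknown method {method!r}")


def individual_het(gm: GenotypeMatrix, chrom: str | None = None,
                   start: int | None = None, end: int | None = None) -> pd.Series:
    """Per-sample heterozygous fraction over non-missing calls in a region."""
    sub = gm if chrom is None else gm.region(chrom, start, end)
    d = sub.dosage
    called = (d >= 0).sum(axis=1)
    het = (d == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    return pd.Series(frac, index=sub.samples, name="het")


def geno_r2(gm: GenotypeMatrix, site_i: int, site_j: int) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples."""
    x = gm.dosage[:, site_i].astype(float)
    y = gm.dosage[:, site_j].astype(float)
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_snp_windows(gm: GenotypeMatrix, samples=None, n_snps: int = 50) -> pd.DataFrame:
    """Mean pairwise r^2 in windows of ``n_snps`` consecutive SNPs per chromosome."""
    sub = gm if samples is None else gm.take_samples(samples)
    rows = []
    for chrom in sub.chroms:
        reg = sub.region(chrom)
        d = reg.dosage.astype(float)
        d[d < 0] = np.nan
        pos = reg.sites["pos"].to_numpy()
        for w0 in range(0, reg.n_sites - 1, n_snps):
            blk = d[:, w0 : w0 + n_snps]
            if blk.shape[1] < 2:
                continue
            df = pd.DataFrame(blk)
            r = df.corr().to_numpy()  # pairwise-complete
            iu = np.triu_indices_from(r, k=1)
            vals = r[iu] ** 2
            rows.append(
                (chrom, int(pos[w0]), int(pos[min(w0 + n_snps, reg.n_sites) - 1]),
                 blk.shape[1], float(np.nanmean(vals)))
            )
    return pd.DataFrame(rows, columns=["chrom", "pos_first", "pos_last", "n_snps", "mean_r2"])


# ---------------------------------------------------------------------------
# landscape driver and flagging

def window_stats(gm: GenotypeMatrix, popA, popB, size: int = 5000,
                 min_sites: int = 15, method: str = "hudson",
                 chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Per-window pi/pi/d_XY/F_ST table for one population comparison.

    Vectorized over sites: per-site terms are computed once and summed
    into windows. Unusable windows keep their coordinates but carry NaN
    statistics.
    """
    ia, ib = gm.sample_index(popA), gm.sample_index(popB)
    win = make_windows(gm.sites, size=size, min_sites=min_sites, chrom_lengths=chrom_lengths)

    pA, hA, _, okA = _pop_site_stats(gm, ia)
    pB, hB, _, okB = _pop_site_stats(gm, ib)
    ok = okA & okB
    hw = np.where(ok, (hA + hB) / 2.0, 0.0)
    hb = np.where(ok, pA * (1 - pB) + pB * (1 - pA), 0.0)
    hA_ = np.where(okA, hA, 0.0)
    hB_ = np.where(okB, hB, 0.0)
    if method == "wc":
        a_c, b_c, c_c, ok_wc = _wc_components(gm, ia, ib)
        wc_num = np.where(ok_wc, a_c, 0.0)
        wc_den = np.where(ok_wc, a_c + b_c + c_c, 0.0)

    chrom_arr = gm.sites["chrom"].to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1

    out = win.copy()
    out["pi_A"] = np.nan
    out["pi_B"] = np.nan
    out["dxy"] = np.nan
    out["fst"] = np.nan
    for chrom, widx in out.groupby("chrom", sort=False).groups.items():
        m = chrom_arr == chrom
        wsub = out.loc[widx]
        starts = wsub["start"].to_numpy()
        bins = np.append(starts, wsub["end"].to_numpy()[-1])
        wid = np.digitize(pos0[m], bins) - 1
        nwin = len(starts)
        valid = (wid >= 0) & (wid < nwin)

        def wsum(x):
            return np.bincount(wid[valid], weights=x[m][valid], minlength=nwin)

        span = (wsub["end"] - wsub["start"]).to_numpy().astype(float)
        pi_a = wsum(hA_) / span
        pi_b = wsum(hB_) / span
        dxy_w = wsum(hb) / span
        with np.errstate(invalid="ignore", divide="ignore"):
            if method == "hudson":
                den = wsum(hb)
                fst_w = np.where(den > 0, 1.0 - wsum(hw) / np.maximum(den, 1e-300), np.nan)
            else:
                den = wsum(wc_den)
                fst_w = np.where(den != 0, wsum(wc_num) / den, np.nan)
        usable = wsub["usable"].to_numpy()
        out.loc[widx, "pi_A"] = np.where(usable, pi_a, np.nan)
        out.loc[widx, "pi_B"] = np.where(usable, pi_b, np.nan)
        out.loc[widx, "dxy"] = np.where(usable, dxy_w, np.nan)
        out.loc[widx, "fst"] = np.where(usable, fst_w, np.nan)
    return out


def quantile_flags(stat_table: pd.DataFrame, value_col: str = "fst",
                   q_low: float = 0.95, q_high: float = 0.99) -> pd.DataFrame:
    """Flag windows strictly above genome-wide empirical quantiles.

    Thresholds use linear-interpolation quantiles over usable windows
    with a defined statistic; flags are ``q95`` (above the low quantile)
    and ``q99`` (above the high one, a subset of q95).
    """
    out = stat_table.copy()
    vals = out.loc[out["usable"] & out[value_col].notna(), value_col].to_numpy()
    out["flag"] = "none"
    if len(vals) == 0:
        return out
    t_low = np.quantile(vals, q_low)
    t_high = np.quantile(vals, q_high)
    v = out[value_col].to_numpy()
    with np.errstate(invalid="ignore"):
        above_low = out["usable"].to_numpy() & (v > t_low)
        above_high = out["usable"].to_numpy() & (v > t_high)
    out.loc[above_low, "flag"] = "q95"
    out.loc[above_high, "flag"] = "q99"
    return out


def chromosome_sv_flag(stat_table: pd.DataFrame, threshold: float = 0.025,
                       comparator: str = ">") -> pd.Series:
    """Flag chromosomes whose q95-window fraction exceeds ``threshold``.

    The fraction is taken over usable windows only; ``comparator``
    selects strict ``>`` (default, 'more than') or ``>=`` ('at least').
    """
    if comparator not in (">", ">="):
        raise ValueError("comparator must be '>' or '>='")
    res = {}
    for chrom, sub in stat_table.groupby("chrom", sort=False):
        usable = sub["usable"]
        n = int(usable.sum())
        k = int((sub.loc[usable, "flag"].isin(["q95", "q99"])).sum())
        frac = k / n if n else 0.0
        res[chrom] = frac > threshold if comparator == ">" else frac >= threshold
    return pd.Series(res, name="sv_flag")
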