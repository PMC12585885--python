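"""SV detection and karyotype genotyping from chromosome-wide PCA clusters.

A megabase-scale, non-recombining SV shows up on a chromosome-wide PCA
as three clusters along one axis (the two homokaryote groups flanking
the heterokaryotes, whose heterozygosity is elevated). Karyotypes are
called from a 1-D three-component Gaussian mixture on the selected axis,
leaving low-posterior samples unassigned; the ``00`` label is polarized
to the homokaryote cluster holding the most southern-ancestry samples.
Block boundaries come from runs of outlier windows (differentiation
flags and/or local-PCA cluster membership, lostruct-style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .matrix import GenotypeMatrix
from .ancestry import GenotypePCA
from .windows import individual_het, make_windows

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


def chrom_pca(gm: GenotypeMatrix, chrom: str, n_axes: int = 4, scaling: str = "patterson"):
    """Chromosome-restricted PCA (same conventions as the genome-wide one)."""
    sub = gm.region(chrom)
    est = GenotypePCA(n_axes=n_axes, scaling=scaling)
    coords = est.fit_transform(sub)
    return {
        "coords": coords,
        "explained_var": est.explained_variance_ratio_,
        "samples": list(sub.samples),
        "chrom": chrom,
    }


class _Partition:
    """Three ordered karyotype groups merged from a 1-D Gaussian mixture.

    ``groups`` assigns each mean-ordered mixture component to group 0
    (left homokaryotes), 1 (middle heterokaryotes) or 2 (right
    homokaryotes). With more than three components, sub-structure inside
    a homokaryote cluster (e.g. a secondary haplotype split) is absorbed
    by merging adjacent components into one group.
    """

    def __init__(self, gmm, order, split):
        self.gmm = gmm
        self.order = np.asarray(order)
        i, j = split
        k = len(order)
        self.comp_group = np.repeat([0, 1, 2], [i, j - i, k - j])
        self.mu = gmm.means_.ravel()[order]
        self.sd = np.sqrt(gmm.covariances_.ravel()[order])
        self.boundaries = (i, j)

    @property
    def separation(self) -> float:
        """Min standardized gap across the two group boundaries."""
        gaps = []
        for b in self.boundaries:
            gap = (self.mu[b] - self.mu[b - 1]) / max(
                np.sqrt((self.sd[b] ** 2 + self.sd[b - 1] ** 2) / 2), 1e-12)
            gaps.append(gap)
        return float(min(gaps))

    def posteriors(self, x):
        """(n, 3) merged group posteriors for scores ``x``."""
        post = self.gmm.predict_proba(np.asarray(x, float).reshape(-1, 1))[:, self.order]
        out = np.zeros((len(post), 3))
        for g in range(3):
            out[:, g] = post[:, self.comp_group == g].sum(axis=1)
        return out

    def labels(self, x):
        return self.posteriors(x).argmax(axis=1)

    def z_to_group(self, x, group_labels):
        """Standardized distance to the nearest component of the assigned group."""
        x = np.asarray(x, float).ravel()
        z = np.full(len(x), np.inf)
        for g in range(3):
            sel = group_labels == g
            if not sel.any():
                continue
            comps = np.flatnonzero(self.comp_group == g)
            zg = np.min(
                [np.abs(x[sel] - self.mu[c]) / max(self.sd[c], 1e-12) for c in comps],
                axis=0)
            z[sel] = zg
        return z


def _middle_het_elevated(het: np.ndarray, lab: np.ndarray, alpha: float = 0.01) -> bool:
    """Is the middle group's heterozygosity significantly above both outers?

    One-sided Welch tests; guards against chance mean orderings when a
    mixture slices a homogeneous cluster into adjacent components.
    """
    from scipy import stats

    mid = het[lab == 1]
    mid = mid[np.isfinite(mid)]
    if len(mid) < 2:
        return False
    for g in (0, 2):
        out = het[lab == g]
        out = out[np.isfinite(out)]
        if len(out) < 2:
            return False
        t, p = stats.ttest_ind(mid, out, equal_var=False, alternative="greater")
        if not (np.isfinite(p) and p < alpha):
            return False
    return True


def _fit_partition(x: np.ndarray, het: np.ndarray | None = None,
                   min_separation: float = 3.0, seed: int = 0):
    """Find a three-group karyotype partition of 1-D scores.

    Components are fitted with k = 3 first; when no contiguous merge of
    the mean-ordered components into three groups passes the separation
    (and, when heterozygosities are given, the middle-group-elevated)
    checks, k is escalated to 4 then 5 so that sub-structured
    homokaryote clusters can be absorbed. Returns ``None`` when nothing
    qualifies. Among qualifying splits the one with the largest
    heterozygosity contrast (or separation, without het) wins.
    """
    x = np.asarray(x, float).ravel()
    reg = 1e-6 * max(float(np.var(x)), 1e-12)
    x1 = x.reshape(-1, 1)
    bic1 = GaussianMixture(n_components=1, random_state=seed).fit(x1).bic(x1)
    # extra components are only safe under the heterozygosity check;
    # without it a sliced homogeneous cluster could fake a partition
    ks = (3, 4, 5) if het is not None else (3,)
    for k in ks:
        if len(x) < k + 2:
            break
        try:
            gmk = GaussianMixture(n_components=k, n_init=5, init_params="kmeans",
                                  random_state=seed, reg_covar=reg).fit(x1)
        except Exception:
            continue
        if gmk.bic(x1) >= bic1:
            continue
        order = np.argsort(gmk.means_.ravel())
        best, best_score = None, -np.inf
        for i in range(1, k - 1):
            for j in range(i + 1, k):
                part = _Partition(gmk, order, (i, j))
                if part.separation < min_separation:
                    continue
                lab = part.labels(x)
                if min((lab == 0).sum(), (lab == 2).sum()) < 2 or not (lab == 1).any():
                    continue
                if het is not None:
                    if not _middle_het_elevated(het, lab):
                        continue
                    outer = max(np.nanmean(het[lab == 0]), np.nanmean(het[lab == 2]))
                    score = np.nanmean(het[lab == 1]) - outer
                else:
                    score = part.separation
                if score > best_score:
                    best, best_score = part, score
        if best is not None:
            return best
    return None


def select_sv_axis(pca_result: dict, het_by_sample: pd.Series, max_axes: int = 4,
                   min_separation: float = 3.0, seed: int = 0):
    """Pick the PCA axis carrying a three-cluster karyotype signal.

    An axis qualifies when a mixture partition of its scores yields
    three groups whose adjacent boundaries are separated by at least
    ``min_separation`` pooled standard deviations, beats the single
    Gaussian on BIC, and whose middle group shows higher mean
    heterozygosity than both outer groups. The lowest-index qualifying
    axis wins (karyotype structure sits on PC1 unless an unrelated,
    stronger signal displaces it); returns ``None`` when no axis
    qualifies.
    """
    coords = pca_result["coords"]
    het = het_by_sample.reindex(pca_result["samples"]).to_numpy()
    for a in range(min(max_axes, coords.shape[1])):
        part = _fit_partition(coords[:, a], het=het,
                              min_separation=min_separation, seed=seed)
        if part is not None:
            return a
    return None


class KaryotypeGenotyper(BaseEstimator):
    """Karyotype caller: mixture partition of 1-D axis scores.

    ``predict`` returns provisional labels ``00``/``01``/``11`` (left /
    middle / right group; orientation fixed later by polarization) or
    ``unassigned`` when the maximum merged-group posterior falls at or
    below ``threshold`` or the score sits more than ``z_max`` component
    standard deviations from every component of its group (posteriors
    normalise even among vanishing densities, so a lone midway sample
    needs the distance guard to stay ungenotyped). A degenerate fit (an
    outer group holding fewer than 2 samples, or no qualifying
    partition) yields all-unassigned calls with a warning.
    """

    def __init__(self, threshold: float = 0.90, z_max: float = 4.0,
                 min_separation: float = 3.0, seed: int = 0):
        self.threshold = threshold
        self.z_max = z_max
        self.min_separation = min_separation
        self.seed = seed

    def fit(self, x, het=None):
        x = np.asarray(x, dtype=float).ravel()
        self.partition_ = _fit_partition(
            x, het=het, min_separation=self.min_separation, seed=self.seed)
        self.degenerate_ = self.partition_ is None
        if not self.degenerate_:
            lab = self.partition_.labels(x)
            counts = np.bincount(lab, minlength=3)
            self.degenerate_ = bool(min(counts[0], counts[2]) < 2)
        if self.degenerate_:
            log.warning("KaryotypeGenotyper: degenerate partition; all calls unassigned")
        return self

    def predict(self, x):
        x = np.asarray(x, dtype=float).ravel()
        if self.degenerate_ or self.partition_ is None:
            return np.full(len(x), UNASSIGNED, dtype=object), np.zeros(len(x))
        post = self.partition_.posteriors(x)
        names = np.array(["00", "01", "11"])
        best = post.argmax(axis=1)
        conf = post[np.arange(len(x)), best]
        z = self.partition_.z_to_group(x, best)
        out = np.where((conf > self.threshold) & (z <= self.z_max), names[best], UNASSIGNED)
        return out, conf


def genotype_karyotypes(pca_result: dict, axis: int, threshold: float = 0.90,
                        het_by_sample: pd.Series | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Call per-sample karyotypes from one PCA axis.

    Per-sample heterozygosities, when given, steer the component merge
    (the middle group must be the heterozygous one). Returns a frame
    ``sample, genotype, confidence, axis_used`` with provisional
    (unpolarized) genotype labels.
    """
    x = pca_result["coords"][:, axis]
    het = (het_by_sample.reindex(pca_result["samples"]).to_numpy()
           if het_by_sample is not None else None)
    gt, conf = KaryotypeGenotyper(threshold=threshold, seed=seed).fit(x, het=het).predict(x)
    return pd.DataFrame(
        {
            "sample": pca_result["samples"],
            "genotype": gt,
            "confidence": conf,
            "axis_used": axis,
        }
    )


def polarize(calls: pd.DataFrame, profiles: pd.DataFrame):
    """Polarize karyotype labels so ``00`` is the southern-derived cluster.

    The homokaryote cluster containing more southern-class (``S``)
    samples becomes ``00``. With zero S-class samples or a tie the labels
    are left as-is and the record is flagged unpolarized.
    """
    cls = dict(zip(profiles["sample"], profiles["ternary_class"]))
    s_in = {"00": 0, "11": 0}
    for _, row in calls.iterrows():
        if row["genotype"] in s_in and cls.get(row["sample"]) == "S":
            s_in[row["genotype"]] += 1
    record = {"s_in_00": s_in["00"], "s_in_11": s_in["11"], "polarized": True, "swapped": False}
    out = calls.copy()
    if s_in["00"] == s_in["11"]:
        record["polarized"] = False
        log.warning("polarize: no or tied southern evidence; labels arbitrary-but-stable")
        return out, record
    if s_in["11"] > s_in["00"]:
        swap = {"00": "11", "11": "00"}
        out["genotype"] = out["genotype"].map(lambda g: swap.get(g, g))
        record["swapped"] = True
    return out, record


# ---------------------------------------------------------------------------
# local PCA (lostruct-style)

@dataclass
class LocalPCAField:
    """Per-window low-rank eigenstructure and the window-pair distances."""

    windows: pd.DataFrame
    eigvals: np.ndarray  # (n_windows, k)
    eigvecs: np.ndarray  # (n_windows, n_samples, k)
    distances: np.ndarray  # (n_windows, n_windows)
    mds: np.ndarray  # (n_windows, 2)
    sv_windows: np.ndarray = field(default=None)  # boolean membership


def local_pca(gm: GenotypeMatrix, chrom: str, window: int = 5000, k: int = 2,
              min_sites: int = 5, seed: int = 0) -> LocalPCAField:
    """Windowed PCA field over one chromosome.

    Each usable window contributes the top-``k`` eigenpairs of its
    (Frobenius-normalised) sample-covariance matrix; window-pair distance
    is the Frobenius distance between the rank-``k`` approximations,
    computed from the eigenpairs without materialising n x n matrices.
    Classical MDS of the distance matrix gives 2-D window coordinates,
    and a 2-means split of those marks the candidate SV windows (the
    minority cluster).
    """
    sub = gm.region(chrom)
    win = make_windows(sub.sites, size=window, min_sites=min_sites)
    pos0 = sub.sites["pos"].to_numpy() - 1
    evals, evecs, keep = [], [], []
    for _, w in win.iterrows():
        if not w["usable"]:
            keep.append(False)
            continue
        cols = (pos0 >= w["start"]) & (pos0 < w["end"])
        D = sub.dosage[:, cols].astype(float)
        D[D < 0] = np.nan
        mean = np.nanmean(D, axis=0)
        Z = np.where(np.isnan(D), mean[None, :], D) - mean[None, :]
        C = Z @ Z.T / max(Z.shape[1] - 1, 1)
        nrm = np.linalg.norm(C)
        if nrm <= 0:
            keep.append(False)
            continue
        C /= nrm
        vals, vecs = np.linalg.eigh(C)
        evals.append(vals[-k:][::-1])
        evecs.append(vecs[:, -k:][:, ::-1])
        keep.append(True)
    keep = np.array(keep)
    windows = win.loc[keep].reset_index(drop=True)
    if not len(windows):
        raise ValueError(f"no usable local-PCA windows on {chrom}")
    evals = np.stack(evals)
    evecs = np.stack(evecs)

    nw = len(windows)
    sq = (evals**2).sum(axis=1)
    cross = np.zeros((nw, nw))
    for i in range(nw):
        Vi = evecs[i] * evals[i][None, :]  # n x k, scaled
        for j in range(i + 1, nw):
            M = Vi.T @ evecs[j]  # k x k of v_i . v_j, scaled by lambda_i
            cross[i, j] = cross[j, i] = float((M**2 * evals[j][None, :]).sum())
    d2 = sq[:, None] + sq[None, :] - 2 * cross
    np.fill_diagonal(d2, 0.0)
    dist = np.sqrt(np.maximum(d2, 0.0))

    # classical MDS
    J = np.eye(nw) - np.ones((nw, nw)) / nw
    B = -0.5 * J @ (dist**2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:2]
    mds = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))

    # candidate SV windows: minority cluster of a 2-means split, accepted
    # only when the split is real (clear silhouette) — a homogeneous MDS
    # cloud on a collinear chromosome yields no marks
    sv_mask = np.zeros(nw, dtype=bool)
    if nw >= 4:
        from sklearn.metrics import silhouette_score

        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(mds)
        lab = km.labels_
        sizes = np.bincount(lab, minlength=2)
        minority = int(np.argmin(sizes))
        # an SV spans many consecutive windows: a minority cluster needs
        # at least 3 members besides a clear silhouette to count
        if 3 <= sizes[minority] < 0.45 * nw:
            sil = silhouette_score(mds, lab)
            if sil > 0.5:
                sv_mask = lab == minority
    return LocalPCAField(windows, evals, evecs, dist, mds, sv_mask)


def delimit_blocks(window_table: pd.DataFrame, flags: np.ndarray,
                   local_field: LocalPCAField | None = None,
                   max_gap: int = 2) -> list[tuple[int, int]]:
    """Merge flagged windows into SV blocks.

    ``flags`` is a per-window boolean aligned with ``window_table`` (one
    chromosome). A window also counts when it belongs to the local-PCA SV
    cluster. Maximal runs tolerating up to ``max_gap`` unflagged windows
    are merged; each block is the [start, end) bp union span of its run.
    """
    tab = window_table.reset_index(drop=True)
    hit = np.asarray(flags, dtype=bool).copy()
    if local_field is not None and local_field.sv_windows is not None:
        lw = local_field.windows
        sv_spans = lw.loc[local_field.sv_windows, ["start", "end"]].to_numpy()
        for s, e in sv_spans:
            hit |= ((tab["start"] < e) & (tab["end"] > s)).to_numpy()
    blocks = []
    idx = np.flatnonzero(hit)
    if len(idx) == 0:
        return blocks
    run_start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 > max_gap:
            blocks.append((int(tab.loc[run_start, "start"]), int(tab.loc[prev, "end"])))
            run_start = i
        prev = i
    blocks.append((int(tab.loc[run_start, "start"]), int(tab.loc[prev, "end"])))
    return blocks


def freq_tables(calls: pd.DataFrame, profiles: pd.DataFrame,
                sample_sheet=None) -> pd.DataFrame:
    """Genotype and haplotype frequencies per ancestry cluster.

    Unassigned samples are excluded from denominators; the ``0``
    haplotype frequency is (2 n00 + n01) / (2 n_called). When a sample
    sheet is given, clusters are split by habitat as well.
    """
    cls = dict(zip(profiles["sample"], profiles["ternary_class"]))
    df = calls.copy()
    df["cluster"] = df["sample"].map(cls)
    if sample_sheet is not None:
        hab = sample_sheet.habitat_of()
        df["cluster"] = df["cluster"] + "/" + df["sample"].map(hab)
    rows = []
    for cluster, sub in df.groupby("cluster", sort=True):
        called = sub[sub["genotype"] != UNASSIGNED]
        n = len(called)
        counts = called["genotype"].value_counts()
        n00, n01, n11 = (int(counts.get(g, 0)) for g in ("00", "01", "11"))
        hap0 = (2 * n00 + n01) / (2 * n) if n else np.nan
        rows.append(
            (cluster, n, len(sub) - n,
             n00 / n if n else np.nan, n01 / n if n else np.nan, n11 / n if n else np.nan,
             hap0)
        )
    return pd.DataFrame(
        rows, columns=["cluster", "n_called", "n_unassigned",
                       "f00", "f01", "f11", "hap0_freq"]
    )


def third_haplotype_scan(gm: GenotypeMatrix, calls: pd.DataFrame, chrom: str,
                         block: tuple[int, int] | None = None,
                         min_separation: float = 3.0, seed: int = 0) -> dict:
    """Look for a secondary haplotype split within the ``1`` haplogroup.

    Reruns PCA and mixture clustering on the ``11`` homokaryotes only
    (inside the block when given). Reports whether a 3-cluster split
    passes the same BIC + separation score used for axis selection, and
    per-sample sub-karyotype labels ``11 / 12 / 22`` when it does.
    """
    ones = calls.loc[calls["genotype"] == "11", "sample"].tolist()
    if len(ones) < 6:
        return {"status": "insufficient data", "detected": False, "n": len(ones)}
    sub = gm.take_samples(ones)
    sub = sub.region(chrom, *(block if block else (None, None)))
    try:
        res = GenotypePCA(n_axes=2).fit_transform(sub)
    except ValueError:
        return {"status": "insufficient data", "detected": False, "n": len(ones)}
    for axis in range(res.shape[1]):
        x = res[:, axis]
        part = _fit_partition(x, het=None, min_separation=min_separation, seed=seed)
        if part is None:
            continue
        lab = part.labels(x)
        names = np.array(["11", "12", "22"])
        return {
            "status": "ok", "detected": True, "axis": axis, "n": len(ones),
            "calls": pd.DataFrame({"sample": ones, "sub_genotype": names[lab]}),
        }
    return {"status": "ok", "detected": False, "n": len(ones)}


def subset_window_flags(stat_table: pd.DataFrame, chrom: str):
    """Helper: (window frame, q95 boolean) for one chromosome."""
    sub = stat_table[stat_table["chrom"] == chrom].reset_index(drop=True)
    return sub, sub["flag"].isin(["q95", "q99"]).to_numpy()


def sv_scan(gm: GenotypeMatrix, profiles: pd.DataFrame, flagged_tables: dict,
            sv_chroms: list[str], posterior: float = 0.90, max_gap: int = 2,
            use_local_pca: bool = True, seed: int = 0) -> dict:
    """Karyotype every flagged chromosome.

    ``flagged_tables`` maps comparison name -> flagged window table; a
    chromosome's window evidence is the union of q95 flags across
    comparisons. Returns per-chromosome calls, polarization records,
    block spans and frequency tables.
    """
    out = {}
    het_cache = {}
    for chrom in sv_chroms:
        if chrom not in het_cache:
            het_cache[chrom] = individual_het(gm, chrom)
        res = chrom_pca(gm, chrom)
        axis = select_sv_axis(res, het_cache[chrom], seed=seed)
        entry = {"chrom": chrom, "axis": axis}
        if axis is None:
            entry["status"] = "no axis"
            out[chrom] = entry
            continue
        calls = genotype_karyotypes(res, axis, threshold=posterior,
                                    het_by_sample=het_cache[chrom], seed=seed)
        calls, pol = polarize(calls, profiles)
        union_tab, union_flags = None, None
        for tab in flagged_tables.values():
            wtab, fl = subset_window_flags(tab, chrom)
            if union_flags is None:
                union_tab, union_flags = wtab, fl
            else:
                union_flags = union_flags | fl
        lf = local_pca(gm, chrom, seed=seed) if use_local_pca else None
        blocks = delimit_blocks(union_tab, union_flags, local_field=lf, max_gap=max_gap)
        block = max(blocks, key=lambda b: b[1] - b[0]) if blocks else None
        entry.update(
            status="ok", calls=calls, polarization=pol, blocks=blocks, block=block,
            freq_table=freq_tables(calls, profiles),
            third_haplotype=third_haplotype_scan(gm, calls, chrom, block=block, seed=seed),
        )
        out[chrom] = entry
    return out
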