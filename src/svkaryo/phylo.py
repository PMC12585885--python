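"""Allele-sharing distance matrices and neighbour-joining trees.

Distances between individuals are mean per-site genotype differences
(|dosage_i - dosage_j| / 2 over pairwise-complete sites), computed
directly from dosages — equivalent, on homozygote-only subsets of
biallelic SNPs, to distances obtained through a sequence alignment,
while assigning heterozygotes a half-difference per differing allele.
These distances can violate the triangle inequality; NJ does not care.

NJ is the Saitou-Nei algorithm with the standard Q criterion,
deterministic tie-breaking (lowest index pair) and non-negative branch
lengths (a negative pendant length is zeroed and transferred to its
sister so path lengths are conserved). Trees are dendropy objects, so
Newick round-trips and rerooting come for free; the two rooting rules
are rooting on the branch separating two karyotype groups (midpoint of
the separating edge) and outgroup rooting on a named sample.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

log = logging.getLogger(__name__)


def diff_matrix(gm: GenotypeMatrix, samples=None, chrom: str | None = None,
                start: int | None = None, end: int | None = None) -> pd.DataFrame:
    """Pairwise allele-sharing distance matrix.

    d(i, j) = mean over pairwise-complete sites of |dosage_i - dosage_j| / 2.
    """
    sub = gm if chrom is None else gm.region(chrom, start, end)
    if samples is not None:
        sub = sub.take_samples(samples)
    if sub.n_sites == 0:
        raise ValueError("empty region")
    X = sub.dosage.astype(float)
    X[X < 0] = np.nan
    n = sub.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X - X[i]) / 2.0
        cnt = np.sum(~np.isnan(diff), axis=1)
        with np.errstate(invalid="ignore"):
            D[i] = np.where(cnt > 0, np.nansum(diff, axis=1) / np.maximum(cnt, 1), np.nan)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=sub.samples, columns=sub.samples)


def nj(dist: pd.DataFrame) -> dendropy.Tree:
    """Neighbour joining with deterministic tie-breaks.

    Ties in the Q criterion resolve to the lowest (row, column) index
    pair; negative branch lengths are zeroed with the deficit moved to
    the sister branch. Returns an unrooted dendropy tree (trifurcating
    seed node).
    """
    taxa = list(dist.index)
    if len(taxa) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    D = dist.to_numpy().astype(float).copy()
    labels = [f"__leaf__{i}" for i in range(len(taxa))]
    newicks = {lab: _escape(t) for lab, t in zip(labels, taxa)}
    active = list(range(len(taxa)))
    node_of = {i: labels[i] for i in active}
    next_id = len(taxa)

    while len(active) > 2:
        r = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        fi, fj = np.unravel_index(np.argmin(Q), Q.shape)  # first = lexicographic min
        if fi > fj:
            fi, fj = fj, fi
        i, j = idx[fi], idx[fj]
        dij = D[i, j]
        li = 0.5 * dij + (R[fi] - R[fj]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += -li  # conserve the path length through the new node
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        u = next_id
        next_id += 1
        newick_u = f"({newicks[node_of[i]]}:{li:.12g},{newicks[node_of[j]]}:{lj:.12g})"
        newicks[f"__node__{u}"] = newick_u
        node_of[u] = f"__node__{u}"
        # distances from the new node
        duk = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[u, : u] = duk[:u]
        D[: u, u] = duk[:u]
        D[u, u] = 0.0
        active = [a for a in active if a not in (i, j)] + [u]

    a, b = active
    dab = max(D[a, b], 0.0)
    tree_str = f"({newicks[node_of[a]]}:{dab / 2:.12g},{newicks[node_of[b]]}:{dab / 2:.12g});"
    tree = dendropy.Tree.get(data=tree_str, schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    return tree


def _escape(name: str) -> str:
    if any(ch in name for ch in " ()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def read_newick(path_or_str) -> dendropy.Tree:
    import os

    if isinstance(path_or_str, str) and not os.path.exists(path_or_str):
        return dendropy.Tree.get(data=path_or_str, schema="newick", preserve_underscores=True)
    return dendropy.Tree.get(path=str(path_or_str), schema="newick", preserve_underscores=True)


def subset_homokaryotes(gm: GenotypeMatrix, calls: pd.DataFrame) -> list[str]:
    """Samples homozygous at the SV: karyotypes 00, 11 or 22 only.

    Heterokaryotes (01, 12) and unassigned samples are dropped; an empty
    result triggers a warning.
    """
    keep = calls.loc[calls["genotype"].isin(["00", "11", "22"]), "sample"].tolist()
    keep = [s for s in keep if s in set(gm.samples)]
    if not keep:
        log.warning("subset_homokaryotes: no homokaryote samples retained")
    return keep


def _leafset(edge) -> frozenset:
    return frozenset(lf.taxon.label for lf in edge.head_node.leaf_iter())


def root_between_groups(tree: dendropy.Tree, groupA, groupB) -> dendropy.Tree:
    """Root on the branch separating two tip groups, at its midpoint.

    Raises when no single edge bipartitions the tips into exactly
    (groupA, groupB); the error names the minimal set of conflicting tips.
    """
    A, B = frozenset(groupA), frozenset(groupB)
    if A & B:
        raise ValueError("groups overlap")
    tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    if A | B != tips:
        raise ValueError("groups must cover all tips")
    t = tree.clone(depth=1)
    best, best_conflict = None, None
    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node:
            continue
        below = _leafset(edge)
        if below == A or below == B:
            best = edge
            break
        conf = min(len(below ^ A), len(below ^ B))
        if best_conflict is None or conf < best_conflict[0]:
            best_conflict = (conf, sorted(below ^ A if len(below ^ A) < len(below ^ B) else below ^ B))
    if best is None:
        raise ValueError(
            f"groups not separable by any edge; minimal conflicting tips: {best_conflict[1]}"
        )
    half = (best.length or 0.0) / 2.0
    t.reroot_at_edge(best, length1=half, length2=half, update_bipartitions=True)
    t.is_rooted = True
    return t


def root_on_tip(tree: dendropy.Tree, tip_name: str) -> dendropy.Tree:
    """Outgroup rooting: root at the midpoint of a named tip's branch."""
    t = tree.clone(depth=1)
    node = None
    for lf in t.leaf_node_iter():
        if lf.taxon.label == tip_name:
            node = lf
            break
    if node is None:
        raise ValueError(f"tip {tip_name!r} not in tree")
    half = (node.edge.length or 0.0) / 2.0
    t.reroot_at_edge(node.edge, length1=half, length2=half, update_bipartitions=True)
    t.is_rooted = True
    return t


def _depths(tree: dendropy.Tree) -> dict:
    d = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            d[nd] = 0.0
        else:
            d[nd] = d[nd.parent_node] + (nd.edge.length or 0.0)
    return d


def branch_summary(tree: dendropy.Tree, group_labels: dict) -> dict:
    """Divergence summary between two tip groups.

    Reports the stem length between the two group MRCAs, each group's
    mean MRCA-to-tip depth, and the ratio of mean between-group to mean
    within-group tip-pair patristic distance (near 1 for well-mixed
    recombining regions, large for divergent non-recombining haplotypes).
    """
    groups = sorted(set(group_labels.values()))
    if len(groups) != 2:
        raise ValueError("need exactly 2 groups")
    t = tree.clone(depth=1)
    t.is_rooted = True  # treat the seed node as root for MRCA arithmetic
    depths = _depths(t)
    tipnode = {lf.taxon.label: lf for lf in t.leaf_node_iter()}
    members = {g: [s for s, gg in group_labels.items() if gg == g and s in tipnode] for g in groups}
    mrcas = {}
    for g in groups:
        taxa = [tipnode[s].taxon for s in members[g]]
        mrcas[g] = t.mrca(taxa=taxa) if len(taxa) > 1 else tipnode[members[g][0]]

    def node_dist(u, v):
        anc_u = set()
        x = u
        while x is not None:
            anc_u.add(x)
            x = x.parent_node
        x = v
        while x not in anc_u:
            x = x.parent_node
        return depths[u] + depths[v] - 2 * depths[x]

    stem = node_dist(mrcas[groups[0]], mrcas[groups[1]])
    within_depth = {
        g: float(np.mean([depths[tipnode[s]] - depths[mrcas[g]] for s in members[g]]))
        for g in groups
    }

    pdm = {}
    for s in group_labels:
        if s in tipnode:
            pdm[s] = tipnode[s]
    names = list(pdm)
    within, between = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = node_dist(pdm[names[i]], pdm[names[j]])
            if group_labels[names[i]] == group_labels[names[j]]:
                within.append(d)
            else:
                between.append(d)
    mean_within = float(np.mean(within)) if within else float("nan")
    mean_between = float(np.mean(between)) if between else float("nan")
    ratio = mean_between / mean_within if within and mean_within > 0 else float("inf")
    return {
        "stem_length": float(stem),
        "mean_within_depth": within_depth,
        "mean_within_pair": mean_within,
        "mean_between_pair": mean_between,
        "between_within_ratio": float(ratio),
    }
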