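"""Alpha/beta diversity, ordination and permutation testing on CMU profiles.

Weighted UniFrac distances are computed through scikit-bio; because the
branch weights are per-sample abundance *fractions*, absolute (CMU) and
relative input give identical distances.  PCoA is classical metric scaling
(Gower double-centering + eigendecomposition); axes from negative
eigenvalues of non-Euclidean matrices are dropped from the coordinates but
kept in the eigenvalue list.  PERMANOVA is Anderson's one-way distance-based
pseudo-F with an explicit permutation seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .errors import DesignError, MappingError, UndefinedDiversityError
from .quantification import CmuProfile


def _as_abundance_map(profile) -> Mapping[str, float]:
    if isinstance(profile, CmuProfile):
        return profile.cmus
    return dict(profile)


def observed_richness(cmu, detection_threshold: float = 0.0) -> int:
    """Number of taxa with abundance strictly above the detection threshold."""
    if detection_threshold < 0:
        raise ValueError("detection threshold must be >= 0")
    values = _as_abundance_map(cmu).values()
    return int(sum(1 for v in values if v > detection_threshold))


def shannon_weaver(cmu) -> float:
    """Shannon–Weaver diversity H = -sum p_i ln p_i, in nats.

    Proportions are the taxon's share of the profile total; zero-abundance
    taxa contribute nothing.  Undefined (raises) for an all-zero profile.
    """
    values = np.array(list(_as_abundance_map(cmu).values()), dtype=float)
    values = values[values > 0]
    if values.size == 0:
        raise UndefinedDiversityError(
            "Shannon diversity is undefined for an all-zero profile"
        )
    p = values / values.sum()
    p = p[p > 0]  # normalisation can underflow subnormal abundances to zero
    return float(-(p * np.log(p)).sum())


def _tree_tip_names(tree: TreeNode) -> set[str]:
    return {tip.name for tip in tree.tips()}


def _branch_profile_matrix(tree: TreeNode, taxa: Sequence[str]):
    """Branch lengths and the branch x taxon descent-indicator matrix.

    Row b of the matrix marks which taxa sit below branch b, so matrix @ p
    gives the fraction of a sample's total abundance descending each branch.
    Tree tips outside ``taxa`` contribute empty rows and never any distance.
    """
    column = {t: i for i, t in enumerate(taxa)}
    lengths = []
    rows = []
    membership: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            row = np.zeros(len(taxa))
            if node.name in column:
                row[column[node.name]] = 1.0
        else:
            row = np.zeros(len(taxa))
            for child in node.children:
                row += membership[id(child)]
        membership[id(node)] = row
        if node.parent is not None:  # the root carries no branch
            lengths.append(float(node.length or 0.0))
            rows.append(row)
    return np.asarray(lengths), np.asarray(rows)


def weighted_unifrac(
    tree: TreeNode, a, b, normalized: bool = True
) -> float:
    """Weighted UniFrac distance between two abundance profiles.

    Raw form: sum over branches of branch length times the absolute
    difference of the fractions of each sample's total abundance descending
    from the branch.  The normalized form divides by the abundance-weighted
    root-to-tip depth sum, bounding the distance by 1.  Because fractions
    are per-sample, absolute and relative abundances give the same distance.
    """
    a = _as_abundance_map(a)
    b = _as_abundance_map(b)
    taxa = sorted(set(a) | set(b))
    nonzero = [t for t in taxa if a.get(t, 0) > 0 or b.get(t, 0) > 0]
    if not nonzero:
        raise UndefinedDiversityError(
            "weighted UniFrac is undefined when both profiles are empty"
        )
    missing = sorted(set(nonzero) - _tree_tip_names(tree))
    if missing:
        raise MappingError(
            f"taxa absent from the tree: {missing}", taxa=missing
        )
    lengths, branches = _branch_profile_matrix(tree, nonzero)
    u = np.array([float(a.get(t, 0.0)) for t in nonzero])
    v = np.array([float(b.get(t, 0.0)) for t in nonzero])
    p_u = branches @ (u / u.sum()) if u.sum() > 0 else np.zeros(len(lengths))
    p_v = branches @ (v / v.sum()) if v.sum() > 0 else np.zeros(len(lengths))
    raw = float(lengths @ np.abs(p_u - p_v))
    if not normalized:
        return raw
    denom = float(lengths @ (p_u + p_v))
    return raw / denom if denom > 0 else 0.0


def unifrac_distance_matrix(
    tree: TreeNode, table: pd.DataFrame, normalized: bool = True
) -> DistanceMatrix:
    """Pairwise weighted UniFrac over a samples x taxa abundance table."""
    taxa = [str(t) for t in table.columns]
    missing = sorted(set(taxa) - _tree_tip_names(tree))
    if missing:
        raise MappingError(f"taxa absent from the tree: {missing}", taxa=missing)
    lengths, branches = _branch_profile_matrix(tree, taxa)
    values = table.to_numpy(dtype=float)
    totals = values.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise UndefinedDiversityError("every sample needs positive total abundance")
    fractions = (values / totals) @ branches.T  # samples x branches
    n = len(table)
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(fractions[i] - fractions[i + 1 :])
        raw = diff @ lengths
        if normalized:
            denom = (fractions[i] + fractions[i + 1 :]) @ lengths
            raw = np.where(denom > 0, raw / np.where(denom > 0, denom, 1.0), 0.0)
        out[i, i + 1 :] = raw
        out[i + 1 :, i] = raw
    return DistanceMatrix(out, ids=[str(s) for s in table.index])


@dataclass(frozen=True)
class Ordination:
    """PCoA embedding: sample coordinates, eigenvalues, variance explained."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis, over positive eigenvalues


def _as_distance_matrix(d) -> DistanceMatrix:
    if isinstance(d, DistanceMatrix):
        return d
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return DistanceMatrix(arr, ids=[str(i) for i in range(arr.shape[0])])


def pcoa(d, k: int | None = None) -> Ordination:
    """Principal coordinate analysis (classical metric scaling).

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square roots of the positive eigenvalues.  For a Euclidean-embeddable
    matrix the embedded pairwise distances reproduce the input.  Negative
    eigenvalues (non-Euclidean input) yield no coordinates but stay in
    ``eigenvalues``; ``proportion_explained`` is taken over the positive
    eigenvalues only.
    """
    dm = _as_distance_matrix(d)
    n = dm.shape[0]
    if k is not None and not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    d2 = dm.data**2
    centerer = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * centerer @ d2 @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(1e-12, 1e-12 * abs(eigvals[0])) if n else 0.0
    positive = eigvals > tol
    pos_vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)
    n_axes = coords.shape[1] if k is None else min(k, coords.shape[1])
    pos_sum = pos_vals.sum()
    proportion = (
        pos_vals[:n_axes] / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    )
    coordinates = pd.DataFrame(
        coords[:, :n_axes],
        index=list(dm.ids),
        columns=[f"PC{i + 1}" for i in range(n_axes)],
    )
    return Ordination(
        coordinates=coordinates,
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


def permanova(
    d, labels: Sequence, n_perm: int = 999, seed: int | None = None
) -> PermanovaResult:
    """One-way PERMANOVA: permutation test of a grouping on a distance matrix.

    The pseudo-F statistic partitions the total sum of squared distances
    into among- and within-group components; the p-value is
    (1 + #{permuted F >= observed F}) / (1 + n_perm), with label permutations
    drawn from ``numpy.random.default_rng(seed)``.
    """
    dm = _as_distance_matrix(d)
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != dm.shape[0]:
        raise ValueError("one group label per sample is required")
    if n_perm < 99:
        raise ValueError("at least 99 permutations are required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise DesignError("PERMANOVA needs at least two groups")
    if counts.min() < 2:
        raise DesignError("every group needs at least two samples")

    d2 = dm.data**2
    n = len(labels)
    a = len(uniq)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    group_indices = [np.flatnonzero(labels == g) for g in uniq]

    def pseudo_f(indices_by_group):
        ss_within = 0.0
        for idx in indices_by_group:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(group_indices)
    rng = np.random.default_rng(seed)
    sizes = [len(idx) for idx in group_indices]
    bounds = np.cumsum(sizes)[:-1]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if pseudo_f(np.split(perm, bounds)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        n_samples=n,
        n_groups=a,
    )
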