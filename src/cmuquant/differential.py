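"""Group-wise and paired differential abundance on log10 CMUs.

Species are compared between groups (e.g. naturally healthy vs. moderate
gingivitis at baseline) with unpaired two-sample Wilcoxon rank-sum tests on
log10-transformed absolute abundances; no multiplicity adjustment is applied
by default (per-species reporting at p < 0.05), with an optional
Benjamini–Hochberg column.  Longitudinal product effects are summarised as
within-subject changes from baseline, averaged over subjects per visit.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classification import ClassificationTable
from .errors import DesignError, PairingError
from .quantification import log10_cmu

#: Largest per-group size at which the exact null distribution is enumerated
#: in ``auto`` mode (ties force the normal approximation).
EXACT_SIZE_LIMIT = 10


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided two-sample Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the sum of the mid-ranks of ``x`` within
    the pooled sample.  ``mode``:

    - ``exact``: exact enumeration of the rank-sum null distribution
      (appropriate for tie-free data);
    - ``normal_approx``: normal approximation with tie correction and
      continuity correction;
    - ``auto``: exact when min(len(x), len(y)) <= 10 and the pooled data are
      tie-free, otherwise the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if mode == "auto":
        mode = (
            "exact"
            if min(x.size, y.size) <= EXACT_SIZE_LIMIT and not has_ties
            else "normal_approx"
        )
    if mode not in ("exact", "normal_approx"):
        raise ValueError(f"unknown mode '{mode}'")

    if mode == "exact":
        # full enumeration of group assignments (mid-ranks, so ties are
        # handled naturally); falls back to seeded resampling only beyond
        # C(n1+n2, n1) = 500k, far past the exact-mode size range
        method = stats.PermutationMethod(n_resamples=500_000, rng=0)
    else:
        method = "asymptotic"
    result = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    # mannwhitneyu reports U of x; the rank-sum W = U + n1(n1+1)/2
    w = float(result.statistic + x.size * (x.size + 1) / 2)
    return w, float(min(1.0, result.pvalue))


def compare_groups(
    cmu_table: pd.DataFrame,
    group_labels: Mapping[str, str] | pd.Series,
    classification: ClassificationTable,
    log_floor: float = 1.0,
    group_order: tuple[str, str] | None = None,
    adjust: bool = False,
    mode: str = "auto",
) -> pd.DataFrame:
    """Per-species two-group comparison of mean log10 CMUs.

    ``cmu_table`` is samples x taxa; only taxa classified as oral are
    compared.  Each row reports the two group means of log10 CMUs, their
    difference (group2 - group1), and the rank-sum p-value; ``adjust`` adds
    a Benjamini–Hochberg ``q`` column (off by default, matching unadjusted
    per-species reporting).
    """
    labels = pd.Series(group_labels).astype(str)
    labels = labels.reindex([str(s) for s in cmu_table.index])
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    groups = list(pd.unique(labels))
    if group_order is not None:
        if set(group_order) != set(groups):
            raise ValueError(f"group_order {group_order} does not match {groups}")
        groups = list(group_order)
    if len(groups) != 2:
        raise DesignError(f"exactly two groups are required, got {groups}")
    g1, g2 = groups
    idx1 = labels[labels == g1].index
    idx2 = labels[labels == g2].index
    if len(idx1) < 2 or len(idx2) < 2:
        raise DesignError("each group needs at least two samples")

    oral = classification.oral_taxa()
    taxa = [t for t in cmu_table.columns if t in oral]
    log_table = cmu_table.map(lambda v: log10_cmu(v, log_floor))

    rows = []
    for taxon in taxa:
        v1 = log_table.loc[idx1, taxon].to_numpy()
        v2 = log_table.loc[idx2, taxon].to_numpy()
        _, p = wilcoxon_rank_sum(v1, v2, mode=mode)
        record = classification.records[taxon]
        rows.append(
            {
                "taxon": taxon,
                "category": ";".join(sorted(record.categories)),
                f"mean_{g1}": float(v1.mean()),
                f"mean_{g2}": float(v2.mean()),
                "diff": float(v2.mean() - v1.mean()),
                "p": p,
                "n1": len(v1),
                "n2": len(v2),
            }
        )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def group_mean_difference(mean_g1: float, mean_g2: float) -> float:
    """Difference of group means, group2 - group1 (the tables' convention)."""
    return mean_g2 - mean_g1


def paired_baseline_change(
    cmu_table: pd.DataFrame,
    subject_map: Mapping[str, str] | pd.Series,
    visit_labels: Mapping[str, str] | pd.Series,
    baseline: str = "baseline",
    log_floor: float = 1.0,
) -> pd.DataFrame:
    """Mean within-subject change from baseline in log10 CMU, per visit.

    For every post-baseline visit t and species, computes
    delta = log10 CMU(t) - log10 CMU(baseline) per subject and averages over
    the subjects observed at that visit; subjects missing a visit are simply
    excluded from its mean.  Returns a long DataFrame with columns
    (taxon, visit, mean_delta, n_subjects).  A post-baseline sample whose
    subject has no baseline sample raises ``PairingError``.
    """
    subjects = pd.Series(subject_map).astype(str)
    visits = pd.Series(visit_labels).astype(str)
    sample_ids = [str(s) for s in cmu_table.index]
    subjects = subjects.reindex(sample_ids)
    visits = visits.reindex(sample_ids)
    if subjects.isna().any() or visits.isna().any():
        raise ValueError("every sample needs a subject and a visit label")

    log_table = cmu_table.map(lambda v: log10_cmu(v, log_floor))
    log_table.index = sample_ids

    baseline_sample = {}
    for sample, visit in visits.items():
        if visit == baseline:
            baseline_sample[subjects[sample]] = sample

    records = []
    post_visits = [v for v in pd.unique(visits) if v != baseline]
    for visit in post_visits:
        visit_samples = visits[visits == visit].index
        deltas = []
        for sample in visit_samples:
            subject = subjects[sample]
            if subject not in baseline_sample:
                raise PairingError(
                    f"subject '{subject}' has a sample at visit '{visit}' "
                    "but no baseline sample"
                )
            deltas.append(
                log_table.loc[sample] - log_table.loc[baseline_sample[subject]]
            )
        if not deltas:
            continue
        delta_frame = pd.DataFrame(deltas)
        means = delta_frame.mean(axis=0)
        for taxon, mean_delta in means.items():
            records.append(
                {
                    "taxon": taxon,
                    "visit": visit,
                    "mean_delta": float(mean_delta),
                    "n_subjects": len(delta_frame),
                }
            )
    return pd.DataFrame(records)
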