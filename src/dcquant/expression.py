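"""Custom microarray background/detection/differential-expression chain.

Re-implements the array screening procedure used to rank cross-presentation
genes between mutant and wild-type spleens: assuming at most 80% of genes
are expressed on any array, the lowest 20% of probe intensities per array
are tagged as background; the per-array detection threshold is the tagged
set's mean plus two standard deviations; a probe enters the analysis when
it exceeds the threshold in at least 80% of the animals of at least one
group; differential expression is a two-sided Student's t-test filtered at
raw p <= 5% (no multiple-testing correction — FDR can be reported
alongside but never filters); samples are clustered by average-linkage
(UPGMA) agglomeration on 1 - Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DomainError, ExpressionMatrix

__all__ = [
    "tag_background",
    "detection_thresholds",
    "detection_filter",
    "DetectionResult",
    "detect",
    "differential_expression",
    "cluster_samples",
    "Dendrogram",
    "expression_report",
]

BACKGROUND_FRACTION = 0.20
DETECTION_SD_MULTIPLIER = 2.0
MIN_GROUP_FRACTION = 0.80
DEFAULT_ALPHA = 0.05


def tag_background(m: ExpressionMatrix, fraction: float = BACKGROUND_FRACTION) -> pd.DataFrame:
    """Tag the lowest-intensity probes of each array as background.

    Exactly ``floor(fraction * n_probes)`` probes are tagged per sample —
    those with the lowest intensities under a stable rank, ties broken by
    probe order in the matrix (i.e. probe-id order for sorted input).
    """
    if not (0 < fraction < 1):
        raise DomainError("fraction must be in (0, 1)")
    n_probes = m.values.shape[0]
    if n_probes < 5:
        raise DomainError("need >= 5 probes")
    n_tag = int(np.floor(fraction * n_probes))
    mask = pd.DataFrame(
        False, index=m.values.index, columns=m.values.columns
    )
    for s in m.values.columns:
        order = np.argsort(m.values[s].to_numpy(), kind="stable")
        mask.iloc[order[:n_tag], mask.columns.get_loc(s)] = True
    return mask


def detection_thresholds(
    m: ExpressionMatrix, background_mask: pd.DataFrame, ddof: int = 1
) -> pd.Series:
    """Per-array detection threshold: mean + 2*SD of the tagged background.

    SD uses the n-1 (sample) denominator by default; ``ddof=0`` selects the
    population form.
    """
    thresholds = {}
    for s in m.values.columns:
        bg = m.values[s].to_numpy()[background_mask[s].to_numpy()]
        if bg.size < 2:
            raise DomainError(f"sample {s!r}: fewer than 2 background-tagged probes")
        thresholds[s] = float(bg.mean() + DETECTION_SD_MULTIPLIER * bg.std(ddof=ddof))
    return pd.Series(thresholds, name="threshold")


def detection_filter(
    m: ExpressionMatrix,
    thresholds: pd.Series,
    min_fraction: float = MIN_GROUP_FRACTION,
) -> list:
    """Probes retained by the group-wise detection rule.

    A probe is retained iff, in at least one group, the fraction of that
    group's samples whose intensity strictly exceeds the per-sample
    threshold is >= ``min_fraction``.
    """
    missing = set(m.values.columns) - set(thresholds.index)
    if missing:
        raise DomainError(f"thresholds missing for samples: {sorted(missing)}")
    above = m.values.gt(thresholds[m.values.columns], axis=1)
    keep = pd.Series(False, index=m.values.index)
    for g in m.group_labels:
        cols = m.samples_in(g)
        keep |= above[cols].mean(axis=1) >= min_fraction
    return list(m.values.index[keep])


@dataclass
class DetectionResult:
    """Background tagging + thresholding + group-rule output bundle."""

    background_mask: pd.DataFrame
    thresholds: pd.Series
    retained_probes: list


def detect(
    m: ExpressionMatrix,
    fraction: float = BACKGROUND_FRACTION,
    min_fraction: float = MIN_GROUP_FRACTION,
    ddof: int = 1,
) -> DetectionResult:
    """Run the full background-tagging -> threshold -> group-rule chain."""
    mask = tag_background(m, fraction)
    thr = detection_thresholds(m, mask, ddof=ddof)
    retained = detection_filter(m, thr, min_fraction)
    return DetectionResult(background_mask=mask, thresholds=thr, retained_probes=retained)


def differential_expression(
    m: ExpressionMatrix,
    retained: list,
    alpha: float = DEFAULT_ALPHA,
    test: str = "pooled",
) -> pd.DataFrame:
    """Per-probe two-sided t-test between the two groups, filtered at p <= alpha.

    ``test="pooled"`` is the Student's t with pooled variance
    (df = n1 + n2 - 2); ``test="welch"`` the unequal-variance variant.
    Fold change is mean(group2)/mean(group1) on the linear intensity scale.
    Probes with zero pooled variance are excluded with a warning (p is
    undefined for them). Returns the table of retained-and-significant
    probes sorted by p.
    """
    if test not in ("pooled", "welch"):
        raise DomainError(f"unknown test {test!r}; expected 'pooled' or 'welch'")
    if not retained:
        raise DomainError("retained probe set is empty")
    g1, g2 = m.group_labels
    x = m.values.loc[retained, m.samples_in(g1)].to_numpy(float)
    y = m.values.loc[retained, m.samples_in(g2)].to_numpy(float)
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)

    if test == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        zero = sp2 == 0
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full(m1.shape, float(n1 + n2 - 2))
    else:
        se2 = v1 / n1 + v2 / n2
        zero = se2 == 0
        se = np.sqrt(se2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} probe(s) with zero variance in both groups "
            "excluded (t undefined)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        fold = m2 / m1
    table = pd.DataFrame(
        {
            "probe_id": retained,
            "t_statistic": t,
            "p_value": p,
            "fold_change": fold,
            "direction": np.where(fold > 1, "up", "down"),
        }
    )
    table = table[~zero]
    table = table[table["p_value"] <= alpha]
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)


@dataclass
class Dendrogram:
    """Average-linkage merge sequence over samples.

    ``merges`` lists (label_a, label_b, height, merged_size) in merge
    order, labels being the lexicographically smallest member of each
    cluster; ``newick`` serializes the tree with branch lengths equal to
    the difference between parent and child merge heights.
    """

    merges: list = field(default_factory=list)
    newick: str = ""


def _spearman_distance(values: pd.DataFrame) -> np.ndarray:
    for s in values.columns:
        if np.ptp(values[s].to_numpy(float)) == 0:
            raise DomainError(f"sample {s!r} is constant; Spearman undefined")
    rho = stats.spearmanr(values.to_numpy(float)).statistic
    rho = np.atleast_2d(rho)
    return 1.0 - rho


def cluster_samples(
    m: ExpressionMatrix, probe_subset: list | None = None
) -> Dendrogram:
    """UPGMA clustering of samples on 1 - Spearman correlation distance.

    Agglomerative merging with unweighted average linkage: after merging
    clusters i and j, the distance from any cluster k to the union is the
    size-weighted mean (n_i*d_ki + n_j*d_kj)/(n_i + n_j), i.e. the mean of
    all original pairwise distances. Among equal-minimum candidate pairs
    the lexicographically smallest (label_a, label_b) pair merges first, so
    the merge sequence is deterministic.
    """
    values = m.values if probe_subset is None else m.values.loc[probe_subset]
    if values.shape[1] < 3:
        raise DomainError("need >= 3 samples to cluster")
    if values.shape[0] < 3:
        raise DomainError("need >= 3 probes to cluster on")
    dist = _spearman_distance(values)
    samples = list(values.columns)

    # cluster state: label -> (size, newick subtree, height)
    clusters = {s: (1, s, 0.0) for s in samples}
    index = {s: i for i, s in enumerate(samples)}  # row in the distance matrix
    d = dist.copy().astype(float)
    np.fill_diagonal(d, np.inf)
    active = list(samples)
    merges = []
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                la, lb = active[ai], active[bi]
                pair = tuple(sorted((la, lb)))
                dij = d[index[la], index[lb]]
                if best is None or dij < best[0] - 1e-15 or (
                    abs(dij - best[0]) <= 1e-15 and pair < best[1]
                ):
                    best = (dij, pair)
        height, (la, lb) = best
        na, nwa, ha = clusters[la]
        nb, nwb, hb = clusters[lb]
        blen_a = height - ha
        blen_b = height - hb
        newick = f"({nwa}:{blen_a:.10g},{nwb}:{blen_b:.10g})"
        size = na + nb
        merges.append((la, lb, float(height), size))

        ia, ib = index[la], index[lb]
        for lk in active:
            if lk in (la, lb):
                continue
            ik = index[lk]
            dk = (na * d[ik, ia] + nb * d[ik, ib]) / size
            d[ik, ia] = d[ia, ik] = dk
        d[ib, :] = d[:, ib] = np.inf
        clusters[la] = (size, newick, float(height))
        del clusters[lb]
        active.remove(lb)
    root_label = active[0]
    newick = clusters[root_label][1] + ";"
    return Dendrogram(merges=merges, newick=newick)


def expression_report(
    m: ExpressionMatrix, detection: DetectionResult, de: pd.DataFrame
) -> dict:
    """Summary tables: per-probe absolute mean differences and relative
    fold changes (direction-annotated) over the retained probes, plus the
    significant-probe table. Probes with equal group means are excluded
    from the ranked lists (no direction, nothing to rank)."""
    g1, g2 = m.group_labels
    retained = detection.retained_probes
    m1 = m.values.loc[retained, m.samples_in(g1)].mean(axis=1)
    m2 = m.values.loc[retained, m.samples_in(g2)].mean(axis=1)
    diff = m2 - m1
    fold = m2 / m1
    table = pd.DataFrame(
        {
            "probe_id": retained,
            f"mean_{g1}": m1.to_numpy(),
            f"mean_{g2}": m2.to_numpy(),
            "abs_difference": diff.to_numpy(),
            "fold_change": fold.to_numpy(),
            "direction": np.where(fold > 1, "up", "down"),
        }
    )
    ranked = table[table["abs_difference"] != 0]
    by_difference = ranked.reindex(
        ranked["abs_difference"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    log_fold = np.abs(np.log(ranked["fold_change"].to_numpy(float)))
    by_fold = ranked.iloc[np.argsort(-log_fold, kind="stable")].reset_index(drop=True)
    return {
        "n_retained": len(retained),
        "n_significant": len(de),
        "by_absolute_difference": by_difference,
        "by_fold_change": by_fold,
        "significant": de,
    }
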