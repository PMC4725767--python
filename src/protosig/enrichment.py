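"""Rank-based (1D) annotation enrichment.

For one subtype versus the rest, every protein receives a mean difference Δ.
A category (gene set, pathway) is called enriched when the Δ values of its
members are systematically shifted relative to the global Δ distribution.
The shift is tested with the Wilcoxon–Mann–Whitney rank-sum test and
summarized by the score

    s = 2 · (meanRank_in − (n + 1) / 2) / (n − n_in),

which is +1 when the members occupy exactly the ``n_in`` highest ranks and
−1 when they occupy the lowest — so a score near 1 marks enrichment for
high expression in the tested subtype and near −1 for low expression.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CategoryMap, ExpressionMatrix, ParameterError, SampleAnnotation

__all__ = [
    "mean_difference",
    "enrichment_score",
    "rank_shift_pvalue",
    "enrichment_1d",
    "hierarchy_enrichment",
]

#: largest n for which the two-sided p-value is computed by exhaustive
#: enumeration of member rank placements (C(12, 6) = 924 placements at most)
EXACT_ENUMERATION_MAX_N = 12


def mean_difference(
    matrix: ExpressionMatrix, annotation: SampleAnnotation, target_class
) -> pd.Series:
    """Per-protein Δ = mean(target class) − mean(all other classes).

    Uses observed values only; a protein with no observed value on either
    side receives NaN.
    """
    annotation.validate_against(matrix)
    in_mask = annotation.in_class_mask(matrix.sample_ids, target_class)
    if in_mask.sum() == 0 or (~in_mask).sum() == 0:
        raise ParameterError(f"class {target_class!r} leaves an empty side")
    X = matrix.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        m_in = np.nanmean(X[:, in_mask], axis=1)
        m_out = np.nanmean(X[:, ~in_mask], axis=1)
    return pd.Series(m_in - m_out, index=matrix.protein_ids, name=f"delta_{target_class}")


def enrichment_score(ranks_in: np.ndarray, n: int) -> float:
    """Range-normalized rank shift of a member set given all-protein ranks."""
    n_in = len(ranks_in)
    if not 0 < n_in < n:
        raise ParameterError("category must be a proper non-empty subset")
    return 2.0 * (np.mean(ranks_in) - (n + 1) / 2.0) / (n - n_in)


def rank_shift_pvalue(ranks: np.ndarray, member_idx: np.ndarray) -> float:
    """Two-sided p-value for the rank-sum shift of a member subset.

    For n ≤ ``EXACT_ENUMERATION_MAX_N`` the null distribution is obtained by
    exhaustive enumeration of all C(n, n_in) placements of the members over
    the realized rank multiset (which makes the test exact under ties);
    above that, a normal approximation with tie and continuity correction
    is used.
    """
    n = len(ranks)
    n_in = len(member_idx)
    r_obs = float(np.sum(ranks[member_idx]))
    expected = n_in * (n + 1) / 2.0  # average ranks preserve the rank total
    dev = abs(r_obs - expected)

    if n <= EXACT_ENUMERATION_MAX_N:
        total = comb(n, n_in)
        hits = sum(
            1
            for c in combinations(ranks, n_in)
            if abs(sum(c) - expected) >= dev - 1e-9
        )
        return hits / total

    n_out = n - n_in
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n_in * n_out / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values tied: no shift is detectable
        return 1.0
    z = (dev - 0.5) / np.sqrt(var)  # continuity correction toward the mean
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def enrichment_1d(
    values: pd.Series,
    categories: CategoryMap | dict,
    min_size: int = 5,
    fdr: float = 0.05,
    p_threshold: float | None = None,
) -> pd.DataFrame:
    """Test every category for a rank shift of its members' values.

    Parameters
    ----------
    values
        Per-protein real values (typically mean differences); NaN entries
        are dropped from the ranking.
    categories
        Category → member set mapping (a :class:`CategoryMap` or plain dict).
    min_size
        Categories with fewer members *with values* are skipped, as are
        categories covering every ranked protein.
    fdr
        Benjamini–Hochberg level applied across all tested categories.
    p_threshold
        Optional additional raw-p cutoff; when given, ``significant``
        additionally requires ``p_value < p_threshold``.

    Returns
    -------
    DataFrame with columns ``category, n_in, score_s, p_value, q_value,
    significant``, sorted by p-value.
    """
    member_map = categories.members if isinstance(categories, CategoryMap) else categories
    vals = values.dropna()
    if vals.nunique() < 2:
        raise ParameterError("need at least 2 distinct finite values to rank")
    n = len(vals)
    ranks = stats.rankdata(vals.to_numpy())  # ascending, average ties
    pos = {pid: i for i, pid in enumerate(vals.index)}

    rows = []
    for name, members in member_map.items():
        idx = np.array([pos[m] for m in members if m in pos], dtype=int)
        n_in = len(idx)
        if n_in < min_size or n_in == n:
            continue
        s = enrichment_score(ranks[idx], n)
        p = rank_shift_pvalue(ranks, idx)
        rows.append((name, n_in, s, p))

    if not rows:
        return pd.DataFrame(
            columns=["category", "n_in", "score_s", "p_value", "q_value", "significant"]
        )
    out = pd.DataFrame(rows, columns=["category", "n_in", "score_s", "p_value"])
    reject, qvals, _, _ = multipletests(out["p_value"], alpha=fdr, method="fdr_bh")
    out["q_value"] = np.minimum(qvals, 1.0)
    out["significant"] = reject
    if p_threshold is not None:
        out["significant"] &= out["p_value"] < p_threshold
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def hierarchy_enrichment(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    categories: CategoryMap,
    min_size: int = 5,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Two-level enrichment per class: leaf categories and their parents.

    For each class, per-protein mean differences are computed and
    :func:`enrichment_1d` is run once on the leaf categories and once on the
    parent categories (each protein contributes to every parent one of its
    leaves maps to, deduplicated).  The BH correction is applied
    independently per hierarchy level.  Categories without a parent link are
    tested at the leaf level and labelled ``none``.
    """
    if not categories.parents:
        raise ParameterError("hierarchy_enrichment requires parent links")
    orphans = [c for c in categories.members if c not in categories.parents]
    if orphans:
        warnings.warn(
            f"{len(orphans)} categor(ies) without a parent link are tested as "
            f"level 'none': {sorted(orphans)[:5]}..."
        )
    parent_map = categories.parent_members()

    frames = []
    for cls in annotation.classes:
        delta = mean_difference(matrix, annotation, cls)
        leaf = enrichment_1d(delta, categories.members, min_size=min_size, fdr=fdr)
        leaf["hierarchy_level"] = [
            "leaf" if c in categories.parents else "none" for c in leaf["category"]
        ]
        parent = enrichment_1d(delta, parent_map, min_size=min_size, fdr=fdr)
        parent["hierarchy_level"] = "parent"
        for frame in (leaf, parent):
            frame["class_label"] = cls
            frames.append(frame)
    cols = [
        "class_label",
        "category",
        "hierarchy_level",
        "n_in",
        "score_s",
        "p_value",
        "q_value",
        "significant",
    ]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]
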