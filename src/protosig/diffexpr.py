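"""Per-protein inferential statistics.

One-vs-rest two-sample t-tests (the feature-ranking statistic of the
classification framework), one-way ANOVA across all classes, and
permutation-based false-discovery-rate control in which the statistic
vector is recomputed under random relabelings of the samples with class
sizes preserved.
"""

from __future__ import annotations

import warnings
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ParameterError, SampleAnnotation

__all__ = ["ttest_ovr", "anova_f", "permutation_fdr"]

_TINY = np.finfo(float).tiny


def _ttest_arrays(X: np.ndarray, in_mask: np.ndarray, s0: float = 0.0):
    """Pooled-variance two-sample t over rows of X (NaN-aware).

    Returns (t, p, valid); rows need ≥ 2 observed values on each side.
    The sign of t is positive when the in-group mean is higher.
    """
    a, b = X[:, in_mask], X[:, ~in_mask]
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    valid = (n1 >= 2) & (n2 >= 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1, m2 = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
        v1, v2 = np.nanvar(a, ddof=1, axis=1), np.nanvar(b, ddof=1, axis=1)
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)) + s0
        t = (m1 - m2) / se
    # zero pooled variance: equal means -> t = 0; unequal -> infinite t
    degenerate = valid & (se == 0)
    t = np.where(degenerate & (m1 == m2), 0.0, t)
    t = np.where(degenerate & (m1 != m2), np.sign(m1 - m2) * np.inf, t)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p = np.clip(p, _TINY, 1.0)
    return t, p, valid


def _anova_arrays(X: np.ndarray, class_masks: list[np.ndarray]):
    """One-way fixed-effects F over rows of X (NaN-aware).

    Returns (F, p, valid); rows need ≥ 2 observed values in every class.
    Zero between- and within-variance is reported as F = 0, p = 1.
    """
    k = len(class_masks)
    counts, means, ssw = [], [], np.zeros(X.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for mask in class_masks:
            g = X[:, mask]
            n_g = np.sum(~np.isnan(g), axis=1)
            m_g = np.nanmean(g, axis=1)
            v_g = np.nanvar(g, ddof=1, axis=1)
            counts.append(n_g)
            means.append(m_g)
            ssw = ssw + np.where(n_g >= 2, (n_g - 1) * v_g, np.nan)
    counts = np.array(counts)  # k x P
    means = np.array(means)
    valid = np.all(counts >= 2, axis=0)
    N = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = np.nansum(counts * means, axis=0) / N
        ssb = np.nansum(counts * (means - grand) ** 2, axis=0)
    df1, df2 = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    F = np.where(valid & (ssw == 0) & (ssb <= 1e-300), 0.0, F)
    F = np.where(valid & (ssw == 0) & (ssb > 1e-300), np.inf, F)
    with np.errstate(invalid="ignore"):
        p = stats.f.sf(F, df1, np.maximum(df2, 1))
    p = np.where(F == 0, 1.0, p)
    p = np.clip(p, _TINY, 1.0)
    return F, p, valid


def ttest_ovr(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    target_class,
    s0: float = 0.0,
) -> pd.DataFrame:
    """Two-sided one-vs-rest t-test per protein.

    The sign of t is positive when the target class mean is higher.
    Proteins with fewer than 2 observed values on either side get NaN
    statistics (reported, not dropped).  ``s0`` is an optional
    variance-stabilizing offset added to the standard error.
    """
    annotation.validate_against(matrix)
    in_mask = annotation.in_class_mask(matrix.sample_ids, target_class)
    t, p, valid = _ttest_arrays(matrix.values, in_mask, s0=s0)
    return pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "statistic": np.where(valid, t, np.nan),
            "p_value": np.where(valid, p, np.nan),
        }
    )


def anova_f(matrix: ExpressionMatrix, annotation: SampleAnnotation) -> pd.DataFrame:
    """One-way ANOVA F and p per protein across all annotated classes."""
    annotation.validate_against(matrix)
    if len(annotation.classes) < 2:
        raise ParameterError("ANOVA requires at least 2 classes")
    masks = [annotation.in_class_mask(matrix.sample_ids, c) for c in annotation.classes]
    F, p, valid = _anova_arrays(matrix.values, masks)
    return pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "statistic": np.where(valid, F, np.nan),
            "p_value": np.where(valid, p, np.nan),
        }
    )


def _n_distinct_label_permutations(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    total = factorial(int(counts.sum()))
    for c in counts:
        total //= factorial(int(c))
    return total


def permutation_fdr(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    statistic: str = "anova_f",
    target_class=None,
    n_permutations: int = 250,
    level: float = 0.05,
    seed: int = 0,
    s0: float = 0.0,
) -> pd.DataFrame:
    """Permutation-based FDR for per-protein statistics.

    Observed statistics (F, or |t| for ``ttest_ovr``) are computed once.
    For each of ``n_permutations`` random relabelings of the samples (class
    sizes preserved) the full statistic vector is recomputed.  For a
    threshold c,

        FDR(c) = median over permutations of #{perm stats ≥ c}
                 / #{observed stats ≥ c},

    capped at 1, and each protein's q-value is the minimum of FDR(c) over
    thresholds c at or below its own statistic — non-increasing in the
    statistic by construction.  Comparisons use ≥ on both observed and
    permuted statistics.

    Returns protein_id, statistic, p_value, q_value, significant; proteins
    with insufficient data carry NaN statistic fields and are never
    significant.
    """
    if n_permutations < 25:
        raise ParameterError("n_permutations must be >= 25")
    annotation.validate_against(matrix)
    labels = annotation.labels.reindex(matrix.sample_ids).to_numpy()
    X = matrix.values

    def stat_vector(lab: np.ndarray):
        if statistic == "anova_f":
            masks = [lab == c for c in annotation.classes]
            F, p, valid = _anova_arrays(X, masks)
            return F, p, valid
        elif statistic == "ttest_ovr":
            if target_class is None:
                raise ParameterError("ttest_ovr statistic requires target_class")
            t, p, valid = _ttest_arrays(X, lab == target_class, s0=s0)
            return np.abs(t), p, valid
        raise ParameterError(f"unknown statistic: {statistic!r}")

    obs, p_obs, valid = stat_vector(labels)
    obs = np.where(valid, obs, np.nan)

    n_distinct = _n_distinct_label_permutations(labels)
    n_perm = n_permutations
    if n_distinct < n_permutations:
        warnings.warn(
            f"only {n_distinct} distinct label permutations exist; using that many"
        )
        n_perm = int(n_distinct)

    rng = np.random.default_rng(seed)
    obs_valid = obs[valid]
    thresholds = np.sort(np.unique(obs_valid))  # ascending
    # observed exceedance counts per threshold (>= c)
    obs_sorted = np.sort(obs_valid)
    n_obs_ge = obs_valid.size - np.searchsorted(obs_sorted, thresholds, side="left")

    perm_ge = np.empty((n_perm, thresholds.size))
    for b in range(n_perm):
        perm_stats, _, perm_valid = stat_vector(rng.permutation(labels))
        ps = np.sort(perm_stats[perm_valid & np.isfinite(perm_stats)])
        inf_count = np.sum(perm_valid & np.isinf(perm_stats))
        perm_ge[b] = ps.size - np.searchsorted(ps, thresholds, side="left") + inf_count

    fdr_at = np.minimum(np.median(perm_ge, axis=0) / n_obs_ge, 1.0)
    # q(c) = min over thresholds c' <= c of FDR(c'): cumulative min ascending
    q_at = np.minimum.accumulate(fdr_at)

    q = np.full(obs.shape, np.nan)
    idx = np.searchsorted(thresholds, obs_valid, side="right") - 1
    q[valid] = q_at[idx]
    significant = np.where(valid, q <= level, False)
    return pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "statistic": obs,
            "p_value": np.where(valid, p_obs, np.nan),
            "q_value": q,
            "significant": significant,
        }
    )
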