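"""Filtering, missing-value imputation and sample-similarity structure.

Imputation follows the downshifted-Gaussian model used throughout
quantitative proteomics: missing values are assumed to come from proteins
near or below the detection limit, so each sample's missing entries are
drawn from a normal distribution centred *below* that sample's observed
value distribution and narrowed relative to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from .containers import (
    ExpressionMatrix,
    ParameterError,
    SampleAnnotation,
)

__all__ = [
    "ImputationParams",
    "CorrelationResult",
    "filter_min_valid",
    "impute_downshift",
    "correlation_structure",
]


@dataclass(frozen=True)
class ImputationParams:
    """Parameters of downshift imputation.

    width_factor
        Imputed s.d. as a fraction of the observed per-sample s.d. (> 0).
    downshift_factor
        Shift of the imputed mean below the observed per-sample mean, in
        units of the observed per-sample s.d. (≥ 0).
    seed
        Seed of the pseudo-random draws; identical seed gives identical
        output.
    """

    width_factor: float = 0.3
    downshift_factor: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.width_factor > 0:
            raise ParameterError("width_factor must be > 0")
        if self.downshift_factor < 0:
            raise ParameterError("downshift_factor must be >= 0")


@dataclass
class CorrelationResult:
    """Pairwise sample Pearson correlations plus their hierarchical clustering.

    ``linkage_matrix`` is in :func:`scipy.cluster.hierarchy.linkage` format
    over ``clustered_sample_ids`` (samples with undefined correlations are
    excluded from clustering).
    """

    correlations: pd.DataFrame
    linkage_matrix: np.ndarray
    clustered_sample_ids: list


def filter_min_valid(
    matrix: ExpressionMatrix,
    min_fraction: float,
    scope: str = "all_samples",
    annotation: SampleAnnotation | None = None,
) -> ExpressionMatrix:
    """Keep proteins whose valid-value fraction strictly exceeds ``min_fraction``.

    With ``scope="all_samples"`` the fraction is taken over all samples;
    with ``scope="per_class"`` a protein is kept if it exceeds the threshold
    in at least one class.  The inequality is strict: a protein quantified
    in exactly 70% of samples does not pass ``min_fraction=0.7``.
    """
    if not (0 < min_fraction <= 1):
        raise ParameterError("min_fraction must be in (0, 1]")
    observed = ~matrix.missing_mask
    if scope == "all_samples":
        keep = observed.mean(axis=1) > min_fraction
    elif scope == "per_class":
        if annotation is None:
            raise ParameterError("per_class scope requires an annotation")
        annotation.validate_against(matrix)
        keep = np.zeros(matrix.n_proteins, dtype=bool)
        for cls in annotation.classes:
            mask = annotation.in_class_mask(matrix.sample_ids, cls)
            keep |= observed[:, mask].mean(axis=1) > min_fraction
    else:
        raise ParameterError(f"unknown scope: {scope!r}")
    return ExpressionMatrix(matrix.data.loc[keep])


def impute_downshift(matrix: ExpressionMatrix, params: ImputationParams) -> ExpressionMatrix:
    """Replace missing entries with draws from a downshifted Gaussian.

    Per sample ``s`` with observed mean ``m_s`` and s.d. ``sd_s``, each
    missing entry is an independent draw from
    ``Normal(m_s − downshift_factor·sd_s, (width_factor·sd_s)²)``.
    Observed entries are never altered.
    """
    rng = np.random.default_rng(params.seed)
    values = matrix.values.copy()
    missing = matrix.missing_mask
    for j, sid in enumerate(matrix.sample_ids):  # fixed column order => determinism
        col = values[:, j]
        obs = col[~missing[:, j]]
        if obs.size < 2:
            raise ParameterError(
                f"sample {sid!r} has fewer than 2 observed values; cannot impute"
            )
        n_miss = int(missing[:, j].sum())
        if n_miss == 0:
            continue
        m, sd = obs.mean(), obs.std(ddof=1)
        draws = rng.normal(
            m - params.downshift_factor * sd, params.width_factor * sd, size=n_miss
        )
        col[missing[:, j]] = draws
    return ExpressionMatrix(
        pd.DataFrame(values, index=matrix.protein_ids, columns=matrix.sample_ids)
    )


def correlation_structure(
    matrix: ExpressionMatrix, linkage: str = "average", min_shared: int = 3
) -> CorrelationResult:
    """Pairwise-complete Pearson correlations and their hierarchical clustering.

    Correlations use, per sample pair, only proteins observed in both
    samples; pairs sharing fewer than ``min_shared`` proteins get a missing
    correlation and the involved samples are excluded from clustering (with
    a warning).  Clustering is agglomerative on the distance ``1 − r``.
    """
    if linkage not in ("average", "complete"):
        raise ParameterError(f"unsupported linkage: {linkage!r}")
    if matrix.n_samples < 2:
        raise ParameterError("need at least 2 samples")
    corr = matrix.data.corr(method="pearson", min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)

    # greedily drop the sample with the most undefined correlations until the
    # remaining submatrix is complete
    sub = corr.copy()
    dropped = []
    while sub.isna().to_numpy().any():
        worst = sub.isna().sum(axis=1).idxmax()
        dropped.append(worst)
        sub = sub.drop(index=worst, columns=worst)
    if dropped:
        warnings.warn(
            f"samples excluded from clustering (fewer than {min_shared} shared "
            f"observations with some partner): {dropped}"
        )
    kept = list(sub.index)
    if len(kept) >= 2:
        dist = 1.0 - sub.to_numpy()
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2  # enforce exact symmetry for squareform
        Z = sch.linkage(squareform(dist, checks=False), method=linkage)
    else:
        Z = np.empty((0, 4))
    return CorrelationResult(corr, Z, kept)
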