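"""Synthetic expression matrices with known ground truth.

The generator emulates the statistical structure of a super-SILAC tumour
cohort: a log2 ratio matrix of a few thousand proteins over a few dozen
samples in k subtype classes, with

* per-protein baselines (biological abundance differences between proteins),
* a handful of planted subtype markers with signed log2 effects,
* category-level expression shifts planted into named gene sets, and
* abundance-dependent (missing-not-at-random) missingness: the probability
  that an entry is missing rises as its underlying value falls, emulating
  non-detection of low-abundance proteins.

The pre-censoring complete matrix is retained in the truth object — this is
what makes imputation and MNAR behaviour testable at all, and it has no
analogue in real data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import CategoryMap, ExpressionMatrix, ParameterError, SampleAnnotation

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "generate_cohort", "make_default_study"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Scenario description for :func:`generate`.

    Effects are additive in log2 space (multiplicative on raw ratios).
    ``marker_effect`` of 0.8 log2 units corresponds to a ~1.7-fold change —
    typical of the sub-twofold inter-subtype differences seen in tumour
    proteomes.  ``mnar_steepness`` 0 gives uniform (value-independent)
    missingness; larger values concentrate missingness on low values.
    """

    n_classes: int = 3
    samples_per_class: tuple = (14, 15, 11)
    n_proteins: int = 2000
    markers_per_class: int = 5
    marker_effect: float = 0.8
    n_enriched_categories: int = 10
    category_size: int = 30
    category_shift: float = 0.5
    noise_sd: float = 0.5
    protein_baseline_sd: float = 1.0
    missing_target_fraction: float = 0.15
    mnar_steepness: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_class) != self.n_classes:
            raise ParameterError("samples_per_class length must equal n_classes")
        if self.markers_per_class * self.n_classes > self.n_proteins:
            raise ParameterError("more planted markers than proteins")
        if self.n_enriched_categories * self.category_size > self.n_proteins:
            raise ParameterError("enriched categories exceed protein pool")
        if not (0 <= self.missing_target_fraction < 1):
            raise ParameterError("missing_target_fraction must be in [0, 1)")
        if self.mnar_steepness < 0:
            raise ParameterError("mnar_steepness must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated scenario.

    ``complete_matrix`` holds the pre-censoring values (no missingness);
    ``markers`` maps class -> {protein_id: signed log2 effect};
    ``enriched_categories`` maps category name -> (class, shift).
    ``baselines`` and ``effects`` allow drawing further cohorts from the
    same underlying population (:func:`generate_cohort`).
    """

    markers: dict
    enriched_categories: dict
    realized_missing_fraction: float
    complete_matrix: ExpressionMatrix
    baselines: np.ndarray
    effects: pd.DataFrame  # proteins x classes, additive log2 effect per class
    config: SyntheticConfig
    tau: float | None = None

    def config_echo(self) -> dict:
        return asdict(self.config)


def _class_labels(config: SyntheticConfig):
    names = [f"class{i}" if config.n_classes > 3 else c
             for i, c in enumerate(["ERPR", "Her2", "TN"][: config.n_classes])]
    if config.n_classes > 3:
        names = [f"class{i}" for i in range(config.n_classes)]
    return names


def _apply_missingness(values: np.ndarray, config: SyntheticConfig, rng):
    """Censor entries; returns (masked values, realized fraction, tau)."""
    target = config.missing_target_fraction
    if target == 0:
        return values.copy(), 0.0, None
    if config.mnar_steepness == 0:
        mask = rng.random(values.shape) < target
        tau = None
    else:
        k = config.mnar_steepness

        def excess(tau):
            return expit(k * (tau - values)).mean() - target

        lo, hi = values.min() - 50.0 / k, values.max() + 50.0 / k
        tau = brentq(excess, lo, hi)
        mask = rng.random(values.shape) < expit(k * (tau - values))
    out = values.copy()
    out[mask] = np.nan
    return out, float(mask.mean()), tau


def generate(config: SyntheticConfig):
    """Generate (matrix, annotation, categories, truth) for a scenario.

    Value model per protein p and sample s of class c:

        x_ps = b_p + effect_p(c) + ε,   ε ~ Normal(0, noise_sd²),
        b_p ~ Normal(0, protein_baseline_sd²).

    Markers receive ±marker_effect in their class (sign drawn at random and
    recorded); members of a planted category receive +category_shift in the
    category's class.  Identical seed gives bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    classes = _class_labels(config)
    protein_ids = pd.Index([f"P{i:05d}" for i in range(config.n_proteins)], name="protein_id")
    sample_ids, labels = [], []
    for cls, n_c in zip(classes, config.samples_per_class):
        for j in range(n_c):
            sample_ids.append(f"{cls}_{j:02d}")
            labels.append(cls)
    annotation = SampleAnnotation(
        pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"))
    )

    baselines = rng.normal(0.0, config.protein_baseline_sd, size=config.n_proteins)
    effects = pd.DataFrame(
        np.zeros((config.n_proteins, config.n_classes)), index=protein_ids, columns=classes
    )

    # planted markers: distinct proteins across classes, random signs
    n_mark = config.markers_per_class * config.n_classes
    marker_pool = rng.choice(config.n_proteins, size=n_mark, replace=False)
    markers: dict = {}
    for ci, cls in enumerate(classes):
        chosen = marker_pool[ci * config.markers_per_class:(ci + 1) * config.markers_per_class]
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        markers[cls] = {}
        for idx, sign in zip(chosen, signs):
            pid = protein_ids[idx]
            effect = sign * config.marker_effect
            markers[cls][pid] = float(effect)
            effects.loc[pid, cls] += effect

    # planted enriched categories on proteins not used as markers, plus an
    # equal number of null categories for calibration
    non_marker = np.setdiff1d(np.arange(config.n_proteins), marker_pool)
    n_cat_total = 2 * config.n_enriched_categories
    cat_members_pool = rng.choice(
        non_marker, size=min(n_cat_total * config.category_size, non_marker.size), replace=False
    )
    members_map: dict = {}
    parents: dict = {}
    enriched: dict = {}
    for ci in range(n_cat_total):
        start = ci * config.category_size
        block = cat_members_pool[start:start + config.category_size]
        if block.size < config.category_size:
            break
        pids = frozenset(protein_ids[i] for i in block)
        enriched_flag = ci < config.n_enriched_categories
        name = f"{'SET' if enriched_flag else 'NULLSET'}_{ci:03d}"
        members_map[name] = pids
        parents[name] = f"PARENT_{ci // 2:03d}"
        if enriched_flag:
            cls = classes[ci % config.n_classes]
            enriched[name] = (cls, config.category_shift)
            for pid in pids:
                effects.loc[pid, cls] += config.category_shift
    categories = CategoryMap(members_map, parents)

    class_idx = np.array([classes.index(l) for l in labels])
    complete = (
        baselines[:, None]
        + effects.to_numpy()[:, class_idx]
        + rng.normal(0.0, config.noise_sd, size=(config.n_proteins, len(sample_ids)))
    )
    observed, realized, tau = _apply_missingness(complete, config, rng)

    matrix = ExpressionMatrix(pd.DataFrame(observed, index=protein_ids, columns=sample_ids))
    complete_matrix = ExpressionMatrix(
        pd.DataFrame(complete, index=protein_ids, columns=sample_ids)
    )
    truth = SyntheticTruth(
        markers=markers,
        enriched_categories=enriched,
        realized_missing_fraction=realized,
        complete_matrix=complete_matrix,
        baselines=baselines,
        effects=effects,
        config=config,
        tau=tau,
    )
    return matrix, annotation, categories, truth


def generate_cohort(truth: SyntheticTruth, samples_per_class: tuple, seed: int):
    """Draw a fresh cohort from the population defined by an existing truth.

    Uses the same per-protein baselines and class effects with new noise and
    new missingness — a held-out sample set for honest evaluation.
    """
    config = truth.config
    rng = np.random.default_rng(seed)
    classes = list(truth.effects.columns)
    if len(samples_per_class) != len(classes):
        raise ParameterError("samples_per_class length must match the truth's classes")
    sample_ids, labels = [], []
    for cls, n_c in zip(classes, samples_per_class):
        for j in range(n_c):
            sample_ids.append(f"holdout_{cls}_{j:02d}")
            labels.append(cls)
    class_idx = np.array([classes.index(l) for l in labels])
    complete = (
        truth.baselines[:, None]
        + truth.effects.to_numpy()[:, class_idx]
        + rng.normal(0.0, config.noise_sd, size=(config.n_proteins, len(sample_ids)))
    )
    observed, _, _ = _apply_missingness(complete, config, rng)
    matrix = ExpressionMatrix(
        pd.DataFrame(observed, index=truth.effects.index, columns=sample_ids)
    )
    annotation = SampleAnnotation(
        pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"))
    )
    return matrix, annotation


def make_default_study(seed: int = 0):
    """The default study scenario: 3 classes of 14/15/11 samples, 7,000
    proteins, 5 markers per class at 0.8 log2 units, 10 enriched categories
    of size 30, 15% missingness with MNAR steepness 2."""
    config = SyntheticConfig(
        n_classes=3,
        samples_per_class=(14, 15, 11),
        n_proteins=7000,
        markers_per_class=5,
        marker_effect=0.8,
        n_enriched_categories=10,
        category_size=30,
        category_shift=0.5,
        missing_target_fraction=0.15,
        mnar_steepness=2.0,
        seed=seed,
    )
    return generate(config)
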