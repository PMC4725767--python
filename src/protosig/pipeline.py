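"""End-to-end orchestration: read -> filter -> impute -> enrich + test + classify.

All intermediates and results are plain TSV/JSON files in a run directory;
a manifest records every parameter, the seed, and input checksums so that a
rerun from the same manifest is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as psio
from .classify import CVConfig, cv_feature_selection, extract_signature, roc_auc, select_optimal
from .diffexpr import permutation_fdr
from .enrichment import enrichment_1d, hierarchy_enrichment, mean_difference
from .preprocess import ImputationParams, correlation_structure, filter_min_valid, impute_downshift

log = logging.getLogger("protosig")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run.

    A serialized RunConfig (the manifest) reproduces a run exactly.
    """

    matrix_path: str = ""
    annotation_path: str = ""
    gmt_path: str | None = None
    hierarchy_path: str | None = None
    out_dir: str = "run"
    seed: int = 0
    # io
    dialect: str = "generic"
    ratio_orientation: str | None = None
    log_already: bool = True
    # preprocess
    min_valid_fraction: float = 0.7
    impute: bool = True
    imputation: ImputationParams = field(default_factory=ImputationParams)
    # enrichment
    min_category_size: int = 5
    enrichment_fdr: float = 0.05
    # diffexpr
    n_permutations: int = 250
    diffexpr_fdr: float = 0.05
    anova_on_imputed: bool = False
    # classify
    cv: CVConfig = field(default_factory=CVConfig)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        raw["imputation"] = ImputationParams(**raw.get("imputation", {}))
        cv = raw.get("cv", {})
        if "feature_grid" in cv:
            cv["feature_grid"] = tuple(cv["feature_grid"])
        raw["cv"] = CVConfig(**cv)
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all result tables plus a manifest.

    Returns the run directory.  Any stage failure propagates with the stage
    named in the log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage=read matrix=%s", config.matrix_path)
    matrix = psio.read_expression_matrix(
        config.matrix_path,
        dialect=config.dialect,
        ratio_orientation=config.ratio_orientation,
        log_already=config.log_already,
    )
    annotation = psio.read_sample_annotation(config.annotation_path)
    annotation.validate_against(matrix)
    categories = psio.read_gmt(config.gmt_path) if config.gmt_path else None
    if categories is not None and config.hierarchy_path:
        categories.parents.update(psio.read_hierarchy(config.hierarchy_path))
    log.info("stage=read proteins=%d samples=%d", matrix.n_proteins, matrix.n_samples)

    log.info("stage=filter min_fraction=%s", config.min_valid_fraction)
    filtered = filter_min_valid(matrix, config.min_valid_fraction)
    log.info("stage=filter retained=%d", filtered.n_proteins)

    # sample similarity on unimputed data (pairwise-complete)
    corr = correlation_structure(filtered)
    corr.correlations.to_csv(out / "sample_correlations.tsv", sep="\t")
    pd.DataFrame(
        corr.linkage_matrix, columns=["left", "right", "height", "count"]
    ).to_csv(out / "sample_dendrogram.tsv", sep="\t", index=False)

    imputed = None
    if config.impute:
        params = dataclasses.replace(config.imputation, seed=config.seed)
        log.info("stage=impute downshift=%s width=%s", params.downshift_factor, params.width_factor)
        imputed = impute_downshift(filtered, params)

    # enrichment per class
    if categories is not None:
        enrich_input = filtered
        if categories.parents:
            table = hierarchy_enrichment(
                enrich_input, annotation, categories,
                min_size=config.min_category_size, fdr=config.enrichment_fdr,
            )
        else:
            frames = []
            for cls in annotation.classes:
                delta = mean_difference(enrich_input, annotation, cls)
                t = enrichment_1d(
                    delta, categories, min_size=config.min_category_size,
                    fdr=config.enrichment_fdr,
                )
                t.insert(0, "class_label", cls)
                frames.append(t)
            table = pd.concat(frames, ignore_index=True)
        psio.write_result_table(
            table, out / "enrichment.tsv",
            {"fdr": config.enrichment_fdr, "min_size": config.min_category_size},
        )
        log.info("stage=enrich records=%d", len(table))

    # ANOVA with permutation FDR
    anova_input = imputed if (config.anova_on_imputed and imputed is not None) else filtered
    de = permutation_fdr(
        anova_input, annotation, statistic="anova_f",
        n_permutations=config.n_permutations, level=config.diffexpr_fdr,
        seed=config.seed,
    )
    psio.write_result_table(
        de, out / "anova_permutation_fdr.tsv",
        {
            "n_permutations": config.n_permutations,
            "fdr": config.diffexpr_fdr,
            "seed": config.seed,
            "input": "imputed" if config.anova_on_imputed else "unimputed",
        },
    )
    log.info("stage=diffexpr significant=%d", int(de["significant"].sum()))

    # classification
    if imputed is not None:
        cv_cfg = dataclasses.replace(config.cv, seed=config.seed)
        curve = cv_feature_selection(imputed, annotation, cv_cfg)
        psio.write_result_table(
            curve.frame(), out / "accuracy_curve.tsv",
            {"n_runs": cv_cfg.n_runs, "test_fraction": cv_cfg.test_fraction, "seed": config.seed},
        )
        optimal = select_optimal(curve)
        signature, models = extract_signature(
            imputed, annotation, optimal, regularization=cv_cfg.regularization
        )
        psio.write_result_table(
            signature, out / "signature.tsv", {"optimal_counts": optimal}
        )
        log.info("stage=classify signature_size=%d", len(signature))

        labels = annotation.labels.reindex(imputed.sample_ids).to_numpy()
        model_export = {}
        for cls, model in models.items():
            feat_idx = [imputed.protein_ids.get_loc(p) for p in model.feature_ids_]
            scores = model.decision_function(imputed.values.T[:, feat_idx])
            roc = roc_auc(scores, (labels == cls).astype(int))
            psio.write_result_table(
                roc.frame().assign(auc=roc.auc),
                out / f"roc_{cls}.tsv",
                {"class": cls, "mode": "resubstitution", "auc": round(roc.auc, 6)},
            )
            model_export[cls] = model.export()
        (out / "models.json").write_text(json.dumps(model_export, indent=2))

    manifest = {
        "config": json.loads(config.to_json()),
        "inputs": {
            p: _sha256(p)
            for p in [config.matrix_path, config.annotation_path, config.gmt_path, config.hierarchy_path]
            if p
        },
        "n_proteins_read": int(matrix.n_proteins),
        "n_proteins_filtered": int(filtered.n_proteins),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
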