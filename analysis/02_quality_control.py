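#!/usr/bin/env python
"""Cohort-level quality control: ratio spread and sample similarity.

Reports the fraction of log2 ratios within a fivefold range (a narrow
distribution is what makes spike-in ratio quantification accurate), the
per-sample quantification counts, and the pairwise-complete Pearson
correlation structure of the samples with average-linkage clustering.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import protosig as ps


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study-dir", type=Path, default=Path("results/study"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/qc"))
    args = ap.parse_args()

    m = ps.read_expression_matrix(args.study_dir / "matrix.tsv", log_already=True)
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    obs = ~m.missing_mask
    within5 = (np.abs(m.values[obs]) <= np.log2(5)).mean()
    print(f"{100 * within5:.1f}% of observed log2 ratios within a fivefold range")

    counts = pd.DataFrame({
        "sample_id": m.sample_ids,
        "n_quantified": obs.sum(axis=0),
    })
    ps.write_result_table(counts, out / "proteins_per_sample.tsv")
    print(f"proteins quantified per sample: median {int(counts.n_quantified.median())}, "
          f"range {counts.n_quantified.min()}-{counts.n_quantified.max()}")

    corr = ps.correlation_structure(m, linkage="average")
    c = corr.correlations.to_numpy()
    off = c[np.triu_indices_from(c, k=1)]
    print(f"inter-sample Pearson r: mean {off.mean():.2f}, "
          f"range {off.min():.2f}-{off.max():.2f}")
    corr.correlations.to_csv(out / "sample_correlations.tsv", sep="\t")
    pd.DataFrame(corr.linkage_matrix,
                 columns=["left", "right", "height", "count"]).to_csv(
        out / "sample_dendrogram.tsv", sep="\t", index=False)
    print(f"wrote correlation matrix and dendrogram -> {out}")


if __name__ == "__main__":
    main()
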