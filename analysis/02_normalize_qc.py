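"""Quality control and normalisation of both cohorts.

Quantile-normalises each cohort (the stand-in for array preprocessing), then
writes per-sample box summaries and 2-component PCA scores — the tables
behind the usual "before/after normalisation" box plots and HC-vs-OA PCA
panels. After normalisation every sample in a cohort shares an identical
five-number summary, which is the point of the step.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import pandas as pd

from crosstalk import io as cio
from crosstalk.preprocess import column_summaries, pca, quantile_normalize

ROOT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    for tag in ("bl", "sy"):
        mat = cio.read_expression_tsv(ROOT / "data" / f"expr_{tag}.tsv",
                                      ROOT / "data" / f"meta_{tag}.tsv")
        column_summaries(mat).to_csv(out / f"box_raw_{tag}.tsv", sep="\t", lineterminator="\n")
        norm = quantile_normalize(mat)
        summaries = column_summaries(norm)
        summaries.to_csv(out / f"box_normalized_{tag}.tsv", sep="\t", lineterminator="\n")
        res = pca(norm, k=2)
        scores = res.scores.copy()
        scores.insert(0, "group", list(norm.sample_group))
        scores.index.name = "sample_id"
        scores.to_csv(out / f"pca_{tag}.tsv", sep="\t", lineterminator="\n")
        cio.write_expression_tsv(norm, out / f"normalized_{tag}.tsv",
                                 out / f"normalized_{tag}_meta.tsv")
        medians = summaries["median"]
        print(
            f"{mat.tissue}: {mat.n_samples} samples; post-normalisation median "
            f"identical across samples: {medians.nunique() == 1} "
            f"(median = {medians.iloc[0]:.3f}); "
            f"PC1/PC2 variance explained = {res.explained_variance_ratio[0]:.3f}"
            f"/{res.explained_variance_ratio[1]:.3f}"
        )


if __name__ == "__main__":
    main()
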