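#!/usr/bin/env python
"""Stage the tumor groups on the SVF differentiation time course.

Corrects the tissue-vs-culture batch effect with the empirical-Bayes
location-scale model, then computes for each tumor group the per-day
Euclidean distance to the SVF profile, normalized by the distance to
normal tissue, and calls the best-matching differentiation day.  Writes
per-day similarity tables to results/staging/.
"""

import os
import sys
import warnings

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from adipostage import (  # noqa: E402
    FeatureMatrix,
    best_day_stability,
    correct_batches,
    similarity_barplot_table,
    stage_similarity,
)

SIM = os.path.join(os.path.dirname(__file__), "..", "results", "sim")
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "staging")


def main() -> None:
    expr_path = os.path.join(SIM, "expr.tsv")
    if not os.path.exists(expr_path):
        sys.exit("run analysis/01_simulate_cohort.py first")
    os.makedirs(OUT, exist_ok=True)
    fm = FeatureMatrix.from_tsv(expr_path, os.path.join(SIM, "samples.tsv"))

    with warnings.catch_warnings():
        # the tissue/culture batch is confounded with sample source by
        # design, as in any tumor-vs-culture comparison
        warnings.simplefilter("ignore")
        corrected, model = correct_batches(fm)
    eff = model.batch_effects_data_scale()
    print("batch offsets removed (data scale):")
    print(eff.to_string(float_format=lambda v: f"{v:+.3f}"))
    corrected.values.to_csv(os.path.join(OUT, "expr_corrected.tsv"),
                            sep="\t", float_format="%.6g")

    for tumor in ("WDLPS", "DDLPS"):
        prof = stage_similarity(corrected, tumor)
        tab = similarity_barplot_table(prof)
        tab.to_csv(os.path.join(OUT, f"similarity_{tumor}.tsv"), sep="\t",
                   float_format="%.6g")
        stability = best_day_stability(corrected, tumor, n_resamples=25, seed=0)
        print(f"\n{tumor}: best-matching SVF day = {prof.best_day} "
              f"(stable in {stability:.0%} of 80% gene subsamples)")
        print(tab[["d_T", "d_N", "relative_distance", "similarity"]]
              .to_string(float_format=lambda v: f"{v:8.3f}"))


if __name__ == "__main__":
    main()
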