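#!/usr/bin/env python
"""Differential lipidomics of the two tumor groups.

Reads the simulated species table, aggregates to class composition,
computes PCA scores, runs the two-group differential test with the 2-fold
volcano gate, selects the top-48 species for a heatmap, and compares the
significant sets called by the t-test and the rank-sum test.  Tables land
in results/lipids/.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from adipostage import (  # noqa: E402
    FeatureMatrix,
    aggregate_by_class,
    differential_test,
    pca_scores,
    results_table,
    set_overlap,
    top_k_by_significance,
    volcano_gate,
)

SIM = os.path.join(os.path.dirname(__file__), "..", "results", "sim")
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "lipids")


def main() -> None:
    species_path = os.path.join(SIM, "species.tsv")
    if not os.path.exists(species_path):
        sys.exit("run analysis/01_simulate_cohort.py first")
    os.makedirs(OUT, exist_ok=True)
    fm = FeatureMatrix.from_tsv(species_path, os.path.join(SIM, "lipid_samples.tsv"))

    comp = aggregate_by_class(fm, mode="fraction")
    comp.values.to_csv(os.path.join(OUT, "class_composition.tsv"), sep="\t",
                       float_format="%.6g")
    wd = comp.values[comp.samples_in_group("WDLPS")].mean(1)
    dd = comp.values[comp.samples_in_group("DDLPS")].mean(1)
    print("mean class fractions (WDLPS vs DDLPS):")
    for cls in comp.feature_ids:
        print(f"  {cls:8s} {wd[cls]:.3f} vs {dd[cls]:.3f}")

    scores, evr = pca_scores(fm, 2)
    scores.to_csv(os.path.join(OUT, "pca_scores.tsv"), sep="\t",
                  float_format="%.6g")
    print(f"PCA: PC1 {evr[0]:.1%}, PC2 {evr[1]:.1%} of variance")

    res = differential_test(fm, "WDLPS", "DDLPS", test="t")
    n_up, n_down, gated = volcano_gate(res, 1.0, 0.05)
    results_table(gated).to_csv(os.path.join(OUT, "differential.tsv"),
                                sep="\t", float_format="%.6g")
    print(f"differential species (|log2FC| > 1, p < 0.05): "
          f"{n_up} up / {n_down} down in WDLPS of {len(res)}")

    top = top_k_by_significance(gated, min(48, sum(r.significant for r in gated)))
    fm.subset_features(top).values.to_csv(
        os.path.join(OUT, "top48_heatmap_matrix.tsv"), sep="\t",
        float_format="%.6g")
    print(f"top-{len(top)} species exported for the heatmap")

    wil = differential_test(fm, "WDLPS", "DDLPS", test="wilcoxon")
    overlap = set_overlap({
        "t": {r.feature_id for r in gated if r.significant},
        "wilcoxon": {r.feature_id for r in volcano_gate(wil, 1.0, 0.05)[2]
                     if r.significant},
    })
    print(f"t vs rank-sum significant-set overlap: {overlap}")
    with open(os.path.join(OUT, "test_overlap.tsv"), "w") as fh:
        fh.write("partition\tcount\n")
        for key, n in sorted(overlap.items()):
            fh.write("&".join(key) + f"\t{n}\n")


if __name__ == "__main__":
    main()
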