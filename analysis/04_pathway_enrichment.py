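#!/usr/bin/env python
"""Differential expression and gene-set enrichment between tumor groups.

Calls differentially expressed genes between the WDLPS-like and
DDLPS-like groups at the 2-fold gate, ranks all genes by signed log2 fold
change, and runs preranked permutation enrichment against gene sets built
from the simulation's ground truth: the planted differentiation-program
genes split by direction (the sets that should be called) and size-matched
random sets (negative controls).  Tables land in results/enrichment/.
"""

import json
import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from adipostage import (  # noqa: E402
    FeatureMatrix,
    GeneSet,
    differential_test,
    enrich_all,
    rank_genes,
    results_table,
    volcano_gate,
    write_gmt,
)

SIM = os.path.join(os.path.dirname(__file__), "..", "results", "sim")
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "enrichment")
SEED = 17


def main() -> None:
    expr_path = os.path.join(SIM, "expr.tsv")
    if not os.path.exists(expr_path):
        sys.exit("run analysis/01_simulate_cohort.py first")
    os.makedirs(OUT, exist_ok=True)
    fm = FeatureMatrix.from_tsv(expr_path, os.path.join(SIM, "samples.tsv"))
    tumors = fm.subset_samples(
        fm.samples_in_group("WDLPS") + fm.samples_in_group("DDLPS"))

    res = differential_test(tumors, "WDLPS", "DDLPS", test="t", log_scale=True)
    n_up, n_down, gated = volcano_gate(res, 1.0, 0.05)
    results_table(gated).to_csv(os.path.join(OUT, "deg.tsv"), sep="\t",
                                float_format="%.6g")
    print(f"DEGs (2-fold gate, p < 0.05): {n_up} up / {n_down} down "
          f"in WDLPS of {len(res)} genes")

    with open(os.path.join(SIM, "truth.json")) as fh:
        truth = json.load(fh)
    up_genes = sorted(g for g, fc in truth["group_effects"].items() if fc > 0.5)
    down_genes = sorted(g for g, fc in truth["group_effects"].items() if fc < -0.5)
    rng = np.random.default_rng(SEED)
    sets = [
        GeneSet("PROGRAM_UP_WDLPS", "planted program, higher at the WDLPS stage",
                up_genes),
        GeneSet("PROGRAM_DOWN_WDLPS", "planted program, lower at the WDLPS stage",
                down_genes),
    ] + [
        GeneSet(f"RANDOM_{k}", "size-matched negative control",
                sorted(rng.choice(tumors.feature_ids, len(up_genes),
                                  replace=False).tolist()))
        for k in range(3)
    ]
    write_gmt(sets, os.path.join(OUT, "gene_sets.gmt"))

    genes, scores = rank_genes(gated, metric="signed_log2fc")
    enr = enrich_all(genes, scores, sets, n_permutations=1000, seed=SEED)
    with open(os.path.join(OUT, "enrichment.tsv"), "w") as fh:
        fh.write("set_id\tes\tnes\tp_value\tselected\n")
        for r in enr:
            fh.write(f"{r.set_id}\t{r.es:.4f}\t{r.nes:.4f}\t{r.p_value:.4g}"
                     f"\t{r.selected}\n")
    print("\nenrichment under the (|NES| > 1, p < 0.05) gate:")
    for r in enr:
        mark = "SELECTED" if r.selected else "-"
        print(f"  {r.set_id:22s} ES {r.es:+.3f}  NES {r.nes:+.3f}  "
              f"p {r.p_value:.4g}  {mark}")


if __name__ == "__main__":
    main()
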