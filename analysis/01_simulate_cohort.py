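#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes a liposarcoma-style multi-omics cohort to results/sim/: a lipid
species table for 6 WDLPS-like and 7 DDLPS-like tumors, and an expression
matrix covering both tumor groups, 13 normal adipose samples, and an SVF
adipogenic differentiation time course (days 0-10, 3 replicates/day) with
tissue-vs-culture batch effects.  The ground-truth sidecar records every
planted effect.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from adipostage.simulate import (  # noqa: E402
    SimulationConfig,
    simulate_expression,
    simulate_lipidomics,
)

OUTDIR = os.path.join(os.path.dirname(__file__), "..", "results", "sim")
COHORT_SEED = 42


def main() -> None:
    os.makedirs(OUTDIR, exist_ok=True)
    cfg = SimulationConfig(seed=COHORT_SEED)
    expr, truth_e = simulate_expression(cfg)
    lipids, truth_l = simulate_lipidomics(cfg)
    expr.to_tsv(os.path.join(OUTDIR, "expr.tsv"),
                os.path.join(OUTDIR, "samples.tsv"))
    lipids.to_tsv(os.path.join(OUTDIR, "species.tsv"),
                  os.path.join(OUTDIR, "lipid_samples.tsv"))
    truth_e.lipid_species = truth_l.lipid_species
    truth_e.class_effects = truth_l.class_effects
    truth_e.to_json(os.path.join(OUTDIR, "truth.json"))
    print(f"expression: {expr.n_features} genes x {expr.n_samples} samples "
          f"({dict(expr.samples['group'].value_counts())})")
    print(f"lipidomics: {lipids.n_features} species x {lipids.n_samples} samples")
    print(f"planted stages: {truth_e.stage_assignment}; "
          f"planted class effects (log2 WDLPS/DDLPS): {truth_l.class_effects}")
    print(f"written to {os.path.abspath(OUTDIR)}")


if __name__ == "__main__":
    main()
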