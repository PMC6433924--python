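"""Pairwise F_ST between lines and parameter recovery of planted loci.

Runs the Weir-Cockerham reads-as-alleles estimator over every line pair
of a synthetic experiment and scores the SDV call set against the known
causal loci.
"""

import numpy as np

from lekscan import (
    DesignSpec,
    ExperimentConfig,
    evaluate_recovery,
    filter_loci,
    orient_global_minor,
    regimen_fst,
    scan_loci,
    simulate_experiment,
)

rng = np.random.default_rng(1)
config = ExperimentConfig(n_loci=4000, fraction_causal=0.01, sel_coeff=0.8)
table, truth = simulate_experiment(config, rng)
table = filter_loci(orient_global_minor(table))
design = DesignSpec(
    {lid: ("success" if lid.startswith("S")
           else "failure" if lid.startswith("F") else "control")
     for lid in table.line_ids}
)

fst = regimen_fst(table, design, estimator="wc84")
print(f"mean F_ST success pairs : {fst.fst_success:.3f}")
print(f"mean F_ST failure pairs : {fst.fst_failure:.3f}")
print(f"DF_ST                   : {fst.dfst:+.4f}")

scan = scan_loci(table, design)
rec = evaluate_recovery(scan, truth)
print(f"SDVs called             : {rec.n_sdv} (causal planted: "
      f"{rec.n_causal})")
print(f"precision / recall      : {rec.precision:.2f} / {rec.recall:.2f}")
print(f"causal enrichment       : {rec.enrichment:.0f}x")

# Both regimens drifted at the same N here, so DF_ST sits near zero and
# the F_ST level reflects 14 generations of drift at N = 50.  The
# enrichment factor is the SDV precision over the 1% genome-wide causal
# rate: a well-calibrated scan concentrates causal loci by two orders of
# magnitude.
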