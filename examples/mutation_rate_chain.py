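"""Early-embryonic mutation-rate estimation from cohort discovery totals.

22 validated somatic variants were found in 5,906,849 callable bases per
individual across 1461 brain exomes; the rate is corrected for the six
embryonic cells (2 after the first cleavage division, 4 after the second)
in which a detectable high-VAF mutation could have arisen, then
extrapolated to a 3 Gb genome.
"""

import json

import brainmosaic as bm

est = bm.estimate_rate(
    n_validated=22, callable_bp=5_906_849, n_samples=1461, n_cells=6, genome_bp=3e9
)
print(json.dumps(est.report(), indent=2))
print(
    f"\n-> {est.report()['rate_per_bp']:.3g} mutations/bp across the cohort, "
    f"{est.report()['rate_per_bp_per_individual']:.3g} per bp per individual "
    f"in the first two cleavage divisions, i.e. about "
    f"{est.report()['genome_expectation']} genome-wide mutations per person."
)
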