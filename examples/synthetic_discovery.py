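"""Somatic-variant discovery on a simulated cohort with known truth.

Simulates a 200-sample x 2000-site cohort (depth ~ N(51.9, 12.9), germline
hets at VAF 0.47, somatic variants planted at first/second-division VAFs
0.25/0.125, overdispersed base error), runs the full filter chain, and
compares the survivors against the ground truth.
"""

import collections

import brainmosaic as bm
from brainmosaic.filtering import stage_counts

cfg = bm.SimulationConfig(n_samples=200, n_sites=2000, seed=11)
cohort = bm.simulate_cohort(cfg)
print("planted truth:", cohort.truth["kind"].value_counts().to_dict())

survivors, audit, mask = bm.run_discovery(
    cohort.sites, cohort.depth, cohort.alt_count, cohort.sample_ids,
    blacklist=cohort.blacklist, cnv=cohort.cnv, popfreq=cohort.popfreq, seed=1,
)
print(f"callable sites: {mask.callable_bp}/{cfg.n_sites}")
print("filter-chain survival:", stage_counts(audit))

truth_kind = {
    (r.sample_id, r.pos): r.kind for r in cohort.truth.itertuples()
}
kinds = collections.Counter(
    truth_kind.get((r.sample_id, r.pos), "error_only")
    for r in survivors.itertuples()
)
print(f"\n{len(survivors)} candidates:", dict(kinds))
print(
    "-> second-division variants (VAF 0.125) dominate: their counts sit far\n"
    "   below the heterozygous 47% null, while first-division variants\n"
    "   (VAF 0.25) need ~170x depth to reach binomial p < 1e-5, so at ~52x\n"
    "   mean depth only their low-VAF sampling tail is recovered.\n"
    "   error_only survivors are the artifact load the downstream amplicon\n"
    "   validation step is designed to remove."
)
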