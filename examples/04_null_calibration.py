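"""Quick check that cluster-FWE p-values are calibrated under the null.

Simulates cohorts with zero seed-target coupling and counts how often any
cluster reaches p_FWE <= 0.05.  With a valid procedure the rate should
hover around 5%.  (20 cohorts here for speed; the test suite runs 200.)
"""

import metabconn as mc

n_cohorts, rejections = 20, 0
for r in range(n_cohorts):
    cohort = mc.generate_cohort(
        mc.SimulationConfig(coupling_slope=0.0, rng_seed=900 + r)
    )
    res = mc.run_group_analysis(
        cohort.volumes, cohort.participants, cohort.truth.seed_mask,
        n_perm=199, rng_seed=r,
    )
    hit = any(c.p_fwe <= 0.05 for c in res.clusters)
    rejections += hit
    print(f"cohort {r:2d}: {len(res.clusters)} cluster(s), "
          f"min p_FWE = {min((c.p_fwe for c in res.clusters), default=1.0):.3f}"
          f"{'  <- false positive' if hit else ''}")

print()
print(f"family-wise rejections at alpha = 0.05: {rejections}/{n_cohorts} "
      f"({rejections / n_cohorts:.0%}); expected about 5%.")
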