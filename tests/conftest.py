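import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import metabconn as mc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def identity_volume():
    """Small volume on an identity (1 mm) grid for coordinate tests."""
    rng = np.random.default_rng(7)
    return mc.MetabolicVolume(
        data=rng.uniform(50, 150, size=(12, 12, 12)),
        affine=np.eye(4),
        subject_id="sub-id",
    )


@pytest.fixture(scope="session")
def null_calibration():
    """Minimum cluster-FWE p per cohort over 200 pure-null simulations.

    Null cohorts (coupling slope 0, n=27, 16³ grid) are analysed by the
    full pipeline with 199 permutations each; the session caches the
    per-cohort minimum p_fwe (1.0 when no cluster forms) so both the
    calibration and p-value-validity checks share one simulation.
    """
    pvals = []
    for r in range(200):
        cohort = mc.generate_cohort(
            mc.SimulationConfig(coupling_slope=0.0, rng_seed=10_000 + r)
        )
        res = mc.run_group_analysis(
            cohort.volumes,
            cohort.participants,
            cohort.truth.seed_mask,
            n_perm=199,
            rng_seed=r,
        )
        pvals.append(min((c.p_fwe for c in res.clusters), default=1.0))
    return np.asarray(pvals)


@pytest.fixture(scope="session")
def effect_recovery():
    """Top-cluster Dice vs the planted target over 20 strong-effect runs.

    Each replicate plants the default strong negative coupling, runs the
    full pipeline, and records the Dice overlap of the most significant
    cluster with the true target mask plus the fitted score coefficient
    at the true peak (the target centre).
    """
    out = []
    for r in range(20):
        cohort = mc.generate_cohort(mc.SimulationConfig(rng_seed=5000 + r))
        res = mc.run_group_analysis(
            cohort.volumes,
            cohort.participants,
            cohort.truth.seed_mask,
            n_perm=199,
            rng_seed=r,
        )
        dice = 0.0
        if res.clusters:
            top = min(res.clusters, key=lambda c: (c.p_fwe, -c.size_voxels))
            blob = np.zeros(cohort.truth.target_mask.data.shape, dtype=bool)
            blob[tuple(top.member_indices.T)] = True
            dice = mc.dice_coefficient(blob, cohort.truth.target_mask.data)
        peak = tuple(
            mc.mm_to_voxel(cohort.config.target_center_mm, cohort.volumes[0].affine)
        )
        out.append({"dice": dice, "beta_score_at_peak": res.glm.beta_maps[1][peak]})
    return out
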