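import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.differing_executors],
)
settings.load_profile("default")

from avscreen.cra import TrainingSet
from avscreen.hemodynamics import DOSClass, FeaturePattern, FluidProperties, Site, SiteMeasurement
from avscreen.synthetic import TABLE_STATS, CohortConfig, VelocityStats


def make_measurement(site=Site.A, subject_id="S1", V_p=103.2, V_m=37.0,
                     heart_rate=1.0, D_H=5.0, V_ed=None):
    return SiteMeasurement(
        subject_id=subject_id, site=site, V_p=V_p, V_m=V_m,
        heart_rate=heart_rate, D_H=D_H, V_ed=V_ed,
    )


#: class centroids of a cleanly separated feature space, loosely shaped like
#: the published per-class feature trends (ratios near 1 / below 1 / above 1)
SEPARATED_CENTROIDS = {
    DOSClass.I: np.array([1.00, 1.0, 1.00, 0.60, 0.55, 0.57]),
    DOSClass.II: np.array([0.80, 1.0, 0.90, 0.67, 0.70, 0.62]),
    DOSClass.III: np.array([1.50, 1.0, 1.50, 0.75, 0.69, 0.77]),
}


def make_separated_training(n_per_class=3, jitter=0.02):
    """Deterministic, well-separated labelled patterns (between-class distance
    far exceeds the within-class jitter)."""
    rng = np.random.default_rng(12345)
    patterns = []
    for c, center in SEPARATED_CENTROIDS.items():
        for i in range(n_per_class):
            phi = center + jitter * rng.standard_normal(6)
            phi[1] = 1.0
            phi = np.clip(phi, 0.0, None)
            patterns.append(
                FeaturePattern(phi=phi, dos_class=c, subject_id=f"{c.value}-{i}")
            )
    return TrainingSet(patterns=tuple(patterns))


@pytest.fixture
def separated_training():
    return make_separated_training()


def shrunk_velocity_stats(factor=0.25):
    """Published velocity table with SDs scaled down -> well-separated classes."""
    return {
        c: {
            s: VelocityStats(st.vp_mean, factor * st.vp_sd, st.vm_mean, factor * st.vm_sd)
            for s, st in TABLE_STATS[c].items()
        }
        for c in TABLE_STATS
    }


@pytest.fixture
def default_cohort_config():
    return CohortConfig(seed=0)


@pytest.fixture
def fluid():
    return FluidProperties()
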