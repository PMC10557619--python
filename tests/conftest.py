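import numpy as np
import pytest

from tractspan import synthetic, trajectory


QUAD_PEAK25 = dict(curve_family="quadratic", params=(0.5, 0.004, -0.00008))
# dynamic range of that curve on [0, 100] is 0.45, so 5% noise is 0.0225


@pytest.fixture
def quad_truth():
    """Quadratic ground truth peaking at age 25 (vertex -c1 / 2 c2)."""
    def make(noise_sd=0.0, ya_offset=0.0, feature="f", bundle="b"):
        return synthetic.TruthRecord(
            bundle_id=bundle, feature=feature, noise_sd=noise_sd,
            ya_offset=ya_offset, **QUAD_PEAK25,
        )
    return make


@pytest.fixture
def quad_table(quad_truth):
    """Feature table generated from the quadratic truth."""
    def make(noise_sd=0.0, ya_offset=0.0, n_per_cohort=100, seed=0):
        table, _ = synthetic.generate_feature_table(
            [quad_truth(noise_sd=noise_sd, ya_offset=ya_offset)],
            synthetic.default_cohorts(n_per_cohort=n_per_cohort),
            seed,
        )
        return table
    return make


@pytest.fixture
def tube_bundle():
    return synthetic.generate_bundle(
        "straight_tube", n_streamlines=50, length=100.0, radius=5.0, seed=1
    )


@pytest.fixture
def arc_bundle():
    return synthetic.generate_bundle(
        "arc", n_streamlines=20, arc_radius=50.0, arc_angle=np.pi, radius=2.0, seed=1
    )
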