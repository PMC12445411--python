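import numpy as np
import pytest

import transperf as tp


@pytest.fixture(scope="session")
def step_phantom_05():
    """Concentric-circle step phantom (inner 1.1 / outer 1.0) at 0.5 mm."""
    spec = tp.PhantomSpec(profile="step", endo_value=1.1, epi_value=1.0,
                          pixel_spacing=0.5, grid_shape=(256, 256))
    pmap, contours, truth = tp.make_phantom(spec)
    masks = tp.assign_layers(pmap, contours)
    return spec, pmap, contours, truth, masks


@pytest.fixture(scope="session")
def default_cohort_frame():
    """One simulated 138-subject cohort with the default parameterisation."""
    return tp.cohort_to_frame(tp.make_cohort(tp.CohortSpec(seed=20250925)))


@pytest.fixture(scope="session")
def fitted_results(default_cohort_frame):
    return tp.TransmuralNormals(default_cohort_frame).fit(seed=3, n_boot=500)


@pytest.fixture()
def uniform_subject():
    """Six uniform phantom maps: stress 2.0, rest 0.6 everywhere."""
    maps, contours = {}, {}
    for sl in ("basal", "mid", "apical"):
        for st, v in (("stress", 2.0), ("rest", 0.6)):
            pmap, ctr, _ = tp.make_phantom(tp.PhantomSpec(
                endo_value=v, epi_value=v, slice_label=sl, state=st))
            maps[(sl, st)] = pmap
            contours[sl] = ctr
    return maps, contours


def offset_centers(n, lo, hi, seed=42):
    rng = np.random.default_rng(seed)
    return [(0.5 * (lo + hi) + rng.uniform(-1, 1),
             0.5 * (lo + hi) + rng.uniform(-1, 1)) for _ in range(n)]
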