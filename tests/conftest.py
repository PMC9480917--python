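import numpy as np
import pytest

from somatomap.hemodynamics import double_gamma_hrf
from somatomap.synthetic_data import CorticalPatch


@pytest.fixture(scope="session")
def hrf():
    return double_gamma_hrf()


@pytest.fixture(scope="session")
def delta_patch():
    """Five delta-tuned voxels with centers exactly 1..5 (one per row)."""
    shape = (5, 1)
    return CorticalPatch(
        grid_shape=shape,
        prf_center=np.arange(1, 6, dtype=float).reshape(shape),
        prf_sigma=np.full(shape, 0.05),
        amplitude=np.ones(shape),
        baseline=np.full(shape, 1000.0),
        noise_sd=np.zeros(shape),
        responsive=np.ones(shape, dtype=bool),
        area_label=np.full(shape, "BA3b", dtype=object),
    )


def make_patch(center, sigma, amplitude=1.0, noise_sd=0.0, n=None, label="BA3b"):
    """Single-band patch with explicit per-voxel truth (column vector grid)."""
    center = np.atleast_1d(np.asarray(center, dtype=float))
    n = n or center.size
    center = np.resize(center, n)
    sigma = np.resize(np.asarray(sigma, dtype=float), n)
    amplitude = np.resize(np.asarray(amplitude, dtype=float), n)
    shape = (n, 1)
    return CorticalPatch(
        grid_shape=shape,
        prf_center=center.reshape(shape),
        prf_sigma=sigma.reshape(shape),
        amplitude=amplitude.reshape(shape),
        baseline=np.full(shape, 1000.0),
        noise_sd=np.full(shape, float(noise_sd)),
        responsive=(amplitude > 0).reshape(shape),
        area_label=np.full(shape, label, dtype=object),
    )


def run_to_psc(run):
    """Exact percent-signal-change of a simulated run using the true
    baseline (noiseless-validation helper)."""
    from somatomap.preprocess import RunTimeseries

    baseline = run.patch.flat(run.patch.baseline)[:, None]
    return RunTimeseries(
        100.0 * (run.values / baseline - 1.0),
        tr=run.tr,
        units="percent_signal_change",
    )
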