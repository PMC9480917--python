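"""Synthetic somatotopic cortical patches and simulated BOLD runs.

The generator provides ground truth for every downstream stage without any
data download.  A :class:`CorticalPatch` is a 2-D voxel grid divided into
bands mimicking Brodmann areas: three postcentral bands (BA3b, BA1, BA2)
plus a flat-tuned associative band (post-BA2), two precentral bands (BA4a,
BA6), and unresponsive background.  Within each responsive band, Gaussian
fingertip population receptive fields (pRFs) are laid out with centers
increasing monotonically along the somatotopic axis (grid rows, inferior
to superior = thumb to pinky) and band-specific tuning widths that grow
away from BA3b/BA4a, emulating the observed selectivity gradients.

A simulated run is the linear forward model the analysis assumes:

    signal = baseline * (1 + (tuning-weighted convolved design
                              + drift + noise) / 100)

where the tuning weight of fingertip f for a voxel with center c and
spread s is ``amplitude * exp(-(f - c)^2 / (2 s^2))`` (percent signal
change at the response-peak scale of the design convention), drift is a
sum of cosines below 0.01 Hz, and noise is white Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .er_design import EventSequence, N_FINGERS
from .hemodynamics import HRFModel, build_design, double_gamma_hrf

__all__ = [
    "PatchConfig",
    "CorticalPatch",
    "SimulatedRun",
    "make_somatotopic_patch",
    "gaussian_tuning",
    "simulate_run",
]

#: band order across the grid columns, with (label, width fraction,
#: mean pRF sigma, responsive?) -- sigma grows BA3b -> BA1 -> BA2 ->
#: post-BA2 and BA4a -> BA6, post-BA2/BA6-flat emulating flat tuning.
_DEFAULT_BANDS = [
    ("background", 0.10, None, False),
    ("BA4a", 0.10, 1.0, True),
    ("BA6", 0.10, 1.8, True),
    ("background", 0.10, None, False),
    ("BA3b", 0.15, 0.8, True),
    ("BA1", 0.15, 1.2, True),
    ("BA2", 0.15, 2.0, True),
    ("post_BA2", 0.15, 20.0, True),
]


@dataclass
class PatchConfig:
    """Layout and generative parameters of a synthetic patch.

    Amplitude ~1% peak signal change and white-noise SD 1% per TR are
    realistic for 1.5-mm 7T voxels; baseline is an arbitrary raw-signal
    level.  ``sigma_jitter`` is the relative SD of voxelwise log-normal
    variation around each band's mean tuning width.
    """

    grid_shape: tuple = (40, 40)
    bands: list = field(default_factory=lambda: [list(b) for b in _DEFAULT_BANDS])
    center_range: tuple = (0.5, 5.5)
    amplitude: float = 1.0  # % signal change at the preferred fingertip
    amplitude_jitter: float = 0.2  # relative SD
    sigma_jitter: float = 0.2
    baseline: float = 1000.0
    noise_sd: float = 1.0  # % signal change per TR
    spacing_mm: float = 1.5

    def validate(self) -> None:
        widths = [w for _, w, _, _ in self.bands]
        if abs(sum(widths) - 1.0) > 1e-6:
            raise ValueError("band width fractions must sum to 1")
        if any(w <= 0 for w in widths):
            raise ValueError("band widths must be positive")
        if not (0 < self.center_range[0] < self.center_range[1]):
            raise ValueError("invalid center range")
        for label, _, sigma, responsive in self.bands:
            if responsive and (sigma is None or sigma <= 0):
                raise ValueError(f"responsive band {label!r} needs a positive sigma")


@dataclass
class CorticalPatch:
    """Synthetic 2-D voxel grid with ground-truth pRFs.

    All per-voxel arrays have the grid shape; the somatotopic axis is
    axis 0 (rows): pRF centers increase from row 0 upward within every
    responsive band.
    """

    grid_shape: tuple
    prf_center: np.ndarray
    prf_sigma: np.ndarray
    amplitude: np.ndarray
    baseline: np.ndarray
    noise_sd: np.ndarray
    responsive: np.ndarray
    area_label: np.ndarray
    spacing_mm: float = 1.5
    seed: int | None = None

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    def flat(self, arr: np.ndarray) -> np.ndarray:
        return np.asarray(arr).reshape(-1)

    def band_mask(self, label: str) -> np.ndarray:
        return self.area_label == label

    def to_dataframe(self) -> pd.DataFrame:
        rows, cols = np.indices(self.grid_shape)
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "area": self.area_label.ravel(),
                "responsive": self.responsive.ravel(),
                "prf_center": self.prf_center.ravel(),
                "prf_sigma": self.prf_sigma.ravel(),
                "amplitude": self.amplitude.ravel(),
                "baseline": self.baseline.ravel(),
                "noise_sd": self.noise_sd.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def make_somatotopic_patch(
    config: PatchConfig | None = None, seed: int = 0
) -> CorticalPatch:
    """Build a synthetic somatotopic patch.

    Within each responsive band, centers are an affine ramp of the row
    index spanning ``center_range`` plus small jitter that never breaks
    row-wise monotonicity; sigmas are log-normal around the band mean.
    """
    cfg = config or PatchConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    n_rows, n_cols = cfg.grid_shape

    center = np.zeros(cfg.grid_shape)
    sigma = np.full(cfg.grid_shape, np.nan)
    amplitude = np.zeros(cfg.grid_shape)
    responsive = np.zeros(cfg.grid_shape, dtype=bool)
    labels = np.full(cfg.grid_shape, "background", dtype=object)

    lo, hi = cfg.center_range
    ramp = lo + (hi - lo) * (np.arange(n_rows) + 0.5) / n_rows

    col0 = 0
    for label, width, band_sigma, is_resp in cfg.bands:
        ncol = int(round(width * n_cols))
        ncol = min(ncol, n_cols - col0)
        sl = (slice(None), slice(col0, col0 + ncol))
        labels[sl] = label
        if is_resp and ncol > 0:
            # monotone center ramp with sub-step jitter (cannot reorder rows)
            step = (hi - lo) / n_rows
            jit = rng.uniform(-0.45 * step, 0.45 * step, size=(n_rows, ncol))
            c = np.clip(ramp[:, None] + jit, lo, hi)
            center[sl] = np.sort(c, axis=0)
            sigma[sl] = band_sigma * np.exp(
                rng.normal(0.0, cfg.sigma_jitter, size=(n_rows, ncol))
            )
            amplitude[sl] = cfg.amplitude * np.exp(
                rng.normal(0.0, cfg.amplitude_jitter, size=(n_rows, ncol))
            )
            responsive[sl] = True
        col0 += ncol

    baseline = np.full(cfg.grid_shape, cfg.baseline)
    noise_sd = np.full(cfg.grid_shape, cfg.noise_sd)
    return CorticalPatch(
        grid_shape=cfg.grid_shape,
        prf_center=center,
        prf_sigma=np.where(responsive, sigma, np.nan),
        amplitude=np.where(responsive, amplitude, 0.0),
        baseline=baseline,
        noise_sd=noise_sd,
        responsive=responsive,
        area_label=np.asarray(labels, dtype=object),
        spacing_mm=cfg.spacing_mm,
        seed=seed,
    )


def gaussian_tuning(center, sigma, fingers=None) -> np.ndarray:
    """Gaussian pRF evaluated at the fingertip indices 1..5."""
    if fingers is None:
        fingers = np.arange(1, N_FINGERS + 1, dtype=float)
    center = np.asarray(center, dtype=float)[..., None]
    sigma = np.asarray(sigma, dtype=float)[..., None]
    return np.exp(-0.5 * ((fingers - center) / sigma) ** 2)


@dataclass
class SimulatedRun:
    """One simulated BOLD run: voxels x TRs raw-signal matrix plus the
    sequence and ground-truth patch that generated it."""

    values: np.ndarray
    sequence: EventSequence
    patch: CorticalPatch
    seed: int
    tr: float = 2.0


def _drift(n_trs: int, tr: float, amplitude: float, rng) -> np.ndarray:
    """Sum of cosines strictly below 0.01 Hz with random phases, scaled so
    the summed waveform has SD ``amplitude`` (% signal change)."""
    if amplitude == 0:
        return np.zeros(n_trs)
    t = np.arange(n_trs) * tr
    total = n_trs * tr
    freqs = []
    k = 1
    while k / (2 * total) < 0.01:
        freqs.append(k / (2 * total))
        k += 1
    if not freqs:
        return np.zeros(n_trs)
    d = sum(np.cos(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) for f in freqs)
    sd = d.std()
    return amplitude * d / sd if sd > 0 else np.zeros(n_trs)


def simulate_run(
    patch: CorticalPatch,
    seq: EventSequence,
    hrf: HRFModel | None = None,
    drift_amplitude: float = 0.5,
    seed: int = 0,
    hrf_delay_jitter: float = 0.0,
) -> SimulatedRun:
    """Simulate a BOLD run for every voxel of a patch.

    ``hrf_delay_jitter`` optionally shifts each voxel's HRF peak by a
    uniform +/- jitter (seconds) to exercise delay-compensation steps
    (default off).  Deterministic given ``seed``.
    """
    if hrf is None:
        hrf = double_gamma_hrf(dt=seq.tr)
    rng = np.random.default_rng(seed)
    n_vox = patch.n_voxels
    n = seq.n_trs
    # phase-encoded runs are steady-state cyclic stimulation: the HRF tail
    # wraps around the run (equivalent to discarding initial transient cycles)
    circular = seq.design_kind.startswith("phase")

    weights = (
        patch.flat(patch.amplitude)[:, None]
        * gaussian_tuning(
            np.nan_to_num(patch.flat(patch.prf_center), nan=3.0),
            np.nan_to_num(patch.flat(patch.prf_sigma), nan=1.0),
        )
    )  # (n_vox, 5), zero for unresponsive voxels

    if hrf_delay_jitter > 0:
        delays = rng.uniform(-hrf_delay_jitter, hrf_delay_jitter, size=n_vox)
        # quantize voxels into a few delay groups to keep this cheap
        n_groups = 8
        edges = np.linspace(delays.min(), delays.max() + 1e-9, n_groups + 1)
        group = np.digitize(delays, edges) - 1
        psc = np.zeros((n_vox, n))
        for g in range(n_groups):
            mask = group == g
            if not mask.any():
                continue
            d = 0.5 * (edges[g] + edges[g + 1])
            hg = double_gamma_hrf(
                peak_delay=6.0 + d, undershoot_delay=16.0 + d, dt=seq.tr
            )
            Xg = build_design(seq, "canonical", hg, circular=circular).values
            psc[mask] = weights[mask] @ Xg.T
    else:
        X = build_design(seq, "canonical", hrf, circular=circular).values  # (n, 5)
        psc = weights @ X.T

    drift = np.stack(
        [_drift(n, seq.tr, drift_amplitude, rng) for _ in range(n_vox)]
    ) if drift_amplitude else np.zeros((n_vox, n))
    noise_sd = patch.flat(patch.noise_sd)[:, None]
    noise = rng.standard_normal((n_vox, n)) * noise_sd

    baseline = patch.flat(patch.baseline)[:, None]
    values = baseline * (1.0 + (psc + drift + noise) / 100.0)
    return SimulatedRun(values, seq, patch, seed, tr=seq.tr)
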