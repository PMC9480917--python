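"""Hemodynamic response models and design-matrix construction.

The canonical hemodynamic response function (HRF) is modelled as a
difference of two gamma densities: a positive response peaking ~6 s after
stimulus onset and a negative undershoot peaking ~16 s, the undershoot
scaled down by a peak ratio (default 6).  Event sequences are convolved
with this kernel (or with a bank of shifted delta functions for
finite-impulse-response, FIR, deconvolution) to build GLM design matrices.

Conventions
-----------
* Events are TR-locked impulses of unit *area*: a single event contributes
  an impulse of discrete amplitude ``TR`` so that convolution with a
  unit-integral HRF approximates the continuous convolution of a unit
  impulse with a kernel integrating to one.  Under this convention a
  regression coefficient is in the same units as the data (e.g. percent
  signal change at the response peak scale set by the HRF).
* The HRF is sampled on the TR grid; sub-TR stimulus structure is not
  modelled (stimulation onsets coincide with volume acquisitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = [
    "HRFModel",
    "DesignMatrix",
    "double_gamma_hrf",
    "temporal_derivative",
    "build_design",
    "fir_design_kronecker",
]


@dataclass
class HRFModel:
    """A sampled hemodynamic response function.

    Attributes
    ----------
    samples : 1-D array of the kernel sampled every ``dt`` seconds from 0.
    dt : sampling step in seconds (the TR for TR-resolution designs).
    kind : 'double_gamma' or 'empirical'.
    normalization : 'unit_integral' (sum(h)*dt == 1) or 'unit_peak'
        (max(h) == 1).
    """

    samples: np.ndarray
    dt: float
    kind: str = "double_gamma"
    normalization: str = "unit_integral"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("HRF samples must be a non-empty 1-D array")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    def normalized(self, normalization: str) -> "HRFModel":
        """Return a copy under a different amplitude normalization."""
        h = self.samples.copy()
        if normalization == "unit_integral":
            area = h.sum() * self.dt
            if area == 0:
                raise ValueError("cannot integral-normalize a zero-area kernel")
            h = h / area
        elif normalization == "unit_peak":
            peak = h.max()
            if peak == 0:
                raise ValueError("cannot peak-normalize a kernel with zero peak")
            h = h / peak
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        return HRFModel(h, self.dt, kind=self.kind, normalization=normalization)


def double_gamma_hrf(
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 6.0,
    dt: float = 2.0,
    duration: float = 40.0,
    normalization: str = "unit_integral",
) -> HRFModel:
    """Difference-of-gammas canonical HRF.

    Each gamma density has scale 1 s and shape ``delay + 1`` so that its
    mode falls exactly at the stated delay.  The undershoot density is
    scaled by ``1/ratio``.  ``h(0) == 0`` since both shapes exceed 1.
    """
    if peak_delay <= 0 or undershoot_delay <= 0:
        raise ValueError("peak delays must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration, dt)
    h = _gamma.pdf(t, peak_delay + 1.0, scale=1.0)
    h = h - _gamma.pdf(t, undershoot_delay + 1.0, scale=1.0) / ratio
    return HRFModel(h, dt, kind="double_gamma", normalization="none").normalized(
        normalization
    )


def temporal_derivative(hrf: HRFModel) -> np.ndarray:
    """First-difference proxy for the HRF temporal derivative on the TR grid."""
    d = np.diff(hrf.samples, prepend=0.0)
    return d


@dataclass
class DesignMatrix:
    """TR x regressor design matrix with labelled columns."""

    values: np.ndarray
    labels: list = field(default_factory=list)
    basis: str = "canonical"
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("one label per regressor required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("regressor labels must be unique")

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _segment_slices(n_trs: int, run_boundaries) -> list:
    """Slices of the TR axis delimited by run boundaries (never crossed)."""
    bounds = list(run_boundaries) if run_boundaries else []
    edges = [0] + [b for b in bounds if 0 < b < n_trs] + [n_trs]
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _convolve_segmented(
    E: np.ndarray, kernel: np.ndarray, segments, circular: bool = False
) -> np.ndarray:
    out = np.zeros_like(E)
    for sl in segments:
        seg = E[sl]
        n = seg.shape[0]
        for j in range(seg.shape[1]):
            full = np.convolve(seg[:, j], kernel)
            y = full[:n].copy()
            if circular:
                # steady-state cyclic stimulation: fold the kernel tail back
                for start in range(n, full.size, n):
                    chunk = full[start : start + n]
                    y[: chunk.size] += chunk
            out[sl, j] = y
    return out


def build_design(
    seq,
    basis: str = "canonical",
    hrf: HRFModel | None = None,
    n_fir_points: int = 20,
    circular: bool = False,
) -> DesignMatrix:
    """Build the design matrix for an event sequence.

    basis 'canonical' -> one HRF-convolved column per fingertip;
    'canonical_plus_derivative' -> each fingertip column followed by its
    temporal-derivative column; 'fir' -> ``5 * n_fir_points`` columns of
    TR-shifted delta regressors (deconvolution design).  Null events
    contribute nothing.  Convolution restarts at every run boundary of a
    concatenated sequence.
    """
    E = seq.event_matrix()
    if not np.any(E):
        raise ValueError("cannot build a design for a sequence with no events")
    segments = _segment_slices(seq.n_trs, getattr(seq, "run_boundaries", None))
    fingers = [f"finger{j}" for j in range(1, 6)]

    if basis == "canonical":
        if hrf is None:
            raise ValueError("canonical basis requires an HRF model")
        X = _convolve_segmented(E, hrf.samples, segments, circular=circular)
        return DesignMatrix(X, fingers, basis="canonical", tr=seq.tr)

    if basis == "canonical_plus_derivative":
        if hrf is None:
            raise ValueError("canonical basis requires an HRF model")
        Xc = _convolve_segmented(E, hrf.samples, segments, circular=circular)
        Xd = _convolve_segmented(E, temporal_derivative(hrf), segments,
                                 circular=circular)
        cols, labels = [], []
        for j in range(5):
            cols += [Xc[:, j], Xd[:, j]]
            labels += [fingers[j], fingers[j] + "_derivative"]
        return DesignMatrix(
            np.stack(cols, axis=1), labels, basis="canonical_plus_derivative", tr=seq.tr
        )

    if basis == "fir":
        n = seq.n_trs
        X = np.zeros((n, 5 * n_fir_points))
        for sl in segments:
            seg = E[sl]
            m = seg.shape[0]
            for j in range(5):
                for k in range(n_fir_points):
                    X[sl.start + k : sl.stop, j * n_fir_points + k] = seg[: m - k, j]
        labels = [
            f"finger{j}_lag{k}" for j in range(1, 6) for k in range(n_fir_points)
        ]
        return DesignMatrix(X, labels, basis="fir", tr=seq.tr)

    raise ValueError(f"unknown basis {basis!r}")


def fir_design_kronecker(seq, n_fir_points: int = 20) -> np.ndarray:
    """FIR design built explicitly as (lagged event matrix) = the Kronecker
    product of the event matrix with an identity of size ``n_fir_points``
    applied along the lag axis.

    Provided as an independent construction of the same matrix as
    ``build_design(..., basis='fir')`` for cross-checking: the stimulus
    convolution matrix of condition j is ``sum_k E[t-k, j] * I[k]``, i.e.
    each event is expanded into an identity block over the following
    ``n_fir_points`` TRs.
    """
    E = seq.event_matrix()
    n = seq.n_trs
    X = np.zeros((n, 5 * n_fir_points))
    eye = np.eye(n_fir_points)
    onset_lists = {}
    for t, j in zip(*np.nonzero(E)):
        onset_lists.setdefault(j, []).append(t)
    for j, onsets in onset_lists.items():
        for t in onsets:
            amp = E[t, j]
            span = min(n_fir_points, n - t)
            X[t : t + span, j * n_fir_points : (j + 1) * n_fir_points] += (
                amp * eye[:span]
            )
    return X
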