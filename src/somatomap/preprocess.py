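"""Timeseries conditioning: percent-signal change, high-pass filtering and
run concatenation.

The high-pass filter is implemented as a discrete-cosine projection: the
component of each voxel timeseries lying in the span of DCT-II basis
functions with frequency below the cutoff (plus the constant) is
regressed out.  This is exact, phase-free, and the standard fMRI drift
model.  Conversion to percent signal change uses the pre-filter run mean
of each voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .er_design import EventSequence

__all__ = [
    "RunTimeseries",
    "dct_basis",
    "highpass_filter",
    "percent_signal_change",
    "concatenate_runs",
]


@dataclass
class RunTimeseries:
    """Voxels x TRs timeseries in raw or percent-signal-change units."""

    values: np.ndarray
    tr: float = 2.0
    units: str = "raw"
    run_boundaries: list = field(default_factory=list)
    mask: np.ndarray | None = None  # False where a voxel was flagged invalid

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_trs(self) -> int:
        return self.values.shape[1]


def dct_basis(n_trs: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """DCT-II cosine regressors with frequency strictly below the cutoff
    (excluding the constant).  Component k has frequency k / (2 * n * TR)."""
    total = n_trs * tr
    ks = []
    k = 1
    while k / (2 * total) < cutoff_hz:
        ks.append(k)
        k += 1
    t = np.arange(n_trs)
    if not ks:
        return np.zeros((n_trs, 0))
    return np.stack(
        [np.cos(np.pi * k * (2 * t + 1) / (2 * n_trs)) for k in ks], axis=1
    )


def highpass_filter(ts: RunTimeseries, cutoff_hz: float = 0.01) -> RunTimeseries:
    """Project out drift components below ``cutoff_hz`` (and the mean),
    independently within each run segment."""
    if cutoff_hz >= 0.5 / ts.tr:
        raise ValueError("cutoff must be below the Nyquist frequency")
    values = ts.values.copy()
    edges = [0] + [b for b in ts.run_boundaries if 0 < b < ts.n_trs] + [ts.n_trs]
    for a, b in zip(edges[:-1], edges[1:]):
        seg = values[:, a:b]
        n = b - a
        B = np.column_stack([np.ones(n), dct_basis(n, ts.tr, cutoff_hz)])
        # mean removed by projection; re-added so PSC conversion stays valid
        mean = seg.mean(axis=1, keepdims=True)
        coef = np.linalg.lstsq(B, seg.T, rcond=None)[0]
        values[:, a:b] = seg - (B @ coef).T + mean
    return RunTimeseries(values, tr=ts.tr, units=ts.units,
                         run_boundaries=list(ts.run_boundaries), mask=ts.mask)


def percent_signal_change(ts: RunTimeseries) -> RunTimeseries:
    """Convert each voxel to 100 * (x - mean) / mean per run segment.

    Voxels whose mean is zero or negative in any segment are flagged in
    the output mask and set to zero.
    """
    values = np.empty_like(ts.values)
    ok = np.ones(ts.n_voxels, dtype=bool)
    edges = [0] + [b for b in ts.run_boundaries if 0 < b < ts.n_trs] + [ts.n_trs]
    for a, b in zip(edges[:-1], edges[1:]):
        seg = ts.values[:, a:b]
        mean = seg.mean(axis=1)
        bad = mean <= 0
        ok &= ~bad
        safe = np.where(bad, 1.0, mean)
        values[:, a:b] = 100.0 * (seg - mean[:, None]) / safe[:, None]
        values[bad, a:b] = 0.0
    mask = ok if ts.mask is None else (ok & ts.mask)
    return RunTimeseries(values, tr=ts.tr, units="percent_signal_change",
                         run_boundaries=list(ts.run_boundaries), mask=mask)


def concatenate_runs(runs, sequences) -> tuple:
    """Concatenate runs time-major and merge their event sequences.

    Event onsets of later runs are offset by the cumulative TR count and
    the run boundaries are recorded on both outputs so that no HRF
    regressor is ever carried across a boundary.
    """
    runs = list(runs)
    sequences = list(sequences)
    if len(runs) != len(sequences):
        raise ValueError("need one event sequence per run")
    if not runs:
        raise ValueError("no runs to concatenate")
    n_vox = runs[0].n_voxels
    tr = runs[0].tr
    if any(r.n_voxels != n_vox for r in runs):
        raise ValueError("voxel counts differ between runs")
    if any(r.tr != tr for r in runs):
        raise ValueError("TR differs between runs")
    if any(s.n_trs != r.n_trs for r, s in zip(runs, sequences)):
        raise ValueError("sequence length does not match its run")

    boundaries = []
    offset = 0
    events = []
    for r, s in zip(runs, sequences):
        if offset:
            boundaries.append(offset)
        events.extend((o + offset, c) for o, c in s.events)
        offset += r.n_trs

    values = np.concatenate([r.values for r in runs], axis=1)
    mask = None
    masks = [r.mask for r in runs if r.mask is not None]
    if masks:
        mask = np.logical_and.reduce(masks)
    ts = RunTimeseries(values, tr=tr, units=runs[0].units,
                       run_boundaries=boundaries, mask=mask)
    seq = EventSequence(events, tr=tr, n_trs=offset,
                        design_kind=sequences[0].design_kind,
                        run_boundaries=boundaries)
    return ts, seq
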