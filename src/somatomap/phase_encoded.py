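"""Traveling-wave (phase-encoded) analysis.

A voxel driven by the cyclic fingertip sweep responds periodically at the
cycle frequency (0.05 Hz for 20-s cycles); the phase of that component
encodes the preferred fingertip.  Averaging a forward run (shifted back k
TRs) with a time-reversed reverse run (shifted back k+1 TRs before
reversal) cancels the hemodynamic lag: the combined response of a voxel
preferring fingertip i peaks at the center of its stimulation window, at
cycle phase (2i-1)*pi/5, for any hemodynamic delay common to both runs.

Phase convention: ``phase = mod(-arg F, 2*pi)`` for the DFT coefficient F
at the cycle frequency, i.e. the cycle position of the cosine peak — a
pure ``cos(2*pi*f*t)`` has phase 0 and a response peaking a quarter cycle
in has phase pi/2.  Coherence is the amplitude at the cycle frequency
relative to the root-sum-square amplitude over all nonzero frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from .preprocess import RunTimeseries

__all__ = [
    "PhaseMapResult",
    "combine_forward_reverse",
    "phase_coherence",
    "coherence_p_value",
    "stagewise_bonferroni",
    "phase_to_fingertip_bin",
    "analyze_phase_encoded",
    "delineate_fingertip_regions",
]

N_FINGERS = 5


def combine_forward_reverse(
    fwd: RunTimeseries, rev: RunTimeseries, k: int
) -> RunTimeseries:
    """Delay-compensated average of forward and reverse phase-encoded runs.

    The forward run is circularly shifted back ``k`` TRs; the reverse run
    is shifted back ``k + 1`` TRs and then time-reversed (the extra TR
    accounts for the half-open sample grid under reversal); the two are
    averaged samplewise.  Shifts are circular because the stimulation is
    cyclic and steady-state.
    """
    if fwd.values.shape != rev.values.shape:
        raise ValueError("forward and reverse runs must have the same shape")
    f = np.roll(fwd.values, -k, axis=1)
    r = np.roll(rev.values, -(k + 1), axis=1)[:, ::-1]
    return RunTimeseries((f + r) / 2.0, tr=fwd.tr, units=fwd.units)


def phase_coherence(ts, period_s: float = 20.0, tr: float = 2.0):
    """Phase (radians in [0, 2*pi)) and coherence ([0, 1]) of the Fourier
    component at 1/period for each voxel.

    ``ts`` may be a RunTimeseries or a voxels x TRs array.  The run
    length must be an integer number of cycles.  Constant rows get
    coherence 0 and phase NaN (flagged undefined).
    """
    if isinstance(ts, RunTimeseries):
        tr = ts.tr
        X = ts.values
    else:
        X = np.atleast_2d(np.asarray(ts, dtype=float))
    n = X.shape[1]
    cycles = n * tr / period_s
    if abs(cycles - round(cycles)) > 1e-9:
        raise ValueError("run length must be an integer number of cycles")
    target = int(round(cycles))
    F = np.fft.rfft(X - X.mean(axis=1, keepdims=True), axis=1)
    amps = np.abs(F[:, 1:])  # exclude DC
    denom = np.sqrt((amps**2).sum(axis=1))
    constant = denom == 0
    coherence = np.zeros(X.shape[0])
    np.divide(np.abs(F[:, target]), denom, out=coherence, where=~constant)
    phase = np.mod(-np.angle(F[:, target]), 2 * np.pi)
    phase[constant] = np.nan
    return phase, coherence


def coherence_p_value(coherence, n_samples: int):
    """p-value for coherence under independent Gaussian noise.

    Equivalent to the F test of the sine+cosine regression at the target
    frequency: F = (C^2/2) / ((1-C^2)/(n-3)) on (2, n-3) degrees of
    freedom; p decreases monotonically in C.
    """
    if n_samples <= 3:
        raise ValueError("need more than 3 samples")
    C = np.asarray(coherence, dtype=float)
    C2 = np.clip(C**2, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (C2 / 2.0) / ((1.0 - C2) / (n_samples - 3))
    p = f_dist.sf(F, 2, n_samples - 3)
    return np.where(C2 >= 1.0, 0.0, p)


def stagewise_bonferroni(p_values, alpha: float = 0.05):
    """Hochberg step-up rejection mask: sort p ascending and reject all
    hypotheses up to the largest i with p_(i) <= alpha / (m - i + 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(p, alpha=alpha, method="simes-hochberg")
    return reject


def phase_to_fingertip_bin(phase) -> np.ndarray:
    """Bin phases into five 2*pi/5-wide fingertip bins over [0, 2*pi).

    Fingertip i's ideal phase (2i-1)*pi/5 is the center of bin i."""
    phase = np.asarray(phase, dtype=float)
    b = np.floor(np.mod(phase, 2 * np.pi) / (2 * np.pi / N_FINGERS)).astype(int) + 1
    return np.clip(b, 1, N_FINGERS)


@dataclass
class PhaseMapResult:
    """Voxelwise phase map with inference results."""

    phase: np.ndarray
    coherence: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    fingertip_bin: np.ndarray  # 1..5, 0 where not significant or undefined


def analyze_phase_encoded(
    fwd,
    rev,
    k: int = 1,
    period_s: float = 20.0,
    alpha: float = 0.05,
) -> PhaseMapResult:
    """Full phase-encoded pipeline: combine runs, Fourier phase/coherence,
    Hochberg-corrected inference, fingertip binning.

    ``fwd``/``rev`` may be single runs or equal-length lists of runs;
    multiple forward/reverse pairs are combined pairwise and averaged
    samplewise (runs aggregated across sessions).
    """
    if not isinstance(fwd, (list, tuple)):
        fwd, rev = [fwd], [rev]
    if len(fwd) != len(rev):
        raise ValueError("need matching numbers of forward and reverse runs")
    pairs = [combine_forward_reverse(f, r, k) for f, r in zip(fwd, rev)]
    combined = RunTimeseries(
        np.mean([p.values for p in pairs], axis=0), tr=pairs[0].tr,
        units=pairs[0].units,
    )
    phase, coherence = phase_coherence(combined, period_s=period_s)
    valid = np.isfinite(phase)
    p = np.ones_like(coherence)
    p[valid] = coherence_p_value(coherence[valid], combined.n_trs)
    significant = np.zeros_like(valid)
    if valid.any():
        significant[valid] = stagewise_bonferroni(p[valid], alpha=alpha)
    bins = np.zeros(phase.shape, dtype=int)
    bins[significant] = phase_to_fingertip_bin(phase[significant])
    return PhaseMapResult(phase, coherence, p, significant, bins)


@dataclass
class FingertipRegion:
    """A contiguous cluster of voxels preferring one fingertip."""

    fingertip: int
    voxel_indices: np.ndarray  # flat indices into the grid
    centroid: tuple  # (row, col)

    @property
    def size(self) -> int:
        return self.voxel_indices.size


def delineate_fingertip_regions(
    pm: PhaseMapResult,
    grid_shape: tuple,
    somatotopic_axis: int = 0,
    min_size: int = 1,
    mask: np.ndarray | None = None,
) -> list:
    """Delineate one ordered fingertip region per phase bin.

    Suprathreshold voxels of each bin are split into 4-connected
    components; among all candidate clusters, the chain maximizing total
    voxel count subject to (a) one cluster per fingertip bin, (b) cluster
    centroids strictly increasing along the somatotopic axis with bin
    number, is retained.  Isolated clusters breaking the inferior-to-
    superior progression are dropped.  ``mask`` optionally restricts the
    search to one somatotopic representation (e.g. the postcentral or the
    precentral voxels).  May return an empty list.
    """
    bins = pm.fingertip_bin.reshape(grid_shape).copy()
    if mask is not None:
        bins[~np.asarray(mask, dtype=bool).reshape(grid_shape)] = 0
    candidates = []  # (fingertip, centroid_coord, size, flat_indices)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for f in range(1, N_FINGERS + 1):
        lab, n_lab = ndimage.label(bins == f, structure=structure)
        for li in range(1, n_lab + 1):
            idx = np.nonzero(lab == li)
            if idx[0].size < min_size:
                continue
            centroid = (idx[0].mean(), idx[1].mean())
            flat = np.ravel_multi_index(idx, grid_shape)
            candidates.append((f, centroid[somatotopic_axis], idx[0].size, flat,
                               centroid))
    if not candidates:
        return []

    # dynamic program: heaviest chain with increasing (fingertip, position)
    candidates.sort(key=lambda c: (c[0], c[1]))
    best_w = [c[2] for c in candidates]
    parent = [-1] * len(candidates)
    for i, ci in enumerate(candidates):
        for j in range(i):
            cj = candidates[j]
            if cj[0] < ci[0] and cj[1] < ci[1]:
                if best_w[j] + ci[2] > best_w[i]:
                    best_w[i] = best_w[j] + ci[2]
                    parent[i] = j
    end = int(np.argmax(best_w))
    chain = []
    while end != -1:
        chain.append(candidates[end])
        end = parent[end]
    chain.reverse()
    return [
        FingertipRegion(f, flat, centroid)
        for f, _, _, flat, centroid in chain
    ]
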