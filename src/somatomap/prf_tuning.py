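"""Gaussian population-receptive-field (pRF) fitting, recentered ROI
tuning curves, FWHM estimation, and cortical-magnification distances.

A voxel's tuning curve (five GLM amplitudes, one per fingertip) is fitted
with a Gaussian over fingertip index: free center in [0.5, 5.5], free
spread up to 30 fingertip units, free nonnegative amplitude (betas are
unnormalized percent signal change).  FWHM = sigma * 2*sqrt(2*ln 2)
(~2.355 * sigma) everywhere.

ROI tuning curves recenter each voxel's five betas on a voxelwise
preferred fingertip BEFORE averaging, yielding a 9-point curve over
offsets -4..+4.  The preference used for recentering must come from an
independent dataset (the phase-encoded map): recentering on the argmax of
the same betas recenters noise peaks and manufactures spurious tuning
(circularity bias).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FWHM_FACTOR",
    "PRFFit",
    "TuningCurve",
    "fit_voxel_prf",
    "fit_prf_map",
    "recenter_and_average",
    "fit_tuning_fwhm",
    "cortical_distances",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548

CENTER_BOUNDS = (0.5, 5.5)
SIGMA_MAX = 30.0
_FINGERS = np.arange(1.0, 6.0)


@dataclass
class PRFFit:
    """Gaussian pRF parameters for one voxel (or one ROI curve)."""

    center: float
    sigma: float
    amplitude: float
    rss: float
    responsive: bool = True

    @property
    def fwhm(self) -> float:
        return self.sigma * FWHM_FACTOR


def _gauss(f, center, sigma):
    return np.exp(-0.5 * ((f - center) / sigma) ** 2)


def _profiled_amplitude(curve, g, nonnegative=True):
    denom = g @ g
    if denom == 0:
        return 0.0
    a = float(curve @ g / denom)
    return max(a, 0.0) if nonnegative else a


def fit_voxel_prf(curve, multistart_centers=None, multistart_sigmas=None) -> PRFFit:
    """Bounded nonlinear least squares of ``a * G(f; center, sigma)`` to a
    5-point tuning curve.

    The amplitude is profiled out (closed-form optimum given the Gaussian
    shape), leaving a 2-parameter problem solved from a deterministic
    multi-start grid; the best-RSS solution is returned.  An all-zero
    curve is flagged non-responsive and not fitted.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.shape != (5,) or not np.all(np.isfinite(curve)):
        raise ValueError("curve must be 5 finite values")
    if np.all(curve == 0):
        return PRFFit(np.nan, np.nan, 0.0, 0.0, responsive=False)

    if multistart_centers is None:
        multistart_centers = np.arange(1.0, 5.5, 0.5)
    if multistart_sigmas is None:
        multistart_sigmas = np.array([0.3, 1.0, 3.0, 10.0, 30.0])

    def residuals(theta):
        c, s = theta
        g = _gauss(_FINGERS, c, s)
        a = _profiled_amplitude(curve, g)
        return a * g - curve

    # coarse grid pre-selection keeps the solver count small
    best_starts = []
    for c0 in multistart_centers:
        for s0 in multistart_sigmas:
            r = residuals((c0, s0))
            best_starts.append(((r @ r), (c0, s0)))
    best_starts.sort(key=lambda t: t[0])

    best = None
    for _, x0 in best_starts[:4]:
        sol = least_squares(
            residuals,
            x0=np.array(x0),
            bounds=([CENTER_BOUNDS[0], 1e-3], [CENTER_BOUNDS[1], SIGMA_MAX]),
            method="trf",
        )
        rss = float(2 * sol.cost)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, sol.x)
    rss, (c, s) = best
    g = _gauss(_FINGERS, c, s)
    a = _profiled_amplitude(curve, g)
    return PRFFit(float(c), float(s), a, rss)


def fit_prf_map(betas: np.ndarray) -> list:
    """Fit every row of a voxels x 5 beta matrix; returns a list of
    PRFFit."""
    return [fit_voxel_prf(row) for row in np.asarray(betas, dtype=float)]


@dataclass
class TuningCurve:
    """Positionwise-averaged tuning curve.

    Recentered curves span offsets -4..+4 (9 points); edge positions
    average fewer voxels.
    """

    positions: np.ndarray
    values: np.ndarray
    n_voxels: np.ndarray
    sem: np.ndarray | None = None


def recenter_and_average(betas: np.ndarray, preferred, roi=None) -> TuningCurve:
    """Average voxel tuning curves after recentering on the preferred
    fingertip.

    ``betas`` is voxels x 5; ``preferred`` gives each voxel's preferred
    fingertip (1..5), which must be derived from data independent of
    ``betas`` for the average to be unbiased.  ``roi`` optionally
    restricts to a set of voxel indices.
    """
    betas = np.asarray(betas, dtype=float)
    preferred = np.asarray(preferred, dtype=int)
    if roi is not None:
        idx = np.asarray(getattr(roi, "voxel_indices", roi), dtype=int)
        if idx.size == 0:
            raise ValueError("empty ROI")
        betas = betas[idx]
        preferred = preferred[idx]
    positions = np.arange(-4, 5)
    sums = np.zeros(9)
    sq = np.zeros(9)
    counts = np.zeros(9, dtype=int)
    offsets = _FINGERS[None, :].astype(int) - preferred[:, None]  # voxels x 5
    for off, val in zip(offsets.ravel(), betas.ravel()):
        k = off + 4
        sums[k] += val
        sq[k] += val * val
        counts[k] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(counts > 1,
                       (sq - counts * mean**2) / np.maximum(counts - 1, 1), np.nan)
        sem = np.sqrt(var / np.maximum(counts, 1))
    return TuningCurve(positions, mean, counts, sem)


def fit_tuning_fwhm(curve: TuningCurve, variant: str = "sigma_floor"):
    """Gaussian fit to a recentered ROI tuning curve; returns
    ``(fwhm, params)``.

    The Gaussian is centered at offset 0 (the curve is recentered by
    construction) with free amplitude and spread.  Variants:

    * 'sigma_floor'        -- spread bounded below at 0.4 fingertip units
      (no upper bound), no offset term (ROI-comparison fit).
    * 'offset_nonpositive' -- free spread > 0 plus an offset restricted
      to <= 0, absorbing below-baseline responses (design-comparison
      fit).
    """
    vals = np.asarray(curve.values, dtype=float)
    pos = np.asarray(curve.positions, dtype=float)
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError("tuning curve has no finite values")
    vals, pos = vals[ok], pos[ok]

    if variant == "sigma_floor":
        def residuals(theta):
            a, s = theta
            return a * _gauss(pos, 0.0, s) - vals
        x0 = np.array([max(vals.max(), 1e-3), 1.0])
        sol = least_squares(residuals, x0, bounds=([0.0, 0.4], [np.inf, np.inf]))
        a, s = sol.x
        params = {"amplitude": float(a), "sigma": float(s), "offset": 0.0}
    elif variant == "offset_nonpositive":
        def residuals(theta):
            a, s, b = theta
            return a * _gauss(pos, 0.0, s) + b - vals
        x0 = np.array([max(vals.max(), 1e-3), 1.0, min(0.0, float(vals.min()))])
        sol = least_squares(
            residuals, x0, bounds=([0.0, 1e-3, -np.inf], [np.inf, np.inf, 0.0])
        )
        a, s, b = sol.x
        params = {"amplitude": float(a), "sigma": float(s), "offset": float(b)}
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return params["sigma"] * FWHM_FACTOR, params


# ---------------------------------------------------------------------------
# cortical magnification
# ---------------------------------------------------------------------------


def _center_line(flat_indices, grid_shape, somatotopic_axis=0):
    """Center line of an ROI: for each position along the axis orthogonal
    to the somatotopic axis, the median cell of the ROI along the
    somatotopic axis (a line through the ROI perpendicular to the
    somatotopic gradient)."""
    coords = np.stack(np.unravel_index(np.asarray(flat_indices, int), grid_shape))
    other = 1 - somatotopic_axis
    line = []
    for v in np.unique(coords[other]):
        sel = coords[:, coords[other] == v]
        med = int(np.median(sel[somatotopic_axis]))
        cell = [0, 0]
        cell[somatotopic_axis] = med
        cell[other] = int(v)
        line.append(tuple(cell))
    return line


def cortical_distances(
    fingertip_rois,
    grid_shape,
    spacing: float = 1.0,
    somatotopic_axis: int = 0,
) -> list:
    """Mean grid-graph distances between consecutive fingertip regions.

    For each region a center line perpendicular to the somatotopic axis
    is drawn; the distance for a consecutive fingertip pair is the
    symmetric mean nearest-vertex 4-connected grid-graph shortest-path
    length between the two lines (each line vertex contributes its
    geodesic distance to the closest vertex of the other line; the two
    directed means are averaged), in units of ``spacing``.  Two parallel
    stripes d rows apart are therefore exactly d*spacing apart.  Pairs
    with a missing region are reported as NaN.  Returns four values
    (pairs 1-2, 2-3, 3-4, 4-5).
    """
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import dijkstra

    if not isinstance(fingertip_rois, dict):
        fingertip_rois = {r.fingertip: r.voxel_indices for r in fingertip_rois}
    present = {f: v for f, v in fingertip_rois.items()
               if np.asarray(v).size > 0}
    if len(present) < 2:
        raise ValueError("need at least two fingertip regions")

    n_rows, n_cols = grid_shape
    n = n_rows * n_cols
    adj = lil_matrix((n, n))
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if r + 1 < n_rows:
                adj[i, i + n_cols] = 1.0
                adj[i + n_cols, i] = 1.0
            if c + 1 < n_cols:
                adj[i, i + 1] = 1.0
                adj[i + 1, i] = 1.0
    adj = adj.tocsr()

    lines = {
        f: [r * n_cols + c for r, c in _center_line(v, grid_shape, somatotopic_axis)]
        for f, v in present.items()
    }
    out = []
    for f in range(1, 5):
        if f not in lines or (f + 1) not in lines:
            out.append(np.nan)
            continue
        src = lines[f]
        dst = lines[f + 1]
        dmat = dijkstra(adj, indices=src, unweighted=False)[:, dst]
        forward = dmat.min(axis=1).mean()  # each src vertex -> nearest dst
        backward = dmat.min(axis=0).mean()  # each dst vertex -> nearest src
        out.append(float(0.5 * (forward + backward) * spacing))
    return out
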