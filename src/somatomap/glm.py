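"""Two-step voxelwise GLM: FIR deconvolution, participant HRF, fingertip
amplitudes, contrasts, FDR, and an HRF-delay proxy.

Step 1 deconvolves each voxel's response to each fingertip with a
20-point FIR basis (one free value per post-stimulus TR over 40 s).
Averaging the dominant-fingertip FIR estimates across the five
phase-encoded fingertip regions gives the participant's average HRF,
normalized to unit integral.  Step 2 refits a canonical GLM using that
HRF as the basis, yielding one amplitude per fingertip per voxel (the
voxel's tuning curve, in percent signal change).

Ordinary least squares with homoscedastic voxelwise variance is used
throughout (noise is simulated white; no prewhitening).  Per-run
intercept columns are appended for concatenated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .er_design import EventSequence, N_FINGERS
from .hemodynamics import DesignMatrix, HRFModel, build_design, double_gamma_hrf
from .preprocess import RunTimeseries

__all__ = [
    "GLMResult",
    "ParticipantHRF",
    "fit_glm",
    "estimate_voxel_hrfs",
    "participant_average_hrf",
    "fingertip_amplitudes",
    "compute_contrasts",
    "fdr_step_up",
    "delay_ratio",
]


@dataclass
class GLMResult:
    """OLS fit: betas, standard errors and residual variance per voxel."""

    betas: np.ndarray  # voxels x regressors
    beta_se: np.ndarray
    sigma2: np.ndarray  # residual variance per voxel
    dof: int
    labels: list
    xtx_inv: np.ndarray

    def finger_betas(self) -> np.ndarray:
        """The five fingertip columns (excludes nuisance regressors)."""
        idx = [i for i, l in enumerate(self.labels) if l.startswith("finger")
               and "derivative" not in l]
        return self.betas[:, idx]


@dataclass
class ParticipantHRF:
    """Average HRF over fingertip regions, unit integral (sum * TR == 1)."""

    samples: np.ndarray
    tr: float = 2.0

    def as_model(self) -> HRFModel:
        return HRFModel(self.samples, self.tr, kind="empirical",
                        normalization="unit_integral")


def _add_run_intercepts(X: DesignMatrix, run_boundaries, n_trs: int):
    edges = [0] + [b for b in (run_boundaries or []) if 0 < b < n_trs] + [n_trs]
    cols, labels = [], []
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        c = np.zeros(n_trs)
        c[a:b] = 1.0
        cols.append(c)
        labels.append(f"intercept_run{i}")
    return np.column_stack([X.values] + cols), list(X.labels) + labels


def fit_glm(ts: RunTimeseries, X, labels=None, add_intercepts=True) -> GLMResult:
    """Voxelwise ordinary least squares.

    ``X`` may be a DesignMatrix (per-run intercepts appended unless
    ``add_intercepts=False``) or a plain array (used as-is with
    ``labels``).  Raises on rank deficiency, naming offending columns.
    """
    if isinstance(X, DesignMatrix):
        if X.n_trs != ts.n_trs:
            raise ValueError("design and timeseries TR counts differ")
        if add_intercepts:
            M, labels = _add_run_intercepts(X, ts.run_boundaries, ts.n_trs)
        else:
            M, labels = X.values, list(X.labels)
    else:
        M = np.asarray(X, dtype=float)
        labels = list(labels) if labels else [f"x{i}" for i in range(M.shape[1])]
    n, p = M.shape
    rank = np.linalg.matrix_rank(M)
    if rank < p:
        q, r = np.linalg.qr(M)
        bad = [labels[i] for i in range(p) if abs(r[i, i]) < 1e-10 * abs(r).max()]
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {p}); "
            f"suspect columns: {bad or 'unknown'}"
        )
    xtx_inv = np.linalg.inv(M.T @ M)
    betas = ts.values @ M @ xtx_inv  # (voxels, p)
    resid = ts.values - betas @ M.T
    dof = n - p
    sigma2 = (resid**2).sum(axis=1) / dof
    beta_se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    return GLMResult(betas, beta_se, sigma2, dof, labels, xtx_inv)


def estimate_voxel_hrfs(
    ts: RunTimeseries, seq: EventSequence, n_points: int = 20
):
    """Step 1: FIR deconvolution GLM.

    Returns ``(hrfs, result)`` where ``hrfs`` is (voxels, 5, n_points):
    the estimated response of each voxel to each fingertip over
    ``n_points`` TRs.
    """
    X = build_design(seq, "fir", n_fir_points=n_points)
    res = fit_glm(ts, X)
    hrfs = res.betas[:, : 5 * n_points].reshape(ts.n_voxels, N_FINGERS, n_points)
    return hrfs, res


def participant_average_hrf(
    voxel_hrfs: np.ndarray,
    fingertip_regions,
    tr: float = 2.0,
) -> ParticipantHRF:
    """Average the dominant-fingertip FIR response across fingertip
    regions and normalize to unit integral.

    ``fingertip_regions`` maps fingertip number (1..5) to voxel indices
    (dict, or a list of objects with ``fingertip``/``voxel_indices``).
    Empty regions are skipped with a warning; all-empty is an error.
    """
    import warnings

    if not isinstance(fingertip_regions, dict):
        fingertip_regions = {
            r.fingertip: r.voxel_indices for r in fingertip_regions
        }
    curves = []
    for f, vox in sorted(fingertip_regions.items()):
        vox = np.asarray(vox, dtype=int)
        if vox.size == 0:
            warnings.warn(f"fingertip region {f} is empty; excluded")
            continue
        curves.append(voxel_hrfs[vox, f - 1, :].mean(axis=0))
    if not curves:
        raise ValueError("all fingertip regions are empty")
    h = np.mean(curves, axis=0)
    area = h.sum() * tr
    if area == 0:
        raise ValueError("average HRF has zero integral")
    return ParticipantHRF(h / area, tr=tr)


def fingertip_amplitudes(
    ts: RunTimeseries, seq: EventSequence, hrf
) -> GLMResult:
    """Step 2: canonical GLM with the participant HRF as basis; returns
    one amplitude (percent signal change) per fingertip per voxel."""
    model = hrf.as_model() if isinstance(hrf, ParticipantHRF) else hrf
    X = build_design(seq, "canonical", model)
    return fit_glm(ts, X)


def compute_contrasts(res: GLMResult, kind: str):
    """Contrast statistic and p-value maps from a step-2 GLM.

    kind 'preference' -> five one-sided t maps of e_i - mean(others);
    'activation' -> five one-sided t maps of e_i vs baseline;
    'main_effect_F' -> F map for any fingertip difference (4 dof);
    'any_positive_F' -> F map for any nonzero fingertip response (5 dof).
    Returns ``(stats, p_values)`` with leading voxel axis.
    """
    finger_idx = [i for i, l in enumerate(res.labels)
                  if l.startswith("finger") and "derivative" not in l]
    p_total = res.betas.shape[1]

    def row(c5):
        c = np.zeros(p_total)
        c[finger_idx] = c5
        return c

    if kind in ("preference", "activation"):
        tmaps, pmaps = [], []
        for i in range(N_FINGERS):
            c5 = np.zeros(N_FINGERS)
            if kind == "preference":
                c5[:] = -0.25
                c5[i] = 1.0
            else:
                c5[i] = 1.0
            c = row(c5)
            var = res.sigma2 * float(c @ res.xtx_inv @ c)
            t = (res.betas @ c) / np.sqrt(var)
            pv = stats.t.sf(t, res.dof)  # one-sided, positive direction
            tmaps.append(t)
            pmaps.append(pv)
        return np.stack(tmaps, axis=1), np.stack(pmaps, axis=1)

    if kind == "main_effect_F":
        C = np.stack([row(np.eye(N_FINGERS)[i] - np.eye(N_FINGERS)[i + 1])
                      for i in range(N_FINGERS - 1)])
    elif kind == "any_positive_F":
        C = np.stack([row(np.eye(N_FINGERS)[i]) for i in range(N_FINGERS)])
    else:
        raise ValueError(f"unknown contrast kind {kind!r}")

    q = C.shape[0]
    mid = np.linalg.inv(C @ res.xtx_inv @ C.T)
    cb = res.betas @ C.T  # voxels x q
    F = np.einsum("vq,qr,vr->v", cb, mid, cb) / (q * res.sigma2)
    pv = stats.f.sf(F, q, res.dof)
    return F, pv


def fdr_step_up(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(reject, p_adjusted)`` where adjusted p-values are the
    monotone envelope of m * p_(i) / i.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def delay_ratio(
    ts: RunTimeseries, seq: EventSequence, canonical_hrf: HRFModel | None = None
) -> np.ndarray:
    """Derivative-to-canonical beta ratio, an HRF-delay proxy.

    Larger (more positive) values correspond to a shorter hemodynamic
    delay.  The ratio averages the per-fingertip derivative/canonical
    beta pairs weighted by the canonical betas; voxels whose summed
    canonical beta is non-positive are masked (NaN).
    """
    if canonical_hrf is None:
        canonical_hrf = double_gamma_hrf(dt=seq.tr)
    X = build_design(seq, "canonical_plus_derivative", canonical_hrf)
    res = fit_glm(ts, X)
    can_idx = [i for i, l in enumerate(res.labels)
               if l.startswith("finger") and "derivative" not in l]
    der_idx = [i for i, l in enumerate(res.labels) if l.endswith("derivative")]
    can = res.betas[:, can_idx].sum(axis=1)
    der = res.betas[:, der_idx].sum(axis=1)
    ratio = np.full(ts.n_voxels, np.nan)
    ok = can > 0
    ratio[ok] = der[ok] / can[ok]
    return ratio
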