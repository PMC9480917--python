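"""Event-related (ER) stimulation sequences and design efficiency.

Three run types are generated, all TR-locked (TR = 2 s, 126 TRs = 252 s
acquisitions by default), for vibrotactile stimulation of the five
fingertips (condition 1 = thumb ... 5 = pinky, 0 = null event):

* fast ER   -- 126 consecutive events (90 stimulations + 36 nulls),
  randomized in six blocks of 21 events each containing exactly 6 nulls
  and 3 events per fingertip; rate-based average ITI between
  stimulations = 2.8 s.
* slow ER   -- 30 events (6 per fingertip), onset-to-onset gaps drawn
  uniformly from {2..6} TRs (4-12 s), no fingertip repeated in
  consecutive events; average ITI ~ 8 s.
* phase-encoded -- each fingertip stimulated for 2 consecutive TRs (4 s)
  in order, 20-s cycles repeated 9 times, forward (thumb->pinky) or
  reverse.

Design efficiency of a sequence for a set of contrasts C_i is

    efficiency = 1 / [ (1/K) * sum_i Tr( C_i (X'X)^-1 C_i' ) ]

i.e. the reciprocal of the average variance of the OLS contrast
estimates under unit-variance white noise.  Detection efficiency uses
the canonical-HRF-convolved design with the five fingertip-vs-baseline
contrasts; HRF-estimation efficiency replaces the convolved design with
the FIR stimulus-convolution design (event matrix (x) identity) and
selection contrasts per fingertip; difference-detection efficiency
averages the 10 pairwise fingertip contrasts on the canonical design.
A constant baseline column is appended to the design by default (the
contrasts do not touch it); without it the advantage of including null
events disappears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hemodynamics import HRFModel, double_gamma_hrf

__all__ = [
    "EventSequence",
    "EfficiencyReport",
    "generate_fast_er_sequence",
    "generate_fully_randomized_fast_er_sequence",
    "generate_no_null_fast_er_sequence",
    "generate_slow_er_sequence",
    "generate_phase_encoded_sequence",
    "mean_stimulation_iti",
    "contrast_efficiency",
    "detection_contrasts",
    "pairwise_difference_contrasts",
    "fir_selection_contrasts",
    "design_efficiencies",
    "batch_detection_efficiency",
    "optimize_fast_er",
]

DEFAULT_TR = 2.0
DEFAULT_N_TRS = 126
N_FINGERS = 5


@dataclass
class EventSequence:
    """Timed fingertip/null events for one run (or concatenated runs).

    ``events`` is an ordered list of ``(onset_TR, condition)`` with
    condition in {0..5}, 0 meaning a null event.  Onsets are strictly
    increasing and coincide with volume acquisitions.
    """

    events: list
    tr: float = DEFAULT_TR
    n_trs: int = DEFAULT_N_TRS
    design_kind: str = "fast_er"
    run_boundaries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [int(o) for o, _ in self.events]
        conds = [int(c) for _, c in self.events]
        if any(o1 >= o2 for o1, o2 in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] >= self.n_trs):
            raise ValueError("event onsets must lie in [0, n_TRs)")
        if any(c < 0 or c > N_FINGERS for c in conds):
            raise ValueError("conditions must be in {0..5}")
        self.events = list(zip(onsets, conds))

    # -- accessors ---------------------------------------------------------

    @property
    def onsets(self) -> np.ndarray:
        return np.array([o for o, _ in self.events], dtype=int)

    @property
    def conditions(self) -> np.ndarray:
        return np.array([c for _, c in self.events], dtype=int)

    def stimulation_events(self) -> np.ndarray:
        """Onsets of non-null events, in TRs."""
        return np.array([o for o, c in self.events if c > 0], dtype=int)

    def event_matrix(self, unit_area: bool = True) -> np.ndarray:
        """n_TRs x 5 impulse matrix; amplitude TR (unit impulse area) by
        default, 1 otherwise.  Null events contribute nothing."""
        E = np.zeros((self.n_trs, N_FINGERS))
        amp = self.tr if unit_area else 1.0
        for o, c in self.events:
            if c > 0:
                E[o, c - 1] = amp
        return E

    def condition_counts(self) -> dict:
        counts = {c: 0 for c in range(N_FINGERS + 1)}
        for _, c in self.events:
            counts[c] += 1
        return counts

    # -- serialization -----------------------------------------------------

    def to_dataframe(self, duration_s: float = 0.8) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [o * self.tr for o, _ in self.events],
                "duration_s": duration_s,
                "condition": [c for _, c in self.events],
            }
        )

    def to_tsv(self, path, duration_s: float = 0.8) -> None:
        self.to_dataframe(duration_s).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tr: float = DEFAULT_TR, n_trs: int = DEFAULT_N_TRS,
                 design_kind: str = "unknown") -> "EventSequence":
        df = pd.read_csv(path, sep="\t")
        events = [
            (int(round(o / tr)), int(c))
            for o, c in zip(df["onset_s"], df["condition"])
        ]
        return cls(events, tr=tr, n_trs=n_trs, design_kind=design_kind)


@dataclass
class EfficiencyReport:
    """The three efficiency figures of merit for one sequence."""

    detection: float
    hrf_estimation: float
    difference_detection: float


# ---------------------------------------------------------------------------
# sequence generators
# ---------------------------------------------------------------------------

_FAST_BLOCK = np.array([0] * 6 + list(range(1, N_FINGERS + 1)) * 3)


def generate_fast_er_sequence(
    seed: int, n_blocks: int = 6, tr: float = DEFAULT_TR
) -> EventSequence:
    """Block-randomized fast ER run: ``n_blocks`` blocks of 21 consecutive
    events, each an independent permutation of 6 nulls + 3 events per
    fingertip."""
    rng = np.random.default_rng(seed)
    conds = np.concatenate([rng.permutation(_FAST_BLOCK) for _ in range(n_blocks)])
    events = list(zip(range(conds.size), conds.tolist()))
    return EventSequence(events, tr=tr, n_trs=conds.size, design_kind="fast_er")


def generate_fully_randomized_fast_er_sequence(
    seed: int, tr: float = DEFAULT_TR
) -> EventSequence:
    """Same event multiset as the fast ER run (90 stimulations + 36 nulls)
    shuffled uniformly over the whole run instead of per block."""
    rng = np.random.default_rng(seed)
    conds = rng.permutation(np.repeat(np.arange(N_FINGERS + 1), (36, 18, 18, 18, 18, 18)))
    events = list(zip(range(conds.size), conds.tolist()))
    return EventSequence(events, tr=tr, n_trs=conds.size, design_kind="fast_er_fullrand")


def generate_no_null_fast_er_sequence(
    seed: int, tr: float = DEFAULT_TR
) -> EventSequence:
    """Fast ER variant without null events: every TR carries one of 18
    stimulations per fingertip (90 TRs of uninterrupted stimulation)."""
    rng = np.random.default_rng(seed)
    conds = rng.permutation(np.array(list(range(1, N_FINGERS + 1)) * 18))
    events = list(zip(range(conds.size), conds.tolist()))
    return EventSequence(events, tr=tr, n_trs=conds.size, design_kind="fast_er_nonull")


def generate_slow_er_sequence(
    seed: int,
    n_trs: int = DEFAULT_N_TRS,
    tr: float = DEFAULT_TR,
    max_attempts: int = 10_000,
) -> EventSequence:
    """Slow ER run: 30 events (6 per fingertip), onset-to-onset gaps drawn
    uniformly from {2..6} TRs, no consecutive repeat of a fingertip, whole
    sequence rejection-sampled to fit inside ``n_trs``."""
    n_events = 6 * N_FINGERS
    if n_trs < 2 * (n_events - 1) + 1:
        raise ValueError(
            f"n_trs={n_trs} cannot admit {n_events} events with minimum 2-TR gaps"
        )
    rng = np.random.default_rng(seed)
    labels_pool = np.array(list(range(1, N_FINGERS + 1)) * 6)
    for _ in range(max_attempts):
        gaps = rng.integers(2, 7, size=n_events - 1)
        onsets = np.concatenate([[0], np.cumsum(gaps)])
        if onsets[-1] >= n_trs:
            continue
        labels = rng.permutation(labels_pool)
        if np.any(labels[1:] == labels[:-1]):
            continue
        events = list(zip(onsets.tolist(), labels.tolist()))
        return EventSequence(events, tr=tr, n_trs=n_trs, design_kind="slow_er")
    raise RuntimeError(
        f"could not draw a slow ER sequence satisfying the gap and no-repeat "
        f"constraints within {max_attempts} attempts for n_trs={n_trs}"
    )


def generate_phase_encoded_sequence(
    direction: str = "forward",
    n_cycles: int = 9,
    tr: float = DEFAULT_TR,
) -> EventSequence:
    """Phase-encoded localizer: each fingertip stimulated for 2 consecutive
    TRs (4 s) per 20-s cycle; forward = thumb->pinky, reverse = the
    opposite."""
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    order = list(range(1, N_FINGERS + 1))
    if direction == "reverse":
        order = order[::-1]
    cycle = [c for c in order for _ in range(2)]
    conds = cycle * n_cycles
    events = list(zip(range(len(conds)), conds))
    kind = "phase_fwd" if direction == "forward" else "phase_rev"
    return EventSequence(events, tr=tr, n_trs=len(conds), design_kind=kind)


def mean_stimulation_iti(seq: EventSequence, circular: bool | None = None) -> float:
    """Mean onset-to-onset interval between stimulation (non-null) events,
    in seconds.

    For steady-state designs whose events tile the whole run (fast ER,
    phase-encoded) the cyclic convention is used by default: the
    wrap-around gap closes the run, so the mean equals
    ``n_TRs * TR / n_stimulations`` exactly (the rate-based average the
    run is designed for).  For sparse designs (slow ER) the plain mean of
    the sampled gaps is used.
    """
    st = seq.stimulation_events()
    if st.size < 2:
        raise ValueError("need at least two stimulation events")
    if circular is None:
        circular = seq.design_kind.startswith(("fast_er", "phase"))
    gaps = np.diff(st).astype(float)
    if circular:
        wrap = seq.n_trs - st[-1] + st[0]
        gaps = np.concatenate([gaps, [wrap]])
    return float(gaps.mean() * seq.tr)


# ---------------------------------------------------------------------------
# efficiency
# ---------------------------------------------------------------------------


def contrast_efficiency(X: np.ndarray, contrasts) -> float:
    """Reciprocal of the mean contrast-estimate variance trace.

    ``efficiency = 1 / [ (1/K) * sum_i Tr( C_i (X'X)^-1 C_i' ) ]`` where
    each C_i has one column per regressor of X (row vectors allowed).
    Scale-equivariant: scaling X by a scales the result by a**2.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    XtX = X.T @ X
    p = X.shape[1]
    if np.linalg.matrix_rank(XtX) < p:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; X'X is singular"
        )
    inv = np.linalg.inv(XtX)
    traces = []
    for C in contrasts:
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[1] != p:
            raise ValueError(
                f"contrast has {C.shape[1]} columns, design has {p} regressors"
            )
        traces.append(np.trace(C @ inv @ C.T))
    return float(1.0 / np.mean(traces))


def _pad(C: np.ndarray, p: int) -> np.ndarray:
    """Zero-pad contrast columns up to p regressors (baseline columns)."""
    C = np.atleast_2d(C)
    out = np.zeros((C.shape[0], p))
    out[:, : C.shape[1]] = C
    return out


def detection_contrasts(p: int) -> list:
    """Five fingertip-vs-baseline row contrasts, padded to p columns."""
    return [_pad(np.eye(N_FINGERS)[i], p) for i in range(N_FINGERS)]


def pairwise_difference_contrasts(p: int) -> list:
    """The 10 pairwise fingertip-difference row contrasts."""
    out = []
    for i in range(N_FINGERS):
        for j in range(i + 1, N_FINGERS):
            c = np.zeros(N_FINGERS)
            c[i], c[j] = 1.0, -1.0
            out.append(_pad(c, p))
    return out


def fir_selection_contrasts(p: int, n_fir_points: int = 20) -> list:
    """Per-fingertip block-selection contrasts on the FIR design: contrast
    i selects the ``n_fir_points`` deconvolution regressors of fingertip
    i (an identity block), padded to p columns."""
    out = []
    for i in range(N_FINGERS):
        C = np.zeros((n_fir_points, p))
        C[:, i * n_fir_points : (i + 1) * n_fir_points] = np.eye(n_fir_points)
        out.append(C)
    return out


def _with_baseline(X: np.ndarray, include: bool) -> np.ndarray:
    if not include:
        return X
    return np.column_stack([X, np.ones(X.shape[0])])


def design_efficiencies(
    seq: EventSequence,
    hrf: HRFModel | None = None,
    n_fir_points: int = 20,
    include_baseline: bool = True,
    fir_acquisition_trs: int | None = None,
) -> EfficiencyReport:
    """Detection, HRF-estimation and difference-detection efficiencies of
    one sequence (the three rows of the design-comparison table).

    The canonical design convolves unit-area event impulses with the
    unit-integral double-gamma HRF; the FIR design is the stimulus
    convolution matrix (event matrix (x) identity of size
    ``n_fir_points``).  ``include_baseline`` appends a constant column to
    both (on by default; without it null events confer no detection
    advantage).
    """
    from .hemodynamics import build_design

    counts = seq.condition_counts()
    if any(counts[c] == 0 for c in range(1, N_FINGERS + 1)):
        raise ValueError("sequence must contain at least one event per fingertip")
    if hrf is None:
        hrf = double_gamma_hrf(dt=seq.tr)

    Xc = _with_baseline(build_design(seq, "canonical", hrf).values, include_baseline)
    p = Xc.shape[1]
    detection = contrast_efficiency(Xc, detection_contrasts(p))
    difference = contrast_efficiency(Xc, pairwise_difference_contrasts(p))

    # A run whose every TR carries an event cannot identify 5*n_fir_points
    # deconvolution parameters on its own grid; fir_acquisition_trs extends
    # the FIR design to the full acquisition (rest TRs after the sequence
    # ends), which makes the FIR fit barely identifiable.
    fir_seq = seq
    if fir_acquisition_trs is not None and fir_acquisition_trs > seq.n_trs:
        fir_seq = EventSequence(
            list(seq.events), tr=seq.tr, n_trs=fir_acquisition_trs,
            design_kind=seq.design_kind,
        )
    Xf = _with_baseline(
        build_design(fir_seq, "fir", n_fir_points=n_fir_points).values,
        include_baseline,
    )
    pf = Xf.shape[1]
    hrf_est = contrast_efficiency(Xf, fir_selection_contrasts(pf, n_fir_points))

    return EfficiencyReport(detection, hrf_est, difference)


# ---------------------------------------------------------------------------
# vectorized efficiency over many draws + sequence selection
# ---------------------------------------------------------------------------


def _batch_canonical_xtx(conds_batch: np.ndarray, h: np.ndarray, tr: float,
                         include_baseline: bool = True) -> np.ndarray:
    """X'X for a batch of consecutive-event sequences.

    ``conds_batch`` is (n_seq, n_trs) of integer conditions (0 = null);
    returns (n_seq, p, p) with p = 5 (+1 baseline)."""
    n_seq, n = conds_batch.shape
    E = np.zeros((n_seq, n, N_FINGERS))
    idx = np.nonzero(conds_batch)
    E[idx[0], idx[1], conds_batch[idx] - 1] = tr
    m = h.size
    # causal convolution along the TR axis
    pad = np.zeros((n_seq, m - 1, N_FINGERS))
    Ep = np.concatenate([E, pad], axis=1)
    F = np.fft.rfft(Ep, axis=1)
    H = np.fft.rfft(np.concatenate([h, np.zeros(n)]), n=Ep.shape[1])
    X = np.fft.irfft(F * H[None, :, None], n=Ep.shape[1], axis=1)[:, :n, :]
    if include_baseline:
        X = np.concatenate([X, np.ones((n_seq, n, 1))], axis=2)
    return np.einsum("stp,stq->spq", X, X)


def batch_detection_efficiency(
    conds_batch: np.ndarray,
    hrf: HRFModel | None = None,
    tr: float = DEFAULT_TR,
    include_baseline: bool = True,
) -> np.ndarray:
    """Detection efficiency for a batch of consecutive-event sequences
    given as an (n_seq, n_trs) condition array.  Vectorized equivalent of
    ``design_efficiencies(...).detection`` (asserted equal in tests)."""
    if hrf is None:
        hrf = double_gamma_hrf(dt=tr)
    xtx = _batch_canonical_xtx(conds_batch, hrf.samples, tr, include_baseline)
    inv = np.linalg.inv(xtx)
    # diagonal of the fingertip sub-block = per-contrast variances
    diag = np.diagonal(inv, axis1=1, axis2=2)[:, :N_FINGERS]
    return 1.0 / diag.mean(axis=1)


def optimize_fast_er(
    n_draws: int,
    top_k: int,
    seed: int,
    hrf: HRFModel | None = None,
    tr: float = DEFAULT_TR,
    chunk: int = 2000,
) -> list:
    """Draw ``n_draws`` block-randomized fast ER sequences and return the
    ``top_k`` by detection efficiency, best first, as
    ``(EventSequence, EfficiencyReport)`` pairs.  Deterministic given
    ``seed`` (sequence i is regenerated from child seed i)."""
    if top_k > n_draws:
        raise ValueError("top_k must not exceed n_draws")
    if hrf is None:
        hrf = double_gamma_hrf(dt=tr)
    root = np.random.SeedSequence(seed)
    child_states = root.generate_state(n_draws).astype(np.int64)
    dets = np.empty(n_draws)
    for start in range(0, n_draws, chunk):
        stop = min(start + chunk, n_draws)
        batch = np.stack(
            [
                generate_fast_er_sequence(int(s), tr=tr).conditions
                for s in child_states[start:stop]
            ]
        )
        dets[start:stop] = batch_detection_efficiency(batch, hrf, tr)
    order = np.argsort(dets)[::-1][:top_k]
    out = []
    for i in order:
        s = generate_fast_er_sequence(int(child_states[i]), tr=tr)
        out.append((s, design_efficiencies(s, hrf)))
    return out
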