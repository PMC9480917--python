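# Methods

This note records the models implemented by somatomap, the conventions
and defaults they rely on, and the design choices made where more than
one reasonable implementation existed.

## Stimulation sequences

All designs are TR-locked (TR = 2 s): every event onset coincides with
a volume acquisition. Conditions are fingertips 1 (thumb) … 5 (pinky),
0 for null events.

* **Fast ER** — 126 consecutive events over 126 TRs (252 s): six blocks
  of 21 events, each an independent permutation of 6 nulls and 3 events
  per fingertip. The block constraint keeps fingertip counts locally
  balanced. The *average stimulation ITI* is rate-based: 90
  stimulations tile 252 s, i.e. 2.8 s per stimulation; the
  `mean_stimulation_iti` function uses the cyclic (wrap-around) gap
  convention for these steady-state designs so that the per-sequence
  value is exactly `n_TRs·TR/n_stim`; the plain linear-gap mean is
  ≈ 2.79 s.
* **Slow ER** — 30 events (6 per fingertip), 29 onset-to-onset gaps
  drawn uniformly from {2,…,6} TRs (4–12 s, mean 8 s), no fingertip
  repeated consecutively, the whole sequence rejection-sampled (10⁴
  attempt cap) to fit a 126-TR run. Conditioning on fitting pulls the
  realized mean ITI slightly below 8 s (≈ 7.95 s in expectation).
* **Phase-encoded** — each fingertip stimulated for 2 consecutive TRs
  (4 s) in order; 20-s cycles repeated 9 times per run, forward
  (thumb→pinky) or reverse.
* Variants for the efficiency comparison: *fully randomized* (same
  126-event multiset shuffled over the whole run) and *no-null*
  (90 stimulation events on 90 consecutive TRs, 18 per fingertip).

## Design efficiency

`efficiency = 1 / [(1/K) Σ_i Tr(C_i (XᵀX)⁻¹ C_iᵀ)]` — the reciprocal of
the mean OLS contrast-estimate variance under unit white noise; higher
is better, and scaling X by *a* scales efficiency by *a²*, so the
absolute scale is a pure convention. The conventions here are:

* events enter the design as impulses of unit **area** (discrete
  amplitude = TR), so discrete convolution approximates the continuous
  convolution of a unit impulse;
* the canonical HRF is normalized to unit **integral** (the same
  normalization used for the estimated participant HRF);
* a constant baseline column is appended (contrasts do not touch it).

These choices are not cosmetic. The baseline column is what makes null
events valuable: without it, a design stimulated on every TR loses no
detection efficiency, contrary to both intuition and the published
comparisons this package mirrors. And with unit-area events the FIR
(HRF-estimation) row has **no free scale at all** — the values it
produces (≈ 0.43 fast, ≈ 0.21 slow) need no calibration factor, which
is why this convention was adopted over unit-peak/unit-amplitude
alternatives (spec'd values reproduced without any fitted constant;
calibration scale = 1).

Two reproducibility caveats, documented after a systematic attempt to
recover them (intercept-only, DCT drift regressors of several orders,
AR(1) noise covariances, null-event-as-condition contrasts, iid rather
than permuted randomization): under the formula above the fully-
randomized variant is never *less* efficient than the block-randomized
one for the same event multiset (local clumping raises regressor
variance), and the no-null variant lands near 1.8 rather than ~1.45.
Published tables that show block > full randomization evidently include
an additional nuisance model that is not stated; this implementation
reports what the stated formula gives.

The FIR design of the no-null variant deserves its own note: 90 TRs
cannot identify 100 deconvolution parameters (the design is rank
deficient), so its HRF-estimation efficiency is computed on the full
126-TR acquisition grid — the rest TRs after the sequence ends make the
fit barely identifiable, correctly yielding a near-zero efficiency
(≈ 0.04) rather than an undefined one.

`optimize_fast_er` scores draws with a vectorized batch evaluator
(FFT-based convolution, batched 6×6 inversions; asserted equal to the
scalar path) and regenerates the selected sequences from per-draw child
seeds, so selection is deterministic given one integer seed. 50,000
draws take ~10 s on one CPU.

## Hemodynamics

The canonical HRF is a difference of gamma densities, scale 1 s, shape
= stated peak delay + 1 so the density **mode** equals the stated delay
(positive peak 6 s, undershoot 16 s, undershoot scaled by 1/6). The
exact shape/scale convention behind the published delays is not stated
anywhere; the mode-at-delay convention was chosen because it honors the
two delays literally. The trough of the difference falls ~1 s after the
undershoot mode because the positive lobe's tail overlaps it. h(0) = 0.
The temporal-derivative regressor is the first difference of the
sampled HRF — a TR-grid-consistent proxy. Convolution is at TR
resolution; the 0.4-s within-event pulse structure is not modelled.
Convolution restarts at run boundaries of concatenated data.

## Synthetic data

`make_somatotopic_patch` builds a 40×40 voxel grid (default) divided
into column bands: background, BA4a, BA6, background, BA3b, BA1, BA2,
post-BA2. Within each responsive band, pRF centers ramp monotonically
from 0.5 to 5.5 along the rows (the somatotopic axis) with sub-step
jitter that cannot reorder rows; tuning widths are log-normal around
band means 0.8 (BA3b) < 1.2 (BA1) < 2.0 (BA2) and 1.0 (BA4a) < 1.8
(BA6), with post-BA2 effectively flat (σ = 20) — the gradient of
decreasing selectivity away from the primary areas, including an
untuned associative band.

Generative model per voxel:
`signal = baseline·(1 + (Σ_f w_f·X_f + drift + noise)/100)` with
`w_f = amplitude·exp(−(f−center)²/2σ²)`, X the same design construction
the GLM uses (linearity is the model's premise; response nonlinearity
at short ITIs is deliberately not simulated), drift a random-phase sum
of cosines below 0.01 Hz, and white Gaussian noise. Defaults chosen
once as realistic for 1.5-mm 7T voxels: amplitude 1% peak signal
change (matching the ~1% preferred-fingertip responses such experiments
report), noise SD 1% per TR, drift SD 0.5%, baseline 1000 a.u.
Optional per-voxel HRF delay jitter (uniform, ±given seconds,
quantized into 8 delay groups for speed) exercises delay-compensation
steps; default off.

Phase-encoded runs are simulated with **circular** convolution: cyclic
steady-state stimulation means the kernel tail wraps around the run
(equivalently, initial transient cycles are discarded). This is what
makes the delay-cancellation property exact; causal ER runs use
ordinary causal convolution. What the simulator does *not* emulate —
spatially correlated noise, physiological noise, motion, response
nonlinearity, real cortical geometry — bounds what passing tests show:
they validate the estimators under the analysis model's own
assumptions, not robustness to their violation.

## Preprocessing

High-pass filtering is a discrete-cosine projection: DCT-II regressors
with frequency strictly below the 0.01-Hz cutoff (plus the mean) are
regressed out per run segment — exact, phase-free, standard for fMRI
drift. Percent signal change is `100·(x−mean)/mean` per voxel per run,
using the pre-filter run mean; voxels with non-positive means are
flagged and zeroed. Concatenation offsets event onsets and records run
boundaries so that no HRF regressor crosses a boundary and each run
gets its own GLM intercept.

## Phase-encoded analysis

Phase is reported as the cycle position of the response peak:
`phase = mod(−arg F, 2π)` for the DFT coefficient F at the cycle
frequency (a pure cosine has phase 0). With the forward run shifted
back k TRs and the reverse run shifted back k+1 TRs then time-reversed
(circularly; the extra TR accounts for the grid's half-open reversal),
the average of the two runs has phase exactly (2i−1)π/5 for a voxel
preferring fingertip *i*, independent of the hemodynamic delay and of
k; k only maximizes the combined amplitude (k = 2 ≈ 4 s works well for
a 6-s peak). Coherence is the amplitude at the cycle frequency over the
root-sum-square of all non-DC amplitudes; its p-value is the F test of
the sine+cosine regression, F = (C²/2)/((1−C²)/(n−3)) on (2, n−3) df.
Familywise correction across in-patch voxels uses the Hochberg step-up
(the step-up variant was chosen over Holm's step-down; both control
FWER, Hochberg is uniformly more powerful under independence).

Fingertip regions: phases are binned into five 2π/5 bins (bin centers
at the ideal fingertip phases), suprathreshold voxels split into
4-connected components, and a dynamic program keeps the chain of one
cluster per fingertip that maximizes total voxel count subject to
cluster centroids increasing along the somatotopic axis — out-of-order
islands are dropped. Delineation can be masked to one somatotopic
representation (postcentral vs precentral).

## GLM

Voxelwise OLS with homoscedastic per-voxel variance and no
prewhitening (noise is simulated white, and matching the estimator to
the simulation keeps the efficiency↔SE link exact). Per-run intercepts
are appended after concatenation. Contrast machinery: one-sided t maps
for *activation* (each fingertip vs baseline) and *preference* (each
fingertip vs the mean of the other four), F maps for the fingertip main
effect (4 df) and for any-positive response (5 df); FDR control is
Benjamini–Hochberg step-up with monotone-envelope adjusted p-values.
The HRF-delay proxy fits canonical + temporal derivative and returns
the derivative/canonical beta ratio (summed over fingertips, masked
where the canonical sum is non-positive); larger values mean an
earlier response, and the ratio decreases monotonically in simulated
delay shifts.

## pRF fitting and ROI analysis

The voxel pRF fit profiles the amplitude out analytically (nonnegative
closed-form optimum given center and spread), leaving a 2-parameter
bounded least-squares problem (center ∈ [0.5, 5.5], σ ∈ (0, 30]); a
deterministic coarse grid (centers 1–5 step 0.5 × σ ∈ {0.3, 1, 3, 10,
30}) pre-ranks starts and the best four are polished, avoiding local
minima with ~4 solver calls per voxel. A flat curve correctly drives σ
to its upper bound; all-zero curves are flagged non-responsive.
Whether amplitudes should be fitted or curves normalized was open; a
free nonnegative amplitude was chosen because the inputs are
unnormalized percent-signal-change betas.

ROI tuning curves place each voxel's five betas at offsets from its
preferred fingertip (from the *phase* map: phase → [0.5, 5.5] →
rounded) and average positionwise into a 9-point curve (edge offsets
average fewer voxels). Two Gaussian-fit variants, both centered at
offset 0 (the curves are recentered by construction): `sigma_floor`
(σ ≥ 0.4, no offset, no upper bound) for ROI comparisons, and
`offset_nonpositive` (free σ, offset ≤ 0) to absorb below-baseline
responses in design comparisons.

Cortical magnification: per fingertip region a center line is drawn
through the ROI perpendicular to the somatotopic axis (median row per
column); the distance between consecutive regions is the symmetric
mean nearest-vertex shortest-path length on the 4-connected grid graph,
in voxel-spacing units (1.5 mm default) — parallel stripes d rows
apart are exactly d·spacing apart, and the implementation is verified
against an independent all-pairs Dijkstra oracle.

## Pipeline and reproducibility

`run_pipeline` chains simulation (2 forward + 2 reverse localizer runs,
4 fast and 4 slow ER runs by default, mirroring a realistic session) →
preprocessing → phase analysis → two-step GLM → pRF fits (restricted to
FDR-significant voxels) → ROI tuning and BA3b/BA1 magnification tables,
with stage-level logging and wall-times. One top-level seed fans out to
per-stage child seeds through `numpy.random.SeedSequence`, so every
run is bit-reproducible given its config; outputs carry a hash of the
config. The default pipeline completes in well under a minute on one
CPU (the pRF stage dominates).

Problem sizes used by the test suite and the acceptance script — 1,000
random draws per design variant for efficiency means (the selection
step runs at the full 50,000), 500 curves for pRF recovery, 10⁴
replicates for null error-rate checks — were chosen so the whole
validation runs in a few minutes on one CPU while keeping Monte-Carlo
error well inside the tolerances tested.

## Known limitations

* The efficiency scale matches the published table's conventions only
  up to the two caveats above (fully-randomized and no-null detection
  columns); ratios between fast and slow designs are robust to all
  convention choices tested.
* Real-data quantities (FWHM in fingertip units per BA, millimetre
  magnification distances) depend on cortical geometry and SNR that the
  synthetic patch only caricatures; the pipeline's numbers demonstrate
  estimator correctness and gradients, not anatomy.
* No autocorrelation modelling: with temporally correlated noise the
  OLS SEs and the coherence p-values would both be optimistic.
* The spec-level claim that untuned regions show "almost perfectly
  flat" curves is emulated with a large-σ band rather than a separate
  response model.
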