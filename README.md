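# somatomap

Fingertip somatotopy mapping for event-related (ER) fMRI: efficiency-
optimized stimulation-sequence design, synthetic somatotopic BOLD
simulation, phase-encoded (traveling-wave) analysis, two-step GLM
response estimation, and Gaussian population-receptive-field (pRF)
fitting with ROI tuning and cortical-magnification analysis.

It is written for researchers who map body-part representations in
sensorimotor cortex (S1 and precentral motor/premotor areas) and want
to (a) generate and rank ER stimulation sequences before scanning,
(b) analyze phase-encoded and ER runs voxelwise, and (c) validate the
whole chain against a generative ground truth without any real data.

## The models

**Design efficiency.** For a design matrix `X` (event impulses convolved
with a canonical HRF, plus a baseline column) and contrast matrices
`C_i`, the efficiency of a design is

```
efficiency = 1 / [ (1/K) Σ_i Tr( C_i (XᵀX)⁻¹ C_iᵀ ) ]
```

— the reciprocal of the average variance of the OLS contrast estimates
under unit-variance noise. Three figures of merit: *detection* (five
fingertip-vs-baseline contrasts on the canonical design), *HRF
estimation* (per-fingertip selection contrasts on the FIR design, the
event matrix ⊗ I₂₀), and *difference detection* (the ten pairwise
fingertip contrasts). Fast ER sequences (2.8-s average ITI, six null +
fifteen stimulation events per 21-TR block) roughly double-to-triple
every metric relative to slow ER sequences (8-s average ITI), and
selecting the best of many random draws adds another ~35% detection
efficiency.

**Phase-encoded mapping.** Cyclic fingertip sweeps (4 s per fingertip,
20-s cycles) drive periodic responses; the phase of the 0.05-Hz Fourier
component encodes the preferred fingertip. Averaging a forward run
(shifted back k TRs) with a shifted, time-reversed reverse run cancels
the hemodynamic delay: a voxel preferring fingertip *i* lands at phase
(2i−1)π/5 exactly, for any delay. Coherence-based p-values are
corrected with the Hochberg step-up procedure.

**Two-step GLM.** A 20-point FIR deconvolution estimates each voxel's
response to each fingertip over 40 s; dominant-fingertip responses
averaged over the five phase-defined fingertip regions give the
participant HRF (normalized to unit integral), which is then used as
the canonical basis to obtain one amplitude per fingertip per voxel —
the voxel's tuning curve, in percent signal change.

**pRF fitting.** Each tuning curve is fitted with a Gaussian over
fingertip index 1–5 (center in [0.5, 5.5], spread up to 30, free
nonnegative amplitude); FWHM = σ·2√(2 ln 2) ≈ 2.355 σ. ROI tuning
curves recenter voxel curves on an *independently* estimated preferred
fingertip (the phase map) before averaging — recentering on the same
data's argmax manufactures spurious tuning (circularity bias).

## Worked example

```bash
python examples/01_design_efficiency.py
```

prints

```
fast ER: 126 events, mean stimulation ITI 2.8 s
slow ER: 30 events, mean stimulation ITI 7.8 s

mean efficiencies over 200 random draws (detection / HRF estimation / fingertip difference):
  fast ER: 3.26 / 0.42 / 2.29
  slow ER: 1.26 / 0.21 / 0.90

best 5 of 2,000 fast ER draws: mean detection efficiency 4.28
```

Reading: a random fast ER sequence detects fingertip responses with
~2.6× the efficiency of a slow ER sequence at the same scan time (i.e.,
~1.6× smaller standard errors), estimates the HRF twice as efficiently,
and separates fingertips ~2.5× more efficiently; selecting the best of
thousands of draws raises detection efficiency further (3.26 → 4.28).
The other examples map the somatotopy from simulated localizer runs
(`02`), run the two-step GLM and the fast-vs-slow reliability
comparison (`03`), and fit pRFs, ROI tuning curves and cortical
magnification distances end-to-end (`04`).

A thin CLI wraps the same functions:

```bash
somatomap design --kind fast --n-draws 2000 --top-k 5 --seed 0 --out seqs/
somatomap run --seed 0 --out results/
somatomap table1 --n-draws 1000
somatomap compare-designs --seed 0
```

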