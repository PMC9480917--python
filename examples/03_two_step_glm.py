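"""Two-step GLM response estimation and the fast-vs-slow ER comparison.

Step 1 deconvolves each voxel's response with a 20-point FIR basis and
averages the dominant-fingertip responses over fingertip regions into a
participant HRF; step 2 refits with that HRF to get one amplitude per
fingertip per voxel.  The same analysis at matched scan time shows the
fast ER design's smaller estimate SEs — the reliability advantage that
motivates efficiency optimization.
"""

import numpy as np

from somatomap.pipeline import experiment_fast_vs_slow
from somatomap.er_design import generate_fast_er_sequence
from somatomap.glm import estimate_voxel_hrfs, fingertip_amplitudes, participant_average_hrf
from somatomap.hemodynamics import double_gamma_hrf
from somatomap.preprocess import RunTimeseries, concatenate_runs, highpass_filter, percent_signal_change
from somatomap.synthetic_data import PatchConfig, make_somatotopic_patch, simulate_run

hrf = double_gamma_hrf()
patch = make_somatotopic_patch(PatchConfig(grid_shape=(20, 20)), seed=0)
seqs = [generate_fast_er_sequence(s) for s in range(4)]
prep = lambda r: highpass_filter(percent_signal_change(RunTimeseries(r.values, tr=2.0)))
runs = [prep(simulate_run(patch, s, hrf, 0.5, seed=i)) for i, s in enumerate(seqs)]
ts, cat = concatenate_runs(runs, seqs)

voxel_hrfs, _ = estimate_voxel_hrfs(ts, cat)           # step 1: FIR
centers = np.nan_to_num(patch.prf_center.ravel(), nan=0)
regions = {f: np.nonzero(np.round(centers) == f)[0] for f in range(1, 6)}
participant = participant_average_hrf(voxel_hrfs, regions)
r = np.corrcoef(participant.samples, hrf.samples)[0, 1]
print(f"participant HRF vs generating HRF: correlation {r:.3f} "
      f"(unit integral: {participant.samples.sum() * 2:.3f})")

res = fingertip_amplitudes(ts, cat, participant)        # step 2: amplitudes
resp = patch.responsive.ravel()
print(f"mean amplitude SE over {resp.sum()} responsive voxels: "
      f"{res.beta_se[resp, :5].mean():.3f} %sc")

out = experiment_fast_vs_slow(seed=0, n_runs=2,
                              patch_config=PatchConfig(grid_shape=(12, 24)))
print("\nmatched-scan-time comparison (2 runs each):")
for kind in ("fast", "slow"):
    d = out[kind]
    print(f"  {kind} ER: beta SE {d['mean_beta_se']:.3f}, preferred-fingertip "
          f"amplitude {d['mean_preferred_amplitude']:.2f} %sc, "
          f"tuning FWHM {d['tuning_fwhm']:.1f} fingertips")
print(f"  SE ratio slow/fast = {out['se_ratio_slow_over_fast']:.2f} "
      f"(sqrt-efficiency prediction {out['predicted_se_ratio']:.2f})")
print("both designs recover the same tuning; the fast design simply "
      "measures it with less uncertainty.")
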