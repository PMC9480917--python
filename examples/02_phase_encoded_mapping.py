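"""Phase-encoded (traveling-wave) fingertip mapping on synthetic data.

Simulates forward (thumb->pinky) and reverse localizer runs on a
synthetic somatotopic patch, combines them with hemodynamic-delay
compensation, and recovers each voxel's preferred fingertip from the
phase of the 0.05-Hz response component.  The delineated regions are the
five fingertip representations, ordered inferior-to-superior along the
somatotopic axis.
"""

import numpy as np

from somatomap.er_design import generate_phase_encoded_sequence
from somatomap.hemodynamics import double_gamma_hrf
from somatomap.phase_encoded import analyze_phase_encoded, delineate_fingertip_regions
from somatomap.preprocess import RunTimeseries, highpass_filter, percent_signal_change
from somatomap.synthetic_data import PatchConfig, make_somatotopic_patch, simulate_run

hrf = double_gamma_hrf()
patch = make_somatotopic_patch(PatchConfig(grid_shape=(30, 30)), seed=0)

fwd_seq = generate_phase_encoded_sequence("forward")   # 9 cycles x 20 s
rev_seq = generate_phase_encoded_sequence("reverse")
prep = lambda run: highpass_filter(
    percent_signal_change(RunTimeseries(run.values, tr=2.0))
)
fwd = [prep(simulate_run(patch, fwd_seq, hrf, 0.5, seed=s)) for s in (1, 2)]
rev = [prep(simulate_run(patch, rev_seq, hrf, 0.5, seed=s)) for s in (3, 4)]

pm = analyze_phase_encoded(fwd, rev, k=2)  # shift back 2 TRs (~4 s delay)
print(f"significant voxels (Hochberg-corrected p < 0.05): "
      f"{pm.significant.sum()} of {pm.phase.size}")

s1 = np.isin(patch.area_label.ravel(), ["BA3b", "BA1", "BA2", "post_BA2"])
regions = delineate_fingertip_regions(pm, patch.grid_shape, mask=s1)
print("postcentral fingertip regions (ordered thumb -> pinky):")
for r in regions:
    true_center = np.nanmean(patch.prf_center.ravel()[r.voxel_indices])
    print(f"  fingertip {r.fingertip}: {r.size} voxels, centroid row "
          f"{r.centroid[0]:.1f}, mean true pRF center {true_center:.2f}")
print("each region's mean ground-truth center should sit near its "
      "fingertip number: the traveling-wave phase decodes the map.")
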