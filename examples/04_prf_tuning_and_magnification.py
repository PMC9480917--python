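"""Gaussian pRF fitting, recentered ROI tuning curves, the circularity
bias, and cortical magnification distances — via the full pipeline.

Runs the end-to-end synthetic experiment (localizer + fast/slow ER +
two-step GLM + pRF fits + ROI report), then demonstrates on untuned
noise why recentering tuning curves on a preference estimated from the
SAME data manufactures spurious tuning.
"""

import numpy as np

from somatomap.pipeline import PipelineConfig, run_pipeline
from somatomap.prf_tuning import recenter_and_average
from somatomap.synthetic_data import PatchConfig

cfg = PipelineConfig(seed=0, patch=PatchConfig(grid_shape=(30, 30)),
                     n_fast_runs=3, n_slow_runs=0)
bundle = run_pipeline(cfg)
report = bundle["report"]
print(f"fingertip regions found: {report['n_fingertip_regions']} postcentral, "
      f"{report['n_precentral_fingertip_regions']} precentral")

print("\nROI tuning (sigma in fingertip units, FWHM = 2.355 sigma):")
for row in report["roi_table"]:
    print(f"  {row['roi']:>8}: n={row['n_voxels']:3d}  "
          f"ROI-curve FWHM {row['tuning_fwhm']:.2f}  "
          f"median voxel pRF sigma {row['median_prf_sigma']:.2f}")
print("tuning width grows BA3b -> BA1 -> BA2 (and BA4a -> BA6): "
      "selectivity decreases away from the primary areas.")

d = report["cortical_distances_mm"]
for band, dists in d.items():
    pretty = ", ".join("n/a" if np.isnan(x) else f"{x:.1f}" for x in dists)
    print(f"consecutive fingertip distances in {band} (mm): {pretty}")

# circularity bias: untuned voxels, two recentering rules
rng = np.random.default_rng(0)
noise_betas = rng.standard_normal((3000, 5))
independent = recenter_and_average(noise_betas, rng.integers(1, 6, 3000))
circular = recenter_and_average(noise_betas, noise_betas.argmax(axis=1) + 1)
for name, curve in [("independent", independent), ("circular", circular)]:
    peak = curve.values[4] - np.nanmean(np.delete(curve.values, 4))
    print(f"{name} recentering of pure noise: offset-0 excess "
          f"{peak:.3f} ({peak / curve.sem[4]:.1f} SE)")
print("only the circular rule shows a (spurious) peak: always recenter "
      "on an independent preference estimate (here, the phase map).")
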