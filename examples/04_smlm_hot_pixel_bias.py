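"""Hot-pixel localization bias and its removal by map-aware fitting.

Simulates astigmatic 3D single-molecule frames (DNA-PAINT preset: 35,100
photons, 500 ms exposure) next to a strong dark-current defect, then fits
each frame twice: with per-pixel exposure-time-dependent camera maps
("corrected") and with field-average scalar camera constants
("uncorrected").
"""

from dataclasses import replace

import numpy as np

import darkcal as dc
from darkcal.psf import PSFModel
from darkcal.smlm import BiasExperimentConfig, bias_rmse_experiment, modality_preset

gt = dc.make_synthetic_camera((32, 32), hot_pixel_fraction=0.0, seed=3)
dcm = gt.dark_current.copy()
dcm[16, 17] = np.median(dcm) * 100  # one strong hot pixel
gt = replace(gt, dark_current=dcm, hot_pixels=((16, 17),))

cfg = BiasExperimentConfig(
    camera=gt,
    psf=PSFModel(kind="astigmatic3d", sigma0=130.0),
    modality=modality_preset("paint", "scmos"),
    grid=[(16, 16), (16, 18), (16, 20), (10, 10)],  # around + away from defect
    n_repeats=500,
    seed=5,
)
report = bias_rmse_experiment(cfg)

cols = ["row", "col", "hot_distance_px",
        "uncorrected_bias_x", "corrected_bias_x",
        "uncorrected_rmse_x", "corrected_rmse_x", "sqrt_crlb_x"]
print(report.table[cols].round(2).to_string(index=False))
print()
print("Uncorrected fitting is biased by several nm next to the hot pixel and")
print("the bias flips sign across it; per-pixel maps remove the bias and")
print("restore the lateral RMSE to the theoretical sqrt-CRLB limit.")
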