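# darkcal

Photon-free per-pixel characterization of CMOS/sCMOS cameras, and
variance-aware single-molecule localization fitting that uses the
resulting exposure-time-dependent camera maps.

## The problem

sCMOS and industry-grade CMOS cameras have per-pixel electronics: every
pixel has its own offset, readout noise, dark current and gain.
Quantitative image analysis — single-molecule localization microscopy
(SMLM) in particular — must account for these pixel-wise properties or it
produces structured artifacts, most visibly near "hot" pixels with high
dark current. Conventional characterization varies the light level at one
fixed exposure time, which (a) needs controlled illumination and (b) bakes
the thermal signal of that one exposure time into the offset and noise
maps, so the calibration silently loses validity at any other exposure
time.

`darkcal` characterizes the camera entirely in the dark. Thermally
generated electrons obey Poisson statistics just like photoelectrons, so
*exposure time* can replace *light level* as the signal knob. For each
pixel `k`, from dark-frame stacks at several exposure times `t`:

* mean ADU vs `t` is linear: y-intersect = baseline `BL_k` (offset free of
  thermal effects), slope = dark current `DC_k` (ADU/s);
* variance vs `t` is linear: y-intersect = read noise squared `RN_k²`,
  slope = thermal noise squared per second `TN_k²` (Poisson statistics
  make `TN² = DC` in electron units);
* variance vs mean is linear with slope equal to the pixel gain
  (ADU/electron); the median over pixels serves as the global gain.

Maps for **any** exposure time then follow:

```
offset_k(t)   = BL_k + DC_k · t
variance_k(t) = RN_k² + TN_k² · t
photon_response_k = median_gain · flatfield_k
```

This trio is exactly what map-consuming correction algorithms and
sCMOS-specific SMLM fitters take as input. The fitter included here folds
the per-pixel Gaussian noise variance `v_k` into a Poisson likelihood via
the variance-shift device (effective data `e_k + v_k`, effective model
`N·E_k + bg + v_k`) and maximizes it with analytic-gradient
Levenberg–Marquardt, for 2D Gaussian and astigmatic 3D PSF models, with
Cramér–Rao lower bounds from the analytic Fisher information.

A synthetic camera model (smooth baseline/flatfield fields, log-normal
dark current with designated hot pixels, Gaussian read noise, per-pixel
gain, quantization and clipping) generates all test data, so every claim
is checked against a known ground truth.

## Worked example

`examples/01_characterize_camera.py` builds a 32×32 synthetic camera with
1% hot pixels, simulates a nested dark series (five exposure times from
1 ms to 500 ms, 3,000 frames each) and calibrates it:

```
Photon-free calibration vs ground truth (32x32 camera, 3000 frames/time)
  median gain     : 2.003 ADU/e-   (true 2.000)
  baseline RMS err: 0.037 ADU
  dark current    : median 27.5 e-/s  (true 27.7)
  read noise      : median 1.51 e-    (true 1.50)
  hot pixels      : 10 planted; largest fitted dark current 815 e-/s
```

All five parameter maps are recovered from dark frames alone; the
baseline is accurate to a few hundredths of an ADU per pixel and the gain
to ~0.2%. `examples/02_derive_maps.py` shows why the exposure-time
dependence matters — at a hot pixel the offset grows from 102 ADU at 1 ms
to 1257 ADU at 1 s while the field median only moves from 101 to 155.

`examples/04_smlm_hot_pixel_bias.py` simulates 3D DNA-PAINT frames
(35,100 photons, 500 ms) next to a strong hot pixel and fits them with and
without the per-pixel maps:

```
 row  col  hot_distance_px  uncorrected_bias_x  corrected_bias_x  uncorrected_rmse_x  corrected_rmse_x  sqrt_crlb_x
  16   16             1.00                4.53              0.05                4.63              0.96         0.96
  16   18             1.00               -2.68              0.01                2.83              0.97         0.96
  16   20             3.00              -11.80             -0.03               11.84              0.99         0.97
  10   10             9.22               -0.61             -0.03                1.15              0.98         0.95
```

Uncorrected fitting is laterally biased by up to ~12 nm with a sign that
flips across the defect; map-aware fitting removes the bias (≤ 0.05 nm)
and restores the RMSE to the theoretical sqrt-CRLB (~0.96 nm).

There is also a thin CLI (`darkcal simulate-darks / calibrate /
derive-maps / smlm-bias / validate`) over the same functions, writing
maps as float32 TIFFs (`baseline.tif`, `dark_current_per_s.tif`,
`read_noise_sq.tif`, `thermal_noise_sq_per_s.tif`, `gain.tif`,
`flatfield.tif`, `offset_<t>ms.tif`, `variance_<t>ms.tif`,
`photon_response.tif`) with a JSON sidecar.

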