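# Methods

## Measurement model

Each photograph shows one fruit slice on a near-white background inside a
controlled light box. The imaging stage reduces it to one record:

1. **Denoising.** A per-channel spatial median filter with edge
   replication. Default kernel 3×3 — the smallest window that removes
   salt-and-pepper sensor noise without blurring the slice boundary; the
   kernel is configurable because cameras differ.
2. **Segmentation.** Either a fixed rectangle (reproducing a manual crop,
   0-based half-open coordinates) or automatic: Otsu thresholding of the
   per-pixel Euclidean distance from the background white, keeping the
   largest connected component, then eroding the boundary by a margin
   (default 3 px) so edge glare and demosaicing halos do not contaminate
   the color summary. Auto mode is the package default since it needs no
   manual coordinates.
3. **Color conversion.** 8-bit sRGB → CIELAB: sRGB transfer-function
   decoding, linear RGB → XYZ under the sRGB primaries (matrix rows
   normalised so that RGB (1,1,1) maps exactly to the reference white),
   then the CIELAB equations. Default reference white is D65/2°, the
   native white of the sRGB pipeline and of open reference
   implementations; D50 is available via Bradford chromatic adaptation
   because desktop image editors compute Lab under D50, and studies
   processed with such tools are better reproduced in that mode. The
   inverse transform (used by the renderer) picks the ΔE-nearest of the
   eight surrounding integer RGB corners rather than rounding channels
   independently; per-channel rounding has a worst-case round-trip error
   of ΔE ≈ 0.8, the corner search keeps it below 0.4.
4. **Summary.** Mean and SD of L\*, a\*, b\* over the masked pixels.

Replicates are separate images; they are combined by unweighted mean at
the time-series stage, with the across-replicate SD carried for reporting
only (no weighting information is available for these designs). ΔE is
computed per replicate against that replicate's own day-0 measurement —
the only reference consistent with a trajectory that starts at 0 and
grows as the slice discolors — and hue uses the quadrant-aware
arctangent, a deliberate correction of the naive tan⁻¹(b\*/a\*), which is
wrong by 180° in the second quadrant where fresh slices start
(a\* slightly negative, b\* strongly positive).

## Kinetic fitting

Zero-order fits are ordinary least squares of C on t. First-order fits
regress ln C on t and, by default, refine the estimate by nonlinear least
squares on the original scale initialised from that linearized fit —
preferable when the observation noise is additive in attribute units, as
it is for ROI-averaged color. Both estimates are available; the
linearized one is always computed as the initializer. The rate constant
is stored as a positive magnitude plus a decay/growth direction flag, so
downstream inversion never depends on a sign convention.

FOFC works on the fraction converted f(t) = (C₀ − C(t))/(C₀ − C∞) with
C₀ fixed at the first observation. ln(1 − f) is regressed on storage
day t. Days where f falls outside (0, 1) — before conversion has begun,
or at/after complete conversion where the logarithm is undefined — are
excluded and reported, never imputed; at least three retained points are
required. C∞ may be supplied, taken as the last observation, or fitted by
a bounded 1-D search (Brent) minimising the RMSE of the reconstructed
trajectory. The search interval extends half the observed span beyond
the observed extreme value. That bound is a modelling statement: FOFC
describes an attribute that demonstrably levels off within the
observation window, so its plateau must lie near the data's extreme. A
looser bound lets the plateau run far past the data, where the FOFC curve
degenerates into an over-parameterised exponential that can shadow plain
first-order kinetics point-for-point — the family would then no longer be
identifiable in model comparison.

R² and RMSE are always computed on the original attribute scale over the
retained days, whatever scale estimation used, so the three families are
directly comparable. Constant series are flagged degenerate (k = 0, R²
undefined) rather than erroring. A ΔE trajectory is exactly 0 at day 0,
where the exponential family is ill-posed; for that attribute the
first-order fit drops leading non-positive values and flags them.

Model ranking is by R² descending; fits within 1e-6 of each other are
tied and ordered by lower RMSE, then by fewer parameters (zero < first <
FOFC). Degenerate fits sort last.

## Shelf-life inversion

The threshold is a mandatory user input — an acceptability limit is a
product decision, not a data property, so no default is shipped. It may
be absolute or a fraction of the fitted C₀ (the example configuration
uses L\* at 0.8·C₀ and ΔE at 30, as illustrations only). Inversion is
closed-form per family (see README); the direction flag resolves the
sign so PSL ≥ 0. Thresholds already passed at day 0 give PSL 0 with a
warning; thresholds beyond the FOFC plateau (or non-positive for a
first-order decay) are unreachable and error; k = 0 flags an infinite
shelf-life. By default shelf-life is predicted from the L\* and ΔE fits,
the attributes with the strongest, most monotone response to browning;
any attribute can be requested.

## Synthetic studies

The generator emulates the structure of a refrigerated fresh-cut storage
experiment: 13 treatments (uncoated control plus three herb-extract
coatings × spray/2-, 4-, 6-minute dip application), days 0–15 sampled
every 3 days, 3 replicates — 234 images by default. Per attribute one
law from each family is used so that model selection is exercised: L\*
decays first-order (spray coatings ~91 → 67.5 over 15 days, k ≈
0.019–0.022/day; dip coatings to the low 50s or 42, k up to ≈ 0.05; the
control fastest at ≈ 0.058), a\* rises by FOFC from slightly negative
starts toward a brown plateau of +16 to +20 (k ≈ 0.11–0.16), and b\*
grows zero-order from ~24 to ~40 (k ≈ 0.9–1.1 per day). Replicate
trajectories get i.i.d. Gaussian noise (default SD 0.5 CIELAB units, the
scale of the day-to-day scatter such studies report); scenes are uniform
discs (radius 50 px in a 140×200 frame) of the replicate color on a
near-white (250,250,250) background with per-pixel Gaussian noise
(default SD 2 eight-bit units), written losslessly as PNG by default —
a JPEG mode exists to study compression-induced color bias. All
randomness flows through a single seeded generator; equal seeds give
byte-identical images, manifests and truth sidecars.

What the simulator does *not* emulate: spatial browning fronts, texture,
specular highlights, illumination gradients, or camera calibration error.
Passing end-to-end tests therefore demonstrate that the measurement,
fitting and inversion chain is correct and unbiased under the stated
noise model — not that a particular camera setup is accurate. Real
deployments still need controlled illumination and, if absolute color
matters, chart-based calibration (out of scope here).

## Numerical choices and edge cases

- FOFC plateau search: Brent on a bounded interval, absolute tolerance
  1e-10 of the observed span; noiseless data recover k and C∞ to better
  than six significant digits.
- First-order nonlinear refinement: `scipy.optimize.curve_fit`, p0 from
  the linearized fit, up to 10⁴ function evaluations.
- The rate-constant standard error comes from the OLS slope error
  (linearized/FOFC) or the curve-fit covariance (nonlinear).
- Quantities in JSON/CSV outputs are rounded to six significant digits so
  reruns are byte-stable and diffable; each pipeline stage writes through
  a temp file and atomic rename.
- Validation problem sizes: Monte-Carlo harnesses use 200 simulations per
  condition and the end-to-end check uses the full default 234-image
  study; both complete in well under a minute on one core.

## Known limitations

- Single storage temperature: no Arrhenius/Q10 extrapolation, so a PSL is
  valid only at the temperature the data were collected at.
- Euclidean ΔE only (no CIEDE2000); adequate for large browning
  differences, less perceptually uniform for subtle ones.
- The free-plateau FOFC rate is weakly identified on short, narrow-range
  trajectories (e.g. a\* spanning ~20 units with noise 0.5): its median
  recovery error is a few percent but individual fits can err by ~20%.
  When the plateau is known or the series is long relative to 1/k the
  estimate tightens to the level of the other families.
- The automatic segmenter assumes one dominant object on a near-uniform
  bright background.
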