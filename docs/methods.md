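# Methods

## Scope and data flow

The toolkit covers the measurement-to-dose chain for ¹³¹I-mIBG therapy:

1. **probe** — external-counter readings → whole-body retention curve in MBq;
2. **tac** — mono/multi-exponential fitting, model selection, time-integrated
   activity Ã;
3. **camera** — calibration factor Q, recovery curve R(v), paralysable
   dead-time constants τ (one per count-rate mode);
4. **spect** — TEW scatter correction, first-order Chang attenuation
   correction, VOI segmentation and count-rate → activity conversion;
5. **dosimetry** — S-value power laws, MIRD dose D = Ã·S, fractionation
   planning, first-order uncertainty propagation;
6. **synth** — seeded generators providing ground truth for all of the above.

Image reconstruction (OSEM, collimator-detector-response modelling) and
registration are out of scope: the toolkit consumes reconstructed,
co-registered count-rate images. Radiobiological endpoints (BED/EUD) and
voxel S-value kernels are likewise not modelled.

Canonical units are MBq, hours, Gy, kg for body mass and g for organ/lesion
mass (unit density, so ml ↔ g); S values convert exactly between Gy/(MBq·h)
and mGy/(MBq·s) (factor 3.6). The ¹³¹I physical half-life is fixed at
8.0252 d (192.6 h), from standard decay data, for decay-correcting phantom
activities.

## Whole-body retention

Counting statistics are Poisson, so a reading of N counts carries relative
noise 1/√N; readings of ≤ 500 counts (> ~4.5 % noise) are flagged rather
than rejected. Each patient reading is corrected with the most recent prior
background (falling back to the pre-administration background), replicate
readings within 15 min are averaged (σ shrinks by √k), and AP/PA pairs are
combined by geometric mean with first-order error propagation. The first,
pre-void reading anchors the curve: its net rate corresponds to the full
administered activity, and a residual pre-administration rate from an
earlier therapy cycle is subtracted from both numerator and denominator of
the retained fraction. Net rates exceeding the baseline after t = 0 warn
(geometry or contamination suspect) but do not abort.

## Time–activity fitting and Ã

Fits are unweighted nonlinear least squares (optional 1/σ² weighting) with
Levenberg–Marquardt, initialised by curve stripping: the slowest phase is
estimated log-linearly from the tail, subtracted, and the procedure repeated
for each faster phase. A negative fitted amplitude triggers a refit with one
fewer phase (flagged): a clearance curve with a genuinely negative component
is indistinguishable from an over-parameterised fit here, because lesion
uptake phases are deliberately not modelled — the fitted model is evaluated
from t = 0 with no rise phase, and the tail always uses the fitted effective
λ rather than forced physical decay.

Model order is chosen by the extra-sum-of-squares F test
(F = ((RSS₁−RSS₂)/(df₁−df₂))/(RSS₂/df₂), complex model accepted iff
p < α = 0.05) or by small-sample-corrected AIC (AICc, with k counting the
residual variance; ties break toward fewer phases). When the more complex
fit collapses (merged phase) or lands on a local optimum no better than the
simple fit, that is treated as no evidence for the extra phase. Ã is the
closed-form integral Σ A_j/λ_j·(e^(−λ_j t₁) − e^(−λ_j t₂)); a coverage
fraction Ã(t_first, t_last)/Ã(0, ∞) with an 80 % recommendation flags
under-sampled curves.

## Camera characterisation

**Calibration.** Q = Ċ_VOI/(c·V) from a uniform cylinder; a uniformity check
over ≥ 3 sub-VOIs (default 10 % tolerance) guards against partial-volume or
noise contamination of the calibration VOI.

**Recovery.** R_i = Ċ_i/(Q·A_i) per insert; the interpolant
R(v) = R_max·vⁿ/(vⁿ + v50ⁿ) is a saturating, monotone-by-construction model
choice (the measurement prescribes only the points). On optimiser failure it
degrades to a flagged monotone piecewise-linear interpolant. Evaluations
below the smallest measured insert warn as extrapolations and are clamped to
(0, R_max].

**Dead time.** The paralysable model Ċ_obs = Ċ_inc·e^(−Ċ_inc·τ) is fitted to
an increasing-activity series. A zero-intercept linear fit to the points
observed below 10 kcps initialises the sensitivity (zero intercept because
zero activity gives zero rate after background subtraction); sensitivity and
τ are then refined **jointly** over all points. Freezing the sensitivity at
the linear-fit value would import a bias of several percent into τ, because
at τ ≈ 13 µs even "low-rate" points below 10 kcps already lose up to ~13 %
of counts; the joint refinement removes this while keeping the linear fit as
the initialiser. Cameras with a high-count-rate mode carry one τ per regime
with a hard switch threshold on the observed rate.

**DTF.** The correction factor solves DTF = e^(DTF·τ·Ċ) by fixed-point
iteration from DTF₀ = 1, which converges monotonically to the physical
(lower) branch whenever Ċ·τ < 1/e; a Newton step is the fallback. Observed
rates at or beyond the paralysable maximum are rejected as uncorrectable.

## SPECT quantification

**TEW.** C_SC = C_peak − (W_peak/2)·(C₁/W₁ + C₂/W₂), element-wise on
projections, clamped at zero per pixel (counts are non-negative). Standard
¹³¹I windows: 20 % photopeak at 364 keV, 6 % flanking windows. Images carry
a corrections-applied provenance list so scatter/attenuation corrections
cannot be applied twice.

**Chang.** First-order correction with in-plane rays (the classical 2-D
form): for each in-mask voxel, the in-mask path length d_m to the boundary
is traced along M = 64 equally spaced rays with bilinear mask sampling at
half-voxel steps, the boundary placed midway between the last inside and
first outside sample; the factor is M/Σ_m e^(−μ·d_m). Default
μ = 0.11 cm⁻¹. At the centre of a 10-cm cylinder the factor matches the
closed form e^(μR) within 1 %, and M = 64 agrees with a dense-ray (M = 4096)
evaluation within 2 % off-centre.

**Segmentation.** The adaptive threshold bisects a fraction of the local
maximum (the maximum of the connected object containing the seed) until the
seed's connected component matches the target volume within half a voxel
(≤ 50 steps, nearest volume returned); unreachable targets report the
achievable range. 3×3×3-block extrema over blocks fully inside a mask give
noise-robust maximum/minimum-uptake sub-volumes.

**Activity.** A = Ċ/(Q·R)·DTF, exactly invertible; the average-rate
dead-time correction (mean over projections) is the default, applied post
reconstruction.

## Dosimetry

D = Ã·S with unit normalisation centralised and exact. Fraction planning
assumes the first fraction's dose per unit activity holds for later
fractions (stated in the plan report); the planned activities close
algebraically to the target. Red-marrow dose uses the empirical whole-body
ratio 1.6. Cross-dose between lesion and organs is neglected. Uncertainty
propagation is first-order uncorrelated quadrature on products
(σ² = (y·σ_x)² + (x·σ_y)² + 2ρxyσ_xσ_y), with the power-law mass term
σ_S = |b|·(σ_m/m)·S(m); reported ± values are indicative first-order
estimates only.

## Synthetic data

Generators are seeded (`numpy.random.default_rng`, one stream per call) and
byte-reproducible. Noise models: Poisson for detected counts, multiplicative
Gaussian for count rates. The sphere phantom rasterises analytically with
partial-voxel edge weighting (4³ supersampling of edge voxels) and blurs
with an isotropic Gaussian PSF — a stand-in for the high-energy-collimator
system response, default FWHM 15 mm (an assumption; the real ¹³¹I HEGP PSF
is broader-tailed and distance-dependent). Recorded "enclosed" rates are
counts inside the binary voxelised sphere mask, so even at FWHM = 0 the
enclosed fraction is below 1 by the rasterisation share of partial edge
voxels — a pure grid-geometry effect that vanishes with refinement and that
tests assert explicitly rather than hide.

What the generators do **not** emulate: projection-domain physics (scatter,
attenuation, septal penetration), anthropomorphic geometry, patient motion,
and inter-scan repositioning. Passing round-trip tests therefore
demonstrates the estimators' correctness and noise behaviour, not clinical
end-to-end accuracy.

## Problem sizes and numerical choices

Validation studies use sizes a physics service could realistically acquire:
probe series of ~30 readings over 5 days; dead-time series of 25 geometric
activity steps driving the camera past its count-rate maximum (the
NEMA-style design; with 2 % rate noise this recovers τ with < 1 % bias and
< 5 % RMSE over 100 seeded series); sphere phantoms on 48³ grids at 4.67-mm
voxels; F-test calibration over 500 seeded replicates of 20-point
mono-exponential curves with Poisson counting noise (~2,000 counts at t = 0),
whose empirical type-I error at α = 0.05 falls within [0.02, 0.09].

Optimiser: `scipy.optimize.least_squares`, tolerances 1e-10 to 1e-14,
max 500·n_params evaluations; curve-stripping initialisation makes random
restarts unnecessary. Degenerate inputs fail loudly: empty masks, seeds in
background, non-positive rates for geometric means, observed rates beyond
the paralysable maximum, plans whose target is already met.

## Known limitations

* The Chang implementation is slice-wise 2-D; strongly oblique body
  outlines would need 3-D rays.
* Recovery coefficients measured on spheres transfer imperfectly to
  non-spherical lesions and non-zero background uptake.
* Probe dead time is not modelled separately; at therapy count rates a
  Geiger counter should be characterised like the camera if saturation is
  suspected.
* Uncertainty reporting ignores correlations between Ã and S introduced by
  shared calibration factors.
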