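# Methods

## Signal model and candidates

A voxel's magnitude signal at diffusion weighting `b` (s/mm²) is modelled
as a two-compartment sum of an extravascular (tissue) and an intravascular
(capillary) part,

    S(b) = Se0 · E(b; D, K) + Sv0 · exp(−b·D*),      fp = Sv0 / (Sv0 + Se0),

where `D` (mm²/s) is the tissue diffusion coefficient, `K` (dimensionless)
the diffusional kurtosis, `D*` (mm²/s) the pseudo-diffusion coefficient of
capillary blood and `fp` the perfusion fraction. Three candidate
attenuation functions are supported:

* Gaussian: `E = exp(−bD)` — free water, a single well-mixed compartment.
* Kurtosis: `E = exp(−bD + b²D²K/6)` — a truncated cumulant expansion for
  restricted diffusion; it is only meaningful while the curve decreases,
  i.e. for `b ≤ 3/(DK)`.
* Gamma: `E = (1 + bDK/3)^(−3/K)` — a continuous mixture of Gaussian
  compartments whose diffusivities follow a gamma distribution with shape
  `α = 3/K` and rate `β = 3/(KD)` (mean `D`, variance `KD²/3`). For
  `b ≪ 27/(6DK)` it coincides with the Kurtosis model; with `DK` around
  10⁻³ mm²/s the two differ by less than 1% below b ≈ 600 s/mm², so only
  the high-b tail separates them.

Both non-Gaussian models reduce exactly to the Gaussian model at `K = 0`.
The Gamma attenuation is evaluated as `exp(−(3/K)·log1p(bDK/3))`, which is
numerically stable for small `K`; inside the optimiser a second-order
expansion takes over below `K = 10⁻⁸` so the gradient with respect to `K`
stays finite at the `K = 0` bound.

## Two-step fit with per-voxel model selection

The acquisition is assumed to provide a b-value ladder (default: 17 values,
0–2,500 s/mm²) in several gradient directions (default: 6), with the
ladder repeated per direction. Fitting proceeds per voxel:

1. **Diffusion step.** For each direction, the high-b window
   (b ≥ 600 s/mm², 11 points by default) is fitted with
   `S ≈ Se0·E(b; D, K)` for each candidate model by bounded trust-region
   least squares. The window threshold exploits that `exp(−b·D*)` is
   negligible there for physiological `D*`.
2. **Selection.** Each candidate's corrected Akaike criterion
   `cAIC = 2P + n·ln(RSS/n) + 2P(P+1)/(n−P−1)` (P = 2 for Gaussian, 3
   otherwise) is averaged over the directions; the minimal mean wins. A
   candidate that fails to converge in any direction is excluded; if an
   exact tie occurs, the model with fewer parameters wins, then the fixed
   order Gaussian → Kurtosis → Gamma.
3. **Perfusion step.** The selected model's fitted tissue component is
   subtracted from the *full* series of each direction and the six residual
   series are fitted jointly by `Sv0·exp(−b·D*)` — capillary perfusion is
   treated as isotropic, so one (Sv0, D*) is shared. `fp` follows from
   `Sv0` and the direction-mean `Se0`.
4. **Refinement.** A single pass leaves a bias: the perfusion tail still
   contributes ~0.1–0.5% of the signal at b = 600–800, which the diffusion
   fit absorbs, which in turn biases the extracted residuals (on noiseless
   tissue-like voxels: ~1% in D, ~10% in fp). The two steps are therefore
   alternated — the current perfusion estimate is subtracted from the
   high-b window and the selected model refitted (warm-started) — until the
   relative change of (D, Sv0) falls below `refine_rtol` (10⁻⁷) or
   `refine_iterations` (16) rounds are spent. The alternation contracts
   geometrically (ratio ≈ 0.5–0.75 depending on `D*`), so an Aitken
   extrapolation of the (Sv0, D*) iterates is applied every third round;
   on noiseless voxels the defaults recover all parameters to ≤ 10⁻⁵
   relative. Model selection always uses the first-pass fits.

Per-voxel outputs are the direction means of the selected model's
estimates: mean diffusivity MD, apparent mean kurtosis (the direction
average used when full kurtosis-tensor estimation is impossible; a
Gaussian-selected voxel contributes K = 0), mean Se0, plus (fp, D\*) and a
flag bitmask (non-convergence, optimiser at a bound, low-quality input,
`b_max` above the Kurtosis validity bound — a diagnostic only, never an
optimiser constraint — and absent perfusion signal). Forced single-model
modes (`gaussian`/`kurtosis`/`gamma`) skip selection and reproduce the
conventional one-model analysis.

## Numerical choices

* **Optimiser.** `scipy.optimize.least_squares` (trf) with analytic
  Jacobians, `xtol = ftol = gtol = 10⁻¹²`, explicit parameter scales
  (Se0 ~ 1 after normalisation, D ~ 10⁻³, K ~ 1) and at most 200 function
  evaluations per fit. Initialisation: `D` and `Se0` from a log-linear fit
  of the leading window points, `K` starts at 0.8, `D*` at 10⁻² mm²/s,
  `Sv0` at the mean b = 0 residual. Bounds: `D ∈ [10⁻⁵, 5×10⁻³]` mm²/s,
  `K ∈ [0, 5]`, `D* ∈ [10⁻⁴, 0.5]` mm²/s, `Se0, Sv0 ∈ [0, 2·S(0)]` —
  wide enough for CSF and all reported tissue values.
* **Scale equivariance.** Every fit divides its signals by their maximum
  before optimising and restores the scale afterwards, so multiplying the
  input data by α changes nothing but Se0, Sv0 (by α) and every cAIC (by
  exactly `2n·ln α`); for binary-representable α the fitted D, K, fp, D*
  are bit-identical. Absolute cAIC values are therefore meaningless across
  datasets; only within-voxel differences matter.
* **RSS floor.** On noise-free data every candidate that nests the
  generator fits to machine-precision RSS and `ln(RSS)` becomes numerical
  noise, making the selection ill-defined. The cAIC is therefore computed
  with RSS floored at `n·(10⁻⁹·scale)²`: exactly-fitting models tie on RSS
  and the parsimony penalty decides. Real (noisy) RSS values sit far above
  the floor, which is then inert.
* **Degenerate inputs.** All-zero voxels, non-finite values and voxels
  where no model converges are flagged, never raised, so a volume run
  always completes. Residual series that are entirely ≤ 0 yield
  `Sv0 = 0, fp = 0` with `D*` undefined (NaN, flagged).

## Rician noise handling

Magnitude MRI noise is Rician: `S_meas² ≈ S_true² + NCF` with NCF the
squared noise floor. The floor is estimated as the histogram mode of the
b = 0 image (in background the magnitude is Rayleigh with mode equal to the
per-channel σ): Freedman–Diaconis bins over nonzero voxels, counts smoothed
with a short moving average (the raw argmax jitters where the density is
flat), and the mode refined to the median of the peak window — which is
also exact for effectively discrete histograms. Whether the histogram uses
the whole field of view (sensible in vivo, where air dominates) or a mask
is configurable; piecewise-constant phantoms *need* a background mask,
because their tissue classes form histogram peaks that can out-vote the
background. The correction `S → sqrt(max(S² − NCF, 0))` is applied to all
frames before both fitting steps.

## Digital phantom

The generator produces a 4D series emulating the target protocol — the
17-b ladder acquired once per direction block in 6 directions, with
repeats for number-of-averages (NA) studies — on a grid of nested
in-plane slabs: a CSF core, a gray-matter shell, a white-matter shell and
a background rim (kept for noise-floor estimation). Default grid
32×32×8; the test suite uses 8×8×1 up to 16×16×4 (a few hundred fitted
voxels), which keeps whole-suite runtime at a few minutes while exercising
every region class.

Default region truths are physiologically plausible regional means:
CSF Gaussian (Se0 = 2000, D = 2.9×10⁻³ mm²/s, fp = 0), WM Kurtosis-type
(Se0 = 900, D = 0.79×10⁻³, K = 0.82, fp = 5.4%, D* = 5.2×10⁻³), GM
Gamma-type (Se0 = 1000, D = 1.05×10⁻³, K = 1.0, fp = 6.6%, D* = 6.4×10⁻³).
The default noise σ = 10 per complex channel gives b0 SNR ≈ 100 at a
single average; noise is realised per volume and repeat as the magnitude
of `(S + g₁, g₂)`, `gᵢ ~ N(0, σ²)`, reproducibly from a seed. Perfusion
and (by default) diffusion are generated isotropically; a per-direction
diffusivity option exists to exercise the per-direction fitting path.

What the phantom does *not* emulate: realistic anatomy, partial-volume
mixtures at tissue borders, spatially varying coil noise, eddy-current or
EPI distortion, or motion. Passing phantom tests therefore demonstrates
the correctness of the estimator chain, not robustness to those in-vivo
effects — segmentation, registration and distortion handling are outside
this package (tissue probability maps are accepted as input).

## Regional analysis

Tissue masks are built from co-registered probability maps with a strict
threshold (`P > 0.95` by default) to suppress partial-volume and
registration errors. Two exclusion rules then drop physically
uninterpretable fits: tissue (GM/WM) voxels with `MD > D*`, and CSF voxels
with apparent kurtosis above 0.1 (tissue contamination). The exclusions
filter the region mask as a whole, so every parameter of a region is
summarised over the same voxel set. Summaries report per-region mean ± SD
and the GM/WM ratios of fp and D*; multi-subject studies should average
per-subject representative means rather than pooling voxels.

## Known limitations

* Model selection between the Kurtosis and Gamma families is
  noise-limited: after fitting, the two curves differ by well under 1% of
  the signal over the high-b window, so at moderate SNR (b0 SNR ~100 with
  six averages) the per-voxel cAIC contrast between them is of the same
  order as its own sampling noise and a substantial minority of tissue
  voxels select the neighbouring model. The test suite quantifies this on
  the noisy phantom; selection is exact on noiseless data whenever
  K ≥ 0.3. Since the wrong family carries a systematically different Se0
  extrapolation, mis-selection propagates into per-voxel fp errors —
  regional means are far more stable than single voxels.
* The high-b window start (600 s/mm²) trades perfusion contamination
  against kurtosis sensitivity; it is configurable but untested elsewhere.
* The biexponential (two-compartment diffusion) model is deliberately not
  a candidate: its fourth parameter demands a much smaller residual before
  the cAIC prefers it (see the equal-cAIC ratios computed by
  `scripts/acceptance.py`).
* `D*` is reported but poorly conditioned in voxels with little perfusion
  signal; inspect the flag map before interpreting it.
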