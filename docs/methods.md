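# Methods

## Problem setting

Short-wave-infrared (900–1700 nm) hyperspectral imaging can see through
centimetres of soft-tissue-like material because absorption in the NIR-II
biological window (~1000–1350 nm) is low. Tissue phantoms — agar ("collagen")
slabs with embedded lard ("lipid") inclusions of known geometry — provide
exact ground truth for validating two analysis chains on such images:
subpixel target detection (is a buried lipid inclusion detectable, and where?)
and linear spectral unmixing (what fraction of each constituent does a mixed
pixel carry?). This package implements both chains together with a scene
simulator that reproduces the phantom geometries with exact per-pixel truth.

## Endmember spectra

Constituent reflectance is modelled as a Beer–Lambert exponential of a smooth
absorbance curve: a flat baseline plus one unit-height Gaussian per absorption
feature,

    R(λ) = exp(−b − Σᵢ dᵢ · exp(−(λ − cᵢ)² / 2wᵢ²)).

Feature centres follow the constituents' known SWIR absorption bands — water
970/1180/1430 nm, lipid 920/1210/1730/1760 nm, collagen 1200/1500/1725 nm;
centres above the grid maximum are dropped (logged), since a 900–1700 nm
sensor cannot realise them. Depths (0.35–1.2 absorbance), widths (30 nm) and
baselines (0.08–0.15) are declared defaults chosen so the spectra are cleanly
separable yet overlapping — the regime that makes detection and unmixing
non-trivial — not fits to any camera. Each built spectrum is verified to have
a local reflectance minimum within one band of every realised centre.

The default wavelength grid is 900–1700 nm at 5 nm (161 bands); the band
count is configurable (some SWIR sensors deliver several hundred bands over
the same range).

Collagen concentration enters in two ways: `beer_lambert` scaling
(`R^(c/c_ref)`, reference 4 %), used to construct the 2 % and 5 % endpoint
spectra; and `linear_reflectance` mixing, where a panel at concentration `c`
is the convex combination of the endpoints with weight `(5 − c)/3` on the 2 %
spectrum. The panel scenes use the linear rule, which makes the endpoint
spectra exact endmembers and the true abundances known in closed form.

## Optical forward model

A layer buried at depth `z` contributes to the surface spectrum with weight

    f(z) = exp(−2 μ_eff z),

the factor 2 accounting for the two-way illumination/return path through the
overlying medium. This is a deliberate diffuse-reflectance heuristic, not
radiative transfer: it preserves the structure the analysis chain is
validated against (strictly monotone signal loss with depth, exactly linear
mixtures with known abundances) while keeping ground truth exact. The default
μ_eff = 0.04 mm⁻¹ spans strong-to-faint targets over the 7–68 mm depth range
(f ≈ 0.57 down to 0.004).

Noise is i.i.d. Gaussian per band in reflectance units (default
σ = 0.005; 0.002 for the concentration panels), clipped at zero. Identical
(scene, seed) pairs give bit-identical cubes; different seeds change only the
noise realisation, never the ground truth.

What the simulator does **not** emulate: wavelength-dependent attenuation and
scattering phase functions, partial-volume (boundary) pixels with fractional
coverage, spatial noise correlation, stray light and spectral crosstalk
between adjacent phantoms, and radiometric calibration residuals. Passing
tests therefore demonstrate the correctness and numerical robustness of the
algorithms under a controlled linear forward model — not detection limits on
real camera data, where boundary effects and model mismatch dominate.

### Scene geometries and defaults

* **Slab series** — homogeneous collagen slabs (10–80 mm) over a bright grid
  pattern; pixel spectrum = grid(x, y) · collagen(λ) · f(thickness). The mean
  reflectance at the 1073 nm band is the thickness probe (a band where water
  absorption is locally low and collagen absorption locally high).
* **Embedded target** — 120×120 px scene, centred 40×40 px lipid block at
  depth `z`: target pixels `f·lipid + (1−f)·collagen`, background pure
  collagen; ground truth is the block mask (boundary pixels included). The
  mixing fraction can be pinned directly to study detection limits
  independent of the optics.
* **Concentration panels** — four 30×30 px vertical panels at 2/3/4/5 %
  collagen; true abundances `((5−c)/3, 1−(5−c)/3)` over the endpoint
  endmembers.
* **Sloped wedge** — 120 rows × 80 columns; lipid depth grows linearly with
  column from 0 to 40 mm at a 28.25° slope (pixel pitch chosen so the last
  column reaches the maximum depth), clipped there; column spectra are
  `f(z)·lipid + (1−f)·collagen`.

## Detection chain (CEM → Otsu → Tanimoto)

`R` is computed over **all** pixels, target included (global statistics).
Because synthetic scenes can make `R` numerically singular (few distinct
spectra), a ridge `ε = 10⁻⁶ · trace(R)/L` is added before a symmetric solve
(never an explicit inverse); the ridge actually applied is recorded on the
fitted filter, and the unit-response constraint `dᵀw = 1` is enforced to
1e-8. The filter output is invariant to pixel ordering and to positive
rescaling of `R`.

Otsu binarization uses 256 bins on min–max-normalized map values; candidate
thresholds are interior bin edges, the between-class variance is computed
from the actual values via cumulative sums (so the result coincides exactly
with an exhaustive bin-edge search), and variance ties resolve to the lower
threshold. Note that on maps with a wide empty gap between modes every
threshold inside the gap ties, so the reported threshold sits at the gap's
lower edge — the classification is unaffected.

The Tanimoto index of two empty masks is undefined (0/0) and raises rather
than returning a silently misleading value. The depth pipeline additionally
reports the index with a 1-pixel ring around the ground-truth boundary
excluded, since detection errors concentrate at the target/background
boundary.

## Unmixing chain (LS / SCLS / FCLS)

The sum-to-one solution uses the standard Lagrange correction of the LS
estimate,

    α̂ˢᶜᴸˢ = α̂ᴸˢ + (MᵀM)⁻¹1 · (1 − 1ᵀα̂ᴸˢ) / (1ᵀ(MᵀM)⁻¹1),

verified in tests against a raw KKT-system solve. FCLS runs a
Heinz–Chang-style active set: start from SCLS, clamp the most negative
coordinate to zero, re-solve on the surviving support, repeat; the support
only shrinks (no re-entry), so the loop terminates within `p − 1` clamps
(`max_iter = 10p` as a safety net, tol = 1e-9, final clamp-and-renormalize).
On all tested instances this matches both an exhaustive simplex grid search
(step 1e-3) and a nonnegative-least-squares solve of the
sum-to-one-augmented system. All solves go through Cholesky factorizations
of `MᵀM`; condition numbers above 1e10 raise a singular-design error naming
the near-collinear endmembers.

Whole-cube FCLS is vectorized: the SCLS solution is computed for every pixel
in one pass and only pixels with a negative coordinate fall back to the
per-pixel active set — on the phantom scenes that is a small minority, so a
120×120×161 cube unmixes in well under a second.

Endmembers for the pipelines come from in-image reference regions (mean
spectra): the extreme concentration panels, or the shallowest and deepest
wedge columns. A spectral-library signature can be supplied instead; neither
choice is asserted as canonical.

## Experiment pipelines and summary statistics

* **Depth detection**: one embedded-target scene per depth (independent child
  seeds spawned from the pipeline seed), CEM with the pure lipid signature,
  Otsu, Tanimoto vs. truth. A failed depth is recorded as NaN, not fatal.
* **Concentration**: R² is the squared Pearson correlation between the
  panel-mean abundance of the high-concentration endmember and the true
  concentrations — a 4-point linear-trend summary, not a per-pixel
  correlation.
* **Slope**: Spearman ρ between column-mean FCLS fraction and column depth,
  computed cumulatively over all columns from the surface down to each marker
  depth (1–4 cm). The per-marker sample could also be defined as a window
  around each marker; the cumulative convention is this package's documented
  choice. When per-column fractions sum to one, the two endmembers' ρ are
  exact negatives.
* **Penetration**: mean reflectance at the band nearest 1073 nm per slab
  thickness, strictly decreasing whenever μ_eff > 0 and σ = 0.

## Problem sizes and numerical choices

Default scenes are desk-scale: 120×120 px single-target scenes with 40×40 px
blocks, 30×30 px panels, an 80-column wedge — large enough that boundary
pixels are a small fraction of the target, small enough that the full test
suite and the acceptance script run in seconds. Degenerate inputs (constant
maps, empty masks and regions, rank-deficient endmember matrices,
out-of-range wavelengths, non-finite reflectance) raise distinct named
errors rather than propagating NaNs.

## Known limitations

The forward model's depth dependence is band-independent, so simulated deep
targets keep an undistorted (only scaled) lipid signature; real attenuation
is wavelength-dependent and reshapes spectra with depth. Ground-truth blocks
have crisp boundaries, so the simulator understates boundary-driven detection
error. Noise clipping at zero slightly biases very dark pixels. The Otsu
threshold's position inside an empty histogram gap follows the lower-edge tie
rule and should not be interpreted as a calibrated decision boundary.
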