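# Methods

## Point-dipole coupling model

Two unpaired electrons at distance r (nm) couple at

ν_DD(θ) = (μ0/4πh) · g₁g₂ μB² · (1 − 3cos²θ) / r³,

evaluated from CODATA 2018 constants; the prefactor per unit g₁g₂ is
12.98 MHz·nm³, i.e. 52.04 MHz·nm³ for two free-electron spins. The model
neglects exchange coupling J, g-anisotropy and orientation selection by the
pump/observe excitation profiles — adequate for nitroxide–nitroxide pairs
beyond ~1.5 nm at X-band.

Distances are inverted from the θ = 90° (perpendicular) turning point of
the dipolar spectrum, the most intense feature of a powder pattern and the
frequency conventionally read off experimental spectra. The g value
defaults to the free-electron 2.0023 for both spins, including the Co(II)
partner in mixed measurements (overridable; the effective g of low-spin
Co(II) differs, so Co–label distances converted at the default carry extra
systematic uncertainty and are not treated as exact anchors). Distances are
carried in nm internally and reported as integer Å, matching the
significant figures such measurements support.

The powder-averaged time-domain kernel

K(r, t) = ∫₀^{π/2} cos(2π ν_DD(θ) (t − τ)) sinθ dθ

is evaluated by Gauss–Legendre quadrature in u = cosθ, doubling the order
from 32 until successive estimates agree to 1e-6 (absolute) at every time
point; non-convergence by order 8192 raises a diagnostic error. The
adaptive result is verified in the tests against dense-grid Riemann
summation (10⁵–10⁶ nodes) to 1e-5.

## PELDOR processing chain

Fixed stage order: polynomial baseline subtraction → Hamming apodization →
zero-filling → cosine Fourier transform → peak picking → distance
inversion. Choices made where the procedure was genuinely open:

* **Baseline is subtracted, not divided**, preserving the additive cosine
  model of the echo modulation. The default order is 2 with the full trace
  as fit region, appropriate for experimental traces with smoothly decaying
  intermolecular backgrounds. **For synthetic traces with a flat
  background, order 0 is the model-matched choice**: numerically, a
  quadratic fitted across the 1.18-μs window absorbs a large part of any
  dipolar component that completes less than one cycle there (0.5–0.7 MHz),
  biasing the recovered distance by 4–7 Å. Recovery tests therefore pair
  the flat-background generator with order-0 correction.
* **Window convention**: a descending Hamming half-window
  w_k = 0.54 + 0.46·cos(πk/(N−1)) over the acquired points (first point
  ×1.00, last ×0.08), tapering the decay to completion before zero-filling;
  a full symmetric window is available by flag.
* **Phase reference**: the transform uses cos(2πν(t−τ)), with the echo
  refocusing time τ as time origin; pre-τ samples are retained and enter
  coherently.
* **Zero-filling** to 1024 points interpolates the spectrum to a
  1/(1024·8 ns) = 0.122 MHz grid; this is interpolation, not added
  information.
* **Peak picking**: local maxima of the signed transform above 0.2 of the
  spectrum maximum, at ν ≥ 2 resolution bins, refined by three-point
  parabolic interpolation (magnitude mode by flag). Frequencies below one
  resolution bin are flagged sub-resolution.

### Accuracy of recovered distances

The distance error implied by one resolution bin grows as r⁴ (Δr ≈
r·Δν/3ν): ~0.6 Å at 29 Å but ~4.6 Å at 47 Å for this acquisition window.
Two further lineshape effects matter at this short (1.18 μs) window:

* For the **powder-averaged kernel**, folding of the Pake pattern into the
  non-negative cosine-transform axis plus window convolution shifts the
  apparent horn by up to ~0.3 MHz; single-component recovery at 2 % noise is
  accurate to ≤ 2 Å at 29–47 Å (20 seeded replicates per distance), the
  bound used in the tests.
* For the **collapsed perpendicular-cosine model** (modulation exactly
  cos(2πν⊥(t−τ)), the form in which echo modulation is usually written),
  recovery is within max(1 Å, one bin) across 20–47 Å.

Two overlapping components (0.5 + 2.1 MHz) are resolvable in the cosine
model but not from the powder kernel at this window: the sub-cycle 0.5 MHz
leakage tail swallows a 25 %-weight horn at 2.1 MHz regardless of baseline
order or window. Multi-component round trips therefore use the cosine
model; this is a statement about the short acquisition window, not about
the analysis chain.

## Kinetics

**Coupled assay.** Slopes convert via rate = (dA/dt)/(ε·l) with
ε = 6220 M⁻¹cm⁻¹ and l = 1 cm defaults, divided by the catalytic-site
concentration (default 100 nM) for per-enzyme rates. Michaelis–Menten fits
use nonlinear least squares with deterministic starts (k_cat⁰ = max v,
K_m⁰ = s at half-max by interpolation) and, by default, **residuals
weighted by 1/|v|** — the matched estimator when rate noise has constant
coefficient of variation, the usual error structure of initial-rate assays;
unweighted fitting is available. Parameter errors come from the covariance
at the optimum; k_cat/K_m errors use the full first-order formula including
the covariance term.

**Stopped flow.** Single-exponential fits initialize from a log-linear fit
of baseline-subtracted data (tail mean as the offset estimate) and refine
(a₀, ΔA, k_obs) by least squares; the fit is invariant to offset and
amplitude sign. A configurable dead-time prefix (default 1 ms) is discarded
to exclude mixing artifacts in instrument data; synthetic ideal transients
are fitted with dead time 0, since discarding the first millisecond removes
the most rate-informative part of a ~900 s⁻¹ decay. Rates implying less
than one half-life in the observation window are flagged low-confidence.

## Synthetic data

Generators are pure functions of their spec (seed included).

* **PELDOR**: V(t) = B(t)·[(1−λ) + λ·Σ wᵢK(rᵢ,t)] + ε, with modulation
  depth λ defaulting to 0.3 (typical of X-band nitroxide PELDOR; the value
  is not critical because processing is linear), flat background by default
  (B = exp(−k|t−τ|) available), Gaussian noise with SD given as a fraction
  of λ, and the acquisition timing defaulting to 148 points × 8 ns,
  τ = 200 ns. A flag collapses the orientation average to θ = 90°.
* **Michaelis–Menten**: v = k_cat·s/(K_m+s)·(1+ε), ε ~ N(0, CV). The
  default 10-point design spans 10–2250 μM with a low block around K_m
  (which carries the K_m information) and replicates at saturation (which
  carry the k_cat information) — the standard way initial-rate designs
  split their information budget. At 5 % noise this yields median recovery
  errors of ~1.5 % (k_cat) and ~4 % (K_m) over 100 replicates.
* **Stopped flow**: A(t) = a₀ + ΔA e^(−k_obs t) + ε on a uniform grid over
  0.25 s (5000 points ≈ 20 kHz), decreasing absorbance as at 528 nm.
* **Dimer fixtures**: synthetic coordinate embeddings (not crystallographic
  coordinates) realizing the open-state label distances (49 Å
  Cys700–Cys352, 29 Å Cys352–Cys352′, all other Cys pairs > 60 Å, C2
  dimer symmetry) and the closed-state Co–label distances (19 Å Co–Cys352
  with a 17 Å alternative Co position, 31 Å Co–Cys352′). Constraints are
  verified to 0.01 Å at build time; files are valid PDB text.

What the generators do **not** emulate: orientation selection, label
rotamer distributions (distances are point positions, not conformer
ensembles), electron-spin relaxation, heteroscedastic assay noise, and
multi-step homolysis kinetics. Passing tests therefore demonstrate the
correctness of the processing mathematics and estimator behaviour under
the stated noise models, not robustness to every pathology of real data.

## Structure mapping

Label positions default to the cysteine SG atom; the MTSL nitroxide
midpoint lies several Å further out, so a configurable offset along the
Cα→SG direction could be added where coordinates support it (fixtures
encode stated distances directly, so the default offset is 0).
Measurability requires the perpendicular dipolar frequency to complete at
least 0.4 cycles in the evolution window (n·dt) and to lie below Nyquist
(1/2dt); 0.4 cleanly separates 49 Å (0.52 cycles) from the > 60 Å pairs
(< 0.29 cycles) at the default timing. Reconciliation is greedy one-to-one
nearest matching within a 5 Å default tolerance (ties broken by smaller
gap, then lexical site names), with an optional spin-pair-kind filter so
that Co(II)-to-label measurements are never matched against label–label
predictions that merely happen to have similar lengths.

## Problem sizes

Recovery studies use 20 seeded replicates per distance (PELDOR), 100
datasets (Michaelis–Menten) and 20–50 traces (stopped flow) — enough for
stable medians at the stated noise levels while keeping the full suite in
a few seconds.

## Known limitations

* No Tikhonov distance-distribution inversion or background-dimension
  fitting; the chain reads turning points, it does not recover P(r).
* The Co(II) effective g is not modelled; mixed-pair distances converted at
  g = 2.0023 are approximate by design and flagged in results metadata.
* Sub-cycle frequencies (≲ 0.85 MHz at this window) carry the documented
  lineshape bias; lengthening the evolution window is the physical remedy.
* The coupled/isolated regime cutoff (default 10 Å) is a heuristic
  classification aid, not a quantitative exchange/dipolar model.
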