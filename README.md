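# oamspin

Tools for measuring and interpreting nanometre-scale conformational changes
in a dimeric adenosylcobalamin (AdoCbl)-dependent radical enzyme — ornithine
4,5-aminomutase (OAM) — from pulsed EPR distance data and rapid kinetics.

These enzymes are thought to couple a large-scale motion of the
cobalamin-binding domain onto the substrate-loaded TIM-barrel domain to the
homolysis of the Co–C bond that starts radical catalysis. Three kinds of
measurement probe that model, and this package implements the analysis for
each:

1. **Four-pulse PELDOR (DEER) distance analysis.** Two unpaired electron
   spins — nitroxide (MTSL) labels on engineered cysteines, or a label and
   the Co(II) radical pair — modulate the refocused echo at the dipolar
   coupling frequency

   ν_DD = (μ0 / 4πh) · g₁g₂μB² · (1 − 3cos²θ) / r³,

   where r is the inter-spin distance and θ the angle to the applied field.
   The processing chain is: second-order polynomial baseline subtraction →
   Hamming apodization → zero-filling to 1024 points → cosine Fourier
   transform phase-referenced at the echo time τ → peak picking → inversion
   of the θ = 90° turning-point frequency to a distance (52.04 MHz ↔ 1 nm
   for two free-electron spins).

2. **Enzyme kinetics.** A coupled assay (NAD⁺ reduction at 340 nm,
   Δε = 6220 M⁻¹cm⁻¹) yields rates fitted to v = k_cat·s/(K_m + s) with
   catalytic efficiency k_cat/K_m and full covariance error propagation;
   stopped-flow 528-nm transients reporting Co–C homolysis are fitted to
   A(t) = a₀ + ΔA·e^(−k_obs·t).

3. **Structural distance mapping.** Label-site distances predicted from a
   coordinate model are classified as measurable or not under a given
   acquisition window (minimum dipolar cycles + Nyquist criteria) and
   reconciled with measured distances by one-to-one nearest matching,
   optionally restricted by spin-pair type (label–label vs. Co–label).

A seeded synthetic-data module generates every input class — dipolar traces
at the experimental timing (148 points, 8-ns steps, τ = 200 ns), coupled
assay datasets (k_cat ≈ 0.1–3 s⁻¹, K_m ≈ 180–195 μM), stopped-flow
transients (500–1000 s⁻¹ over 0.25 s), and synthetic open/closed dimer
coordinate fixtures — so the full pipeline is testable without downloads.

## Worked example

Simulate a two-component resting-state-like trace (4.703 nm at weight 0.75,
2.916 nm at weight 0.25, 2 % noise) and run the analysis chain:

```python
from oamspin import (PeldorSimSpec, PipelineConfig, analyze, simulate_peldor,
                     efficiency_with_error)

spec = PeldorSimSpec(components=((4.703, 0.75), (2.916, 0.25)),
                     noise_sd=0.02, seed=1, perpendicular_only=True)
report = analyze(simulate_peldor(spec), PipelineConfig(baseline_order=0))
for a in report.assignments:
    print(f"nu = {a.nu_dd:.2f} MHz  rel. amp = {a.rel_amplitude:.2f}  ->  r = {a.r_A} A")

value, _ = efficiency_with_error(2.97, 189.0)
print(f"kcat/Km = {value/1e3:.1f} x10^3 M^-1 s^-1")
```

prints

```
nu = 0.55 MHz  rel. amp = 1.00  ->  r = 46 A
nu = 1.86 MHz  rel. amp = 0.42  ->  r = 30 A
kcat/Km = 15.7 x10^3 M^-1 s^-1
```

Both dipolar components come back (the longer distance dominant, as in the
doubly labeled dimer, where the weaker 2.1 MHz feature reflects the
cross-dimer Cys352–Cys352′ pair), each within the frequency-resolution
bound of its true distance: the 0.5 MHz feature completes only ~0.6 of a
cycle in the 1.18-μs window, so its distance carries a few-Å uncertainty.
The efficiency line reproduces the wild-type value on the conventional
×10³ M⁻¹s⁻¹ scale.

The same operations are available from the shell:

```sh
oamspin simulate peldor --r 2.916 --weight 1 --out sim/
oamspin analyze-peldor --trace sim/trace.csv --timing sim/timing.json \
    --baseline-order 0 --out results/
oamspin fit-kinetics mm --data mm.csv --enzyme-nM 100 --out results/
oamspin map-structure --pdb dimer.pdb --sites sites.yaml \
    --timing timing.yaml --assignments measured.csv --out results/
oamspin reproduce --seed 1 --out results/
```

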