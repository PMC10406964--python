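# trbva — time-resolved burst variance analysis for smFRET

Single-molecule FRET experiments on freely diffusing molecules deliver, per
molecule, a short burst of donor and acceptor photons collected while the
molecule transits the confocal spot. Conformational exchange between states
with different FRET efficiencies broadens the apparent-efficiency
distribution beyond shot noise, but the kinetic rates behind that broadening
are hard to extract: correlation methods are blinded near the ~1 ms
diffusion time, and likelihood methods need explicit model fits before any
dynamics are visible. Time-resolved burst variance analysis (trBVA) extends
classical burst variance analysis into a quantitative rate estimator that
works from roughly 5 µs to 5 ms and needs only a few thousand bursts.

This package provides, for experimentalists and method developers:

* a photon-by-photon Brownian-dynamics simulator of diffusing,
  interconverting, bleachable FRET particles with pulsed interleaved
  excitation (PIE), channel crosstalk, direct acceptor excitation and
  background;
* burst search, standard count corrections, and PIE-based filtering
  (stoichiometry and acceptor-bleaching cuts);
* the trBVA statistic itself and closed-form kinetic fits;
* the donor–acceptor cross-correlation `G_DA(τ)` as a comparison method;
* a CLI (`trbva-kit simulate|bursts|trbva|fit|gda|benchmark`).

## The statistic

Bursts are partitioned into consecutive segments of `m` photons. With
`ε_ij = a_ij/m` the acceptor fraction of segment `j` of burst `i`, the
pooled variance over all segments

    s²(m) = Σ_ij (ε_ij − ⟨ε⟩)² / (Σ_i M_i − 1),      ⟨ε⟩ = Σ a_i / Σ n_i,

is compared with the shot-noise variance of a single emitting state,
`σ²(m) = ⟨ε⟩(1−⟨ε⟩)/m`. The excess variance `S²(m) = s²(m) − σ²(m)` is zero
for a static single state, grows like `⟨δε²⟩(1 − 1/m)` for frozen
heterogeneity, and for dynamic exchange first rises and then decays with
`m`. Writing the FRET autocorrelation `g(t) = ⟨δε(0)δε(t)⟩`, the excess
variance of segments with duration `t` is

    Δs²(m,t) = (1/m²)[ 2g(t) + (4(m−2)/t)∫₀ᵗ g
                       + (2(m−2)(m−3)/t²)∫₀ᵗ (t−t′) g(t′) dt′ ],

with all integrals in closed form for multi-exponential `g`. Averaging
`Δs²(m,t)` over the *measured* histogram of segment durations `H(t|m)`
predicts `S²(m)`, and an unweighted least-squares fit over the `m` grid
yields the amplitude `⟨δε²⟩` and the observed rate
`k_obs = k₁₂ + k₂₁ = 1/τ`. For a two-state system
`g(t) = ⟨δε²⟩ e^(−k_obs t)`; a three-state system adds a second
exponential whose rates are the nonzero eigenvalues of the rate matrix.

## Worked example

```python
import numpy as np
from trbva import (DiffusionConfig, KineticConfig, DetectionConfig,
                   run_simulation, CorrectionParams, process_stream,
                   trbva_trace, fit_trace)

# two-state molecule, k12 = k21 = 0.5 /ms  ->  tau = 1/(k12+k21) = 1 ms
diff = DiffusionConfig(t_total_s=300.0)
kin = KineticConfig.two_state(5e-4, 5e-4)          # rates in 1/us
det = DetectionConfig()                            # study-condition defaults

stream = run_simulation(diff, kin, det, seed=1)
print(f"photons: {stream.n_photons}")

corr = CorrectionParams.from_detection(det)
kept, all_bursts = process_stream(stream, corrections=corr)
print(f"bursts: {len(kept)} kept of {len(all_bursts)}")

trace = trbva_trace(kept, stream)
fit = fit_trace(trace, n_exponentials=1)
print(f"amplitude <d eps^2> = {fit.amplitudes[0]:.4f}")
print(f"relaxation time tau = {fit.tau_us[0]:.0f} us")
```

Output:

```
photons: 3223817
bursts: 875 kept of 1278
amplitude <d eps^2> = 0.1277
relaxation time tau = 1121 us
```

The five simulated minutes yield 875 vetted bursts. The fitted relaxation
time (1121 µs) recovers the ground truth (1000 µs) within 12%, and the
fitted amplitude matches the expectation for apparent efficiencies
ε₁ ≈ 0.18 and ε₂ ≈ 0.89 with equal populations,
`⟨δε²⟩ = ¼(ε₂−ε₁)² ≈ 0.126`. Longer runs (the benchmark uses ~5000 bursts
per rate) tighten the estimate further.

The same pipeline from a shell:

```
trbva-kit simulate --seed 1 --out run.h5
trbva-kit bursts   --in run.h5 --out bursts.csv
trbva-kit trbva    --bursts bursts.csv --photons run.h5 \
                   --out trace.csv --hist-out hist.csv
trbva-kit fit      --trace trace.csv --hist hist.csv --out fit.json
```

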