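# Methods

## Scope and model

The package quantifies conformational exchange rates from diffusing-molecule
smFRET photon streams via time-resolved burst variance analysis (trBVA). The
molecular model is a continuous-time Markov chain (CTMC) over conformational
states, each with a fixed apparent FRET efficiency; the observable is the
acceptor fraction ε of m-photon burst segments. The estimator compares the
pooled segment variance with the binomial shot-noise expectation and fits
the decay of the excess variance S²(m) with closed forms derived from the
FRET autocorrelation g(t).

Key assumptions:

* photon colors are conditionally independent Bernoulli draws given the
  instantaneous state (no antibunching, no lifetime information);
* g(t) is a finite sum of decaying exponentials — exact for any
  irreducible CTMC with real relaxation spectrum;
* the segment-duration distribution H(t|m) is estimated from the data
  themselves, so no diffusion model enters the fit.

## Simulator

The simulator emulates a confocal smFRET experiment with radial symmetry:

* **Diffusion.** 1-D radial Euler steps
  `r ← r + 2DΔt/r + N(0, 2DΔt)` with Δt = 1 µs, D = 5×10⁻⁵ µm²/µs
  (a ~4 nm Stokes radius in water), inside a sphere of R = 3 µm; particles
  are absorbed at the boundary. A negative candidate radius is reflected
  (`|r'|`), which preserves the radial flux at this step size.
* **Concentration.** The initial count is Poisson with mean
  n₀ = (4/3)πR³c₀ (c₀ = 50 pM → n₀ ≈ 3.4). Every T_new a Poisson number of
  particles enters near the boundary; the mean
  `n_new = n₀[1 − (6/π²)Σ n⁻² exp(−Dn²π²T_new/R²)]` and the entry-radius
  density `P_new(r) ∝ 4πr²c_new(r)` both follow from the series solution of
  the radial diffusion equation with c(R) = c₀. (The volume integral fixes
  the sign of the series so that n_new → 0 as T_new → 0.) T_new is a free
  parameter of the scheme; the default 1000 µs keeps the per-period influx
  below one particle while the entry layer stays thin (≈ 0.25 µm). Series
  are truncated at a 10⁻¹² relative term.
* **States.** Basis {donor-only, FRET states…, acceptor-only}. Conformational
  switching uses the exact per-step transition matrix exp(K₀Δt);
  photobleaching is layered on top as per-step Bernoulli hazards
  ka·E_s·I(r) (acceptor → donor-only) and kd·(1−E_s)·I(r) (donor →
  acceptor-only), with I(r) = exp(−2r²/w₀²), w₀ = 0.4 µm and
  ka = kd = 5×10⁻⁴ µs⁻¹. The operator splitting error is O((kΔt)²) and
  far below all statistical errors at these rates. Initial states follow
  p₀ = (0.1, 0.8·p_eq, 0.1).
* **Emission.** Per step, Poisson photon counts with mean rate λ_tot·I(r)
  (λ_tot = 0.4 µs⁻¹ at the center). A FRET state with corrected efficiency
  E emits donor-channel photons at λ(1−E) and acceptor-channel photons at
  λ(γE + β(1−E)) plus direct excitation; γ = 1.16, β = 0.054, α = 0.048.
  Direct excitation is modeled at α times the acceptor-excitation rate so
  that the standard correction nDA − α·nAA removes it exactly in
  expectation; with the printed factors, corrected E = 0.1/0.9 correspond
  to apparent ε ≈ 0.18/0.89. PIE is represented by per-photon excitation
  labels: species with an active acceptor respond to acceptor excitation at
  λ_tot·I(r)/γ_PIE (γ_PIE = 2); no nanotimes or IRFs are modeled, because
  downstream analysis consumes only labels and macrotimes. Backgrounds are
  homogeneous Poisson processes (5.6×10⁻³ and 3×10⁻³ µs⁻¹ for donor and
  acceptor channels) with excitation labels at equal duty cycle.
* **Performance.** One fused numba kernel simulates each particle's life.
  Beyond r = r_cut (where I(r) = 10⁻⁶) emission and bleaching are skipped —
  the neglected emission is four orders of magnitude below the background
  rate — and beyond r_cut + 0.3 µm the time step is coarsened by an integer
  factor (default 16). Coarsening a pure Gaussian step is statistically
  exact; the O(Δt) drift-term error at r > 1.3 µm is negligible, and the
  0.3 µm margin is ≳7 standard deviations of a coarse step, so a particle
  cannot jump from the dark zone into the emitting zone unseen. Setting
  `far_field_factor=1` disables the coarsening. Runs are bit-reproducible
  per seed; all randomness derives from one `SeedSequence`.

### What the generator does not emulate

3-D/elliptical point-spread functions, saturation, antibunching, triplet
photophysics as an explicit species, lifetime/IRF effects, and detector
afterpulsing. Passing benchmarks therefore demonstrate correctness of the
estimator under the stated generative model, not robustness to every
instrumental artifact of real data.

## Burst selection

Photon traces are binned at 100 µs; a burst is a maximal run of bins with
more than two photons, kept if it contains ≥ 100 donor-excitation photons.
The per-bin threshold counts all photons by default (a flag restricts it to
donor-excitation photons; the choice is not determined by the method's
definition and changes burst edges only marginally). Corrections are applied
in the community-standard order background → leakage → direct excitation →
γ, and the corrected efficiency is E = nDA/(nDA+nDD). Negative corrected
counts are clamped at zero and flagged.

Two PIE filters vet the list. The stoichiometry
S_PIE = (nDD+nDA)/(nDD+nDA+γ_PIE·nAA) must be < 0.65 (removes donor-only
molecules). The detection-time asymmetry α_PIE = ⟨t_Dex⟩ − ⟨t_Aex⟩ (ms) is
compared with its shot-noise scale σ_PIE = (T/2√3)·√(1/(n'DD+n'DA) +
1/n'AA); the default cut keeps a burst when σ_PIE < 0.15 ms **and**
|α_PIE| ≤ 2σ_PIE. The published threshold is stated only as
"σ_PIE < 0.15", which by itself does not involve the measured asymmetry;
the conjunction above is this package's reading, and `sigma_only` /
`alpha_only` modes are available. T is the last-minus-first photon time of
the burst.

## trBVA estimator

Segments use donor-excitation photons only, uncorrected, in time order;
each burst contributes ⌊n_i/m⌋ segments and trailing photons are discarded
(never wrapped across bursts). The pooled mean ⟨ε⟩ counts all photons of
the selected bursts (the difference from segment-covered photons is
O(m/n_i)); in FRET-resolved mode ⟨ε⟩ is recomputed from the windowed
subset. The default m grid is every integer 2–10 plus log-spaced values up
to the largest m that retains ≥ 1000 segments. Duration histograms use 100
equal-width bins on [0, max t] with bin centers as representative times.

The closed forms for Δs²(m,t) per exponential term use
`(1−e^(−x))/x` and `(x−1+e^(−x))/x²` with x = λt, evaluated via `expm1`
and switched to 3rd-order Taylor expansions below x = 10⁻⁶ (the two
branches agree to ~10⁻¹⁰ at the switch). The static λ = 0 limit,
Δs² = A(1−1/m), falls out of the same guard. Fits minimize the unweighted
χ² = Σ_m (S²_meas − S²_model)² with bounded trust-region least squares,
multi-started from 8 log-spaced rates over 10⁻³–10³ ms⁻¹ (best χ² wins,
ties to the smaller rate); amplitudes are bounded by the theoretical
maximum 0.25. Rates at a bound are flagged. Model order (1 vs 2
exponentials) is reported through residuals and χ², not automated.

In the FRET-resolved amplitude profile, windowed amplitudes are fitted with
the constrained parabola ⟨δε̄²⟩ = −(ε̄−ε₁)(ε̄−ε₂) — linear least squares in
(ε₁+ε₂, ε₁ε₂) — whose roots estimate the state positions. Windowed *rates*
are biased upward near the midpoint (transition-free bursts are depleted
there), which the tests assert rather than correct: rates should be taken
from the global trace.

## Cross-correlation comparison

G_DA(τ) is computed on 1 µs binned donor-excitation counts of the selected
bursts, with a quasi-logarithmic lag grid, and normalized by the global
mean channel rates of the pooled bursts (per-burst normalization would
cancel the across-burst heterogeneity that carries most of the kinetic
signal). The empirical fit f(τ) = a(1−e^(−k_obs·τ)) + b·e^(−(τ/t_D)^β) + c
uses bounded least squares with β ∈ (0.5, 2], t_D within 0.1–10× the mean
burst duration, amplitudes in [0, 3], and a multi-start over k_obs. Near
the diffusion time the (a, k_obs) and (b, t_D, β) terms are strongly
degenerate, so the recovered timescale there is unstable from dataset to
dataset — which is precisely the failure mode trBVA avoids; the *magnitude*
of that failure depends on correlator and fit details, and this
implementation's global multi-start often lands closer to the truth than a
single-start fit would.

## Problem sizes

The accuracy benchmarks use four rate points with relaxation times 5 µs,
50 µs, 1 ms and 5 ms at ~5000 vetted bursts per point (≈ 25 simulated
minutes each), chosen as the package's desk-scale benchmark; the
`BenchmarkSpec` default provides the full 9-point log-spaced sweep for
larger runs. The burst-economy analysis subsamples three independent
mid-range datasets at 625–5000 bursts. Property tests use diffusion-free
CTMC photon processes (hundreds to thousands of pseudo-bursts), where every
expected value has an analytic or bootstrap oracle.

## Known limitations

* The radial-symmetry reduction makes transit-time statistics only
  approximately those of a 3-D Gaussian volume; since H(t|m) is measured,
  this does not bias the kinetic fit, but absolute burst rates are not
  calibrated against real instruments.
* Corrected E may leave [0, 1] after background subtraction on dim bursts;
  values are clamped only at the count level, not at the efficiency level.
* Rates far outside 10⁻³–10³ ms⁻¹ hit the fit bounds and are flagged
  rather than extrapolated.
* For ≥ 3 states only eigen-amplitudes and eigenrates are fitted, not the
  full rate matrix.
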