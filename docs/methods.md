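# Methods

## The model

`quantalca` implements the computational machinery behind quantal
("incremental") Ca²⁺ release from the endoplasmic reticulum through IP₃
receptors (IP₃Rs): submaximal IP₃ concentrations rapidly release only part
of the store, release then stops, yet the store remains fully responsive
to a further IP₃ increment.

The model has three coupled layers.

### 1. Tetrameric occupancy

The IP₃R is a tetramer that opens only when all four subunits have bound
IP₃. With independent, identical sites (per-site Hill coefficient 1) the
per-site occupancy at ligand concentration *L* is the Langmuir isotherm
α = (*L*/K_D)/(1 + *L*/K_D), and the fraction of fully liganded
(open-eligible) receptors is α⁴. Because α⁴ is a steep function of *L*
below K_D, a cell expressing tens of thousands of receptors holds only a
handful of tetra-liganded ones at functionally effective concentrations —
the "spare receptor" arithmetic that makes quantal increments possible.
The default K_D is 794 nM (competition binding under the ionic conditions
of the functional assays); default receptor counts are 49,146 per
HEK-IP₃R1 cell, 9,101 per wild-type HEK cell, and 2×10¹⁰ per 96-well
population (4×10⁵ cells/well).

Ligand binding/unbinding (k_on ≈ 3.5 s⁻¹ at 100 nM, k_off ≈ 28 s⁻¹) is
orders of magnitude faster than gating, so each IP₃ addition is treated
as an instantaneous jump in the tetra-liganded count; partially liganded
receptors are not modelled.

### 2. Three-state stochastic gating

Tetra-liganded receptors move among closed (C₄), open (O₄) and
inactivated (I₄) states on a triangular scheme with one forbidden edge:

    C₄ →O₄ k₁ = 0.4 s⁻¹        O₄ →C₄ k₁/100
    O₄ →I₄ k₂ = 0.2 s⁻¹        I₄ →O₄ k₂/100
    I₄ →C₄ k₃ = 0.004 s⁻¹      C₄ →I₄ forbidden

A receptor therefore opens quickly once tetra-liganded (mean closed
residence 1/k₁ = 2.5 s), inactivates within seconds (mean open residence
1/(k₂+k₁/100) ≈ 4.9 s), and recovers slowly (mean inactivated residence
1/(k₃+k₂/100) ≈ 167 s; 250 s when the I₄→O₄ reverse step is disabled).
Each addition drives a near-synchronous surge of openings followed by
stable inactivation — the quantal pattern.

The chain advances on a fixed step Δt = 12.5 ms: each receptor takes
allowed exit *i* with probability k_i·Δt per step (at most one transition
per step; construction rejects max(k)·Δt ≥ 0.1, keeping the O((kΔt)²)
discretization error negligible — halving Δt moves the exact mean
trajectory by less than one binomial standard error at 10⁵ receptors).
Because receptors are exchangeable, the default engine advances
per-state *counts* with binomial/multinomial draws, which is
distributionally identical to looping over receptors and makes 2×10¹⁰
receptors per well tractable; a literal per-receptor mode is retained for
validation. A matrix-exponential master-equation solver
(`meanfield_occupancies`) and the null space of the generator
(`stationary_distribution`) serve as deterministic oracles. Note that the
stationary O₄/I₄ ratio is (k₃+k₂/100)/k₂ = 0.03, since I₄ drains through
both its exits.

All randomness flows through `numpy.random.Generator` (PCG64) from a
single explicit integer seed recorded in every output.

### 3. ER luminal Ca²⁺

Luminal free Ca²⁺ (C_ER, μM) obeys

    dC_ER/dt = −(k_leak + k_rel·O₄)·(C_ER − C) [+ (500 − C_ER)/τ_SERCA]

with k_leak = 1.8×10⁻⁴ s⁻¹ (IP₃-independent leak), k_rel = 8×10⁻⁴ s⁻¹
per open receptor, the cytosolic level C clamped at 0.22 μM by the
buffered medium, C_ER(0) = 500 μM, and — when SERCA pumps are active —
refill toward the 500 μM loading plateau with τ_SERCA = 100 s (the refill
target is fixed at 500 μM, not a free parameter). A competitive
antagonist (heparin-like) is simulated by setting k_rel = 0 from the
addition time. The analytic steady state with pumps active and no open
receptors, (500/τ + k_leak·C)/(1/τ + k_leak) ≈ 491.2 μM, is used as a
refill oracle in tests.

**Releasable pool.** Only 80% of the store is releasable through IP₃Rs.
C_ER is split at t = 0 into releasable (80%) and non-releasable (20%)
pools; the k_rel·O₄ term draws exclusively on the releasable pool, the
leak acts on the total (apportioned by pool share), and SERCA refill is
split by the same 80/20 ratio so a loading phase preserves the pool
fractions. Reported C_ER is the sum. This reading reproduces both the
early kinetics of the release equation and the sub-100% plateau of
IP₃-evoked release; whether the leak should also be restricted to the
releasable pool is not determined by the source material, and the
total-pool choice is ours.

Integration is explicit Euler locked to the gating step (12.5 ms), which
is deeply stable for these rates (total rate ≪ 1/Δt); halving the step
changes the final content by < 0.01% over 1,000 s (property-tested).
Population wells are integrated on the per-cell mean open count
(O₄_well / cells) with the per-cell k_rel, so fractional depletion
matches the single-cell equation.

**Cell geometry.** Total ER Ca²⁺ content = free luminal Ca²⁺ (500 μM) ×
buffer ratio (5) × ER volume, with ER volume = cell volume (1.1×10⁻¹² L)
× 0.9 (non-nuclear) × 0.35 (ER share) = 3.465×10⁻¹³ L, giving ≈ 8.7×10⁻¹⁶
mol (~9×10⁻¹⁶). A single channel conducting 5×10⁵ ions/s for 20 s
releases just under 2% of that. The same arithmetic inverted
(`estimate_k_rel`) gives k_rel ≈ 9.6×10⁻⁴ s⁻¹; the printed model default
of 8×10⁻⁴ s⁻¹ is retained since the exact volume normalization behind it
is not written out, and the two agree to ~20%.

## Inverse analysis

The inverse pipeline (`quantalca.analysis`) reconstructs open-receptor
time courses from luminal fluorescence traces (sampling interval 1.44 s;
fluorescence assumed linear in ER free Ca²⁺):

1. **Leak fit.** A mono-exponential is fitted to the window between SERCA
   inhibition and the first stimulus; its analytic derivative gives the
   leak flux J_leak(t), and the (content, J_leak) pairs are fitted by a
   second-degree polynomial (default) or exponential so the leak can be
   subtracted at matched content anywhere in the record.
2. **Leak subtraction.** evoked_flux = −dF/dt − J_leak(content). The
   stimulus-window derivative uses central differences after
   Savitzky–Golay smoothing (default window 7 samples ≈ 10 s, order 2;
   raw finite differences on noisy 1.44 s data are unusable).
3. **Reconstruction.** C_ER(t) is rebuilt by trapezoidal integration of
   the evoked flux from the content at the first stimulus.
4. **Open receptors.** open_au(t) = evoked_flux/(C_ER − C_cyt),
   proportional to the true open count by the unknown k_rel. Samples with
   gradient below 2% of the initial gradient are masked (not divided);
   noise-negative fluxes are kept in the flux output but clipped at zero
   only at this final step (`clip=False` gives the signed, mean-unbiased
   estimate used for null checks on unstimulated traces).
5. **k_leak.** J_leak evaluated at a reference content (e.g. the 500 μM
   plateau) divided by the gradient there.

**Leak-fit conditioning.** When the pre-stimulus window covers only a few
percent of the full decay (k_leak·window ≈ 0.1), the free three-parameter
exponential fit is ill-conditioned: rate and asymptote trade off, and at
1% noise the median rate error is ~80%. `fit_leak` therefore accepts a
fixed asymptote — in permeabilized-cell experiments the cytosolic level
is clamped and known — which brings the median rate error to ~1% under
the same noise. The free fit remains the default and is exact on clean
data.

## Synthetic data

`quantalca.synthetic` composes the three layers into plate-reader-style
recordings with the canonical load–inhibit–stimulate shape: SERCA loading
from 150 μM toward the ~500 μM plateau (ATP at t = 0), SERCA inhibition
at t = 300 s, a 500 s bare-leak segment, then stimulus additions from
t = 800 s (templates with stimuli run 1,100 s). Additive white Gaussian
noise is specified as a fraction of the clean trace's dynamic range
(default 1% — the source material gives no noise magnitude, so this is a
calibration knob chosen to make recovery nontrivial but achievable, and
it is configurable). Every generated trace carries a ground-truth bundle
(true O₄(t), C_ER(t), injected counts, parameters, seed) and regenerates
bit-for-bit from its seed.

Ready-made templates: `population_96well` (sequential 60/90/120 nM),
`population_direct`, `single_cell` (additions forming 5, then ×4.41, then
×2.76 tetra-liganded receptors out of 9,101), `incremental` (population
additions 120/186/300 nM spanning the Ca²⁺-release EC₅₀ of 186 nM, used
for inverse-reconstruction checks because its evoked fluxes are well
above the derivative noise floor), `antagonist` (1 μM stimulus with pumps
active, release zeroed at 600 s), and `leak_only`.

**What the generator does not emulate:** well-to-well biological
variability, indicator photophysics and bleaching, nonlinearity of the
fluorescence–Ca²⁺ relation, ER heterogeneity or fragmentation, and
cytosolic Ca²⁺ feedback on gating (absent from the scheme by design).
Because the generator's noise is additive and white and its leak is
exactly mono-exponential, the inverse pipeline is correctly specified on
synthetic data by construction; passing round-trip tests therefore
demonstrates internal consistency and statistical power, not robustness
to the mis-specification real recordings would add.

## Design notes and numerical choices

- Concentrations are nM in the pharmacology layer (p-values computed
  after conversion to molar), μM in the luminal layer, s throughout.
- Hill fits are nonlinear least squares initialized from the data
  (bottom = min, top = max, midpoint = concentration nearest half-range,
  h = 1) and raise on degenerate input rather than returning defaults.
- The IC₅₀→K_D conversion uses the standard Cheng–Prusoff correction
  K_D = IC₅₀/(1 + [L*]/K_D*); the antagonist K_D uses the Schild relation
  K_D = [B]/(DR − 1), valid only for DR > 1.
- Binding energetics: ΔG = −RT ln K_D (K_D in molar); ΔΔG between the
  isolated binding core and the longer N-terminal construct reports the
  binding energy diverted into conformational change. Default T = 277.15 K
  (4 °C binding assays).
- Injected tetra-liganded counts are rounded to the nearest integer
  (floor 0): stochastic simulation needs integers, and the single-cell
  protocols are specified as exact small counts (5/10/20).
- The residence times quoted as ~2.5/5/250 s are the reciprocals of the
  exit-rate sums, and the reciprocal reading is used throughout.

## Scale of the shipped checks

Test and acceptance runs are sized for a laptop-class single core:
stochastic-vs-master-equation comparisons use 2×10⁴ receptors over 60 s,
dwell-time statistics use 2×10⁴ samples, Monte-Carlo fit-recovery uses
100 replicates, and the incremental-vs-direct comparison uses 12 seeds of
a single 9,101-receptor cell over 80 s. All agreements are asserted in
units of the corresponding Monte-Carlo standard error, so they are
scale-honest.

**Incremental vs direct additions.** The scheme predicts that sequential
additions reaching a given final concentration release the same total
Ca²⁺ as one direct addition of that concentration, because the final
tetra-liganded count — and hence the total open time — is the same. This
holds exactly only up to slow I₄→C₄ recycling: receptors injected earlier
in a sequential protocol have more time to recover and reopen, so at
~100 s spacings the model predicts a few percent more cumulative release
for the sequential path. The equivalence test uses closely spaced
additions (10 s), where that recycling correction is far below
Monte-Carlo resolution, to measure the occupancy-equivalence property
itself.

## Known limitations

- The gating scheme is empirical: no cytosolic Ca²⁺ feedback, no
  partially liganded intermediates, no spatial clustering, no ligand
  depletion.
- The releasable/non-releasable partition is phenomenological; the
  mechanism that renders 20% of the store unavailable is not modelled.
- The inverse pipeline's derivative estimator (Savitzky–Golay window) is
  a tunable: wider windows bias sharp O₄ peaks downward, narrower ones
  admit noise. The defaults suit 1.44 s sampling and ~1% noise.
- `estimate_k_rel` and the model default k_rel differ by ~20% (see
  above); results that depend on absolute open-receptor numbers inherit
  that uncertainty, while the arbitrary-unit reconstructions do not.
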