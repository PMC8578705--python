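# quantalca

Modelling and analysis tools for **quantal Ca²⁺ release** through IP₃
receptors (IP₃Rs): why a submaximal IP₃ concentration rapidly releases
only part of the ER Ca²⁺ store, stops, and yet leaves the store fully
responsive to the next IP₃ increment.

The package is aimed at Ca²⁺-signalling labs who want to (i) do the
occupancy and pharmacology arithmetic for tetrameric receptors, (ii)
forward-simulate receptor gating coupled to store content, and (iii) run
the inverse analysis that turns plate-reader recordings of luminal Ca²⁺
into open-receptor time courses.

## The model in brief

- **Occupancy.** The IP₃R opens only when all four subunits bind IP₃.
  With independent sites, per-site occupancy is
  α = ([L]/K_D)/(1 + [L]/K_D) and the open-eligible fraction is α⁴ — so
  at functionally effective concentrations only a tiny fraction of a
  cell's receptors (e.g. ~0.13% at the release EC₅₀) can open at all.
- **Gating.** Tetra-liganded receptors move among closed, open and
  inactivated states (C₄ → O₄ at k₁ = 0.4 s⁻¹, O₄ → I₄ at k₂ = 0.2 s⁻¹,
  I₄ → C₄ at k₃ = 0.004 s⁻¹; reverse steps 100× slower; the direct
  C₄ → I₄ edge is forbidden), simulated stochastically in 12.5 ms steps
  with exact-distribution multinomial count updates and checked against
  a matrix-exponential master-equation oracle.
- **Store.** Luminal Ca²⁺ follows
  dC_ER/dt = −(k_leak + k_rel·O₄)(C_ER − C) with optional SERCA refill
  (500 − C_ER)/τ_SERCA, an 80% releasable sub-pool, and antagonists
  modelled as k_rel = 0.
- **Inverse analysis.** From a fluorescence trace: fit the
  post-SERCA-inhibition leak, subtract it at matched content, integrate
  the evoked flux to rebuild C_ER(t), and divide by the luminal-cytosolic
  gradient to get open receptors in arbitrary units.
- **Synthetic data.** A generator composes all of the above into
  plate-reader-style traces (1.44 s sampling, load–inhibit–stimulate
  shape, additive noise) with full ground truth for recovery testing.

See `docs/methods.md` for assumptions, parameter provenance and
numerical choices.

## Worked example

Occupancy arithmetic from the command line — how many of a HEK-IP₃R1
cell's 49,146 receptors are tetra-liganded at 186 nM IP₃, and what
concentration would put 60 receptors in that state:

```sh
$ quantalca occupancy --kd 794 -n 49146 -L 186 --count 60
quantity,input,alpha,alpha4,tetra_count,concentration_nM
occupancy,186.0,0.18979591836734694,0.0012976198311095213,63.77282421970853,
inverse,60.0,,,,182.53884175201898
```

At 186 nM, each site is 19% occupied but only α⁴ ≈ 0.13% of receptors
carry four IP₃ — about 64 per cell; conversely 60 tetra-liganded
receptors correspond to ~183 nM.

Full round trip in Python — generate a noisy synthetic population
recording with three IP₃ additions spanning the EC₅₀, then recover the
leak rate and the open-receptor time course:

```python
import numpy as np
from quantalca.synthetic import paper_protocols, generate_trace, NoiseModel
from quantalca.analysis import analyze_trace

tpl = paper_protocols()["incremental"]
trace, truth = generate_trace(tpl, NoiseModel(additive_sd=0.01), seed=7)
res = analyze_trace(trace, offset=0.22, c_cyt=0.22)

mask = ~np.isnan(res.open_receptors_au)
o4 = np.interp(res.times, truth.times, truth.O4_per_cell)
r = np.corrcoef(res.open_receptors_au[mask], o4[mask])[0, 1]
print(f"recovered k_leak = {res.k_leak_estimate:.3e} /s (true 1.800e-04)")
print(f"open-receptor correlation with ground truth: r = {r:.3f}")
```

```
recovered k_leak = 1.754e-04 /s (true 1.800e-04)
open-receptor correlation with ground truth: r = 0.929
```

The leak rate constant is recovered within ~3% at 1% measurement noise,
and the reconstructed open-receptor trace (arbitrary units) tracks the
true per-cell open count through each addition's surge-and-inactivate
transient.

The same pipeline is available as shell subcommands: `quantalca generate`
(synthetic traces + ground truth), `quantalca simulate` (gating + store
trajectories), `quantalca analyze` (leak fit, flux, reconstruction), and
`quantalca occupancy`.

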