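# psfsim

A spatially explicit stochastic simulator of plant communities coupled to
dynamic soil microbial communities, for theoretical community ecologists
studying plant–soil feedback (PSF) and Janzen–Connell-style negative
density dependence.

Trees of `k` species occupy a one-dimensional circular lattice of `n`
cells. Each tree hosts one mutualist and one pathogen community (one
microbial taxon per guild per plant species). Each five-year time step:

1. a random 10% of adults die;
2. every adult casts seed and microbial propagules under truncated
   discrete power-law kernels, `w(d) ∝ (1 + d)^(-b)`;
3. each vacated cell recruits one seedling, drawn with probability

   `Π_j ∝ seeds_j · ζ_j · σ(g (h θ_m − θ_p))`

   where `θ_f = F_x · e_fj` is the local guild effect on a species-`j`
   seedling, `e_fij = 1` on the preferred host and `s_f` otherwise,
   `ζ_j` is plant fitness, and `σ` the logistic function;
4. the recruit's microbiome is seeded from the local community filtered
   by compatibility-scaled competitive ability (`e^c`);
5. every tree's microbial guilds advance one step of Lotka–Volterra
   competition,

   `dF_i/dt = r_f e_ij^{q_f} F_i (1 − (F_i + α_f Σ_{n≠i} e_nj^{c_f} F_n))`.

Feedback is measured with Bever's interaction coefficient
`I_s = S(a_A) + S(b_B) − S(a_B) − S(b_A)` (negative values = stabilizing
feedback), and runs are summarized by the abundance–feedback Spearman
correlation ρ, the feedback spread σ(I_s), the equilibrium metric `P_e`,
and the heterospecific-neighbour fraction. The package also ships the
surrounding experiment machinery: random parameter sweeps with
random-forest outcome classification (permutation importance and
per-sample feature contributions), component-removal ablations, and a
hierarchical particle-swarm search of trait space guided by a
random-forest surrogate.

## Worked example

Run the reference parameterization (the trait combination identified as
most likely to maintain five-species coexistence under negative feedback
while producing a positive abundance–feedback correlation) at reduced
scale:

```python
import numpy as np
from psfsim import reference_parameterization, Simulation
from psfsim.metrics import measure_end_psf

params = reference_parameterization(n=199, steps=1000, rng_seed=1)
sim = Simulation(params)
trajectory = sim.run()
abundance = trajectory.abundance[-1]
report = measure_end_psf(sim, abundance)
print("final abundance:", abundance)
print("focal I_s:", np.round(report.focal_Is, 3))
print("rho(abundance, I_s):", round(report.rho, 2))
```

prints

```
final abundance: [44 39 47 39 30]
focal I_s: [-0.332 -0.373 -0.361 -0.29  -0.417]
rho(abundance, I_s): 0.46
```

All five species coexist, every species' focal feedback is negative
(each recruits better away from conspecific adults — the stabilizing
rare-species advantage), and feedback is weaker for more abundant
species, here giving a moderately positive rank correlation in a single
reduced-scale replicate. At the full published scale (499 trees, 3000
steps) the correlation is consistently ≥ 0.9: pathogens of common
species persist on non-preferred hosts (slow decline at rate
`r_p s_p^{q_p}`), depressing common species' away-survival, while their
mutualists accumulate at home.

The same run from a shell:

```bash
psfsim run --preset reference --seed 1 --steps 1000 --out runs/demo
psfsim sweep --runs 64 --seed 7 --n 99 --steps 600 --out sweeps/demo
psfsim ablate --preset reference --mode remove_pathogens --trigger-step 800 --out runs/ablate
```

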