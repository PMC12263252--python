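# pteroevo

Body-size evolution of island flying foxes (*Pteropus* and related
frugivorous Pteropodinae), analysed with phylogenetic comparative methods.

Flying foxes that share an island tend to differ conspicuously in body
size. This package asks whether that pattern reflects selection — character
displacement toward distinct size optima among sympatric species — or
neutral divergence, using skull condylobasal length (CBL, mm) as the size
proxy on a dated molecular phylogeny. It provides:

* **Regime assignment** (`pteroevo.regimes`): every species is placed in a
  size category — small (S), medium (M), large (L), or isolated (I) — from
  its rank among the species it co-occurs with on each island,
  archipelago or continental area; widespread species take their modal
  category, and species with no sympatric relatives are either pooled into
  M or given their own I category.
* **Model fitting** (`pteroevo.models`): exact Gaussian likelihoods and ML
  fits for BM, BMS (per-regime Brownian rates), EB (early burst), OU1 and
  the multi-optimum Hansen models OUM / OUMV / OUMA / OUMVA, compared by
  AICc and Akaike weights, plus a random-regime null in which categories
  are reshuffled across the tips.
* **Phylogenetic signal** (`pteroevo.signal`): Pagel's λ and δ (profiled
  ML), Blomberg's K with a permutation test on independent contrasts.
* **Ancestral states** (`pteroevo.ancestral`): REML/GLS reconstruction
  under Brownian motion with 95% intervals, and per-category accounting of
  each species' percent size change relative to its reconstructed parent.
* **Disparity through time** (`pteroevo.disparity`): the DTT curve, a
  Brownian null envelope and the morphological disparity index (MDI), plus
  per-island coefficients of variation.
* **Synthetic data** (`pteroevo.synthdata`): Yule chronograms, traits
  evolved under BM/EB/OU with regime-dependent optima, and island
  communities with planted size displacement — so the whole chain is
  testable without any empirical download.

## The model

Under the Hansen (multi-optimum Ornstein–Uhlenbeck) model a trait X on a
branch painted with regime r evolves as

    dX = α (θ_r − X) dt + σ dW

with pull strength α (1/Myr), optima θ_r (mm), and stochastic intensity σ²
(mm²/Myr). Tip expectations are convex combinations of the root state and
the regime optima, weighted by exponentially discounted residence times;
tip covariances on an ultrametric tree with a single α are
σ²/(2α)·e^{−α d_ij}(1 − e^{−2α s_ij}) for shared time s and patristic
separation d. Model selection uses AICc = −2 logL + 2k + 2k(k+1)/(n−k−1).

## Worked example

```python
import numpy as np
from pteroevo import (RegimeScheme, SimulationConfig, compare, fit,
                      simulate_trait, simulate_yule)

tree = simulate_yule(56, crown_age=8.7, seed=1)           # dated chronogram
rng = np.random.default_rng(1)
cats = ["L", "M", "S", "I"]
scheme = RegimeScheme("four_cat",
                      dict(zip(tree.tip_labels,
                               (cats[i] for i in rng.integers(0, 4, 56)))),
                      internal_category="M")
cfg = SimulationConfig(seed=7)          # OU truth: alpha 0.60, sigma^2 52,
sim = simulate_trait(tree, cfg, scheme)  # optima 93.4/65.1/47.5/54.4 mm
fits = [fit("BM", tree, sim.traits),
        fit("OU1", tree, sim.traits),
        fit("OUM", tree, sim.traits, scheme)]
print(compare(fits).to_string(index=False))
```

prints (machine-dependent only in the last digits):

```
model     logLik  k       AICc      dAICc       weight
  OUM -165.70761  6 345.129515   0.000000 1.000000e+00
  OU1 -202.77542  3 412.012369  66.882854 2.996214e-15
   BM -210.92843  2 426.083284  80.953768 2.637015e-18
```

The four-optimum Hansen model carries essentially all Akaike weight — the
planted selective regimes are recovered from the tip data — and
`fit("OUM", ...)` reports the estimated optima (here θ̂_L ≈ 92.9 mm,
θ̂_M ≈ 66.2 mm, θ̂_S ≈ 49.0 mm, θ̂_I ≈ 53.5 mm) with standard errors.

A full configuration-driven run (regimes → signal → fits → null →
ancestral states → DTT → CV → island report) is available from the shell:

```bash
pteroevo simulate --seed 3 --n-tips 56 --out data/
pteroevo run --config analysis.yaml
```

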