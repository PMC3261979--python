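# mixkin — mixture toxicokinetics from first-principles enzyme kinetics

Predicting how co-exposure to several volatile chemicals changes their blood
kinetics usually requires empirical pairwise interaction constants — two per
pair, so the parameter demand grows quadratically with mixture size.
`mixkin` takes the mechanistic route instead: each chemical carries a small
mass-action reaction network for its hepatic oxidation, all networks are
composed with a generic physiologically based pharmacokinetic (PBPK)
transport template into one joint ODE system, and the enzyme pools
(CYP2E1 in the reference case) are shared. Competitive metabolic
interactions then *emerge* from depletion of the free-enzyme pool; no
interaction constants exist anywhere in the model. The package targets
toxicokinetic modelers working on occupational/environmental co-exposures
(the worked case is BTEX — benzene, toluene, ethylbenzene, *m*-xylene, in
the rat), and anyone who needs calibrated, uncertainty-quantified mixture
predictions from single-chemical data.

## Model

Per chemical, a four-compartment flow-limited rat PBPK template (liver,
fat, poorly and richly perfused tissues; inhalation only):

    dQ_i/dt = F_i (C_art − Q_i/(V_i P_i))
    C_ven   = Σ_i F_i Q_i/(V_i P_i) / Σ_i F_i
    C_art   = (F_card C_ven + F_alv C_inh) / (F_card + F_alv/P_art)
    C_exh   = C_art / P_art

Metabolism is *not* Michaelian. The hepatic oxidation is written in
elementary microconstants, e.g. for benzene B with enzyme E:

    B + E  →(k1)  BE      BE →(k2) B + E      BE →(k3) E + BO

with rates acting on liver amounts (nmol), so k1 is in min⁻¹·nmol⁻¹.  The
free-enzyme ODE is automatically the sum of binding/unbinding/catalysis
terms over *all* co-exposed chemicals — that single shared state is the
whole interaction mechanism. The quasi-steady reduction recovers the
familiar pair (diagnostic only):

    Vmax = k3 · E_total        Km = (k2 + k3) / k1

For an *n*-chemical mixture with one reaction each, the classical
formulation needs 2n + n(n−1) parameters (Vmax, Km, plus two interaction
constants per pair); the microconstant formulation needs 3n.

Three pathway variants are built in: **type I** (one enzyme), **type II**
(a second, lower-affinity cytochrome, k1′ = k1/10 by default), **type III**
(the primary metabolite competes with its parent for the enzyme and is
cleared first-order with constant kh).

Microconstants are not tabulated in the literature, so the package includes
Bayesian calibration: a log-normal observation model (per-point geometric
SD moment-matched from reported mean ± SD), component-wise adaptive
random-walk Metropolis over packaged priors, Gelman–Rubin convergence
diagnostics, and posterior predictive simulation with multiplicative
GSD-1.28 noise. A Monte Carlo sensitivity screen (±10% uniform sampling,
|r| > 0.3 flags) selects which physiological parameters join the fit, and a
synthetic-data generator reproduces the single-chemical calibration design
(4-hr exposures at 50/100/200 ppm, five post-exposure samples, five animals,
log-normal noise) for end-to-end recovery testing.

## Worked example

```python
import numpy as np
import mixkin as mk

model = mk.build_btex_model()          # type I, calibrated posterior modes
ppm = {"benzene": 100, "toluene": 50, "ethylbenzene": 50, "m_xylene": 50}
mixture = mk.ExposureScenario.constant(ppm)            # 4 h + 2 h washout
singles = {c: mk.ExposureScenario.constant({c: p}) for c, p in ppm.items()}

ratios = mk.mixture_interaction_ratio(model, mixture, singles, t_eval=240.0)
for chem, r in ratios.items():
    print(f"{chem:12s} mixture/single venous ratio at end of exposure: {r:.2f}")
print(f"mean fold-increase: {np.mean(list(ratios.values())):.2f}")
```

prints

```
benzene      mixture/single venous ratio at end of exposure: 1.39
toluene      mixture/single venous ratio at end of exposure: 2.54
ethylbenzene mixture/single venous ratio at end of exposure: 3.25
m_xylene     mixture/single venous ratio at end of exposure: 3.56
mean fold-increase: 2.68
```

i.e. sharing one CYP2E1 pool roughly doubles venous concentrations under
quaternary co-exposure relative to matched single exposures — the hallmark
competitive-interaction signature — with the smallest increase for benzene
(whose low Km already saturates the enzyme alone) and the largest for the
high-Km xylenes.

A command-line interface mirrors the library
(`mixkin counts|compose|simulate|sensitize|calibrate|predict|synth`); every
run writes a resolved `run_manifest.json` so outputs are reproducible
bit-for-bit from the recorded seed.

```bash
$ mixkin counts --n 50
classical 2550
microconstant 150
```

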