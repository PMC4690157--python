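# sulfrac

Closed-system, branched-product **sul**fur isotope **frac**tionation
analysis for in vitro sulfite reduction by dissimilatory sulfite reductase
(DsrAB), the central redox enzyme of microbial sulfate reduction (MSR).

When purified DsrAB reduces sulfite in a closed vessel it produces no
sulfide; the sulfur ends up in thiosulfate and trithionate, each carrying
both oxidized (sulfonate) and reduced S moieties. Extracting the enzyme's
intrinsic isotope effect from such an experiment therefore needs more than
a textbook Rayleigh fit: the distillation model must track two cumulative
product pools with distinct branch fractionations and a constant molecular
split. `sulfrac` implements that model in both directions, with full
triple-isotope (³³S/³⁴S/³⁶S) support, analytic and Monte-Carlo error
propagation, small-sample IRMS scale correction, and the meta-analysis
statistics used to put enzyme-level fractionations in context with
whole-cell literature data. It is aimed at stable-isotope
biogeochemists working with multi-isotope distillation experiments.

## Model

With `f` the fraction of sulfite remaining and `j` the fraction of product
S in thiosulfate, the product pools carry atom weights
`w_red = j/2 + (1-j)/3` and `w_ox = 1 - w_red`. Per isotope (x = 33, 34, 36):

```
R_a(f) = R_a0 · f^(α_total - 1)                        residual sulfite
R_z(f) = (α_z/α_total) · R_a0 · (1 - f^α_total)/(1-f)  cumulative pool z ∈ {red, ox}
α_total = w_red·α_red + w_ox·α_ox
```

The inversion applies the exact algebra in reverse at every measured time
point:

```
R_p     = w_red·R_red + w_ox·R_ox
α_total = ln(R_p/R_a0 · (f-1) + 1) / ln f
α_z     = (R_z/R_a0) · α_total · (f-1)/(f^α_total - 1)
³ˣλ_z   = ln(³ˣα_z) / ln(³⁴α_z)
```

Headline values are reported as reactant−product epsilons,
`ε_r−p = 10³(1/α − 1)`, and summarised on the early-reaction window
(f ≥ 0.85) where secondary back-reactions are negligible. Uncertainties
combine power-law propagation of concentration and ratio errors with the
analytic λ-error formula in (δ³⁴S, Δ³³S) space, cross-checked by Monte
Carlo.

## Worked example

```python
import numpy as np
from sulfrac import (BranchFractionation, ReactionScheme, DeltaTriple,
                     epsilon_to_alpha, simulate, invert_series)

branch = BranchFractionation(
    a34_red=epsilon_to_alpha(15.3, "reactant-product"),   # depleting branch
    a34_ox=epsilon_to_alpha(-3.2, "reactant-product"),    # enriching branch
    lam33_red=0.5150, lam33_ox=0.495)
traj = simulate(branch, ReactionScheme(j=0.19), 15.0,
                DeltaTriple(0.0, 0.0, 0.0), np.linspace(0.99, 0.85, 8))
window = invert_series(traj.to_frame(), f_threshold=0.85).window
print({k: round(v, 4) if v else v for k, v in window.report().items()})
```

prints

```
{'f_threshold': 0.85, 'n_points': 8,
 'eps34_red': 15.3,   'eps34_red_2sigma': 1.0487,
 'eps34_ox': -3.2,    'eps34_ox_2sigma': 0.4709,
 'lam33_red': 0.515,  'lam33_red_2sigma': 0.0011,
 'lam33_ox': 0.495,   'lam33_ox_2sigma': 0.0054,
 'lam36_red': 1.9,    'lam36_red_2sigma': 0.0216,
 'lam36_ox': 1.9,     'lam36_ox_2sigma': 0.0987}
```

i.e. the windowed inversion returns the generating branch parameters
exactly (the forward model and the inversion are exact algebraic
inverses), and the analytic error propagation puts a 2σ of ~0.001 on the
reduced-branch ³³λ and ~1‰ on its ³⁴ε under the default measurement-error
model — the precision scale at which such experiments resolve
mass-dependent fractionation laws.

The same pipeline runs from a shell: `sulfrac simulate`, `sulfrac invert`,
`sulfrac uncertainty`, `sulfrac fit-rate-curve`, `sulfrac
summarize-compilation`, `sulfrac correct-scale`.

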