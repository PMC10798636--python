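# nutriq

Bacterial growth laws with **plastic nutrient quality**: a modelling and
analysis toolkit for the question of why *E. coli* grows at very different
rates on different carbon sources — and whether those rates reflect hard
biochemical limits or regulated resource-allocation decisions.

It is written for quantitative microbial physiologists: it implements the
steady-state proteome-allocation model, the cAMP/C-sector titration
picture, the integration of proteomics tables into a protein-cost versus
growth-rate analysis, the standard phenotype quantifications (semi-log
growth-rate fits, diauxic lag times, CFU starvation survival, soft-agar
motility metrics), and seeded synthetic-data generators so every estimator
can be validated against known ground truth.

## The model

Steady-state growth balances two proteome-limited fluxes. Translation
produces protein at rate κt(φR − φ0), where φR is the ribosomal proteome
fraction, φ0 an offset and κt the translational capacity; catabolism
supplies precursors at rate κn·φP, where φP is the catabolic P-sector and
κn the *nutrient quality*. With the sector constraint φR + φP = φR^max,
the growth rate follows

    λ = λmax · κn / (κn + κt),       λmax = κt (φR^max − φ0).

The plasticity extension decomposes the P-sector: only a fraction *f* of
it is the core machinery (C\*-sector) specific to the substrate actually
consumed; the rest is an adaptability reserve φAD = φP(1 − f) of
preparatory proteins (alternative uptake systems, stress response,
motility). The effective nutrient quality is then a *regulated* quantity,

    κn = f · κn*,

with κn\* set by enzyme kinetics alone. Raising *f* (a promoter swap on
the substrate's transporter/enzyme operon) raises λ up to the rate of a
"good" substrate — at the cost of the adaptability reserve, which is what
the diauxic-lag, starvation-survival and motility metrics quantify.

When the C-sector is titrated externally (e.g. via cAMP), growth is
bottlenecked by the smaller of uptake flux κn·x and translation flux
κt(φR^max − x − φ0); the titration curve is unimodal and its peak
reproduces the growth law exactly. Poor substrates peak at higher
induction x\* but lower λ\* — a strict inverse relation.

## Worked example

```python
import math
import numpy as np
from nutriq import (GrowthContext, SubstrateParams, steady_state_allocation,
                    predict_promoter_swap, optimal_induction,
                    gen_diauxic_series, analyze_diauxie)

ctx = GrowthContext(kappa_t=4.0, phi_0=0.1, phi_R_max=0.6)   # illustrative
mannose = SubstrateParams("mannose", kappa_n_star=10.0, f=0.1)

alloc = steady_state_allocation(ctx, mannose)
print(f"wild type on mannose:  lambda = {alloc.growth_rate:.3f}/h, "
      f"phi_P = {alloc.phi_P:.3f}, phi_AD = {alloc.phi_AD:.3f}")
swapped = predict_promoter_swap(ctx, mannose, f_new=1.0)
print(f"promoter swap (f=1.0): lambda = {swapped:.3f}/h")
x_star, lam_star = optimal_induction(ctx, mannose.kappa_n)
print(f"titration optimum:     x* = {x_star:.3f}, lambda* = {lam_star:.3f}/h")

t1 = 4.6
series = gen_diauxic_series(0.7, 0.5, 2.0, 0.3, np.arange(0, 14.05, 0.05),
                            noise_cv=0.02, seed=7,
                            od0=0.5 / math.exp(0.7 * t1))
result = analyze_diauxie(series, smooth_points=9)
print(f"diauxic shift:         t_shift = {result.t_shift:.2f} h, "
      f"lag = {result.lag:.2f} h (true 2.00 h)")
```

Output:

```
wild type on mannose:  lambda = 0.400/h, phi_P = 0.400, phi_AD = 0.360
promoter swap (f=1.0): lambda = 1.429/h
titration optimum:     x* = 0.400, lambda* = 0.400/h
diauxic shift:         t_shift = 4.60 h, lag = 1.99 h (true 2.00 h)
```

Reading: on a poor substrate (effective κn = 0.1·10 = 1), the cell runs a
large P-sector (0.40), most of it adaptability reserve (0.36), and grows
at 0.40/h; fully inducing the substrate-specific machinery (f → 1) nearly
quadruples the predicted rate to 1.429/h. The titration optimum at the
same κn reproduces the 0.40/h growth law exactly. The diauxic pipeline
recovers a built-in 2 h lag from a noisy simulated OD curve to 0.01 h.

The same functionality is available from the shell:

```bash
nutriq recipe --mass 4 --fw 174.26 --volume 1        # 22.9542 mM (1-decimal: 23.0 mM)
nutriq simulate diauxic --lag 2 --noise-cv 0.02 --seed 7 --out-dir sim/
nutriq lag sim/od_series.tsv --smooth 9
nutriq cost --abundance a.tsv --foldchange fc.tsv --substrates s.tsv --stats-out stats.tsv
```

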