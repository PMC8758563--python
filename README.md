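# healthprod

Three-stage spatial analysis of provincial **health production efficiency**
with environmental pollution treated as an undesirable output, built for
health economists and regional scientists working with yearbook-style
province × year panels (the packaged reference case is 31 Chinese
provincial units, 2009–2019).

The pipeline answers three questions in sequence:

1. **How efficiently does each province turn health inputs into health
   outcomes?** — a non-oriented *super-efficiency epsilon-based measure*
   (EBM) DEA model with undesirable outputs scores each province-year
   against a yearly frontier.
2. **Do efficient provinces cluster in space?** — global and local Moran's
   *I* and the Getis–Ord Gi\* statistic describe the spatial pattern of the
   scores.
3. **What drives the pattern, and does it spill over?** — a
   diagnostic-driven spatial panel regression (HT unit-root screen, LM
   tests, Hausman, LR/Wald) selects among OLS/SLM/SEM/SDM; the spatial
   Durbin model's direct and indirect (spillover) effects are decomposed.

## The models

**Stage 1 — EBM DEA.** For evaluated unit *k* with inputs *x*, desirable
outputs *y* and undesirable outputs *u*, the score is

```
γ* = min  [ θ − ε⁻ Σᵢ wᵢ⁻ sᵢ⁻ / x_ik ]
          ──────────────────────────────────────────────
          [ φ + ε⁺ ( Σᵣ wᵣ⁺ sᵣ⁺ / y_rk + Σ_p w_p^u s_p^u / u_pk ) ]

s.t.  Σ_{j≠k} λⱼ x_ij + sᵢ⁻ = θ x_ik
      Σ_{j≠k} λⱼ y_rj − sᵣ⁺ = φ y_rk
      Σ_{j≠k} λⱼ u_pj + s_p^u = φ u_pk ,   λ, s ≥ 0
```

ε ∈ [0, 1] weights the non-radial slack part: ε = 0 recovers the radial
model, θ = ε = 1 the slacks-based measure (both equivalences are tested
against independent solvers). The *j ≠ k* constraint is the
super-efficiency device: efficient units may score above 1 and remain
ranked. The fractional program is linearised exactly (Charnes–Cooper) and
solved with HiGHS. ε and the weights default to a diversity/affinity
analysis of the data and can be overridden.

**Stage 2 — spatial autocorrelation.** Moran's
*I = n Σᵢⱼ W_ij (γᵢ−γ̄)(γⱼ−γ̄) / (Σᵢⱼ W_ij · Σᵢ (γᵢ−γ̄)²)* with
permutation and analytic inference, HH/LH/LL/HL quadrant labels, and the
self-inclusive share statistic Gi\* = Σⱼ W_ij γⱼ / Σⱼ γⱼ. The packaged
weight matrix is queen contiguity over the 31 units plus the
Hainan–Guangdong sea link, row-standardised.

**Stage 3 — spatial panel econometrics.** Maximum-likelihood SLM
(*y = ρWy + Xβ + ε*), SEM (*y = Xβ + u, u = λWu + ε*) and SDM
(*y = ρWy + Xβ + WXθ + ε*) with time/individual/two-way fixed effects
(within transformation, eigenvalue-exact log-determinant, Lee–Yu
degrees-of-freedom correction). Effects of covariate *k* are decomposed
through the spatial multiplier *S_k = (I − ρW)⁻¹(Iβ_k + Wθ_k)*: direct =
mean diagonal, indirect (spillover) = mean off-diagonal row sum.

## Worked example

Score aggregation and spatial pattern of the packaged published grid:

```python
from healthprod import (fixture_table3, assign_regions, aggregate_regional,
                        grade_efficiency, china_contiguity, moran_inference)

table = fixture_table3()                     # 31 units x 2009..2019
scheme = assign_regions(table.unit_ids)      # Eastern/Middle/Western/Northeastern
means = aggregate_regional(table, scheme, "mean")
print(means[[2009, 2019]].round(3))
#                2009   2019
# Eastern       0.817  0.882
# Middle        0.852  0.862
# Northeastern  0.864  0.805
# Western       0.862  0.830

grade_efficiency(table.scores.loc["HaiNan", 2019])    # ('high', 6)
grade_efficiency(table.scores.loc["ShanDong", 2019])  # ('low', 3)

W = china_contiguity()
r = moran_inference(table.values_for(2019), W, n_perm=999, seed=1)
print(f"I={r.I:.3f}  E[I]={r.expected:.3f}  z={r.z:.2f}  p={r.p:.3f}")
# I=0.186  E[I]=-0.033  z=1.86  p=0.055
```

The regional means read off the efficiency story directly: the Eastern
mean rises from ≈0.82 to ≈0.88 over the decade while the Northeastern
mean falls from ≈0.86 to ≈0.81; Hainan stays in the high band (score > 1)
and Shandong in the low band (≤ 0.8). In 2019 Moran's *I* of 0.186 against
an expectation of −0.033 indicates positive spatial clustering of
efficiency under the packaged contiguity matrix.

The same analysis runs from the command line:

```bash
healthprod esda --efficiency fixture --out report --seed 1
healthprod simulate --out sim_report --seed 1      # synthetic end-to-end run
healthprod run --config pipeline.yaml              # full three-stage run
```

Every run writes tidy CSV tables (scores + grades + regional means, Moran
per year, local clusters, diagnostics, SDM coefficients, effect
decomposition) and a `manifest.json` recording the seeds, the weight
matrix choice and the ε values used.

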