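# cbbkin — ensemble kinetic analysis of the Calvin–Benson–Bassham cycle

`cbbkin` is a Python package for probabilistic kinetic analysis of the
Calvin–Benson–Bassham (CBB) cycle embedded in the central carbon metabolism
of the cyanobacterium *Synechocystis* sp. PCC 6803.  It is aimed at
systems-biology and metabolic-engineering researchers who want to ask, for
a CO2-fixing network whose enzyme parameters are largely unknown: *which
metabolic states are dynamically stable, and which reactions control the
flux?*

Instead of fitting one parameter set, the package samples millions of
candidate states and parameterizations and analyzes the ensemble:

1. **Feasible metabolomes.**  Metabolite concentration sets are drawn
   log-uniformly within physiological ranges and kept only when every
   reaction is thermodynamically downhill in its flux direction
   (ΔG = ΔG°′ + RT ln Q < 0), the total concentration stays below 100 mM,
   cofactor ratios (ATP/ADP, NADPH/NADP, NADH/NAD) are growth-compatible,
   and the phosphate pool is a 1.1–5× multiple of free phosphate.
2. **Kinetic parameterization.**  Around each feasible metabolome (fMCS),
   every binding and regulation constant is drawn log-uniformly from
   0.01×–100× the concentration of its metabolite (1–99 % enzyme
   saturation).  Rates follow reversible Michaelis–Menten-like laws

       v = Vmax · (A/K_A) · (1 − Q/K_eq) / (1 + A/K_A + B/K_B)

   (convenience-kinetics generalization for multi-substrate reactions,
   competitive inhibitors in the denominator, allosteric modifiers as
   prefactors), and Vmax is calibrated as `Vmax = v0 / f` so each set
   reproduces the steady-state input flux v0 exactly.
3. **Stability.**  Each parameterized steady state is classified by the
   eigenvalues of the reduced Jacobian `J' = S′ · ∂v/∂X · L`, where
   `S = L·S′` factors out conserved moieties (ATP+ADP, NADPH+NADP); all
   eigenvalues with negative real part ⇔ locally stable.
4. **Metabolic control analysis.**  For every stable set the scaled control
   coefficients are computed by linear analysis,

       C_X = −D_X0⁻¹ · L · J′⁻¹ · S′ · D_v0
       C_J = I + D_v0⁻¹ · ∂v/∂X · D_X0 · C_X

   and verified against the summation theorems (ΣC_X = 0, ΣC_J = 1).
5. **Ensemble statistics.**  Per-fMCS stable fractions, concentration
   densities of the most- vs least-stable deciles, saturation–stability
   splits, median/MAD flux control coefficient (FCC) matrices, and
   hierarchical clustering of control patterns (asinh transform → PCA →
   correlation-distance clustering with bootstrap support).

The shipped model (`src/cbbkin/data/cbb_synechocystis.model`) has
29 reactions, 36 metabolites and 149 kinetic parameters: the 13 CBB
catalytic steps, lower glycolysis to acetyl-CoA, the phosphoketolase
bypass, lumped photosystem reactions for ATP/NADPH supply, a phosphate
pool, and six biomass sinks, with enzyme promiscuity (FBPase/SBPase,
ald/fba, tkt1/tkt2, xfpk1/xfpk2) encoded as shared binding constants and
cross-competitive inhibition.  All external inputs are synthesized by the
package itself: the steady-state flux vector comes from a linear program on
the model's own stoichiometry, and concentration ranges ship with the model
file.  See `docs/methods.md` for the model assumptions and defaults.

## Worked example

Run the reduced-scale analysis (100 metabolomes × 200 parameter sets,
about one minute on one CPU):

```bash
cbbkin run-all --out run --seed 1 --target-fmcs 100 --sets 200
```

which prints

```
100 fMCSs; median stable 69.8% (range 55.5-86.0%)
```

i.e. for the median feasible metabolome, 69.8 % of the 200 random
parameterizations yield a locally stable steady state — the CBB network is
intrinsically stable over most of its thermodynamically allowed state
space.  The run directory now contains, among others:

- `fmcs.tsv` — the feasible metabolomes (mM) with their phosphate-pool size;
- `stability_summary.tsv` — per-fMCS stable/marginal counts and fractions;
- `fcc_median.tsv` / `fcc_mad.tsv` — 29×29 median and MAD flux-control
  matrices (targets × effectors).  In this run the strongest positive
  effector over the 13 CBB-cycle reactions is the ATP supply
  (median FCC ≈ 0.34), followed by phosphate supply and phosphoglycerate
  kinase; the phosphoketolase bypass (xfpk1/xfpk2/pta) controls essentially
  nothing but itself (|median FCC| < 0.002) — flux control is distributed,
  with no single "bottleneck" enzyme;
- `clusters_effector.nwk` / `clusters_target.nwk` — newick dendrograms of
  reactions clustered by how they exert / experience control, with
  bootstrap support in `cluster_support_*.tsv`;
- `decile_densities.tsv` — per-metabolite log10-concentration densities for
  the most- and least-stable deciles of metabolomes.

Every stage is checkpointed: deleting a downstream file and rerunning the
same command reproduces it byte-identically, and the same seed always
yields the same ensemble.  The equivalent library entry point is
`cbbkin.run_pipeline(RunConfig(...))`; the individual stages are available
as CLI subcommands (`make-fixtures`, `sample-states`, `sample-params`,
`stability`, `mca`, `postprocess`).

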