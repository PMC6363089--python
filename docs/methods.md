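# Methods

This note documents the model, the sampling procedures, the numerical
choices and the limitations of `cbbkin`.  Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Network model

The shipped model describes the Calvin–Benson–Bassham (CBB) cycle of
*Synechocystis* sp. PCC 6803 embedded in central carbon metabolism:
29 reactions over 36 metabolites.

- **CBB catalytic steps (13):** Rubisco, pgk, gapd, tpi, ald, FBPase,
  tkt1, tkt2, fba, SBPase, rpe, rpi, prk.  Reaction directions are the
  input-flux (carbon-fixing) directions.
- **Lower glycolysis (4):** pgm (3PG↔2PG mutase), eno, pyk, pdh, ending in
  acetyl-CoA.
- **Phosphoketolase bypass (3):** xfpk1 (F6P), xfpk2 (Xu5P), pta.
- **Cofactor supply (3):** ATPSyn and NADPase, lumped light-driven
  photosystem reactions regenerating ATP and NADPH with effective negative
  ΔG°′ (−30 kJ/mol each); Supply_Pi, a symmetric mass-action exchange
  `v = k (PPool − Pi)` between free phosphate and an abstract phosphate
  pool whose size is sampled as a 1.1–5× multiple of Pi.
- **Biomass sinks (6):** irreversible Michaelis–Menten drains on 3PG, GAP,
  F6P, R5P, PEP and PYR into unbalanced sink pools, so no thermodynamic
  data are needed for biomass products.

22 metabolites are dynamic state variables.  CO2, O2, CoA and H2O are
clamped at fixed concentrations (water at unit activity, excluded from all
rate laws and reaction quotients).  NAD, NADH and acetyl-CoA are *sampled*
per metabolome — their concentrations enter the pdh/pta rate laws and the
NADH/NAD ratio constraint — but are clamped in the dynamics, because their
turnover (respiratory electron transport, downstream acetyl-CoA
consumption) lies outside the network boundary; treating them as balanced
would make a positive steady-state flux impossible.  The conservation
analysis (exact rational row reduction, so the factorization `S = L·S′` is
deterministic and reproducible to machine precision) finds exactly two
conserved moieties, ATP+ADP and NADPH+NADP.

### Rate laws

All reactions except the bisphosphatases, the sinks and the phosphate
supply follow reversible Michaelis–Menten-like kinetics.  For substrates
`S_i` (stoichiometric multiplicity `n_i`) and products `P_j` (`m_j`):

    v = Vmax · R · T · (1 − Q/K_eq) / D
    T = Π_i (S_i/K_{S_i})^{n_i}
    D = Π_i Σ_{k=0..n_i} (S_i/K_{S_i})^k + Π_j Σ_{k=0..m_j} (P_j/K_{P_j})^k
        − 1 + Σ_c I_c/K_{I_c}
    R = Π_act a/(K_a + a) · Π_inh K_i/(K_i + i)

For a 1:1 conversion this is exactly
`v = Vmax (A/K_A)(1 − B/(A·K_eq)) / (1 + A/K_A + B/K_B)`.  The reaction
quotient `Q` uses molar concentrations, matching the 1 M reference state of
the equilibrium constants (`K_eq = exp(−ΔG°′/RT)`, R = 8.314 J mol⁻¹ K⁻¹,
T = 298.15 K), so `v = 0` exactly at equilibrium and
`sign(v) = sign(1 − Q/K_eq)` everywhere.  FBPase, SBPase and the sinks are
irreversible (no product pool, no thermodynamic factor); allosteric
modifiers use first-order (Hill 1) hyperbolic prefactors.

### Promiscuity

Promiscuous enzyme pairs (FBPase/SBPase, ald/fba, tkt1/tkt2, xfpk1/xfpk2)
couple their reactions two ways: metabolites of one reaction that carry a
binding constant there and do not participate in the partner act as
competitive inhibitors of the partner *referencing the same constant* (the
SBP binding constant of SBPase is the SBP inhibition constant in the
FBPase law), and `shared:` regulator entries (e.g. the ATP inhibition of
both phosphoketolase reactions) are drawn once.  Products of the
irreversible bisphosphatase laws carry no binding constant, so their cross
inhibition is instead encoded explicitly as product inhibition (F6P on
FBPase, S7P on SBPase) with own constants.

### Regulator table

The exact regulator set of the organism is not fully established; the
shipped table is a literature-motivated default encoding the qualitative
regulatory structure reported for cyanobacterial central metabolism:
photorespiration abstracted as O2 competitive inhibition of CO2 binding at
Rubisco; redox activation of carboxylation (NADPH) and phosphate
signalling (Pi) on Rubisco and the bisphosphatases; Pi competitive
inhibition of the phosphoglycerate branch (pgk, pgm, eno, tpi, prk, pyk);
adenylate inhibition (ATP/ADP) of prk, pyk, pdh, pta and the
phosphoketolases; PEP inhibition of tpi, prk and the phosphoketolases; FBP
activation of pyruvate kinase; NADPH/NADH inhibition of pdh and gapd.
Users can replace the table in the model file; promiscuity-shared
constants are counted once, so the shipped model has exactly 100 sampled
constants, plus 29 Vmax/rate constants and 20 equilibrium constants
(149 kinetic parameters in total).  Equilibrium constants are fixed by
thermodynamics, never sampled.

### Thermodynamic defaults

Standard transformed Gibbs energies (298.15 K, pH ≈ 7.5) ship with the
model file and are literature-bracketing defaults, overridable per
reaction.  They control which metabolome candidates survive the
feasibility filter; the strongly uphill steps (pgk at +18.5 kJ/mol, the
aldol condensations in the synthesis direction) dominate the rejection
statistics and force high 3PG, high ATP/ADP and low BPG — the same
qualitative constraint structure that the feasibility analysis is meant to
capture.

## Metabolome sampling

Candidates are drawn log10-uniformly and independently per metabolite
within the shipped ranges (spanning roughly two orders of magnitude each,
bracketing reported cyanobacterial metabolomics values), then filtered by
the four constraints (ΔG < 0 per checked reaction; Σ balanced
concentrations ≤ 100 mM; ATP/ADP and NADPH/NADP in [1, 10], NADH/NAD in
[0.1, 1]; phosphate-pool multiple in [1.1, 5]).  Sink reactions and the
phosphate supply carry no ΔG°′ and are exempt from the filter.  Rejection
sampling is vectorized over fixed-size blocks of 65 536 rounds; each block
derives a counter-based stream from `(seed, stage, block index)`, so the
result is bit-identical regardless of chunking.  With the shipped
defaults the acceptance rate is ≈ 5×10⁻⁵ (recomputed by
`scripts/acceptance.py` as the implied yield per 5×10⁷ rounds).

## Parameter sampling and calibration

Every binding/regulation constant is drawn log-uniformly from 0.01×–100×
the concentration of its metabolite in the current metabolome, which maps
exactly to 1–99 % enzyme saturation at the reference state.  1000 sets per
metabolome is the full-scale default (`sets_per_fmcs`); the reduced scale
used by the tests and the acceptance script is 300 metabolomes × 200 sets,
chosen so the decile analyses retain a few tens of metabolomes per decile
while the whole analysis runs in minutes on one CPU.  Vmax (or the
mass-action `k`) is calibrated per reaction as `Vmax = v0/f`; feasibility
guarantees `f > 0`, and after calibration the network is at steady state to
machine precision (`‖S·v(X⁰)‖∞ < 1e−9·‖v⁰‖∞` is asserted).

## Stability classification

Elasticities `∂v/∂X` are evaluated analytically from the rate-law
structure (closed-form log-derivatives of every factor; a central
finite-difference oracle at relative step 1e−6 is kept as a test).  The
reduced Jacobian `J′ = S′·∂v/∂X·L` removes exactly the conserved-moiety
zero modes; this is asserted against the full Jacobian spectrum.  A set is
stable iff the largest eigenvalue real part is below `−ε` with
`ε = 1e−9·(1 + spectral radius of J′)`; eigenvalues within ε of zero are
conservatively counted unstable and tallied as "marginal".

An independent ODE oracle validates the classification: the state is
perturbed by 1e−4 (relative) along the leading Jacobian eigenmode plus a
10 % random component, projected to preserve the conserved moieties, and
`dX/dt = S·v(X)` is integrated (LSODA, rtol 1e−8, atol 1e−10, analytic
Jacobian, geometric checkpoints up to a horizon of 1500 time units).  The
probe direction matters: an isotropic random perturbation leaves slowly
growing modes hidden under the fast-decaying ones.  The displacement is
tracked in both the relative and the absolute norm — a growing mode living
on a large metabolite pool is invisible in the relative norm early on, and
vice versa — and a verdict is issued only when the worse of the two
metrics supports it.  Verdicts are conservative: "returns" after the
displacement shrinks 100-fold at two successive checkpoints (or decays
monotonically through the horizon), "diverges" on 10-fold growth or net
growth past the initial displacement following a decay, otherwise
inconclusive (excluded from agreement statistics).  Near-marginal sets
(|Re λ| ≲ 1/horizon) are the inconclusive ones by construction.

## Control analysis

Scaled concentration and flux control coefficients come from the linear
solve at the steady state (see README for the matrix expressions); the
summation theorems are asserted for every computed set at 1e−6, and the
connectivity theorem is spot-checked on toy chains.  Sets whose reduced
Jacobian has condition number above 1e12 are dropped from control analysis
and tallied (none occur in typical runs).  The finite-difference oracle
scales one reaction's Vmax by (1±δ), δ = 1e−3, re-equilibrates the full
nonlinear system (stiff relaxation plus root polish in reduced
coordinates) and measures Δln v_j/Δln Vmax centrally; it agrees with the
linear analysis within 1 % on well-conditioned sets.

## Ensemble statistics

Metabolomes are ranked by their fraction of stable parameter sets with
deterministic tie-breaking by index, so deciles are permutation-invariant.
Densities are Gaussian kernel estimates (Silverman bandwidth) in log10
space.  FCC aggregation uses element-wise median and median absolute
deviation over all stable sets.  Control-pattern clustering rounds
|FCC| < 1e−6 to exact zero, applies asinh, arranges one row per reaction
(columns: one entry per parameter set × partner reaction), subsamples a
tenth of the columns, standardizes, rotates the 29 reaction observations
onto their principal components, and clusters the PC scores with
correlation distance and average linkage.  Cluster support is an ordinary
bootstrap proportion over the score dimensions (resampled columns,
recomputed dendrogram, fraction of replicates containing each original
cluster); multiscale-bootstrap approximately-unbiased p-values are
deliberately out of scope.  All PCA components with finite scores are
retained.

## Synthetic inputs: what they emulate and what they do not

The package generates every external input itself:

- **Steady-state flux vector.**  A linear program on the 29-reaction
  stoichiometry (maximize weighted sink flux subject to `S·v = 0` and
  `0.01 ≤ v ≤ 10`) replaces a genome-scale flux balance computation.  All
  downstream mathematics depends only on `S·v⁰ = 0` and the directions,
  not the absolute flux scale, so the ensemble statistics are comparable;
  a measured flux table (TSV: reaction, v0) can be supplied instead and is
  validated against the same invariants.  Flux units are therefore
  arbitrary; the pipeline is unit-agnostic.
- **Concentration ranges.**  The shipped per-metabolite ranges bracket
  reported cyanobacterial measurements but are not a measured dataset; a
  Table-of-ranges TSV can override them.
- **Thermodynamic constants.**  Defaults as above; the acceptance-rate and
  stable-fraction statistics depend on them quantitatively.

Consequently, passing tests demonstrate the correctness and reproducibility
of the machinery and the robustness of the qualitative ensemble statements
(intrinsic stability, distributed control, inert bypass), not agreement
with any particular measured metabolome or fluxome of the organism.

## Known limitations

- The stable-fraction distribution at reduced scale (hundreds of
  metabolomes, 200 sets each) has the right median but narrower extremes
  than a full-scale run (thousands of metabolomes, 1000 sets each) can
  reach; binomial noise alone is ±3 % per metabolome at 200 sets.
- The RuBP–instability association reported experimentally and in prior
  modeling is *not* reproduced by this ensemble (the decile contrast is
  computed by `scripts/acceptance.py`; its sign is unstable across seeds).
  A plausible reason: because every K is sampled around the local
  metabolite concentration, saturation distributions are independent of
  absolute concentrations, removing the most direct route from a high RuBP
  pool to a qualitatively different Jacobian.  Mechanisms that would
  restore the association (e.g. RuBP inhibition of uncarbamylated Rubisco)
  are documented candidates but are not in the default regulator table.
  Several other metabolite–stability associations (low S7P/F6P with
  stability; low PEP/SBP/Pi with instability) do emerge with the expected
  signs.
- No isoenzymes, no compartmentalization, no thioredoxin/CP12 protein-level
  regulation, no bifurcation or global stability analysis, no response
  coefficients to external effectors.
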