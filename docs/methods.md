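# Methods

## Scope and model

`mccflux` implements the quantitative layer of a chain-elongation
bioreactor study with in-line membrane extraction: COD-basis bookkeeping,
period-level production/yield/specificity balances, the pertraction
mass-transfer correlation with cross-study flux prediction, and
OTU-abundance-vs-productivity correlation. It deliberately contains no
microbial kinetics (no Monod terms, no thermodynamic feasibility): the
synthetic generator and the accounting both treat production as an
exogenous, piecewise-constant rate per operating period, which is how
period-averaged reactor performance is reported in practice.

## COD bookkeeping

All concentrations and rates are expressed in oxygen equivalents. The ThOD
identity `32·(n_C + n_H/4 − n_O/2)` g O₂/mol is evaluated in exact rational
arithmetic so the registry constants (96, 64, 112, 160, 208, 256, 304,
352 g COD/mol for ethanol and the C2–C8 carboxylates) are bit-stable. The
dissociated carboxylate and the free acid share one COD factor (H⁺ carries
no oxygen demand); molar masses are stored for the free acids.

Acid speciation uses the Henderson–Hasselbalch form
`f_undiss = 1/(1 + 10^(pH − pKa))`. pKa defaults (acetic 4.76, propionic
4.87, n-butyric 4.82, n-valeric 4.84, n-caproic 4.88, n-heptanoic 4.89,
n-caprylic 4.89) are literature values at 25 °C with no temperature or
ionic-strength correction; they are configurable through the registry CSV.
At the default reactor pH 5.2 roughly one third of C6/C8 is undissociated
and hence extractable.

## Period mass balances

- **Extraction rate** M (g COD/d): unweighted OLS slope of the cumulative
  amount of a carboxylate in the alkaline extraction solution against time,
  with the slope standard error and a 95 % CI from the t distribution with
  n−2 df. The trap series is consumed as cumulative amounts (g COD); when
  only (concentration, solution volume) pairs are recorded the caller
  multiplies them first. A negative fitted slope is physically impossible
  for an accumulating trap and is returned flagged, never clamped, to keep
  instrument drift diagnosable.
- **Washout rate**: period-mean broth concentration × effluent flow. The
  averaging window is [t_start, t_end] inclusive of boundary samples;
  transition-day exclusion is available but off by default.
- **Production = extraction + washout**, per species, exactly by
  construction. Productivity divides by the per-period working volume
  (carried in `periods.csv`, not a constant, because the effective volume
  differed between phases); flux divides by the forward-contactor membrane
  area (default 1.4 m²); yield is lumped-MCC productivity over OLR;
  specificity is each product's share of total product COD; "MCC" means
  C6 + C8 on a COD basis unless C7 is explicitly requested.
- Reported tables round rates and ratios to 1 decimal and percentages to
  integers; `performance.csv` keeps full precision.

## Pertraction mass transfer

u = Q_recycle/A_cross (defaults A_cross = 1.56 × 10⁻³ m²,
A_transfer = 1.4 m²). k = M/(A_transfer·ΔC) is stored in mm/d against u in
m/d — the unit identity L·m⁻²·d⁻¹ ≡ mm/d makes the extraction-rate equation
numerically consistent with no conversion factor, and a dedicated test
checks this against an independent dimensional chain. ΔC is the exact
broth-minus-trap difference of undissociated MCCA concentrations by
default; the broth-only approximation (valid because the pH-9 trap holds a
negligible undissociated concentration) is selectable and is what the
recovery pipeline uses. The k–u fit is unweighted OLS with intercept on
per-period mean points; extrapolation beyond the fitted u range is allowed
but flagged. A published correlation (slope 0.24, intercept 1.31) ships as
the default prediction model.

Cross-study flux prediction:
`flux = (k(u)·A_transfer·C_MCCA,undiss + V·C_MCC/HRT) / A_transfer`.
The model agreement statistic `r_squared` is the **squared Pearson
correlation** of observed vs predicted (a constant prediction scores 0);
regression-through-origin R² is a different convention and is intentionally
not used.

## Microbiome analytics

The abundance filter keeps OTUs reaching 1 % relative abundance in at least
one sample, inclusive (≥) by default with a strict (>) mode. Shannon
diversity uses log base 2 by default (the upstream amplicon-pipeline
convention), selectable to natural log. The positive-correlation gate flags
an OTU when Pearson r exceeds the two-sided critical value
`t_(1−α/2, n−2)/√(t² + n − 2)` — 0.754 at n = 7, α = 0.05; p-values are
two-sided and no multiple-testing correction is applied by default (a
Benjamini–Hochberg option exists). Zero-variance abundance vectors return
an explicit `undefined` flag instead of NaN propagation. Bray–Curtis
dissimilarities (on relative abundances) feed average-linkage (UPGMA)
clustering; SciPy's linkage is deterministic, breaking equal merge heights
by condensed-index order, so heat-map orderings are reproducible for a
fixed table. PCoA is classical scaling (via scikit-bio); negative
eigenvalues of non-Euclidean dissimilarities are reported, not hidden.
Weighted UniFrac is out of scope (it needs a phylogeny); ordination of the
Bray–Curtis matrix is provided instead.

## Synthetic generator

The reactor simulator integrates, per species,

    V dC/dt = production − k(u)·A_transfer·f_undiss·C − Q_eff·C

with forward Euler and automatic sub-stepping (step count scales with the
removal rate constant; any step that would overdraw the available mass is
mass-limited and logged). The trap accumulates the extracted mass. Defaults
emulate the semi-continuous phase of a wine-lees campaign: four periods
over days 17–84, V = 4.8 L, HRT 9 d, OLR 5.8 g COD/L-d, pH 5.2, recycle
9 → 90 → 323 → 228 L/d, planted line k = 0.24u + 1.31, MCC productivities
ramping 1.0/2.0/3.9/3.0 g COD/L-d with C8:C6 ratios 0.4/0.7/1.0/0.9, plus a
small non-extracted n-butyrate stream. Only the Period-4 productivity
(3.9 g COD/L-d at ratio 1.0) and the recycle endpoints are anchored
figures; the intermediate values are the package's own realistic choices.

Two design choices matter for testing. First, each period starts at its
analytic quasi-steady state C* = production/(k·A·f_undiss + Q_eff) by
default, so trap curves are exactly linear per period and the noiseless
end-to-end recovery oracle (generate → fit extraction slopes → k per period
→ k–u line) closes to 1e-6 relative; `steady_state_init=False` gives
continuous transients instead. Second, samples are offset by half a
sampling interval so none falls on a period boundary, keeping the inclusive
averaging window unambiguous. Measurement noise is multiplicative Gaussian
truncated at zero (GC-like relative error), CV 5 % per stream by default;
the broth, trap and OTU streams draw from independent generators spawned
from the master seed, so regenerating one stream never perturbs another.
Discrete COD ledgers (fed, extracted, washed, Δbroth) are accumulated with
the same step terms as the state update, so noiseless conservation holds to
1e-9 relative per period and species.

The OTU generator draws multinomial counts over Dirichlet-perturbed
proportions. The planted taxon's expected proportion is
`μ·(1 + c·z)` with z the standardised productivity; c is calibrated from
the target Pearson ρ and the predicted observation noise
`μ(1−μ)·(1/(θ+1) + 1/depth)` (Dirichlet concentration θ, sequencing depth).
When the target is infeasible at the configured noise the slope is capped
and the achievable ρ is reported in the truth record. Defaults: 7 samples
(a semi-continuous-phase campaign), 40 OTUs, depth 10⁴, θ = 200, ρ = 0.9,
productivity ramp 0.5–3.9 g COD/L-d.

What the generator does **not** emulate: substrate hydrolysis and donor
limitation, product inhibition feedback on production rates, solvent-phase
dynamics, compositional correlations between non-planted OTUs beyond the
Dirichlet draw, and chimeras/contaminants. Passing recovery tests therefore
demonstrate correctness of the accounting and estimation chain under the
stated balance model, not biological realism of any fitted value.

## Numerical choices and degenerate inputs

Extraction fits need ≥ 2 strictly increasing time points (SE only for
n ≥ 3); k is an explicit error at ΔC = 0 rather than infinity; the k–u fit
refuses identical velocities; `predict_k` floors at zero; zero OLR with
nonzero production raises rather than reporting an infinite yield; missing
per-species fits or broth data are listed in diagnostics fields, never
silently zeroed. Problem sizes in the test suite (40-replicate noisy
recovery, 500-replicate OTU power at depth 10⁴, 20 000-pair correlation
checks) were chosen so the full suite completes in well under a minute
while keeping Monte-Carlo standard errors far below the asserted margins.

## Known limitations

- The washout term uses the period-mean broth concentration; sub-cycle
  dynamics of every-2-day feeding are not resolved (average flows are
  used).
- The two-film decomposition of k (shell/membrane/lumen resistances) and
  solvent partitioning are not modelled; k is an overall coefficient.
- The flux-prediction model lumps C6 + C8 into one MCCA concentration;
  systems strongly skewed toward C8 extract more easily than the lumped
  model predicts.
- pKa values carry no temperature correction; at 37 °C the speciation error
  is small but nonzero.
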