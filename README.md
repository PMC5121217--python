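# mccflux

COD-basis accounting, membrane-pertraction mass-transfer modelling and
microbiome–productivity correlation for chain-elongation bioreactors.

Chain elongation converts short-chain carboxylates (acetate C2, n-butyrate
C4) plus an electron donor such as ethanol into medium-chain carboxylates
(MCCs: n-caproate C6, n-caprylate C8) with an open reactor microbiome.
Ethanol-rich wastes such as wine lees supply both the donor and the
elongatable carbon. Because substrates and products differ widely in
oxidation state, everything is balanced in oxygen equivalents: a compound
CnHmOp carries a theoretical oxygen demand of

    ThOD = 32 · (n + m/4 − p/2)   g O₂/mol

so ethanol is 96, acetate 64 and n-caprylate 352 g COD/mol. `mccflux` is for
bioprocess researchers who run such reactors with in-line membrane
extraction (pertraction) and need the full quantitative chain from raw
time-series to publishable performance figures:

- **species** — ThOD/COD factors from elemental composition, g/L ↔ mol/L ↔
  g COD/L conversions, Henderson–Hasselbalch speciation at reactor pH
  (only the undissociated, hydrophobic acid crosses the membrane).
- **rates** — per-period mass balances. Extraction rate M = OLS slope of the
  cumulative trap amounts vs time; washout = mean broth concentration ×
  effluent flow; production = extraction + washout; then productivity
  (rate/V), membrane flux (rate/A_transfer), yield (MCC COD / substrate COD
  fed), specificity (product COD / total product COD) and the C8:C6 ratio.
- **pertraction** — superficial velocity u = Q_recycle/A_cross, overall mass
  transfer coefficient k = M/(A_transfer·ΔC) in mm/d, the linear k–u
  correlation, and cross-study MCC-flux prediction
  flux = (k(u)·A·C_MCCA,undiss + V·C_MCC/HRT)/A.
- **microbiome** — relative abundance, the 1 %-in-any-sample OTU filter,
  Shannon diversity, Bray–Curtis + UPGMA heat-map ordering, PCoA, and the
  Pearson gate flagging OTUs whose abundance tracks MCC productivity
  (critical r = t/√(t²+n−2); 0.754 at n = 7, α = 0.05 two-sided).
- **simulate** — a synthetic-data generator with planted production rates,
  a planted k–u line and a planted productivity-correlated OTU, so every
  pipeline stage is testable against known ground truth.
- **io / cli** — documented CSV/TSV schemas, YAML run configuration and the
  `mccflux` command-line tool.

## Worked example

Simulate a four-period campaign in which the broth-recycle rate through the
forward membrane contactor ramps from 9 to 323 L/d and back to 228 L/d
(working volume 4.8 L, HRT 9 d, OLR 5.8 g COD/L-d, pH 5.2, 5 % measurement
noise), then run the period accounting:

```bash
mccflux simulate reactor --out demo --seed 11
mccflux report --timeseries demo/timeseries.csv --periods demo/periods.csv \
               --out demo/report.csv
```

```
Period performance summary (COD basis)
========================================
P2 (phase II): OLR 5.8 g COD/L-d, MCC productivity 1.0 g COD/L-d, yield 17%, specificity C6/C8 55%/22%, C8:C6 ratio 0.4
P3 (phase II): OLR 5.8 g COD/L-d, MCC productivity 2.1 g COD/L-d, yield 35%, specificity C6/C8 51%/36%, C8:C6 ratio 0.7
P4 (phase II): OLR 5.8 g COD/L-d, MCC productivity 4.0 g COD/L-d, yield 68%, specificity C6/C8 46%/47%, C8:C6 ratio 1.0
P5 (phase II): OLR 5.8 g COD/L-d, MCC productivity 2.6 g COD/L-d, yield 45%, specificity C6/C8 22%/68%, C8:C6 ratio 3.2
```

The highest-recycle period (P4) reaches an MCC productivity of
4.0 g COD/L-d — 68 % of the fed COD — with near-equal C6/C8 production
(planted truth: 3.9 g COD/L-d, 67 %, ratio 1.0). The short final period
shows how 5 % noise on large cumulative trap amounts widens per-period
slope estimates. Recovering the mass-transfer correlation from the same
series:

```python
from mccflux import estimate_ku_from_timeseries
from mccflux.io import load_timeseries, load_periods

ts = load_timeseries("demo/timeseries.csv")
periods = load_periods("demo/periods.csv")
model, points, _ = estimate_ku_from_timeseries(ts, periods)
```

```
P2: u =    5.8 m/d   k =   2.7 mm/d
P3: u =   57.7 m/d   k =  15.8 mm/d
P4: u =  207.1 m/d   k =  51.3 mm/d
P5: u =  146.2 m/d   k =  31.4 mm/d
fit: k = 0.232 u + 1.17   (R2 = 0.9849)
```

i.e. the planted line k = 0.24·u + 1.31 is recovered within the fit's
confidence interval; without noise the recovery is exact to 1e-6 relative.
Evaluated at the maximum applied velocity (u = 207 m/d from 323 L/d through
the 1.56 × 10⁻³ m² shell), the packaged published correlation gives
k = 51.0 mm/d, and extrapolated to u = 6 000 m/d it predicts 1 441 mm/d —
an almost 30-fold headroom for in-line extraction at higher recycle rates.

OTU analytics run the same way from TSV inputs:

```bash
mccflux simulate otus --out demo_otus --seed 11
mccflux microbiome-corr --counts demo_otus/otu_counts.tsv \
    --metadata demo_otus/sample_metadata.tsv --out demo_corr
```

which writes `correlations.csv` (per-OTU Pearson r, p and the significance
flag), Shannon indices, the Bray–Curtis distance matrix with UPGMA sample
ordering, and PCoA coordinates with per-axis variance fractions.

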