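# Methods

## Model and procedure

The predicted total mutation load (PTML) estimates a tumor's actual total
mutation load (ATML) — its count of somatic, non-synonymous, exonic
mutations — from a targeted gene panel. Derivation on a whole-exome cohort
has four steps:

1. **Unadjusted gene value.** For each panel gene, the minimum ATML over the
   samples carrying a retained mutation in that gene. Panel genes with no
   carrier are excluded from the table (they carry no information in that
   cancer type). Because recurrent drivers are mutated quasi-independently
   of load, their minimum carrier is a lightly mutated tumor and they earn
   small values; pure passengers are only hit in heavily mutated tumors and
   earn large ones. This is the mechanism the whole method rests on.
2. **Unadjusted sample total.** The sum of unadjusted values over a sample's
   mutated panel genes, each multiplied by the number of mutations in the
   gene (multiplicity can be disabled at derivation via
   `use_multiplicity=False`; scoring always multiplies).
3. **Slope calibration.** Ordinary least squares of the unadjusted total
   (response) on the ATML (predictor) across all cohort samples, including
   ATML-0 samples, which contribute the point (0, 0). The orientation is
   fixed, not configurable: dividing by this slope is what maps panel-scale
   sums back to ATML scale. Two modes: `ols_intercept` (default — a standard
   OLS fit whose intercept is discarded) and `ols_through_origin`. The
   reported r² is the squared Pearson correlation of the two quantities
   under either mode.
4. **Adjusted value.** `RND(unadjusted / slope)` with RND = round half away
   from zero (all operands are positive, so half-up; no tie rule is implied
   by the definition, so one had to be fixed). Values that round to 0 are
   kept (with a logged warning): the gene then contributes nothing to any
   score, which is the literal reading of the equation.

Scoring: `PTML = Σ adjusted[g] × count[g]` over called genes known to the
weight table; called genes absent from the table contribute 0 and are
surfaced in `unknown_genes` (panel versions drift; erroring would make old
weight tables unusable). Classification is **low iff PTML ≤ threshold**
(inclusive), default threshold 100.

### Retained-mutation filter

"Non-synonymous exonic" is implemented as the whitelist
{Missense_Mutation, Nonsense_Mutation, Nonstop_Mutation, Frame_Shift_Del,
Frame_Shift_Ins, In_Frame_Del, In_Frame_Ins, Translation_Start_Site}.
Splice_Site is excluded by default — splice changes are not exonic
substitutions — but the whitelist is an argument everywhere because
TCGA-era pipelines differ. MAF rows are counted as printed (no
deduplication); sample barcodes are used verbatim, with an option to
truncate to the 12-character TCGA patient stem.

## Survival association

Kaplan–Meier estimation and the log-rank test are delegated to lifelines;
this package fixes the conventions: median survival is the earliest event
time with S(t) ≤ 0.5 and is *undefined* (None in reports) when survival
exceeds 50% at the longest follow-up; ties between an event and a censoring
keep the censored subject in the risk set; the log-rank flavor is the
unweighted statistic referred to a 1-df chi-square, two-sided. Multivariate
Cox adjustment is deliberately out of scope — `survival_table` emits the
tidy (time, event, group) frame that `lifelines.CoxPHFitter` or R
`survival::coxph` consume directly:

```python
from lifelines import CoxPHFitter
CoxPHFitter().fit(table.assign(low=(table.group == "low").astype(int))
                       .drop(columns=["sample_id", "group"]),
                  duration_col="time", event_col="event")
```

## Mutagen-signature proxies

Single-base substitutions are collapsed onto the six pyrimidine-context
classes; the C>T fraction is the UV proxy and the C>A fraction the smoking
proxy. This is deliberately a proxy, not a trinucleotide signature
deconvolution: minimal MAFs carry no flanking context, and dinucleotide
CC>TT events are not separately detected. Precomputed per-sample fractions
from an external signature analysis can be substituted wherever a profile
table is consumed. Samples with zero usable SNVs get an all-zero, flagged
profile rather than NaNs.

## Synthetic cohort generator

The simulator emulates the statistical structure the method assumes, not
any particular consortium dataset. Defaults (all configurable through
`SimulationConfig` / YAML):

| parameter | default | why |
|---|---|---|
| load mixture | 0.25·LogNormal(ln 30, 0.8) + 0.75·LogNormal(ln 600, 1.0), rounded | heavy right tail spanning ~1–5,000 mutations with ~26% of samples ≤ 100, the regime where a ≤ 100 threshold is meaningful |
| exome size | 18,000 genes | order of the protein-coding exome |
| panel | 8 drivers + 162 passengers (170 genes) | clinical panel scale |
| driver prevalence | 0.12 per driver, load-independent | recurrent oncogenes present even in low-load tumors; this is what forces small driver weights |
| panel passenger enrichment | 3× background mutability | panels select large, frequently mutated cancer genes |
| UV coupling | C>T probability 0.10 + 0.75·logistic(1.5·(ln L − ln 150)) | low-load tumors depleted of the mutagen signature, saturating in hypermutated ones |
| survival | exponential events, baseline hazard ln 2/600 per day; low-class hazard ratio 2.5; exponential censoring at 5·10⁻⁴ per day | ~600-day median for the favorable class, moderate censoring |

Passenger mutations are distributed multinomially over the non-driver gene
universe per sample; driver hits are Bernoulli and additional, so the
realized load (the emitted row count, reported as `true_load`) is the
latent mixture draw plus driver hits. Substitution classes are serialized
with consistent ref/alt on a uniformly random strand. All randomness flows
from one seed through `numpy.random.SeedSequence.spawn` (separate streams
for loads, drivers, gene assignment and signatures), so cohorts are
byte-identical across runs at a fixed seed.

**Cross-cancer-type experiment.** Two "cancer types" share the panel but own
disjoint driver blocks via `PanelSpec.driver_offset`. The default driver
structure is too mild for mismatched weights to hurt (the 162-passenger
signal dominates), so the cross-application experiment uses types with 15
drivers at 50% prevalence — the realistic prevalence of BRAF-like drivers —
and a smaller, unenriched 50-gene passenger block. Matched weights then
reach r² ≈ 0.7–0.9 against true load while cross-applied weights fall to
≈ 0.3–0.7, reproducing the qualitative specificity of cancer-specific
weight tables.

### What the simulation does and does not show

Passing tests demonstrate that the algorithm recovers load structure it is
designed for: load-independent drivers, load-proportional passengers,
load-coupled signatures. Real cohorts add batch effects across sequencing
platforms, mutation-caller disagreement, subclonality, copy-number
alterations, gene-length and replication-timing mutability structure, and
non-exponential survival — none of which are simulated. Synthetic r² values
(~0.95) are therefore optimistic relative to real-world validation
performance (~0.7–0.8); they validate the implementation, not clinical
accuracy.

## Numerical and design choices

- **Rounding:** half away from zero, chosen once; adjusted values are
  integers by construction.
- **Degenerate regressions** (constant ATML, or slope ≤ 0) raise
  `DegenerateRegressionError` rather than producing weights.
- **Scale behavior:** multiplying all loads by c scales both regression
  axes by c, leaving the slope invariant and scaling the adjusted values by
  c — the dimensionally required behavior for a load estimator.
- **Recurrent-panel ties** (same carrier count at rank k) break by total
  mutation count, then lexicographic symbol, so panels are deterministic.
- **Weight-table TSV** stores the slope and r² with `repr` so round-trips
  are bit-exact.
- **Test problem sizes:** 300 training + 300 held-out simulated samples for
  end-to-end recovery, 200 per cohort for the cross-type experiment, and
  1000 null / 200 alternative trials at n = 80 for log-rank calibration —
  sizes at which the measured quantities are stable to the second decimal
  across seeds.

## Known limitations

- Weights derive from mutation tables only (no expression or copy number),
  and no confidence intervals accompany adjusted values.
- The zero-PTML → low-load property is asymmetric: a nonzero PTML says
  little about a sample's exact load in the low range, since a single
  driver hit yields a small positive score regardless of load.
- The log-rank test assumes non-informative censoring; the simulator
  honors this by construction, real cohorts may not.
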