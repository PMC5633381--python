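# Methods

## The assay being modelled

`lohflux` analyses a diploid *Saccharomyces cerevisiae* loss-of-heterozygosity
(LOH) assay on chromosome II. One homolog ("IIa") carries four ectopic
markers — `TRP1` near the left telomere (~10 kb), a hygromycin-resistance
cassette at ~230 kb, `URA3` at 241 kb just right of the centromere (238 kb),
and a nourseothricin-resistance cassette (`NAT`) at 795 kb near the right
telomere. Both homologs carry distinguishable truncated (non-functional)
`TYR1` alleles at ~583 kb, used purely as a PCR-diagnostic locus. Cells that
lose the functional `URA3` allele become resistant to 5-fluoroorotic acid
(5-FOA); resistance is recessive, all other markers are dominant.

The retention pattern of the three remaining markers in a 5-FOA-resistant
colony assigns the event class:

| trp | hyg | nat | class |
|---|---|---|---|
| − | − | − | chromosome loss (CL): whole-homolog aneuploidy |
| + | + | + | gene conversion (GC): local loss of URA3 only |
| + | + | − | segmental LOH of the right arm (crossover/half-crossover/BIR) |
| + | − | − or − | − | + | complex event (one telomeric marker kept, rest lost) |

The three remaining foa⁺ patterns (any pattern retaining hygromycin
resistance without the full GC/segmental signature) fit none of the modelled
mechanisms. `classify_phenotype` raises a typed `AnomalousPhenotypeError` and
the pipeline tallies them per genotype in an `ANOMALOUS` row; they are never
merged into a class, because the mechanistic model enumerates exactly four
scenarios and silently binning contradicting observations would hide model
violations.

Complex events are resolved further from PCR zygosity at the retained
telomeric locus plus the `TYR1` diagnostic alleles (`-2` = marked homolog,
`-1` = unmarked homolog):

* retained locus **heterozygous** → `HET_TELOMERIC`: the telomeric fragment
  of IIa survived next to an intact IIb (BIR through the centromere, or
  ectopic capture); this is the configuration a trivial
  crossover-then-chromosome-loss sequence cannot produce.
* retained locus **homozygous** for the marked allele, `TYR1-1` only →
  `HALF_CO_NAT_TYR1` (half-crossover breakpoint between NAT and TYR1);
  `TYR1-2` only → `HALF_CO_TYR1_URA3` (breakpoint between TYR1 and URA3).
* retained locus heterozygous with `TYR1` homozygous → `ANOMALOUS`
  (no modelled mechanism; experimentally unobserved).
* missing zygosity data → `UNRESOLVED` (a data state, not an error).

For TRP1-retaining complex events only the left-arm `TRP1` zygosity is
informative (TYR1 is on the right arm): heterozygous → `HET_TELOMERIC`,
homozygous → `UNRESOLVED` because no second diagnostic locus localises a
left-arm breakpoint.

`apply_event` is the generative inverse used by the simulator: each class
edits the starting heterozygous genotype (segment replacement for
crossovers, an acentric-fragment field for `HET_TELOMERIC`, copy-number 0
for chromosome loss), and `classify(phenotype(apply(g₀, e))) = e` holds for
every event class (property-tested). Half-crossover breakpoints are placed
at the midpoint between the flanking loci; any position inside the interval
gives the same marker arithmetic. The `POINT_MUTATION` event inactivates
URA3 in place — phenotypically identical to GC but URA3-heterozygous by PCR,
which is exactly the confound the haploid-control experiments address.

## Synthetic fluctuation cultures

`simulate_culture` grows a culture by synchronous doublings from `n0`
(default 10³) to at least `n_final`. One division produces one new daughter,
so total divisions = `n_final − n0` and rates are "per cell division"
(reported per 10⁷ divisions). In each round, every wild-type division
independently founds an LOH clone of class *k* with probability μ_k
(binomial draw per class); clones double thereafter. This is the simplest
generative model with the defining Luria–Delbrück property — rare early
events yield jackpot cultures, making the variance/mean (Fano factor) of
resistant counts orders of magnitude above the Poisson value of 1 (measured
≈10³ at μ·divisions = 1 with `n_final` = 10⁶).

Deliberate simplifications, and what they imply for the tests: no cell
death; no fitness cost of LOH clones (monosomic clones grow at the wild-type
rate — a `relative_fitness` knob exists, default 1.0, to probe viability
hypotheses); no secondary events on mutant lineages (so a
crossover-then-loss compound pathway is *absent* by construction; the
independence analysis treats it as a null, not a mechanism); full phenotypic
expression and plating efficiency 1.0 by default; synchronous generations
rather than a continuous-time birth process (the realised `n_final` is
`n0·2^⌈log₂(n_final/n0)⌉`, slightly above the request, and all estimators
use the realised value). Passing recovery tests therefore validates the
estimator under the model's own assumptions; they say nothing about e.g.
differential colony size or death in real cultures.

Selective plating with dilution *d* and plating efficiency *e* is binomial
thinning with probability *d·e*. Default per-class rates in the bundled
configurations are reference order-of-magnitude values for wild-type
(GC 12, CL 5, segmental 3, complex 1, ×10⁻⁷ per division) and
cohesin-mutant-like (CL 5531, GC 30, complex 54, ×10⁻⁷) strains; the
complex-subclass mix defaults to the observed 17:3:7 resolution. Note the
wild-type GC *rate share* is 12/21 ≈ 57%, whereas the reference colony
percentage is ~70%; the simulator reproduces the modal
class and the qualitative spectrum, not the exact percentage, since the
reference per-class rates and colony percentages are not mutually
consistent to that precision.

Reproducibility: every stochastic entry point takes a master seed and splits
it with `numpy.random.SeedSequence.spawn`, one child stream per culture or
colony, so outputs are independent of evaluation order and deterministic
end to end.

`simulate_independent_colonies` mirrors the one-colony-per-mini-culture
survey design: each colony's class is drawn with probability proportional to
*its own culture's* per-class resistant counts (not the rate ratios), which
reproduces the jackpot distortion that design carries; all-zero cultures are
redrawn within a retry budget.

## Rate estimation

The expected events per culture *m* solve the Lea–Coulson median equation
`r_med/m − ln m = 1.24`, found by Brent root-finding on the monotone branch
`m > e^{−1.24}` to 10⁻¹² relative tolerance (property-tested against an
independent bisection oracle to 10⁻⁹ over r ∈ [10⁻³, 10⁶]). The rate is
`μ = m / (n_final − n0)`.

Two labelled variants are reported because the classical description leaves
room for either:

* **per-culture** (default): apply the equation to each culture's
  (dilution-corrected) count — with r = 0 mapping to rate 0, the m → 0
  limit — and take the median of per-culture rates with a distribution-free
  order-statistic CI.
* **pooled-median**: apply the equation once to the median count; the CI is
  the order-statistic CI of the counts pushed through the monotone
  count→rate map.

With equal culture sizes and an odd culture count the two coincide exactly;
both are always computed (`pooled_median_rate` rides along on the estimate).
Zero-count cultures are *included* at rate 0 rather than dropped: dropping
them inflates the median severely when m ≈ 1 (the nonzero-count median sits
near m ≈ 1.7 when the true m is 1), breaks monotonicity in the counts, and
de-couples the two variants. When the median count itself is 0 the p0 method
takes over (`m = −ln(fraction of zero cultures)`, flagged, no CI); a class
unobserved in every culture reports rate 0 with the resolution-limit upper
bound `−ln((n−½)/n)/divisions`.

The median CI uses sign-test inversion: ranks `(l, n+1−l)` with the largest
`l` whose two-tailed Binomial(n, ½) mass outside the interval is ≤ 1−level,
reporting the achieved coverage (0.969 at n = 6, 0.977 at n = 24); for n < 6
the requested 95% is unattainable, the full range is returned and flagged.
On the discrete per-culture rate distribution the interval is conservative
(coverage ≥ achieved level), which simulation confirms. The method of the
median is a heuristic with rate-dependent bias: in this growth model the
median estimate runs ~10–15% low at moderate m (1–100 expected events per
culture), drifting to ~20–25% low by m ≈ 100 and further at very high rates
where the synchronous model compresses the jackpot tail; the suite asserts
the documented |bias| < 35% bound over μ ∈ [10⁻⁶, 10⁻⁴] with 10⁶-cell
cultures. Below m ≈ 0.1 with few cultures the assay simply cannot see the
class (all-zero counts; p0 upper bounds only). The simulation-study harness
(`run_simulation_study`) measures bias, 30%-recovery fraction and CI
coverage; at μ·divisions ≈ 1 with 24 cultures the estimate lands within 30%
of truth in roughly 85–90% of assays.

The derived "non-CL" rate is the plain difference of medians
(total − chromosome loss), clamped at 0, with no CI — interval arithmetic on
dependent order statistics would be fictitious precision.

## Statistical tests

All tests wrap established SciPy/statsmodels routines behind a uniform
`TestResult`; choices that were genuinely open:

* Fisher's exact test uses point-probability ordering for the two-sided p
  (the convention that yields 0.0011 on the 17/10 vs 22/0 heterozygosity
  table); verified exhaustively against direct hypergeometric enumeration
  for every 2×2 table with total ≤ 40.
* The two-proportion χ² is 1-df Pearson *without* Yates correction
  (switchable in principle; the uncorrected statistic is the one whose
  large-sample behaviour converges to the exact test, which the suite
  checks at ×1/×10/×100 scalings).
* Multiple-testing correction defaults to Holm step-down (uniformly more
  powerful than Bonferroni, identical for one test); Bonferroni and none are
  selectable.
* The independence null for complex events is the product of the two
  per-division rates, and the bound test is an upper-tail binomial
  P(X ≥ k | n, p₀), exact up to n = 10⁷ and the Poisson limit beyond
  (relative error < 10⁻³ in the validated regime).
* Group comparisons: Welch t (two-sided, unequal variance) and Mann–Whitney
  (exact enumeration for combined n ≤ 20 without ties, tie-corrected normal
  approximation otherwise; fully tied data return p = 1). The PFGE panel
  defaults to Mann–Whitney on chromosome II band fractions
  `vol_II / (vol_II + vol_XIV + vol_X)`, with Welch t behind a flag.

## Pipeline and problem sizes

`run_classify`, `run_rates`, `run_complex_panel` and `run_simulation_study`
operate on TSV tables (tab-delimited, `NA` missing, `+`/`−` growth calls)
and emit JSON reports with a provenance block (config hash, seed, version).
Reported rates are rounded to 2 significant figures ×10⁻⁷ in tables; full
precision is kept in JSON fields. `scripts/acceptance.py` regenerates the
headline quantities from scratch at fixed problem sizes chosen to keep the
whole run in seconds on one CPU: 300 independent colonies per strain
configuration, 10⁴ cultures for the Fano factor, and 20 replicate 24-culture
assays (n_final = 10⁵, μ = 10⁻⁵) for rate recovery.

## Known limitations

* The growth model is discrete-generation and neutral; it is an estimator
  test-bed, not a mechanistic simulator of cohesin biology.
* Per-culture rate estimates are atomic at small m (counts are integers), so
  single-assay estimates jump between a handful of values; summaries over
  replicate assays are the meaningful quantity.
* The half-crossover subclasses assume the centromeric-URA3 marker map; with
  the telomeric-URA3 variant the breakpoint intervals would transfer URA3
  and the subclass round-trip does not apply (the variant map is used for
  segmental-rate work).
* Anomalous patterns and `UNRESOLVED` subclasses are surfaced, not modelled.
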