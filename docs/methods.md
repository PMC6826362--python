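# Methods

## Design and notation

The package analyses a four-group reciprocal-cross design: purebred parental
lines P1 and P2 and the two cross directions F1A (P1 sire × P2 dam) and F1B
(P2 sire × P1 dam). External group labels (breed codes such as CC/RR/CR/RC)
are mapped onto this internal vocabulary at read time, so nothing downstream
is organism-specific.

## Mid-parent heterosis

For a trait with hybrid observations F1ᵢ (i = 1..n₁) and parental group means
P̄₁, P̄₂, the mid-parent value is MP = (P̄₁+P̄₂)/2 and heterosis is
H% = 100·(F̄₁ − MP)/MP. H% is undefined when MP = 0 (an error, never ±∞), is
invariant to rescaling all trait values, and is symmetric in the parents.

Significance uses a delta-method t that treats the parental means as fixed:

    t = H · (P̄₁+P̄₂) · √n₁ / (2·s₁),  df = n₁ − 1,

with H the heterosis fraction and s₁ the hybrid sample SD (divisor n₁−1).
Algebraically this is the one-sample t-test of F̄₁ against the constant MP;
the test suite cross-checks it against an independent one-sample-t
implementation and calibrates its size by Monte Carlo (10⁵ null samples;
empirical size ≈ 0.05). Ignoring parental sampling noise makes the test
mildly anticonservative when the parental groups are small and variable; an
alternative reading that inflates the SE by √2 is exposed as
`t_variant="sqrt2"`. p-values are two-sided (heterosis can be negative), and
a degenerate hybrid SD of 0 is flagged rather than silently producing ±∞.

## Expression units and filtering

FPKM_{g,s} = count_{g,s} · 10⁹ / (length_g · libsize_s), with gene lengths
supplied as a table (no exon-union computation) and library sizes defaulting
to column sums. Genes with mean FPKM across **all** samples below 1.0 are
removed before testing; the boundary value 1.0 is retained (only
sub-threshold genes are removed). The filter threshold is a parameter.

## Negative-binomial Wald differential expression

The engine is intentionally transparent rather than a clone of any published
package:

- **Normalization.** Median-of-ratios size factors (per-sample median of
  count ratios to the per-gene geometric-mean reference, over genes with no
  zeros) are the default. Column-sum factors are available but are biased by
  composition: a minority of genes strongly shifted in one group (e.g.
  over-dominant genes inflating the cross libraries by ~15% in the default
  simulation) moves totals but not the median ratio, and with column-sum
  factors every null gene inherits the compensating shift.
- **Dispersion.** Per-gene method of moments on normalized counts, pooled
  within groups: α = max(floor, (pooled var − pooled mean)/pooled mean²),
  floor 10⁻⁸. The raw estimate is approximately unbiased but noisy at n = 6
  per group, and the Wald test's false-positive rate is dominated by genes
  whose α happens to be underestimated: plugging the true α into the test
  gives empirical size ≈ 0.048, the raw plug-in ≈ 0.08–0.09. Each gene's α
  is therefore floored at the experiment-wide median of the raw estimates
  (`moderation="median-max"`), which restores size ≈ 0.042–0.045 at a small
  uniform power cost. This is a central-value floor, not a mean–dispersion
  trend fit; `moderation="none"` gives the raw estimator.
- **Wald statistic.** Group means m on normalized counts;
  log2FC = log2((m_num+c)/(m_den+c)) with pseudo-mean c = 0.5 guarding zero
  means; delta-method SE from Var(m_g) = (m_g + α m_g²)/n_g; two-sided
  Gaussian p-values; BH adjustment within each contrast separately (each
  comparison is an independently reported analysis).
- **Mid-parent contrast.** Additivity needs a test of the cross against
  ½(P̄₁+P̄₂), which pairwise contrasts cannot express; the engine supports a
  `MID` pseudo-group whose mean is the average of the parental group means
  and whose variance is (Var(m_P1)+Var(m_P2))/4.

Not implemented by design: dispersion-trend shrinkage, outlier handling
(Cook's distance), covariate GLMs, fold-change shrinkage, independent
filtering. On real data, DEG counts will therefore differ from pipelines
using those refinements.

## Inheritance-mode classification

Per cross, genes significant (BH-adjusted p < α, strict) in ≥ 1 of the three
pairwise contrasts (parents, cross vs P1, cross vs P2) are classified from
the evidence tuple of four direction calls (up/down/ns) plus the signs of the
cross-vs-parent point estimates:

| category | types | pattern |
|---|---|---|
| over-dominant | V, VI, VIII | cross significantly above both parents (V: P1 > P2, VIII: P2 > P1, VI: parents ns) |
| under-dominant | III, VII, X | cross significantly below both parents (III: P1 > P2, X: P2 > P1, VII: parents ns) |
| high-parent dominant | II, IV | parents differ; cross ns vs the higher parent, significantly above the lower (II: higher = P1) |
| low-parent dominant | IX, XI | parents differ; cross ns vs the lower parent, significantly below the higher (IX: lower = P1) |
| additive | I, XII | parents differ; cross ns vs the mid-parent and its estimate strictly between the parents (I: P1 > P2) |
| other | none | anything else (e.g. above one parent, below the other) |

Rules are evaluated in the order listed, making the map total and
single-valued; the suite verifies exhaustiveness, exclusivity, and that
relabeling P1↔P2 maps I↔XII, II↔IV, IX↔XI, V↔VIII, III↔X, fixes VI/VII, and
leaves category counts invariant. Dominance patterns deliberately take
precedence over the mid-parent additivity test: in the twelve-bin scheme
"cross = one parent ≠ other" *defines* the dominance bins, so a gene showing
that pattern is dominance even when its mid-parent call is quiet. The known
cost is leakage of true additive genes into dominance bins when one
cross-vs-parent call loses power (~15–25% at the default simulation
settings); the converse ordering would instead misroute ~20% of true
high-parent genes into additivity. Category proportions are reported over
the non-additive total; the over-dominant intersection across the two cross
directions is a plain set intersection of gene ids.

## Over-representation analysis

Upper-tail hypergeometric test, P(X ≥ k) with X ~ Hypergeom(N, K, n), of a
study list against GMT gene sets, both restricted to a universe. The universe
is the *tested* population — genes passing the expression filter — not the
genome: using the genome would manufacture enrichment for merely-expressed
sets. Sets with no member in the universe are skipped (excluded from the BH
family). p-values are verified against direct factorial summation for small
universes.

## qPCR 2^−ΔΔCt

Technical replicates are averaged on the Ct scale (standard practice);
ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the calibrator
group's mean ΔCt; fold change = 2^−ΔΔCt with efficiency fixed at 2 (no
Pfaffl correction). Consequences verified in tests: constant Ct shifts cancel
exactly, and the calibrator group's geometric-mean fold change is exactly 1.
The calibrator group is a required argument — there is no sensible default.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any particular dataset: four groups × n replicates (default 6), NB counts
(gamma–Poisson, var = μ + αμ², default α = 0.05 — a conventional bulk
RNA-seq value), per-gene log-normal baselines (median 100 expected counts at
a 10⁶ reference library, log-SD 1.0), uniform 0.8–1.2 × 10⁶ library sizes,
uniform 200–3000 bp lengths. Each gene is planted in one mode; the group
means satisfy the mode's defining pattern exactly: parents split ±1 log2
around the baseline (magnitude 2.0, direction randomized 50/50 per gene so
library composition stays balanced), crosses at the arithmetic mid-parent
(additive), at the higher/lower parent (dominance), or 1.5 log2 beyond the
parental range (over/under). Default composition: 600 conserved / 100
additive / 100 high-parent / 100 low-parent / 50 over / 50 under —
dominance-heavy non-additive spectrum with rare over/under-dominance, the
ordering typically seen in crosses. Both cross directions share identical
means by default (no parent-of-origin mechanism); `f1b_extra_log2_shift`
breaks the symmetry for testing asymmetric calls. Phenotypes are Gaussian
per group truncated at 0 (the trait is a percentage; the lean parental line
sits at 0 ± 0).

What the generator does **not** emulate — and hence what passing recovery
tests cannot show about real data: mean–dispersion trends, gene–gene
correlation, batch effects, length/GC bias, allele-specific or
sex-chromosome effects, and effect-size spectra (all planted effects share
one magnitude). Recovery rates here are upper bounds for real experiments.

## Problem sizes and numerical choices

The recovery benchmark runs 1000 genes × 23–24 samples; null calibration
uses 5000 genes × 12 samples; the heterosis Monte Carlo uses 10⁵ replicates
— sizes at which every simulation completes in seconds while keeping
binomial noise well inside the asserted bands. Ties and degenerate inputs:
p_adj exactly at α is non-significant (strict inequality throughout); a
fold-change estimate exactly 0 is "not strictly between" the parents;
degenerate within-group variance lands on the dispersion floor; empty
post-filter matrices yield empty, warned results rather than errors. All
randomness flows from explicit integer seeds; fixed seeds give bit-identical
outputs end to end.
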