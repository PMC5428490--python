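# Methods

## Classification model

Each gene of a trio (two inbred parents, one F1 hybrid) is summarized by
three replicate-group means: `x̄_pA`, `x̄_pB`, `x̄_H`. The group statistic is
the arithmetic mean of replicate values, chosen to match the definition of
the mid-parent value, which is itself an average of means. The parent with
the smaller mean is labelled the low parent (LP), the other the high parent
(HP); an exact tie labels parentA as LP, a convention that provably cannot
affect the class (equal parents always yield one of the parents-equal
classes 4, 6 or 8, and these do not depend on which parent is called LP).

Two means are compared by fold change with a pseudocount *c*:
`FC(a, b) = max(a+c, b+c) / min(a+c, b+c)`, defined as 1 when both shifted
values are 0. `y` is *greater* than `x` when `(y+c) ≥ f·(x+c)` with fold
threshold `f` (default 2 — "at least two-fold" counts as different, a fold
change strictly below 2 as equal); *less* symmetrically; otherwise *equal*.
The pseudocount default of 1 expression unit stabilizes ratios for genes
near zero expression; `c = 0` gives exact ratio arithmetic and makes the
classification invariant under rescaling all three means.

The class is decided purely from the pairwise relations
`(LP vs H, HP vs H, LP vs HP)` — fold-change "equality" is not transitive,
so no ordering shortcut is taken. With `r1 = relation(LP→H)` and
`r2 = relation(HP→H)`: (greater, less) → 1, (greater, equal) → 2,
(equal, less) → 3, (equal, equal) → 4, (greater, greater) → 5 or 6 by the
LP-vs-HP relation, (less, less) → 7 or 8 likewise. The remaining pairs
(less, equal) and (equal, greater) are arithmetically impossible when
LP ≤ HP, because the fold change of H against HP can never exceed that
against LP; the code raises an internal-consistency error if they are ever
reached, as that can only mean a broken relation implementation.

## Non-additivity against the mid-parent value

`MPV = (x̄_pA + x̄_pB)/2`. The non-additivity call is a pure significance
test at `alpha = 0.05` with no additional fold-change requirement: when the
parents have equal replicate counts, pseudo-MPV replicates
`m_i = (pA_i + pB_i)/2` are formed by replicate index and compared with the
hybrid replicates by a two-sample unequal-variance (Welch) t-test; with
unequal parent replication the test falls back to a one-sample t-test of
the hybrid replicates against the scalar MPV. The pseudo-MPV pairing uses
the sample order of the design file; since replicates are exchangeable the
pairing only fixes which variance estimate is obtained, not its
distribution. Degenerate inputs are handled explicitly: zero variance
everywhere with equal means gives p = 1 (no evidence of departure), zero
variance with unequal means gives p = 0. At least two replicates per group
are required; anything less raises an error rather than silently producing
a one-replicate "test".

No multiple-testing correction is applied to the per-gene calls by default
— the class-wise non-additive counts are descriptive tallies, not a
discovery list. Benjamini–Hochberg adjustment is available (`fdr=True` /
`--fdr`) for users who want FDR-controlled calls.

## Pathway enrichment

Over-representation of a pathway (size K) among selected genes (size n, by
default the non-additive set) within a universe of N classified genes is
tested with the one-sided hypergeometric upper tail `P(X ≥ k)`; p-values
are BH-adjusted across pathways and results ordered by p-value with
pathway-name tie-breaks. The universe defaults to all classified genes of
the analyzed tissue/stage. Rank-based (GSEA-style) and topology-aware
methods are out of scope.

## AW-box scanning

The AW-box — the WRI1 binding site upstream of fatty-acid synthesis genes —
is represented by the degenerate consensus `[CnTnG](N)7[CG]`, IUPAC string
`CNTNGNNNNNNNCG`; the pattern is configuration, never hard-coded in the
scanner logic. Matching is by per-position IUPAC set membership with one
deliberate asymmetry: an `N` in a *sequence* is an unknown base and matches
only pattern positions that are fully degenerate (`N`), never a constrained
position. Both strands are scanned by default; all overlapping hits are
reported with 0-based half-open forward-strand coordinates (BED
convention), minus-strand matched text reverse-complemented into motif
orientation, and ties at a start position ordered `+` before `-`. Promoter
extent is caller-defined: sequences are scanned as given, with no genome
coordinate extraction. Presence fractions are reported as
`100·n_with_motif/n_total`, rounded to the nearest integer for display with
full precision retained.

## Lipid trait metrics

Fatty-acid profiles are percent-of-total compositions with species labels
`C<chain>:<double_bonds>` (chain 12–24, bonds 0–3, percents summing to
100 ± 0.5). The C18:C16 ratio sums *all* unsaturation states of each chain
length on both sides of the quotient, matching how the C16 and C18 species
are tabulated in fruit-oil GC analyses; the species sets are exposed as an
option. The desaturated:saturated ratio is the percent with ≥ 1 double bond
over the percent with none. Annual lipid yield per tree is
`(lipid content %)/100 × annual tissue yield (kg)`. Ratios with a zero
denominator raise an undefined-ratio error rather than returning infinity.

## Synthetic data

The generator emulates a trio RNA-seq comparison in one tissue/stage at
desk scale. Per gene, a base mean μ is drawn log-uniformly from 5–500
normalized-expression units and a class from configurable proportions whose
default mirrors an endosperm-like transcriptome (class 4 at 70.2%, the rest
split as in the reference class shares). Group means follow geometric class
templates with separation `s` (default 4): e.g. class 1 uses LP = μ,
H = s·μ, HP = s²·μ, so every "different" relation clears the two-fold
threshold with margin while `s` slightly above `f` probes boundary
behaviour. Which parent plays LP is a fair coin flip per gene. Replicates
(default 3 per group) are lognormal around the group mean with a
coefficient of variation (default 0.1), mean-corrected so the expected
replicate equals the template mean; the pipeline consumes normalized
expression, so count-level (negative-binomial) noise is deliberately not
modelled. The planted non-additive flag records whether the template hybrid
mean differs from the template MPV — true for every class except 4 under
these templates. Everything is reproducible bit-for-bit from the seed.

Promoters are uniform-ACGT background sequences with one AW-box instance
planted at rate `motif_rate` (default 0.61 over 338 promoters of 500 bp,
mirroring the lipid-gene census setting), each degenerate position
instantiated uniformly, on a random strand at a recorded position. The
14-nt box has only 5 constrained positions, so random sequence matches it
at `4^-5` per window per strand — roughly one incidental hit per kilobase.
By default the background is therefore scrubbed of incidental matches
(`clean_background=True`), making motif presence equal the planting record
exactly and planted-recall checks exact; disabling it recovers the analytic
spurious-match rate, which the tests verify against the closed-form
per-window probability.

Pathway catalogs draw each pathway's members by weighted sampling without
replacement (Gumbel top-k), weighting planted-non-additive genes
`rate/n_nonadditive` and the rest `(1−rate)/n_additive`. When `rate` equals
the background non-additive fraction the weights are exactly uniform, so a
null pathway is an exact uniform draw and its enrichment p-value is exactly
hypergeometric-superuniform — the property the null-calibration test
(Kolmogorov–Smirnov against uniform over 200 seeds) relies on. The
calibration uses a universe of 2,000 genes, a pathway of 150 and a ~50%
background so the discrete p-value support is fine enough to compare
against the continuous uniform; infeasible rate/size combinations (e.g.
rate 1 with a pathway larger than the non-additive pool) are config errors.

What passing on synthetic data does and does not show: recovery and
calibration results demonstrate the arithmetic and the statistics are
implemented correctly under the generator's assumptions (lognormal
replicate noise, independent genes, exchangeable replicates). Real trios
add library-size and batch effects, gene–gene correlation, hierarchical
(bunch/tree) variance and mapping ambiguity from de novo assembly, none of
which the generator models; results on real data depend on the upstream
normalization being adequate.

## Problem sizes and numerical choices

The default test suite and the acceptance script use 800-gene trios
(separation 4, CV 0.1, 3 replicates), 200 × 1 kb sequences for the
scanner-vs-oracle comparison, 10,000 random triples for the classification
invariants, and 200 seeds for null calibration — sizes at which every
stochastic assertion holds with wide margin while the whole suite runs in
seconds. Statistical primitives come from scipy/statsmodels
(`hypergeom.sf`, Welch and one-sample t, BH); tests verify them against
independent brute-force oracles (exact rational enumeration for the
hypergeometric tail, first-principles Welch formula) to 1e-10. TSV output
uses fixed float formatting and `float_precision="round_trip"` parsing so
write→read round trips are bit-exact and reruns byte-identical.

## Known limitations

* The per-class non-additive counts of a real dataset depend on replicate
  structure and noise; only their arithmetic identities (column sums,
  unions, shares) are treated as reproducible quantities here.
* The AW-box consensus is one literature form; scanning results depend on
  the chosen pattern and promoter window, both caller-supplied.
* Whether the published "ANOVA" and "t-test" labels denote one procedure or
  two is not stated in the source material for this class of analysis; this
  package implements a single MPV location test and documents it as such.
* Expression units are taken as given; fold-change classes computed on
  differently normalized matrices are not comparable across runs.
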