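# Methods

## Sweep statistics and polarization

Statistics operate on the unfolded site frequency spectrum of n sample
haplotypes polarized against one ancestral (outgroup) sequence aligned
to them. Site filters follow an infinite-sites reading of resequencing
data: columns with a gap or N in any row are excluded listwise; columns
with more than two sample alleles are excluded; polymorphic columns
whose sample alleles do not include the ancestral base cannot be
polarized and are excluded; monomorphic and fixed-derived columns do
not segregate. Tajima's D uses the classic 1989 standardization; the
standardized Fay & Wu's H and Zeng's E use the Zeng et al. (2006)
variance formulas with θ̂ = S/a_n and θ̂² = S(S−1)/(a_n²+b_n). At S = 0
the statistics are reported as NaN (undefined), never 0; the n = 2
corner where both the numerator and the variance vanish identically
returns 0. Sliding windows default to 2,000 bp; the step (unstated in
the original procedure) defaults to 100 bp and is configurable. Peak
ties break toward the smaller start coordinate.

## Coalescent null

The null is the standard neutral coalescent with crossover
recombination, simulated exactly on the ancestral recombination graph
(no sequential-Markov approximation — the locus is 2 kb). Lineages
carry intervals of ancestral material, each mapped to the set of sample
leaves below it (a 64-bit mask, so n ≤ 62); material that reaches its
local MRCA is dropped, and recombination acts at rate ρ/2 per unit of a
lineage's span between the ends of its material. Time is in units of
2N generations with θ = 4Nμ, ρ = 4Nr; only rate ratios matter for the
statistics. Mutations are Poisson on branches with uniform positions,
sampled lazily when a lineage is retired (its segments are immutable
over its lifetime), giving each polymorphism a known derived state by
construction. The kernel is compiled with numba; seeded runs are
bit-reproducible, with per-replicate seeds spawned from the model seed.

θ and ρ are interpreted per site and multiplied by the window length
(`per_locus=True` switches to whole-locus values, since simulation
front-ends differ in this convention). Default parameters are the study
conditions: n = 22, θ = 7.6×10⁻³/site, ρ = 2.5×10⁻¹/site, L = 2000,
10,000 replicates. ρ itself derives from
θ × (map length / genome size) / μ with μ = 2.9×10⁻⁹.

Empirical probabilities are raw proportions with ties counted,
P = #(sim ≤ obs)/#defined — a (k+1)/(n+1) pseudocount mode exists but
is off by default, because the procedure being reproduced reports
probabilities of exactly 0. Replicates with S = 0 are dropped from the
null, not imputed. Significance: P ≥ 0.95 for Zeng's E (high tail),
P < 0.05 (strict) for H and D (low tail). The pipeline's combined
"sweep flagged" call requires E and H simultaneously — the two
statistics that specifically indicate high-frequency derived alleles —
which keeps the neutral flag rate at or below the nominal 5% even
though the two tests are positively correlated.

## Synthetic data

The generators define the conditions under which the pipeline is
validated; each writes its seed and parameters into output headers and
is byte-reproducible.

* **Neutral locus**: ARG replicate rendered to FASTA with a perfect
  ancestral record; continuous mutation positions are assigned distinct
  integer columns.
* **Sweep locus**: the neutral replicate post-processed by an explicit
  genealogical distortion rather than a forward selection simulation: a
  fraction f of lineages (default 0.9) is collapsed onto one founder
  haplotype around the sweep position, each swept lineage escaping
  left/right at exponentially distributed distances. The escape scale
  defaults to 10 kb, the order implied by escape probability
  1 − exp(−r·d·T) with the derived crossover rate r = 9.5×10⁻⁸/bp and
  sweep duration T = (2/s)·ln(2N) (7–40 kb for s between 0.02 and 0.1);
  within a 2-kb window the footprint is therefore strong with a mild
  decay, as expected for a strong recent sweep. Mutations rendered
  monomorphic or fixed by the collapse are dropped.
* **BC1 cross**: 132 individuals, 1,533 evenly spaced markers on 14
  linkage groups totalling 1,790 cM (0.9 markers/cM); genotypes follow
  a two-state Markov chain with interval recombination fractions from
  the Kosambi map function. Four log-scale traits mimic the
  head/thorax measurement structure: the QTL acts on head width and
  head length, which also load on thorax width (the covariate); the
  covariate is genetically independent of the QTL. Effects are given in
  residual-SD units; genotypes are error-free and complete.
* **Alignment**: rows mutated from a common reference; a column
  differs with exactly the configured per-column probability (one
  random row substituted), so the induced mismatch rate equals the
  parameter; constrained blocks use their own rate.
* **Morphometrics**: log x_ij = μ_j + s_i + δ_group,j + ε with a
  shared size factor s_i, so the isometric Burnaby projection removes
  s_i exactly.

What the generators do *not* emulate: genotyping error and missing
data, segregation distortion, gene conversion, demographic structure,
alignment error, and measurement covariance beyond a shared size
factor. Passing tests therefore validate the statistical machinery
under clean study-like conditions, not robustness to those artifacts.

## CNS caller

Full phylogenetically weighted footprinting is simplified to a
column-identity two-rate model: the neutral per-column mismatch rate
p_n is the fraction of unmasked columns not identical across rows
(clipped to [0.01, 0.99]; ≥100 columns required), the constrained rate
defaults to p_c = p_n/5, and columns score log[(1−p_c)/(1−p_n)] on
identity, log[p_c/p_n] otherwise. This keeps the statistical skeleton —
neutral-rate estimation, constrained-segment LOD, Karlin–Altschul P,
−log₁₀ threshold — in a calibratable form. Multi-row columns are scored
identical/non-identical with no pairwise averaging, for determinism.
Coding columns come from a BED/GFF3 mask and are skipped (not scored),
which makes calls invariant to inserting masked columns.

Maximal-scoring segments use the linear-time Ruzzo–Tompa
decomposition; exact zero-score ties resolve to the minimal segment.
λ solves E[e^{λ·score}] = 1 under the neutral column distribution
(bisection to 1e−12; for log-odds scores the root is exactly 1). K is
estimated from 10,000 simulated null blocks by anchoring
P(M > s) = 1 − exp(−K·m·e^{−λs}) at the empirical upper-5% point of
the null maxima — the region of the Gumbel tail that the CNS threshold
actually uses, which makes the α = 0.05 false-call rate
self-calibrating and robust to score discreteness. A segment is a CNS
when −log₁₀ P exceeds −log₁₀ 0.05 strictly.

## QTL scan

The scan is Haley–Knott regression on genotype probabilities rather
than multiple imputation: deterministic, testable, and asymptotically
equivalent at ~1 marker/cM density. Genotype probabilities condition
on the nearest flanking non-missing markers, with interval
recombination fractions from the inverse Kosambi function (Haldane
optional) and Markov-chain combination across the interval; typed
markers give 0/1 indicators, wholly untyped individuals 0.5. LOD is
(n/2)·log₁₀(RSS₀/RSS₁) for trait ~ covariate versus
trait ~ covariate + P(h), evaluated on a 1-cM grid plus terminal
markers. A zero null-model residual (e.g. covariate duplicating the
trait) raises a degenerate-model error instead of an infinite LOD.

Permutation thresholds permute the (trait, covariate) rows jointly
against the genotypes, preserving their correlation — the faithful
null for a correlated-trait design. Implementation-wise the scan
residualizes against the null design once (Frisch–Waugh), so the
10,000-permutation genome scan reduces to two matrix products per
permutation chunk. Thresholds are the (1−α) quantile of permuted
genome-wide maxima. Bayesian credible intervals normalize 10^LOD over
one linkage group and grow the interval greedily from the peak (larger
neighbor first, left on ties) until the target mass; variance
explained is 1 − 10^(−2·LOD/n). X-specific permutation counting and
genotype-error cleaning are out of scope; all linkage groups are
treated as autosomal.

## Morphometrics

Body size is the geometric mean of the p measurements; on the log
scale this is the isometric axis g = (1,…,1)/√p, so the size axis
defaults to g rather than a pooled PC1 — the two coincide exactly only
under isometry, and the geometric-mean definition pins the choice.
Each log row is projected off the axis and back-projected so adjusted
log size is exactly 0 (adjusted geometric mean 1, to 1e−12);
the operation is idempotent and preserves between-group shape
contrasts exactly. PC1 (pooled or per-group) is available by option.

## PWM scanning

Counts + 0.1 pseudocount per cell, normalized per column, log₂-odds
against a uniform background (both configurable; the upstream scanning
service's exact defaults are unpublished, so these are documented
choices, not asserted equivalents). Relative score rescales between
the matrix's attainable minimum and maximum, so a consensus word scores
exactly 1. Both strands are scanned, minus via reverse complement with
coordinates reported on the forward strand; windows containing N are
skipped; threshold comparison is inclusive (≥ 0.95). An optional width
filter restricts reports to 5–12 bp motifs. SNP intersection uses
half-open intervals: a SNP at a site's end coordinate does not hit.

## Problem sizes and numerical choices

The validation suite and the acceptance script use: 10,000 null
replicates at the study window configuration; 60 sweep and 200 neutral
loci for power/size; 50–60 BC1 replicates at 10,000 permutations each
(the scan grid is 1 cM); 500 replicates at n = 82 for
variance-explained recovery, read at the planted position to avoid
winner's-curse inflation; 250 null and 50 planted alignments for the
CNS caller. Monte-Carlo acceptance bands are ±3 SE for means and
+2 SE for rates. Floating-point output is written at 6 significant
digits; BED output is 0-based half-open.

## Known limitations

No demographic models (growth, bottlenecks, structure) in the null; no
folded-spectrum statistics; no phylogenetic weighting in the CNS
caller; no multiple-QTL or composite interval mapping; sample size
capped at 62 haplotypes by the bitmask representation; the sweep
generator produces the SFS footprint of a sweep, not linkage or
haplotype structure, so haplotype-based tests cannot be validated
against it.
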