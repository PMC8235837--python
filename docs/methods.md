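# Methods

## Model

`recpeel` estimates meiotic recombination from pedigree + SNP-array data
by multilocus iterative peeling. Loci are biallelic; an individual's
phased genotype at a locus is one of four ordered states
(paternal allele, maternal allele) ∈ {(a,a), (a,A), (A,a), (A,A)}.
Founders carry a uniform prior over the four states. For every individual
and locus the genotype distribution is the normalised product of three
factors:

**Penetrance.** Dosage calls (0/1/2, 9 = missing) are observed through a
symmetric error model with rate ε: states consistent with the call get
`1 − ε` and the inconsistent states share ε equally (ε/3 for a homozygous
call, ε/2 for a heterozygous one); a missing call is uninformative. ε is
a single tunable (`genotype_error`, default 0.01, probability per call).
Real array data motivates a nonzero default even though the validation
simulator emits error-free calls by default (below).

**Anterior.** Transmission from the parents. The two parent sides are
*factorised*: the paternal-allele distribution is computed from the
father's genotype distribution and the paternal segregation probabilities
alone, and likewise for the mother, rather than modelling the joint
distribution over both parents. This is the first of the two
simplifications that make the method scale; it trades some exactness
(the child's data can couple the two sides) for linear cost in pedigree
size.

**Posterior.** Evidence from offspring. Before a parent is peeled, each
offspring's genotype and segregation are *called*: taken as certain where
their probabilities reach `geno_call_threshold` (default 0.90) and
`seg_call_threshold` (default 0.99), and set to missing otherwise —
missing meaning all states or both haplotypes equally likely. A called
offspring then contributes, per locus, a simple factor over the parent's
states: `1 − ε` where the parent haplotype selected by the offspring's
called segregation carries the called transmitted allele, ε elsewhere;
offspring with either call missing contribute a flat factor. Calling is
the second simplification: it collapses offspring contributions to a
small set of patterns (amenable to lookup tables — here, a (5, 4) pattern
matrix driving vectorised counts) and damps feedback loops between
offspring with fractional segregation values. Thresholds are compared
with ≥, so a probability exactly at the threshold is called
(deterministic boundary behaviour).

### Segregation as a two-state chain

Per parent side, inheritance along a chromosome is a Markov chain over
which of the parent's two haplotypes is inherited, with transition
probability `r_j = ½(1 − exp(−2 d_j/100))` per marker interval (Haldane's
map function — memoryless, no crossover interference, matching the
chain's structure). Per-locus evidence is
`e_j(s) ∝ p(child data at j | parent transmits haplotype-s allele)`,
marginalising the parent's genotype distribution and the other parent's
transmitted-allele distribution; a homozygous or data-free parent yields
flat evidence. Exact forward–backward smoothing (per-locus rescaling, so
all outputs are invariant to evidence scale) gives segregation
probabilities γ, and the pairwise posterior over neighbouring loci gives
the expected crossovers per interval as the off-diagonal mass of
`ξ_j(a,b) ∝ α_j(a) T_ab(r_j) e_{j+1}(b) β_{j+1}(b)`. With flat evidence
these expectations reduce exactly to the prior `r_j`.

Two message-passing details sharpen the factors beyond the minimal
description:

* when a parent's distribution is used to peel a given child (anterior
  or segregation evidence), that child's own posterior factor is divided
  out first, the standard peeling discipline that avoids immediate
  self-feedback;
* the anterior at locus j uses *leave-one-out* segregation probabilities
  (forward prediction from j−1 times the backward message, excluding
  locus j's own evidence), so a locus's data is not counted both through
  the segregation chain and through the penetrance.

With these two choices the peeled child marginals in a parent–offspring
trio with one effectively homozygous parent agree with exhaustive
enumeration of the full joint model to numerical precision, which is how
the engine is unit-tested.

### Sweep schedule and convergence

Individuals are processed in generation order (topological depth) on the
downward pass — founders first, so every parent is updated before its
offspring in the same sweep — followed by calling and a rebuild of all
posterior factors. `n_outer_cycles` (default 5) such cycles run per map
iteration, with early stop when the largest absolute genotype-probability
change drops below `convergence_tol` (default 1e-4). In practice a small
subset (≲0.5%) of individual–locus entries enters a phase-relabelling
limit cycle under calling feedback, so the max-change criterion rarely
fires; aggregate quantities (crossover expectations, call fractions)
stabilise by cycle ~4, and doubling the cycle count changes the accuracy
metrics by <0.02. Non-convergence is reported as a warning and results
are returned. A locus whose anterior × penetrance × posterior product is
exactly zero (conflicting evidence, e.g. pedigree errors in real data)
falls back to the individual's own-data likelihood with a logged count
rather than aborting.

### Genetic-map iteration

The chain needs interval lengths; the data determine them. Estimation
starts from uniform 100-cM maps (≈1 expected crossover per chromosome)
for both sexes, and alternates peeling with a map update four times
(`n_map_iterations = 4`; chromosome-length estimates converge in about
four rounds and target-individual estimates are insensitive to the
assumed length). The update sets
`d_j = 100 × mean expected crossovers in interval j` over the
contributing gametes — maternal gametes update the female map, paternal
the male map. Two alternatives are exposed: `rule="inverse_haldane"`
(treat the mean as a recombination fraction and invert the map function —
the exact fixed point under uninformative data; at realistic interval
sizes the two rules differ by O(r) relative, ~1e-3) and
`mode="total_only"` (rescale the current relative spacing to the new
total, for users who want the length re-estimated but the shape held).
Gametes contribute to the update only if the individual passes QC; if no
gamete passes (e.g. nothing is genotyped) the prior map is returned
unchanged with a warning.

### QC filters and phenotypes

Estimates are kept for individuals whose two parents and four
grandparents are all present and genotyped (a relaxed mode requiring one
genotyped grandparent per side is a flag), and whose average rate across
their two gametes is ≤ 5 cM/Mb (strictly greater is removed). Rates use
the markers' physical span (last − first position per chromosome) as the
Mb denominator, so cM/Mb refers to the covered span, not an assembly
length. Each retained offspring then yields one maternal and one paternal
phenotype record attributed to its dam and sire, the repeated-records
layout used for downstream variance-component work.

## Validation simulator

The generator emulates the estimator's target regime, not any particular
genome:

* **Pedigree** — discrete generations (default 5 × 600 = 3000
  individuals), each generation bred from 30 sires and 300 dams drawn
  from the previous one: few sires with many offspring, many dams with
  few, as in commercial breeding.
* **Founder haplotypes** — a seeded Markov linkage-disequilibrium model:
  per-locus allele frequencies uniform on (0.1, 0.9); each allele copies
  its left neighbour with probability `ld_decay` (default 0.8), else
  draws from the locus frequency. This produces monotone LD decay with
  distance. It is deliberately simple — a coalescent founder model would
  add realism the pedigree-driven estimator does not use; accuracy here
  rests on pedigree information, not fine haplotype structure.
* **Landscape** — 1522 SNPs evenly spaced over 100 Mb; interval rates
  constant over the middle 30–70% of the map and rising on each end as a
  second-degree polynomial in relative position (zero slope at the
  junction, so value-and-slope continuous), reaching `end_elevation`
  (default 3) × the mid rate at the terminal interval, then rescaled to
  the target total. Male total 85 cM (≈0.85 cM/Mb, a realistic male pig
  autosome average); female = 1.3 × male.
* **Meiosis** — gametes start on a random parental haplotype and switch
  in interval j with probability `r_j`, independently across intervals
  (no interference, consistent with the estimator's chain). Every
  switch is recorded per interval as truth.
* **Genotyping** — individuals are assigned panels at fractions
  0.39 high / 0.51 low / 0.10 ungenotyped; the low panel observes an
  evenly spaced 25% of loci (≈ the 15K/60K chip-density ratio); observed
  calls flip to a random wrong dosage with probability `genotype_error`.
  The default is 0: the validation design generates clean array calls,
  and the estimator's ε then only encodes its robustness assumption.
  Sensitivity: at 1% call errors the estimated map length inflates by
  roughly a further 10–15 percentage points, which is worth knowing
  before applying the method to noisy real data.

Everything is driven by one integer seed; identical seeds give
byte-identical outputs.

What passing against this generator does **not** show: robustness to
pedigree errors, to non-random panel assignment (real programmes genotype
selectively), to hotspot-scale rate variation (pedigree methods cannot
resolve few-kb features), or to coalescent LD structure. The X chromosome
and crossover interference are out of scope throughout.

## Accuracy at the validation scale

At the default study size (~3000 individuals, 1522 SNPs, one seed) the
estimator reaches dam-gamete accuracy (Pearson r between true and
estimated per-gamete crossover counts) around 0.77 and sire-gamete
accuracy around 0.9; the per-interval landscape correlates ~0.5 raw and
~0.98 after 50-SNP smoothing, and total lengths are overestimated by
~3–15% — the method's characteristic bias. Two scale effects deserve
note: per-interval truth at a few thousand meioses is Poisson-noise
dominated (middle intervals expect ~1 crossover in the whole dataset), so
the raw landscape correlation is substantially noise-limited; and
per-gamete sire accuracy is governed by the male map's between-gamete
variance together with the (well-phased) sire haplotypes, so it sits
*above* dam accuracy at this scale — reproducing a markedly lower sire
figure requires sire families orders of magnitude larger, where
per-parent means lose between-sire variance. `scripts/acceptance.py`
recomputes all four figures from scratch at this problem size.

## Numerical and design choices

* All probability vectors are renormalised per locus; offspring posterior
  products accumulate in log space (a sire with hundreds of offspring
  would underflow otherwise).
* Ordered-state and code lookups are integer tables; the whole engine is
  vectorised across a generation of gametes, with the only per-locus
  Python loop inside forward–backward.
* Ties in calling resolve to the lowest state index via argmax —
  deterministic, and immaterial once a threshold > 0.5 is used.
* Pearson correlation is used for all landscape/accuracy comparisons;
  smoothing defaults to non-overlapping 50-SNP block means, with a
  centred rolling variant for plotting-style series.
* Map-length comparisons between groups use an additive OLS with line and
  chromosome fixed effects; per-line totals are sums of fitted cell means
  with normal-theory 95% CIs. Counts are treated as Morgan directly
  (1 expected crossover = 1 M).
* The truncation-selection helper takes the top ⌈n·p⌉ values after a
  stable descending sort; the breeders'-equation and QTL-fixation
  calculators are plain arithmetic on user-supplied summary statistics.
* Genotype file dialect: single-file dosage rows (id + codes per mapped
  locus), chosen over PLINK .ped as the primary format because mixed
  densities reduce cleanly to dosage-with-missingness; a .ped/.map import
  shim normalises into it (dosage = count of the alphabetically larger
  observed allele). Positions are 1-based bp; intervals and windows are
  half-open.

## Known limitations

* The factorised parent sides and called posteriors are approximations;
  marginals are exact only in the regimes the oracle tests pin down, and
  a small fraction of entries can oscillate between cycles.
* Genetic length is systematically overestimated, increasingly so with
  genotyping error and sparse panels.
* Segregation, and therefore crossover placement, has marker-interval
  resolution at best, and much coarser where panels are sparse; hotspot
  detection is out of reach by construction.
* Single chromosome per run; multi-chromosome inputs are split and run
  independently (no cross-chromosome information exists in the model).
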