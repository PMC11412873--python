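# Methods

## Orthogroup shift statistic

Gene-family counts across species are heavily skewed: most orthogroups have
0–few members per species, a minority are large. To compare a focal
lifestyle group against the background on a common scale, each orthogroup's
counts are converted to standard normal deviates using robust location and
scale estimates: the 50% trimmed mean and the sample standard deviation of
the trimmed set. "50% trimmed" is read as the midmean — `k = floor(0.25·n)`
values removed from **each** tail, half the data removed in total. The
alternative reading (50% per tail, which collapses to the median and leaves
no scale estimate) is exposed through `trim_fraction_per_tail` but is not
the default. The trimmed SD is the sample SD (denominator `n_kept − 1`) of
the kept values. Orthogroups whose trimmed SD is zero carry no usable scale
information; by default their scores are set to zero (keeping the matrix
shape stable for clustering and correlation), with a `drop` policy
available.

The per-orthogroup shift statistic is a Welch-type t on the normalized
scores: `t = (c̄_p − c̄_n)/√(s_p²/n_p + s_n²/n_n)` with plain group means and
sample SDs (no trimming at this step). A literal variant without the `/n`
terms is provided as `t_formula="paper_literal"`; with fixed group sizes the
two orderings are very close but not identical, and the default is the
standard Welch denominator, cross-checked in tests against
`scipy.stats.ttest_ind(equal_var=False)`. When both group SDs vanish, t is
0 for equal means and ±∞ otherwise (ranked extreme). Top-expanded and
top-contracted lists are the descending/ascending-t prefixes with
lexicographic tie-breaks; the contracted candidates exclude already-selected
expanded ids so the lists are always disjoint.

Per-species shift counts use a strict |score| > 0.75 rule. This is a
per-species reading of the group-level threshold: a species' normalized
score beyond ±0.75 marks the orthogroup as expanded/contracted *in that
species*; scores exactly at the threshold count in neither direction.

Species relationships use Pearson correlation between species score
vectors, Ward-linkage clustering on distance `d = 1 − r` (not `1 − |r|`;
anti-correlated species are maximally distant), and PCA of the correlation
matrix (species as samples). Component signs are fixed by making each
component's largest-magnitude loading positive. A constant correlation
matrix has no variance after centering; its explained fractions are
reported as 0.

### Null behavior

Under no planted effect, the t scores of a skewed count distribution with
unequal group sizes are *not* mean-zero: negative-binomial counts are
right-skewed, and when the small focal group happens to catch the upper
tail its own SD inflates and damps t, while missing the tail produces a
modest negative t with a small focal SD. The empirical mean of t in the
11-vs-41 design is ≈ −0.13; with equal group sizes the label-swap symmetry
restores a mean of ≈ 0. Tests assert both behaviors. Rankings (the object
of interest) are unaffected by a common shift.

## Synthetic count matrices

Counts are i.i.d. negative binomial with mean μ and dispersion θ
(variance `μ + μ²/θ`), the standard overdispersed model for gene-family
counts; the defaults (2000 orthogroups, 11 focal vs 41 background species,
μ = 3, θ = 2, 50 expansions and 50 contractions at multiplier 4) mirror a
52-genome comparative design with a sizeable minority lifestyle group.
Planted expansions multiply the focal-group mean before sampling;
contractions divide it. Measured recovery of the planted ids by the top-50
lists under these conditions is ~85% (expansions) and ~80% (contractions),
median over 20 seeds: contraction signal is compressed by the count floor
at zero (focal mean 0.75 yields mostly 0/1 counts), and with exactly 50
planted ids competing for 50 ranked slots, any null orthogroup in the
extreme tail displaces a planted one. These ceilings are properties of the
design, not of the estimator; the statistic is exact against its oracle.

## Composition

GC is `(G+C)/(A+C+G+T)` with ambiguity codes (including N) excluded from
numerator **and** denominator — including gaps in the denominator would
bias gap-rich assemblies downward. GC3 is pooled over all codons of all CDS
(per-gene averaging available behind a flag); stop codons are not excluded;
trailing partial codons are trimmed with a warning rather than rejecting
the record. Group comparisons are per-variable one-way ANOVA followed by
Tukey HSD (scipy); degenerate inputs (zero within-group variance) map to
F = 0/p = 1 for equal means and F = ∞/p = 0 otherwise. Group summaries
weight species equally, not by genome size.

## RIP scanning

Windows are 1000 bp stepped by 500 bp (full windows only; contigs shorter
than one window are analyzed as a single whole-contig window flagged
`short` rather than skipped). The six dinucleotides are counted on the
forward strand over overlapping positions, skipping pairs containing
ambiguity codes. The product index TpA/ApT is strand-symmetric (TA and AT
are reverse-complement palindromes), and the substrate index's numerator
pair (CpA, TpG) and denominator pair (ApC, GpT) are mutual reverse
complements, so the configured indices are strand-invariant — verified by a
test. Zero-denominator windows report the affected index as 0 and are
declared RIP-negative (a conservative convention). All three thresholds
(product > 1.15, substrate < 0.75, composite > 0) and the 4000-bp LRAR
length bound are strict inequalities. RIP-affected bases are the union of
positive windows, so 50%-overlapping windows are never double-counted, and
the genome-wide RIP percentage can never exceed 100.

On random GC-0.5 genomes the scanner is nearly silent (median 0 positive
windows per 100-kb genome), but with ~200 windows per genome the joint
threshold test occasionally fires by binomial fluctuation (~14% of such
genomes contain at least one positive window); the detected RIP percentage
on planted fixtures runs slightly above the planted fraction because
windows straddling region edges qualify.

## K-mer ploidy diagnostics

K-mers are canonicalized as the lexicographic minimum of the k-mer and its
reverse complement (odd k only, so no k-mer is its own reverse complement);
windows containing ambiguity codes are skipped. Counting is vectorized by
packing bases 2 bits each into int64 for k ≤ 31 (the common case, including
the k = 31 default); larger odd k up to 63 falls back to a string-based
path with identical semantics.

The diploid simulator works at the k-mer level: haplotype B is haplotype A
with i.i.d. substitutions at the stated per-base heterozygosity, canonical
k-mers are counted over both haplotypes, and each distinct k-mer of
multiplicity m draws an observed depth from Poisson(m·coverage/2). There is
no read simulation, no sequencing-error model and no repeat structure
beyond chance k-mer collisions, so passing tests demonstrate correct
spectrum arithmetic and peak logic — not robustness to real sequencing
noise, error k-mer swarms at depth 1–3, or repeat-rich genomes.

Peak detection smooths the spectrum with a moving average (halfwidth 2),
truncates the low-depth noise region below the first valley preceding the
global mode (nothing is truncated when the curve rises monotonically),
keeps strict local maxima that reach ≥ 2% of the tallest peak's smoothed
height (suppressing sampling-noise bumps in the sparse Poisson tail), and
merges peaks closer than 25% of their mean depth keeping the taller. A
spectrum is bimodal when the two tallest peaks have a depth ratio in
[1.6, 2.4] — the haploid peak near half the diploid depth — in which case
histogram bins are attributed to the nearest peak and the heterozygous
fraction f (half-depth mass over total attributed mass) is inverted through
the spanning model `h = 1 − (1 − f/2)^(1/k)`: a k-mer avoids all
heterozygous sites with probability `(1−h)^k`, and each heterozygous site
produces two allele k-mer sets, one per haplotype, hence the factor-2
correction. This is a deliberately simple GenomeScope-like surrogate
validated only against the package's own simulator; at 1% planted
heterozygosity it recovers ≈ 0.9% (the nearest-peak bin attribution mixes
a little mass between components).

## Problem sizes and determinism

All generators are pure functions of their arguments and a seed; multi-stage
runs derive stage seeds from one root seed as `seed + 1000003·stage`
(mod 2³¹). Default simulation sizes — 2000-orthogroup matrices, 200-kb
genomes, 50-seed/20-seed medians — keep the full test suite and the
reproduction script in the tens of seconds on one CPU while leaving
standard errors well inside the asserted tolerances.

## Known limitations

- The RIP scanner's conventions for zero denominators, terminal partial
  windows and base attribution are explicit choices; other scanners may
  differ on real genomes.
- The heterozygosity estimator is not a mixture-model fit; it degrades when
  peaks overlap (high h, low coverage) and makes no genome-size estimate.
- The orthogroup statistic ranks; it does not test. No p-values or
  multiple-testing correction are produced.
- Synthetic genomes are i.i.d. base sequences: no isochores, no repeat
  families, no codon structure beyond the GC3 dial.
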