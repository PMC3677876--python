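# Methods

`ovinescan` reimplements, as a tested library and CLI, the analysis
workflow of a five-breed sheep SNP-array study (Suffolk, Rambouillet,
Columbia, Polypay, Targhee; 94 rams on a ~54K chip): sequential
genotype QC, per-breed diversity, Wright/Weir–Cockerham F-statistics,
LD decay, allele-sharing trees and MDS, a per-SNP drift-model F_ST
scan, and calling of differentially selected regions (DSRs).  The raw
genotypes of the original panel are not publicly deposited, so the
package validates every stage on a synthetic genotype generator whose
defaults reproduce the study's design (breed sizes 19/19/16/18/22,
all-male panels, 26 autosomes + X, the chip's QC defect-class counts).

## Genotype model and simulator

Breed allele frequencies follow the Balding–Nichols model: a locus
with ancestral frequency `pi` and per-population drift parameter
`c ∈ (0,1)` has population frequencies

    p_j ~ Beta( pi (1-c)/c , (1-pi)(1-c)/c ),

so `E p_j = pi` and `Var p_j = c pi (1-pi)`; `c` plays the role of the
population's F_ST against the ancestral pool.  Genotypes are
`binomial(2, p_j)` on autosomes and hemizygous `binomial(1, p_j)` for
males on X (coded 0/2).  Ancestral frequencies are uniform on
[0.05, 0.5] by default (chip SNPs are ascertained toward common
variants) with a random strand flip.  The number of generations
behind each breed is never modelled; `c` is purely the variance
parameter.

Optional LD uses a persistent-uniform copying chain: each haplotype
carries a latent uniform refreshed between adjacent markers with
probability `1 - exp(-d/λ)`.  Marginal frequencies are preserved
exactly; the allelic correlation at distance `d` is exactly
`exp(-d/λ)` when the two markers share a frequency and approximately
exponential otherwise.  The simulator does not model coalescent
ancestry, mutation, pedigree structure or selection dynamics, so
passing tests demonstrate correctness of the estimators under the
drift model, not realism of any particular sheep genome.

The QC fixture builder plants exact counts of defective marker
classes — all-missing, call rate just below threshold, monomorphic,
unmapped, minor-allele frequency ≤ 0.05, Hardy–Weinberg failures
(one breed entirely heterozygous), and X markers with heterozygous
male calls — each constructed to fail at, and only at, its intended
stage of the sequential chain.  Clean markers get per-breed genotype
counts at the rounded Hardy–Weinberg expectation of a frequency in
(0.15, 0.45), which passes every filter deterministically.  The
planted counts are therefore recovered exactly as the chain's
per-stage exclusions, by construction.

## Sequential QC

Stages, in order, each marker attributed to the first stage that
removes it: (1) no calls; (2) call rate < 0.95; (3) a single observed
allele pooled over breeds; (4) no map position; (5) pooled MAF ≤ 0.05
(inclusive); (6) exact Hardy–Weinberg test per breed on autosomes,
removed when P < 0.01 in at least one breed; (7) X markers with any
heterozygous male call.  X is never HWE-tested (males carry one
copy).  "Monomorphic" is read as one allele observed overall rather
than literally monomorphic within every breed: the literal reading
would also discard fixed differences between breeds, which are the
strongest possible selection signals.  The HWE combination rule
("failing in ≥ 1 breed") is one of several defensible choices; it is
a parameter of `run_qc` in effect, and the exact test itself uses the
standard conditional (Levene/Haldane) distribution with no mid-p
correction, evaluated by a numerically stable ratio recurrence and
verified against a log-factorial enumeration oracle for every
configuration with n ≤ 50.

## Diversity and F-statistics

Per-marker gene diversity `2pq`, PIC `2pq - 2p²q²`, and observed
heterozygosity are averaged over the post-QC autosomal marker set,
weighting markers equally and without re-filtering per breed.  MAF
spectra use left-open bins partitioning (0, 0.5] (edges configurable;
the default adds a (0, 0.05] bin so the bins cover the whole range)
and are compared across breeds by Pearson chi-squared without
continuity correction.

F-statistics use Weir–Cockerham (1984) variance components `a`
(among breeds), `b` (among individuals within breeds), `c` (within
individuals), summed over markers (ratio of sums):
`F_ST = Σa/Σ(a+b+c)`, `F_IT = Σ(a+b)/Σ(a+b+c)`, `F_IS = Σb/Σ(b+c)`.
This matches FSTAT conventions, may go slightly negative in
undifferentiated data, and on Balding–Nichols simulations is an
unbiased estimator of `c` (checked at c ∈ {0.05, 0.0681, 0.1621,
0.3} with the study's sample sizes; at full scale — 46,850 markers,
10 replicates — the replicate mean lands within fractions of a
standard error of `c`).  The implementation is validated per marker
against an independent nested-ANOVA oracle computed from raw allele
indicators.  Pairwise significance uses a label-permutation test,
`p = (1 + #{θ* ≥ θ}) / (n_perm + 1)`.  X markers are excluded from
diversity and F-statistics (the study computes these on the autosomal
set).

## LD

r² between two loci comes from EM haplotype-frequency estimation over
the phase ambiguity of double heterozygotes (tolerance 1e-8 on the
log-likelihood, ≤ 1000 iterations).  Because tables that are exactly
symmetric in their unambiguous haplotype counts make the linkage-
equilibrium point a stationary saddle of the likelihood, the EM runs
from three deterministic starts (equilibrium and near each end of the
feasible D range) and keeps the best; mirror-image ties resolve
toward D ≥ 0 (r² is unaffected by the sign of D).  Results match a
brute-force likelihood grid (step 1e-4) on random small tables.  The
decay curve averages r² in distance bins (defaults: 1 Mb cap, 10 kb
bins; the original figures do not print their windows).

## Trees and MDS

Allele-sharing distance: mean over co-called markers of
`1 − shared alleles/2`, with pairwise deletion of missing data; this
equals the identity-by-state distance for complete data.  The NJ
implementation (Saitou–Nei with the Studier–Keppler criterion)
recovers additive matrices exactly, joins the lowest-index pair on Q
ties, and clamps negative branch lengths to zero with the deficit
moved to the sibling edge; it is cross-checked against an independent
NJ implementation by Robinson–Foulds distance.  Classical MDS
double-centers `-D²/2` and eigendecomposes; axis signs are fixed so
the largest-magnitude loading is positive.

## Per-SNP F_ST scan

The SNP-specific statistic is the drift-model moment form

    F_ST = (1/J) Σ_j (p_j − π)² / (π(1−π)),   π = (1/J) Σ_j p_j ,

with plug-in sample frequencies and no finite-sample correction
(which is what makes a fixed difference score exactly 1.00, the
anchor value of the scan).  The unweighted mean treats populations
symmetrically.  Two properties matter for interpretation: sampling
noise inflates the statistic, with the inflation shrinking as sample
size grows; and because deviations are measured from the unweighted
mean, the large-n expectation is `(1 − 1/J)·c`, not `c` — for two
populations at drift 0.1 the mean statistic tends to 0.05.  Neither
affects region calling, which only consumes ranks.  The full Bayesian
machinery of the underlying drift model is deliberately out of scope;
the moment form is the scan statistic, with per-SNP Weir–Cockerham
available through the same variance-component code as an alternative.
X frequencies come from male hemizygous counts (one allele per male).

A per-marker two-sided Fisher exact test on the 2×2 allele-count
table (Bonferroni-corrected at 0.05/m) is reported side by side with
the ranking rather than gating it; the original description leaves
the wiring ambiguous, and side-by-side reporting preserves both
signals.  Smoothing is Nadaraya–Watson with a Gaussian kernel whose
local bandwidth is the distance to the k-th nearest marker (default
k = 20, replacing a data-driven plug-in bandwidth whose tuning
constants are not printed); it never crosses chromosome boundaries
and exists for reporting only — region calling always uses raw
ranked values.

## DSR calling

One joint ranking covers all chromosomes in a track (autosomes and X
together; the tie-inclusive quantile thresholds mean several markers
can share the top-0.1% cutoff).  Thresholds are empirical quantile
values: top-q = the ceil(q·m)-th largest value, all ties included.
Each top-0.1% marker seeds a region in descending F_ST order (seeds
inside an already-called region are skipped); the scan extends
outward independently in each direction and stops at the fourth
consecutive marker outside the top 5% ("more than three consecutive"
read literally; the constant is configurable).  Boundaries are the
outermost included top-5% marker positions, not midpoints.  Regions
longer than 3 Mb are truncated to peak ± 1.5 Mb before overlapping
regions are merged (the union keeps the higher peak; counts are
recomputed).  Gene annotation takes BED (0-based half-open,
converted) or GFF3 (1-based closed) intervals and reports ≥ 1 bp
overlaps on closed coordinates.

Recovery behaviour is measured, not assumed: in two-population scans
with background drift 0.15 and five planted 20-marker spans at drift
0.7 among 10,000 markers, on average at least 4 of 5 spans are hit
with at most 2 false calls per replicate (10 replicates).  A planted
span can be missed when none of its markers reaches the global
top 0.1% — with 100 elevated markers competing for ~10 seed slots
this happens to roughly one span in ten — so per-replicate recovery
of 4/5 is the expected operating point, not a deficiency of the
caller.

## Numerical and scale choices

Problem sizes in the test suite are chosen so the whole suite runs in
about a minute: unit tests use 800–4,000 markers, drift-recovery and
ledger checks use the full 46,850/54,241-marker layouts.  All
randomness flows through explicit integer seeds (one generator stream
per dataset); identical config + seed gives byte-identical PED/MAP
and region files.  Known limitations: no sample-level QC (the study
removed no animals), no haplotype-based selection statistics, no
gene-ontology enrichment, and the simulator's independence between
breeds means admixture or shared post-divergence history is not
represented.
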