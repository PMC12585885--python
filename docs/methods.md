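# Methods

This note documents the models behind `svkaryo`, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a user re-deriving results should
know about.

## The synthetic genome

The generator produces the statistical structure the downstream
analyses assume, with closed-form expectations instead of coalescent
machinery.

**Collinear background.** Each site draws an ancestral allele frequency
`p ~ Uniform(0.05, 0.95)`. Each of three parental lineages — coastal
(C), southern (S), marine (M) — drifts independently under the
Balding–Nichols model: the lineage frequency is Beta-distributed with
mean `p` and variance `F_k p (1 - p)`. With independent drift from a
shared ancestor, the expected Hudson F_ST between lineages a and b is
`(F_a + F_b) / 2` (the unbiased within-population heterozygosity
estimator makes this exact in expectation), so three pairwise F_ST
targets determine the three drift parameters by a linear solve;
`calibrate_drift` raises when the solution leaves (0, 1). The default
targets (C–M 0.013, C–S 0.075, S–M 0.066) give
`F_C = 0.022, F_S = 0.128, F_M = 0.004`.

**Admixture.** Each individual carries an ancestry vector `q`. Parental
individuals are unadmixed (`q` at a vertex); admixed groups draw `q`
from a Dirichlet around their group mean (concentration 30, i.e. about
±0.09 spread per component), and groups sit along a one-dimensional
"latitude" so southern ancestry increases monotonically along it. A
collinear genotype is `Binomial(2, q . p_site)`.

**SV blocks.** Inside a block every site is determined by the two
haplotype labels an individual draws, with no recombination. Site
classes: fixed differences between the `0` and `1` haplogroups at
per-bp density `hap_divergence` (default ~0.0018, so homokaryote d_XY
lands in the 0.15–0.20% range); for three-haplotype SVs, additional
fixed differences between haplotypes 1 and 2 at 40% of that density
(the secondary split is shallower than the primary one); per-haplotype
polymorphic sites at 10% of the density (short within-clade branches,
long between-clade branches in trees); all remaining block sites
monomorphic. Heterokaryotes are heterozygous at every primary fixed
difference, which produces the elevated heterozygosity that the
karyotype caller exploits, and fixed-difference sites are in complete
LD (r² = 1) by construction. Copies are drawn from the individual's
ancestry-weighted karyotype frequencies `sum_k q_ik f0_k`; parental
groups realise their configured frequencies exactly (balanced copy
assignment with random pairing, which preserves Hardy–Weinberg genotype
proportions within a group while removing chromosome-level frequency
noise between same-profile SVs).

**The study-shaped default** (`default_study_config`): 24 chromosomes
of 500 kb at ~2000 sites each (density 0.004/bp so a 5 kb window holds
~20 sites against the 15-site usability floor), 185 samples (40 per
parental lineage, 45 two-way admixed, 20 three-way), and 13 SVs of
150 kb on 13 distinct chromosomes in four frequency profiles: three
with the southern haplotype fixed in both S and C (the
shared-with-coastal pattern), seven north-vs-south (S fixed `00`,
northern lineages near-fixed `11`), two with a third haplotype
splitting the `1` haplogroup between coastal and marine backgrounds,
and one polymorphic in both northern lineages. These sizes keep a full
end-to-end run around 15 s on one CPU while leaving every per-window
statistic adequately powered.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: recombination within SVs (gene
conversion, double crossovers), linkage disequilibrium decay in the
collinear background (collinear sites are exchangeable), sequencing
error and missingness patterns, within-lineage spatial substructure,
and variable SNP ascertainment between datasets. The polymorphic-north
SV profile is, by design, invisible to quantile-based flagging (its
window F_ST ~0.33 sits far below the ~0.9 of the other profiles), so
the expected recovery on the default genome is 12 of 13 chromosomes —
a deliberate reminder that the 95th-percentile rule only finds SVs
whose differentiation reaches the genome-wide tail.

## Windowed statistics

All statistics are pairwise-complete over non-missing calls; nothing is
imputed. Windows are 0-based half-open 5 kb tiles; per-bp quantities
divide by the window span. pi per site is `2p(1-p) * n/(n-1)` with `n`
the non-missing allele count; d_XY per site is
`pA(1-pB) + pB(1-pA)`. Hudson F_ST is a ratio of averages
(`1 - mean(hw)/mean(hb)`) with the unbiased within-heterozygosity —
note this makes literally duplicated samples come out at
`-1/(n_alleles - 1)`, not 0; Weir–Cockerham is the 1984 two-population
variance-component estimator, ratio of sums, with negative values kept
in tables. Hudson is the landscape default (robust in small windows).
Quantile flags use genome-wide linear-interpolation quantiles over
usable windows with strict `>` at the 95%/99% thresholds, and a
chromosome is flagged when strictly more than 2.5% of its usable
windows carry the 95% flag (the comparator is configurable; the
"usable windows only" denominator is a declared choice). LD is reported
as per-pair genotype r² and as mean r² in 50-SNP windows.

## Admixture EM

The binomial admixture likelihood is maximized by multiplicative EM
updates. `n_init` short runs (20 iterations; the first seeded from
k-means on PCA scores, the rest random) are scored and the best refined
with SQUAREM extrapolation under a monotonicity safeguard: an
accelerated step is kept only when its log-likelihood is at least that
of the plain double EM step, so the recorded likelihood path is
non-decreasing by construction (plain EM needs thousands of iterations
when two ancestries are weakly differentiated). Convergence is
`|delta loglik| < 1e-3`; cluster labels are aligned to reference groups
by greedy matching of group-mean ancestry.

A capacity note: with coastal–marine background F_ST at 0.013, 5000
collinear sites carry Fisher information of only ~130 for the C–M
contrast per individual (sd ~0.09), and the maximum-likelihood fit
itself sits at a mean absolute ancestry error near 0.06. The SV blocks
carry most of the coastal–marine signal; ancestry estimation in the
pipeline therefore runs on a genome-wide site subsample that includes
them, where the mean error drops below 0.05. This mirrors the empirical
setting, where the ancestry analysis also runs on a marker set that
includes SV regions.

## Ternary classification

Thresholds follow the published wording exactly: parental requires one
ancestry strictly above 0.80; a two-way class requires the smallest
ancestry at or below 0.10; otherwise MCS. Both constants are exposed.
Ties for the smallest component keep the higher-priority ancestry
(C > S > M) in the class name and are logged. The rule is total; only
invalid vectors (not summing to 1, or NaN) return `unclassified`.

## Karyotype calling

Axis selection scans the top four PCA axes of the chromosome. For each
axis a 1-D Gaussian mixture is fitted (k-means initialised, 5 restarts,
fixed random state) and its mean-ordered components are merged into
three contiguous groups. k = 3 is tried first; only when no split of
the 3-component fit qualifies is k escalated to 4 then 5 — this
absorbs sub-structure inside a homokaryote cluster (a secondary
haplotype split can make the `1` haplogroup bimodal on PC1). A
partition qualifies when it beats the single Gaussian on BIC, adjacent
group boundaries are separated by at least 3 pooled standard
deviations, both outer groups hold at least 2 samples, and the middle
group's heterozygosity is significantly higher than both outer groups'
(one-sided Welch tests at p < 0.01 — a bare mean comparison passes by
chance when a mixture slices a homogeneous cluster). The lowest-index
qualifying axis wins, matching the observation that karyotype structure
usually sits on PC1 unless a stronger unrelated signal displaces it.

Calls are maximum-posterior over the merged groups, left unassigned
when the posterior is at or below 0.90 **or** the score lies more than
4 component standard deviations from every component of its group
(posteriors normalise even among vanishing densities, so a midway
sample needs the distance guard to stay ungenotyped, as such samples
were left ungenotyped in the motivating study). Polarization assigns
`00` to the homokaryote cluster containing more southern-class samples
(class membership counts, not raw ancestry sums); zero or tied evidence
leaves labels arbitrary-but-stable and flagged. Blocks are maximal runs
of windows carrying the 95% flag or local-PCA SV-cluster membership,
tolerating up to 2 unflagged windows. The local-PCA field uses
Frobenius distances between rank-2 normalised window covariance
approximations (computed from eigenpairs, never materialising n×n
differences), classical MDS, and a 2-means split accepted only with
silhouette > 0.5, a minority fraction below 45% and at least 3 windows.
The third-haplotype scan reruns PCA and the partition machinery inside
the `11` homokaryotes.

## XP-EHH on unphased genotypes

No phasing: individuals are grouped by identity of their multilocus
genotype vector extending from the core, EHH(d) =
`sum_g n_g(n_g-1) / (n(n-1))`, which is 1 at distance zero and
non-increasing (missing genotypes form their own identity symbol, which
preserves monotonicity). Curves truncate at the chromosome end, at an
inter-site gap above 200 kb, or one point after crossing the 0.05 EHH
cutoff; iHH integrates by trapezoid to the linearly interpolated
crossing, both directions summed. The score is `log(iHH_A) -
log(iHH_B)` (a log difference, so swapping populations negates it
bitwise), z-standardized in a single genome-wide bin — the unphased
statistic lacks the derived-allele frequency conditioning that
motivates bins in the phased convention. Each population's curve is
truncated independently. Cutoff, gap and standardization are all
configurable since the upstream tooling's behaviour varies by version.

## Distances and trees

The allele-sharing distance is the mean over pairwise-complete sites of
`|dosage_i - dosage_j| / 2`; on homozygote-only subsets of biallelic
SNPs this equals alignment-based per-site differences, and a
heterozygote contributes half a difference per differing allele (a
declared convention; the triangle inequality is not guaranteed and not
asserted). NJ is Saitou–Nei with the standard Q criterion, ties
resolved to the lowest index pair, and negative pendant lengths zeroed
with the deficit moved to the sister branch so path lengths are
conserved; on additive matrices topology and branch lengths are exact.
Trees are dendropy objects; rooting is at the midpoint of the single
edge whose bipartition separates the two karyotype groups (an error
naming the minimal conflicting tips otherwise) or at the midpoint of a
named tip's branch. Branch summaries report the stem between group
MRCAs, mean MRCA-to-tip depths, and the ratio of mean between-group to
mean within-group tip-pair patristic distance — near 1 for
well-recombining regions, above 5 for SV regions at the default
divergence.

## Pipeline

One YAML config with flat per-stage namespaces; every published
constant (5 kb windows, 15-site floor, MAF 0.05, K = 3, 95%/99%
quantiles, 2.5% chromosome rule, 0.90 posterior, 0.05 EHH cutoff) is a
named default. Each stage derives its seed from the master seed plus
the stage name (CRC32), so toggling a stage never perturbs another
stage's draws and identical config + seed reproduces identical output
digests. Stage failures abort with a partial JSON report on disk.

## Known limitations

Karyotype calling assumes three clusters along one axis; SVs
polymorphic for more than three common haplotypes, or chromosomes
carrying two unlinked SVs, would need the local-PCA field to separate
blocks first. The quantile flagging cannot find SVs whose
differentiation stays below the genome-wide tail (by design, one
default SV demonstrates this). The EM estimator inherits the
identifiability limits of the admixture likelihood for weakly drifted
ancestries. The simulator's exchangeable collinear sites make
background LD unrealistically low, so XP-EHH background decay is faster
than in real genomes and absolute iHH values are not comparable to
empirical ones — only contrasts within a run are meaningful.
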