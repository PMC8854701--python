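# Methods

This note documents the models implemented in `glandevo`, their
assumptions, the defaults that matter, and what the synthetic-data tests
do and do not establish about real data.

## Somatic-call model and filtering

A `MutationRecord` is one somatic call in one gland with read support in
the gland and in matched blood. Coordinates are 1-based (VCF convention);
trinucleotide contexts are stored on the reference strand and folded onto
the pyrimidine strand only when a spectrum is built. Whole-genome calls
must pass, in a fixed order used for rejection attribution: caller
quality (a boolean pass flag plus the analytic threshold
−10·log₁₀(0.05) = 13.0103), population frequency < 0.001, depth ≥ 20,
≥ 8 mutant reads, MAF ≥ 0.25, blood MAF ≤ 0.05. Targeted-panel mode
applies only the quality and population-frequency criteria, because the
panel caller applies its own read-level model upstream. Filtering is
idempotent and the rejection tally partitions the input; records with
zero depth are set aside as "no coverage". A gland enters the analysis
only if strictly more than 70% of its target bases are covered by ≥ 20
reads.

MAF classification is trimodal: subclonal (< 0.25), clonal ([0.25,
0.75)), and clonal with allelic imbalance (≥ 0.75), the last reflecting
loss or amplification of the wild-type allele and testable per site with
an exact two-sided binomial test against 0.5.

**CNMC.** The cumulative number of menstrual cycles is an explicit,
configurable assumption: `cycles_per_year × (age − menarche) −
cycles_lost_per_parity × parity`, floored at 0, with defaults 13
cycles/year (28-day cycle) and 15 cycles suppressed per pregnancy
(gestation plus typical postpartum amenorrhea). Equality of age and
menarche is allowed and yields 0.

## Burden and association

Burden pools each subject's glands — counts over callable bases, not a
mean of per-gland rates — so it is invariant to how mutations distribute
among glands. Only high-MAF SNVs (default MAF ≥ 0.25) count; indels are
excluded. "Adjusted for age" is implemented as a residual–residual
(partial) Pearson correlation, tested on n − 3 degrees of freedom; the
age-adjusted regression coefficient is also returned, since published
adjusted associations are ambiguous between the two. The Wilcoxon
rank-sum helper is exact for group sizes ≤ 50 without ties and uses the
tie-corrected normal approximation otherwise; a fully tied input returns
p = 1 by convention.

## Signature refitting

The 96-class spectrum is modelled as multinomial over a convex mixture of
fixed signature columns. The point estimate is the constrained MLE found
by EM-style multiplicative updates on the simplex (tolerance 1e-8 on the
log-likelihood, cap 10,000 iterations; each update is monotone).
Uncertainty comes from a multinomial bootstrap of the spectrum
(default 1,000 replicates) with percentile intervals at the 90% level; a
signature is "significantly active" when its lower bound exceeds 0.01.
This is a deliberate frequentist substitute for Bayesian refitting with
HPD intervals: the point estimates agree in practice and the same
activity rule applies, but the intervals are bootstrap percentiles, not
posterior HPDs. De novo extraction is out of scope — small cohorts
cannot support it.

## Selection: trinucleotide-context Poisson dN/dS

Counts of missense, nonsense and synonymous coding SNVs in context class
i follow Poisson(t · r_i · L_i · ω), with ω multiplying only the
nonsynonymous classes. Site opportunities L_i are counted by enumerating
all three substitutions at every CDS position and classifying the codon
change; the conservation ΣL = 3 × CDS length is asserted. Substitutions
in a terminal stop codon count as synonymous when the codon remains a
stop and as missense (stop loss) otherwise.

Relative rates r_i come from a large noncoding SNV catalog. They are
normalized to mean 1, optionally after dividing by a per-class
trinucleotide opportunity vector when one is supplied — whether the
original catalog was opportunity-normalized is not documented, so both
routes exist and the overall scale is irrelevant because t is calibrated
so that total expected coding counts equal total observed counts exactly.

ω is estimated under a shared-scale two-Poisson model (tested class and
synonymous class, with log expected counts as offsets), giving the
closed-form ratio-of-ratios MLE; its equality with a joint numerical MLE
is a test oracle. The 95% CI is Wald on log ω with variance
1/n_obs + 1/n_syn, replaced by a profile-likelihood interval when either
count is below 5. Significance is a 1-df LRT of ω = 1. Gene-level scans
test only genes with ≥ 5 coding SNVs and observed > expected for the
class in question, with BH adjustment applied separately within the
missense and nonsense families across tested genes (FDR < 0.1). With
zero synonymous counts ω is undefined and dN, dS are reported
separately. The driver fraction is f = (ω − 1)/ω, floored at 0. Indels
and splice SNVs are excluded throughout (substitution-only framework);
no covariate-adjusted regional rate model is attempted.

## Clonal structure

Informative sites for clustering require MAF ≥ 0.25 in at least two
glands (after excluding sites with blood MAF > 0.05); the number of
glands co-sharing each site at MAF ≥ 0.10 is annotated. Gland MAF
columns are clustered agglomeratively (average linkage, Euclidean —
configurable; the choice is not critical because cluster membership is
decided by mutations, not by a height cut): a clone cluster is a maximal
dendrogram clade whose members all share at least 2 defining mutations
at MAF ≥ 0.25. Remaining glands are singletons. Grid footprints use
4-neighborhood contiguity on a user-supplied lattice layout.

Sharing classification — public (all members), partial (a strict subset
of ≥ 2), private (exactly one) — uses presence = MAF ≥ 0.25 and
partitions every mutation present in at least one member. Timing must be
fed the *full* site set of a cluster, not the informative-site selection,
because that selection deliberately drops private (single-gland)
mutations.

Phylogenies use pairwise Hamming distances between binary
presence/absence profiles and classic neighbor joining (Saitou–Nei
Q-criterion, standard branch lengths, negatives clamped to 0 with a
warning), returned as a scikit-bio `TreeNode` with a trifurcating root;
additive matrices are reproduced exactly and the implementation is
cross-checked against scikit-bio's NJ in the test suite. Parsimony is
Fitch's algorithm on binary characters, verified against exhaustive
internal labeling; for the binary state space the sequential set-merge
at the trifurcating root is exact. No bootstrap support is computed.

## CN-LOH signal

The imbalance statistic per germline heterozygous site is the absolute
log odds ratio of variant-allele counts, gland vs blood. The mean over
sites outside known CNA regions is subtracted from all sites, and a
centred 100-site moving average (truncated at chromosome ends, computed
per chromosome) smooths the signal. The segment caller — runs of ≥ 100
consecutive sites above 0.2 — is tooling for synthetic signals only; the
cellular fraction ρ of an event is an input everywhere it is needed, as
produced by a dedicated allele-specific copy-number tool on real data.

## Timing

Assumption: each cluster's SNV rate is constant from birth to sampling
(clusters may differ from each other). Then the public fraction of a
cluster's mutations estimates the fraction of life elapsed before its
most recent clonal expansion: T_CE = Age · p with
p = MB_pub/(MB_pub + MB_ps + MB_priv), and CI
Age · (p ± 1.96·√(p(1−p)/m)), clipped to [0, Age]. T_CE increases
strictly in MB_pub.

For a CN-LOH, each public SNV in the affected region is assigned
pre/post from its reads across the n glands: joint probabilities with
per-read success ρ_i (pre: the mutation sits on both copies) versus
ρ_i/2 (post: one copy), computed in log space — the binomial coefficient
cancels in the normalized weights w_pre, w_post. Because pre-event
mutations on the replaced allele were lost, the surviving pre-event
count is doubled: MB_pre = 2 × (#pre), MB_post = #post, and
T_CNLOH = T_CE · MB_pre/(MB_pre + MB_post). Assignment uncertainty is
propagated with a seeded Monte-Carlo of 10,000 iterations (Bernoulli
draws from w_pre); each iteration's CI uses the independence identity
V(XY) = V(X)V(Y) + E(X)²V(Y) + E(Y)²V(X) on the public proportion X and
pre-event proportion Y, and the reported estimate and CI are means over
iterations. With ρ = 1, a single reference read makes the pre-event
likelihood exactly zero — correct behaviour, not underflow.

## Synthetic cohorts

The generator plants what the analysis assumes. Defaults describe a
multi-gland study of normal endometrium: subjects aged 21–53, one
five-gland clone per subject expanding at half the subject's age on a
contiguous grid patch, mean depth 80 (blood 40), 30 Mbp effectively
surveyed per gland, and a clock-like rate of 0.08 high-MAF SNVs/Mbp/year
(which yields the ~1.5–4/Mbp burdens such studies report across this age
range). Mutation contexts are drawn from a mixture (default 0.3/0.7) of
two synthetic signatures — a CpG C>T-concentrated column and a broad
flat-ish column — standing in for the aging-associated
deamination/clock pair; real signature matrices load through the same
TSV reader. Public mutations are emitted at expected MAF 0.5 in every
cluster gland, with reads Binomial(depth, MAF); CN-LOH regions emit
pre-event mutations at MAF ρ (each surviving the allele replacement with
probability 1/2) and post-event mutations at ρ/2, exactly the read model
the timing weights invert. Every mutation of a subject is read-sampled
in every gland of its cluster (mpileup-style), so absence is zero mutant
reads, not a missing record. Per-cluster public/post counts are
independent Poisson draws with means proportional to the planted
expansion age and the remainder of life, so the timing CI's binomial
approximation is exercised honestly. Optional knobs (off by default to
keep oracles exact): beta-binomial read overdispersion and germline
contamination of blood.

What the generator does *not* emulate: mapping artifacts and error
modes that motivate the universal-mask filters, subclonal structure
below the presence threshold, varying callable fraction per gland, CNAs
other than clonal CN-LOH, and any emergent tissue dynamics (clone
structure is specified, not grown). Passing recovery tests therefore
demonstrate correctness of the estimators under their own assumptions,
not robustness to artifacts real pipelines must handle upstream.

## Problem sizes and numerical choices

The test suite runs recovery at reduced but honest scales chosen as
typical for the method: dN/dS calibration uses 8 × 300-codon genes with
~60 expected synonymous counts per catalog and 200 replicate catalogs
per ω ∈ {1, 3, 5, 15}; expansion-timing coverage uses 100 single-cluster
cohorts (~100–200 mutations each); CN-LOH bias uses 20 whole-genome-like
cohorts (the whole 100-Mbp synthetic genome callable) with ~30 public
SNVs in the event region. Monte-Carlo timing uses 2,000 iterations in
tests and the default 10,000 elsewhere — an MC precision knob, not a
threshold. All randomness flows through `numpy.random.default_rng`
seeds; identical config + seed reproduces outputs byte-for-byte, which
the pipeline manifest checksums verify.

## Known limitations

* The CN-LOH read model uses success probabilities ρ and ρ/2 directly;
  for subclonal events (ρ < 1) the exact mixture MAF (ρ·1 + (1−ρ)·0.5
  pre-event) differs slightly — the simulator and the inference share
  the same simplification, so recovery tests cannot detect it.
* Bootstrap percentile intervals for signature exposures undercover near
  the simplex boundary (exposure ≈ 0 or 1), a known percentile-bootstrap
  artifact; the activity rule is one-sided and unaffected in practice.
* The defining-mutation cluster rule can, in principle, merge two clones
  that share ≥ 2 coincidental clonal calls; at realistic burdens the
  probability is negligible, but the thresholds are exposed.
* Timing inherits the constant-rate assumption; no change-point model
  is provided, and burdens entering T_CE are raw counts (the ratio is
  unaffected when callable bases are equal across sharing categories).
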