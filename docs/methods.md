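# Methods

polyrekit implements the inference chain used to detect and characterize a
whole-genome triplication (WGT) and the rediploidization that follows it:
synteny-based detection, Ks dating, retention-group classification,
phylogenetic placement, duplicate expression-divergence testing, and
copy-number-stratified selection inference. Because the real analyses of
this kind depend on genome assemblies and resequencing panels, every stage
here is validated by parameter recovery against a synthetic
genome-evolution simulator with full ground truth. This note records the
models, the defaults and why, the numerical choices, and what the
synthetic data do and do not show about real data.

## The simulated history

`simgenome.simulate_wgt_genomes` produces an ancestral genome of
`n_anc_chromosomes` (default 8, matching an eight-proto-chromosome
ancestral karyotype) carrying `n_anc_genes` ordered genes, multiplies it
by `wgt_multiplier` (3 = triplication), splits it into two descendant
lineages, and then, independently per lineage:

- **Fractionation.** Each duplicate copy is lost with probability
  `loss_prob` (default 0.35, chosen to give a realistic mixture of one-,
  two-, and three-copy survivors). Subgenome 0 is least fractionated:
  its loss probability is multiplied by `1 - bias`. If every copy of a
  gene would be lost, one uniformly chosen survivor is kept, so the
  one/two/three-copy universe of retention groups is exhaustive. The
  closed-form class distribution under this rule (`P(k) = Binom(3, k;
  1-p)` for k >= 2, remainder in class 1) is the oracle for the
  frequency-recovery test.
- **Rearrangement.** Poisson numbers of inversions, fusions and
  fissions (`inv_rate`, `fus_rate`, `fis_rate`; defaults 3, 1, 1 per
  lineage) applied in random order. Every event is written to a typed
  log; replaying the log on the ancestor reproduces the descendant
  exactly, which is asserted in tests.

Sequence divergence is generated at the codon level
(`simulate_codon_pairs`): target Ks per pair is lognormal around
`ks_wgt_peak` (paralogs; default 0.5, comfortably inside the 0.2-1.0
block-median window) or `ks_speciation_peak` (orthologs; default 0.18,
the synonymous divergence consistent with a 57.79 Mya speciation used as
the clock calibration), with log-sd `ks_sd` = 0.1 and Ka = `omega` * Ks
(default 0.2). Substitutions are placed by drawing Poisson numbers of
synonymous and nonsynonymous events (rates Ks*S and Ka*N with S, N the
NG86 site counts of the ancestral sequence) and applying them uniformly
at random over the available synonymous / nonsynonymous single-nucleotide
changes, never creating stop codons. Targets implying an expected
synonymous p-distance beyond 95% of the Jukes-Cantor ceiling of 3/4
(Ks > -0.75 ln 0.05 ~ 2.246) are rejected rather than clamped: such
pairs are unestimable and a silent clamp would bias recovery tests.

## Ka/Ks estimation (NG86)

`ksdivergence.ng86_ka_ks` is the Nei-Gojobori (1986) counting estimator
with Jukes-Cantor correction: per-codon synonymous site fractions
(mutations to stop codons count as nonsynonymous sites), sites averaged
over the two sequences, observed differences resolved by equal-weight
averaging over all minimal mutational pathways, excluding pathways
through intermediate stop codons whenever a stop-free pathway exists.
Ks = -3/4 ln(1 - 4/3 pS); pairs with pS or pN >= 3/4 are flagged
saturated and carry no estimate. NG86 is used instead of a
ti/tv-corrected codon model deliberately: the acceptance surface of this
package is simulation recovery, the simulator has no ti/tv bias, and the
estimator interface is pluggable should a YN00-style model be added.
Consistency is verified by simulation (mean estimate within 2% of a true
Ks of 0.2 over 10,000 pairs of 300 codons) and by a hand-counted
three-codon oracle frozen in the tests.

## Synteny and karyotype

Homology hits are filtered at identity >= 30%, e-value strictly below
1e-10, and alignment coverage >= 30% of both query and subject. Blocks
are chained per chromosome pair and orientation by an exact
maximum-score dynamic program over anchors sorted by rank: chains must
be strictly monotone in both genomes, successive rank gaps at most
`max_gap` (default 25) on either side, score = bitscore sum minus
`gap_penalty` (default 1.0) per skipped rank unit. The best chain is
extracted, its anchors removed, and the process repeated while chains of
at least `min_genes` (default 5) anchors remain; ties break toward
higher bitscore sum, then the lexicographically smallest anchor
coordinates, making output order-independent. The DP is tested for exact
agreement with exhaustive enumeration on instances of up to 12 anchors.
Tandem duplicates (runs of adjacent ranks hitting one gene) are
collapsed to the best hit before chaining (togglable).

Synteny depth of a reference gene is the number of distinct query blocks
in which it occurs as an anchor — i.e. the number of retained
homoeologous copies — so a fractionation-free triplication shows the
3:1 pattern as modal depth 3, and on simulated data depth equals the
truth copy number gene by gene.

Karyotype arithmetic: `expected_ploidy_ladder` multiplies a base number
through successive multiplications (7x3x2x2x2 = 168; 8x3 = 24).
`count_rearrangement_events` is a deliberate lower-bound surrogate, not
a rearrangement-distance solver: descendant chromosomes are collapsed
into maximal runs of one ancestral-chromosome *copy* (post-WGT copies
kept distinct via subgenome labels); r runs on a chromosome imply r-1
fusions, a copy split into m runs implies m-1 fissions, and adjacent
same-copy runs of opposite sign are inversion breakpoints. Run-based
counting makes the conservation identity `fusions - fissions = copies -
descendant chromosomes` exact, which is asserted on rearrangement-only
simulations. (Counting distinct ancestors per chromosome instead of
runs would undercount interleaved patterns like A-B-A and break the
identity.)

## Ks peaks, filtering, and dating

Peak detection fits Gaussian mixtures to log-Ks with component count
chosen by BIC (cap 4, ties toward fewer components, fixed random state);
a peak's mode is reported as exp(mean), i.e. the lognormal median.
Paralog pairs are retained when their block's median anchor Ks lies in
[0.2, 1.0] and their own Ks is at most 1.26; saturated pairs are always
dropped. WGT age is a strict molecular clock: age = peak mode /
(ks_orth_peak / t_calibration), with uncertainty from bootstrapping the
Ks values feeding the peak (geometric-mean mode per resample). When the
Ks values attributed to the event are available, the point-estimate
mode is their geometric mean (`peak_from_values`) — the same statistic
the bootstrap resamples — rather than a GMM component mean: on skewed
unimodal clouds BIC sometimes splits the wave in two, and the heavier
component's mean is then a biased dating input while the geometric mean
is not. The
default calibration (Ks 0.18 at 57.79 Mya) makes a Ks-0.2 peak date to
~64.2 Mya. The full Bayesian relaxed-clock machinery this replaces is a
non-goal; calibration ages are user inputs. LTR insertion ages are
K / (2 x 1.3e-8) years from the 5'-3' LTR divergence; intact elements
require 100-3000 bp LTRs, similarity strictly above 80%, 1-15 kb
spacing, and a complete Gag-Pol record.

## Retention groups

The retained-pair graph (nodes: all genes; edges: Ks-filtered syntenic
paralog pairs) is partitioned into connected components: sizes 1/2/3 are
the copy classes; components larger than 3 — tandem arrays or older
duplicates leaking through the Ks window — are flagged `oversized` and
excluded from class counts rather than force-split, since any splitting
rule would be invented. Classification accuracy is exact on simulations
whose Ks peaks are cleanly separated by the filter window; the dedicated
recovery test adds decoy duplication waves at Ks ~ 1.8 and ~ 0.05 and
requires 100% per-gene accuracy. Cross-species anchoring joins an
outgroup gene to its retention group in each ingroup species and filters
to a copy-class pattern such as (3, 3); orthologs spanning two groups in
one species flag the row ambiguous.

## WGT placement

Gene trees are either supplied (Newick) or built by neighbor joining on
pairwise distances, rooted on a stated outgroup. Topology scenarios for
two duplicates in each of two species: duplicate clades that each mix
the species (((S1,L1),(S2,L2)),O) indicate a shared WGT;
species-monophyletic duplicates indicate lineage-specific duplication;
everything else — missing leaves, multifurcations, other resolutions —
is unresolved, with no silent polytomy resolution.

MAPS-style placement maps gene trees onto a species tree and reports,
per internal node, the percentage of examined subtrees containing a
duplication shared by all descendant species. Duplications are called by
species overlap (children of a gene-tree node sharing a species), which
on the binary, complete-taxon trees this pipeline produces is equivalent
to reconciliation; a duplication supports node N when its species set
equals N's clade and both children cover the whole clade. The
gene-family simulator draws birth-death events along the species tree
and, under the positive model, duplicates every lineage crossing the WGD
node, retaining the extra copy with probability `retention_rate`
(default 0.2, the study's setting). With background rates at zero the
expected WGD-node percentage is exactly the retention rate, which is the
binomial recovery condition used in acceptance (2,000 families); any
nonzero background duplication adds to both observed and simulated
percentages and is handled by the null/positive comparison bands, not by
the point expectation. Verdicts: observed above the null band and at or
above the positive band's lower edge supports the WGD; observed within
the null band is no support; in between is ambiguous. The band
quantiles are a parameter (default 95%); the recovery harness uses 99%
bands because a 95% band would by construction mis-classify about one
run in twenty even when the model is correct, which is exactly the
failure budget the recovery criterion allows for everything else.

## Duplicate expression divergence

The exact conditional test conditions on a pair's total read count in a
sample: under equal expression gene A's count is Binomial(a+b, p0) with
p0 = 0.5 by default; an optional CDS-length correction p0 =
len_a/(len_a+len_b) is provided but not asserted as the original
procedure, which used raw counts. The two-sided p-value sums all
outcomes no likelier than the observed one (scipy's `binomtest` method,
verified against full enumeration). The multiple-testing family is all
pairs tested within one tissue and replicate (Bonferroni); a DEGP call
requires every replicate significant at corrected p < 0.05 with the
same direction. Three-copy groups contribute their three pairwise
comparisons; a group is "divergent" if any of its pairs is a DEGP.
Pairs with a zero total in any replicate of a tissue are excluded from
that tissue's family.

A caveat the tests make explicit: the binomial null describes Poisson
(technical) noise only. The simulator's negative-binomial dispersion
(default phi = 0.1) represents biological variability *between
replicates of the same gene*, and because each member of a pair draws
its NB noise independently, overdispersion inflates the conditional
test's false-positive rate — a known property of this class of test,
shared by the original procedure. Type-I-error tests therefore run in
the Poisson regime (phi = 0), where the null model holds and the
Bonferroni + three-replicate-consistency caller yields essentially zero
false DEGPs; power tests use the diverged-pair offset (default 2 log2
units) under NB noise. In diverged groups the members are spread apart
so every within-group pair differs by at least the offset, making the
pair-level true DEGP fraction equal `degp_fraction` (default 0.6,
matching the reported 58-65% range).

## Selection inference

The Poisson-random-field expected SFS for scaled selection S uses the
density theta (1 - e^{-S(1-q)}) / ((1 - e^{-S}) q (1-q)), binomially
sampled to `n_chrom` chromosomes (default 24) and folded; the S -> 0
limit is the Watterson theta/i spectrum (folded class proportions 8/11
and 3/11 at n = 4, used as a closed-form oracle). Numerics: 400-node
Gauss-Legendre quadrature on allele frequency, validated against
adaptive quadrature to 1e-8.

The gamma DFE over deleterious |Nes| is fitted to the pooled zero-fold
folded SFS by maximum Poisson likelihood with independent classes. Two
numerical choices matter and are deliberate:

- **Mutation-rate tying.** The four-fold SFS fixes the neutral per-site
  theta, and the zero-fold mutation rate is tied to it through the site
  ratio (theta_ns = theta_syn x L0/L4). Tying is what identifies the
  strongly deleterious mass: mutations that never segregate leave a
  count deficit against the tied rate, whereas with a free theta_ns the
  (100, inf) bin trades off exactly against the mutation rate and the
  likelihood is flat. A `theta_mode="free"` option retains the profiled
  variant.
- **Gamma quadrature.** Expectations over the gamma use Gauss-Legendre
  on log |Nes| between extreme gamma quantiles (200 nodes). Plain
  Gauss-Laguerre fails badly here: with mean |Nes| in the thousands the
  integrands (fixation rates, weakly-selected SFS contributions) vary on
  a scale far below the first Laguerre node. The log-grid is validated
  against adaptive quadrature.

Optimization is multi-start (5 fixed starts) Nelder-Mead on log(shape),
log(mean); theta handling as above; ties resolved by best log-likelihood
then smallest shape. Fitted |Nes| bins are the gamma mass over (0,1),
(1,10), (10,100), (100,inf), reported on the conventional negative
scale.

Adaptive divergence: expected non-adaptive nonsynonymous divergence is
Ds (L0/L4) E[S/(1 - e^{-S})] under the fitted DFE; alpha = (Dn -
E[Dn_na])/Dn and omega_a = alpha (Dn/L0)/(Ds/L4). Uncertainty comes
from a 200-replicate by-gene bootstrap that re-pools SFS and counts and
refits the DFE per replicate. The selection-data simulator draws
per-gene Poisson SFS and divergence counts from the same PRF
expectations with neutral divergence `ks_speciation_peak` per site (the
between-species synonymous divergence is the natural neutral divergence
scale, so no separate parameter is introduced) and Dn inflated by
1/(1 - alpha_true); recovery tests check mean alpha within 0.05 at
alpha_true in {0, 0.3, 0.6}.

FI = (Dn/Ds)/(Pn/Ps) with 0.5 added to every cell when any cell is
zero. The constraint and selection effects are closed-form log-ratio
surrogates — constraint = ln((Pn+.5)/(Ps+.5)) - ln(L0/L4), selection =
ln((Dn+.5)/(Ds+.5)) - ln((Pn+.5)/(Ps+.5)) — named after, but not
claiming to be, the Bayesian GLMM estimates they stand in for. Class
contrasts are two-tailed t tests with stars at 0.05 and 0.001. A
directional test simulates class-graded selection (stronger purifying
and adaptive pressure from one- to three-copy classes) and checks that
estimated alpha and FI increase with copy class while the constraint
effect decreases — the qualitative pattern, not any real-data magnitude.

Demography is constant-size throughout: the two-epoch nuisance model of
the original DFE software is omitted, and the simulator makes the same
assumption, so recovery tests are internally consistent. This is the
main caveat when reading the recovery results: real spectra carry
demographic distortion that this package neither simulates nor corrects.

## Problem sizes and runtime

Defaults in tests and the acceptance script are desk-scale by design:
10,000 ancestral genes for retention recovery, 10,000 codon pairs for
estimator consistency, 2,000 gene families for MAPS, 200 genes x 600
zero-fold sites per class for the DFE, 200 bootstrap replicates. These
sizes give Monte-Carlo errors comfortably inside every stated tolerance.
All randomness flows from explicit seeds; every stochastic suite is
byte-reproducible.

## What passing tests do not show

The simulator emulates the *structure* of the real inputs, not their
noise: no annotation error, no alignment error, no read-mapping bias, no
demographic history, no rate heterogeneity among lineages or sites, no
ti/tv bias, and truth-derived homology tables in place of BLAST output.
Recovery results certify the estimators and their couplings under the
stated generative models; they do not certify robustness to violations
of those models.
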