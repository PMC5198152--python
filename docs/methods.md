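# Methods

`trflp` models the complete analytical chain of a terminal restriction
fragment length polymorphism (T-RFLP) study of methanogenic communities
profiled through the *mcrA* marker gene: fragment prediction, fingerprint
processing, taxon assignment with a second enzyme, multivariate and
correlation statistics, and distance phylogenetics, together with a
synthetic study generator that provides ground truth for every stage.

## In-silico amplification and fragment prediction

A degenerate primer (IUPAC alphabet) matches a template window when every
template base lies in the corresponding code's expansion; `N` in a template
is an unknown base and counts as a mismatch against every code. Both
strands are scanned; positions are 0-based, half-open internally.
Amplicons are extracted between exactly one forward and one reverse site
and re-oriented so the 5'-labeled primer (the reverse primer in the *mcrA*
workflow) sits at position 0 — the strand a capillary sequencer actually
sizes. Where a degenerate primer base meets the template, the amplicon
records the template base, so restriction sites overlapping primer regions
digest faithfully; primer incorporation cannot change fragment length.

The predicted T-RF is the offset of the first recognition-site occurrence
from the labeled end plus the enzyme's cut offset (HaeIII GG^CC, offset 2;
MspI C^CGG, offset 1; standard REBASE definitions shipped as constants).
Both sites are palindromic, so a single-strand scan is exhaustive; a
non-palindromic enzyme would be scanned on both strands with the earliest
cut winning. Uncut amplicons report their full length with
`cut_found=False` rather than being dropped — the decision belongs
downstream. T-RF lengths include the labeled primer bases, matching how
capillary sizing reports fragments.

## Fingerprint processing

Processing order is fixed: size window → noise filter → replicate
consensus → cross-sample binning → minor-T-RF filter. Peak **area** is the
abundance measure throughout; all relative abundances are proportions of
per-sample total area and every normalizing step leaves rows summing to 1
within 1e-9.

**Size window.** Peaks outside [50, 500] bp (inclusive) are removed:
below 50 bp sizing is dominated by primer and dye artifacts, above 500 bp
fragments exceed the internal size standard.

**Noise filter (k×SD rule, default k = 6).** Areas are converted to
proportions of total area and the background is estimated iteratively from
below: peaks at or under a seed floor of 0.2% of total fluorescence seed a
noise set; the standard deviation of the noise proportions about zero
(root mean squared proportion) defines a cutoff of k×SD; peaks at or below
the cutoff join the noise set and the SD is recomputed until the
classification stabilizes. Two guards shape the rule. First, only peaks
under a 0.8% ceiling are noise candidates, so the filter can never claim a
peak that the 1% reporting convention would present (0.8% rather than 1%
leaves headroom for the dilution of true-peak proportions by total noise
mass). Second, a table with no peak under the seed floor has no detectable
noise floor and passes through unchanged. Together these make the filter
idempotent — every survivor exceeds the final cutoff, renormalization can
only raise proportions — and make it a provable no-op on noise-free data
whose planted proportions stay above the seed floor. A table of identical
areas consequently passes through untouched (no noise floor is
detectable), and the filter warns only in the opposite degeneracy, when
every peak classifies as noise.

**Replicate consensus.** Peaks from all replicates of a sample/enzyme run
are clustered by single-linkage within ±1 bp under the constraint that a
cluster holds at most one peak per replicate; chains violating the
constraint are split recursively at their largest internal gap, which
separates near-coincident fragment groups (e.g. a 175/176 bp pair) at
their natural boundary independent of input order. A consensus peak is
kept iff present in a majority (⌈r/2⌉) of r replicates; consensus size and
area are means over the replicates containing it.

**Cross-sample binning.** The same constrained single-linkage clustering
(tolerance 2 bp by default, matching the 1–2 bp drift typical of capillary
sizing between near-identical fragments) aligns consolidated peaks across
samples, with at most one peak per *sample* per bin. Bin centers are
area-weighted mean sizes rounded to integers, matching conventional
integer T-RF nomenclature.

**Minor-T-RF filter.** Bins never reaching 1% relative abundance in any
sample are removed and rows renormalized; the discarded mass per sample is
reported alongside the matrix.

## Dual-enzyme taxon assignment

A reference taxon is a candidate for a bin when its predicted T-RF under
that enzyme lies within the assignment tolerance (2 bp, shared with the
binning tolerance) of the bin center. Unique bins transfer their mass
directly. For ambiguous bins — typically a single-enzyme collision such as
an acetoclast and a hydrogenotroph one base pair apart — each candidate
must be corroborated by the second enzyme: its second-enzyme fragment must
carry nonzero abundance in the same sample's other profile. A single
survivor takes the whole bin; multiple survivors split the mass in
proportion to their compatible second-enzyme bin abundances (or the bin is
left unresolved under the `report` rule); no survivor sends the mass to an
explicit unresolved pool, so assigned plus unresolved mass is always 1.

The proportional split is exact in the noise-free limit: summed over a
collision group, each taxon receives (group total) × (its share of the
second-enzyme signal), which equals its true abundance when the second
enzyme separates the pair.

## Ordination and correlation statistics

**Bray-Curtis.** d(i,j) = Σ|x_ik − x_jk| / Σ(x_ik + x_jk); a semimetric in
[0,1] for non-negative data. A pair of all-zero samples is an error.

**NMDS.** Kruskal stress-1 is minimized by alternating isotonic regression
(pool-adjacent-violators, via `scipy.optimize.isotonic_regression`) of
configuration distances on the rank order of the input dissimilarities
with a Guttman-transform configuration update, damped by step halving so
stress never increases within a restart; 20 random restarts, convergence
at stress change < 1e-6 or 500 iterations, best restart returned,
deterministic for a given seed. Ties are handled in the primary (weak)
sense: tied dissimilarities impose no rank constraints. Coordinates are
centered, principal-axis rotated, and sign-fixed for reproducibility.
Caveat: when one sample group is farther from every other sample than any
within-rest pair — the situation created by a reactor overwhelmingly
dominated by a single taxon — a step configuration represents the rank
order perfectly and stress collapses toward zero. This is a legitimate
global optimum of stress-1, not an optimizer failure; the function warns
on near-zero stress so users inspect the configuration.

**Vector fitting.** Each variable is centered and least-squares projected
onto the ordination coordinates; r² is the explained fraction of its
variance and the arrow is the unit-normalized coefficient vector.
Significance is Monte-Carlo: the variable is permuted across samples
(default 1000 permutations) and p = (1 + #{r²_perm ≥ r²_obs}) / (n_perm + 1),
so p is floored at 1/(n_perm+1). Samples with missing values are dropped
per variable; constant variables are skipped with a warning.

**Spearman matrix.** Every abundance column against every parameter, on
pairwise-complete observations (≥5 pairs per cell), with average ranks over
ties and a two-sided p from t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of
freedom; exact enumeration is available for n ≤ 9. Cells are flagged at
p < 0.01 and p < 0.001. **No multiple-testing correction is applied** —
the flags are raw per-cell thresholds, as is conventional for
fingerprint-correlation heatmaps; treat isolated single-star cells
accordingly.

## Distance phylogenetics

Jukes-Cantor distances use pairwise (not complete) gap deletion:
d = −(3/4)·ln(1 − 4p/3) with p the mismatch fraction over sites non-gapped
in both sequences; p ≥ 0.75 is a saturation error naming the offending
pair. Neighbor joining is the classic Saitou-Nei agglomeration on Q(i,j) =
(n−2)d(i,j) − r_i − r_j with ties broken by the smallest index pair and
negative branch-length estimates clamped to zero; the result is an
unrooted, trifurcating tree that reproduces additive inputs exactly.
Bootstrap supports resample alignment columns with replacement, rebuild
each replicate tree, and annotate each internal edge of the full-data tree
with the percentage of replicates containing the same leaf bipartition;
replicates with saturated pairs are skipped and counted (warning above
5%). Outgroup rooting is a post-hoc re-rooting operation. No aligner is
included; inputs are assumed aligned.

## Synthetic study generator

The generator emulates an 11-reactor × 3-timepoint monitoring design
(33 samples) over a panel of 12 methanogen phylotypes, chosen so exactly
one pair collides under HaeIII (175/176 bp) while separating by >10 bp
under MspI, with all other T-RFs ≥5 bp apart and inside [60, 490] bp —
clear of the sizing-window edges by many multiples of the sizing error.

**Reference sequences.** Each template is built on the labeled strand —
realized reverse primer, random core, reverse-complemented realized
forward primer — with recognition sites planted so the first cut falls
exactly at the specified T-RF, all other HaeIII/MspI occurrences scrubbed,
and the construction verified by round-tripping through the package's own
digest.

**Communities.** Non-dominated reactors draw a Dirichlet(α=2) base
composition mixed with a 5% uniform floor, then drift between timepoints
by a bounded multiplicative random walk (log-normal factors clipped to
[0.8, 1.25], renormalized, re-floored at 4%). The floor asserts that every
panel taxon is present at ≥0.3% everywhere — reference panels are built
from taxa actually detected across a study — and guarantees the noise
filter is a no-op on noiseless tables. One reactor is dominated by a
single hydrogenotroph at 94–96% per timepoint, with the remainder spread
nearly evenly so minor taxa stay below 1%, reproducing the high-ammonia
regime in which acetoclastic methanogens are suppressed and minor taxa
fall under the reporting threshold.

**Process parameters.** A coupled parameter is a monotone affine transform
of the named taxon's normal-scored abundance plus Gaussian noise, with the
noise scale set from the coupling strength s through the bivariate-normal
relation ρ_Pearson = 2·sin(πs/6), so the expected Spearman correlation is
≈ s at the default noise multiplier and tends to ±1 as the multiplier goes
to 0. Uncoupled parameters are independent uniforms over plausible
anaerobic-digestion ranges (TAN 1–6 g/L, pH 6.8–8.2, CH₄ 45–65%, SBP
250–720 mL/g_VS, …). One parameter may couple to at most one taxon;
realized rank correlations are recorded on the ground-truth object.

**Peak tables.** Per sample, enzyme, and replicate: one true peak per
taxon at the reference T-RF plus independent Gaussian sizing jitter
(default SD 0.3 bp, typical capillary performance), area proportional to
abundance times a jittered total signal; plus 30 background peaks uniform
over [50, 500] bp with areas uniform on (0, 0.5% of the largest true peak].
All generators are pure functions of their seeds.

### What the generator does and does not emulate

It reproduces the features the pipeline's contracts depend on —
compositional structure with a dominated reactor, collision pairs, sizing
jitter, replicate variation, bounded background noise, monotone
taxon-parameter couplings. It does **not** model electropherogram
baselines, pull-up or stutter artifacts, size-calling error that grows
with fragment length, PCR/primer bias, partial digestion, or phylogenetic
correlation among taxa. Passing tests therefore demonstrate correctness of
the algorithms under the stated noise model, not robustness to every
artifact of real capillary data; with real inputs the binning and
assignment tolerances (2 bp) and the noise-filter parameters are the knobs
to revisit.

## Problem sizes and numerical choices

The test suite and the reproduction script run the study at its native
size (33 samples, 12 taxa, 2 enzymes, triplicates), with 1,000 random
triples for the digest oracle, 100 simulated studies for denoising
efficacy, 200 for coupling recovery, 500 draws for permutation
calibration, and 100 random additive 8-taxon trees for neighbor joining.
Row-sum and recovery tolerances are 1e-9; NMDS convergence is 1e-6 on
stress; all tie-breaks (clustering order, NJ pair choice, candidate
sorting) are deterministic. Degenerate inputs have defined behavior:
empty amplicons, all-zero peak areas, all-zero sample pairs, constant
variables, and saturated distances raise or warn as documented rather than
propagating silently.

## Known limitations

Single-digest assignment resolves collisions only pairwise through one
second enzyme; three-way collisions would need a third digest. The
proportional split assumes the second enzyme's bins are themselves
unambiguous for the candidates. NMDS reports, but does not repair,
degenerate near-zero-stress configurations. Real-data mode validates
fragment predictions only against published T-RF values within ±2 bp, as
clone-level observed-vs-theoretical tables are not machine-readable.
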