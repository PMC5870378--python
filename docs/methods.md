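# Methods

This note records the models, conventions and numerical choices behind the
package, and what its synthetic benchmarks do and do not establish.

## In-silico PCR and digestion

Primer matching is exact under IUPAC degeneracy: each degenerate code
matches precisely the bases in its set, and no mismatches are tolerated.
The rationale is determinism — without an annealing/mismatch model any
tolerance threshold would be arbitrary, and predicted T-RF sizes would stop
being a pure function of the template. A forward-primer match is paired
with the *nearest* downstream reverse-primer site (seen on the top strand
as the reverse complement of the reverse primer), giving the shortest
plausible product per forward site; overlapping amplicons are all reported.
Coordinates are 0-based half-open; a fragment's labeled 5' base is position
1, so a T-RF length equals (index of first recognition-site base) +
cut_offset.

The shipped enzymes use REBASE cut geometry: DdeI C^TNAG (cut_offset 1),
HaeIII GG^CC (2), HhaI GCG^C (3). Their sites are degeneracy-palindromic,
so scanning the top strand finds every double-stranded site; a
non-palindromic user-supplied enzyme triggers a warning rather than an
error. One geometric consequence worth stating: digesting the reverse
complement reproduces the mirrored cut pattern only up to the overhang.
Every cut position on the reverse complement shifts by
site_len − 2·cut_offset relative to the mirrored cut, so interior fragments
are preserved exactly while the two terminal fragments shift by that
constant (zero for the blunt-centered HaeIII cut). The test suite asserts
this exact relation rather than naive fragment-list reversal.

ARDRA fingerprints take non-overlapping site occurrences left to right;
fragments always partition the amplicon (their sum equals its length).
Matching observed T-RF bins to predicted sizes uses a configurable ±1.0 bp
default tolerance — fragment sizing is accurate to roughly a base over the
50-500 bp range — and deliberately returns *all* taxa within tolerance,
since distinct genera routinely co-migrate at one fragment length.

Host-organelle removal is a length threshold: the bacterial product of the
799f/1492R pair runs ~730 bp while the host mitochondrial product runs
~850 bp, so amplified fragments above 800 bp (default) are discarded in
silico.

## Peak processing

Peaks are kept inside an inclusive 50-500 bp window by default (the
reliable range of a 500-size standard). Relative abundance within a
profile is peak area over summed area; unnormalized compositions are never
silently rescaled downstream — a row that does not sum to 1 is an error.

Cross-sample alignment uses single-linkage chaining on pooled sorted
sizes: a new bin starts wherever the gap to the previous size exceeds the
tolerance (default 0.5 bp). Chaining, rather than fixed-width bins, is
chosen because duplicate runs drift by sub-bp amounts; a fragment drifting
0.3 bp between runs must stay one bin regardless of where a fixed boundary
falls. Bin labels are the mean member size rounded to 1 decimal; sizes are
kept at instrument precision until labeling.

Duplicate instrument runs are merged by rebuilding the joint bin set —
re-chaining the union of all runs' member sizes, which also reunites bins
that a single sparse run happened to split — and then averaging each
sample's per-bin relative abundance over runs, counting a bin absent from
a run as 0. The mean damps run-to-run area noise while the union preserves
presence for richness. Because "merging" could also reasonably mean
union-of-presence, `merge_replicates(..., how="union")` exposes the
alternative (average over detecting runs only, rows renormalized); the
mean is the default. No relative-abundance floor is applied by default; an
optional minimum-abundance filter is available.

## Diversity and ribotype classes

Shannon H′ uses the natural log; J′ = H′/ln S is defined as 0 at S = 1
(the formula is 0/0 there). Both Simpson transforms of D = Σp_i² are
computed: the reciprocal 1/D, and the complement 1 − D which lies in
[0, 1 − 1/S] and is the default for table-style reporting — diversity
tables in the fingerprinting literature commonly print the complement even
when the text writes 1/D, and reporting both removes the ambiguity.

Across groups (e.g. cultivars), a bin present in at least one sample of
every group is *core*, in exactly one group *unique* (genotype-specific),
otherwise *shared*; the three classes partition the detected bins.
Genotype-specific percentages are 100 × unique/total to one decimal.

## Ordination and tests

Bray-Curtis dissimilarity is computed on relative abundances; percent
similarity is 100 × (1 − d) where that scale is wanted (ordination always
operates on d).

NMDS minimizes Kruskal stress-1, √(Σ(d−ď)²/Σd²), where d are Euclidean
configuration distances and ď their least-squares monotone
(pool-adjacent-violators) regression onto the rank order of the observed
dissimilarities. Ties in the observed dissimilarities follow Kruskal's
primary approach — tied blocks may reorder to improve fit, implemented by
sorting targets ascending within each tied block before PAVA. Each start
iterates distance computation, isotonic refit and a Guttman-transform
update until the stress change falls below `tol` (default 1e-7) or
`max_iter` (300). Defaults are 100 starts and k = 2. The first start is
initialized from classical scaling (PCoA) of the dissimilarities, the
standard guard against the degenerate tied-distance configurations that
pure nonmetric fitting can otherwise reach near zero stress; all further
starts are random. The best configuration is centered and rotated to
principal axes. Stress-1 is invariant under rotation, translation and
uniform scaling (the isotonic refit absorbs scale).

ANOSIM ranks all off-diagonal dissimilarities (average ranks on ties) and
forms R = (r̄_between − r̄_within)/(n(n−1)/4) ∈ [−1, 1]. Significance is
by label permutation with the (1 + b)/(1 + m) convention so p is never
zero; when the number of distinct labelings does not exceed the requested
permutation count the null is enumerated exactly and p is the exact
exceedance fraction. The default 999 permutations gives a floor of
p = 0.001, matching the "significant at P(%) = 0.1" reporting convention
of PRIMER-style analyses. Pairwise contrasts rerun the test on each group
sub-matrix. With equal-sized groups the statistic is invariant under group
relabeling, which makes the permutation p-value slightly conservative at
small n (ties in the null distribution come in relabeling blocks); the
calibration benchmark below shows the realized α = 0.05 rejection rate
near 0.04.

UPGMA uses group-average agglomeration (scipy linkage); merge heights are
mean inter-cluster dissimilarities and non-decreasing, ties broken by
input order. The Newick export assigns branch lengths as half-height
differences, so leaf depths equal half the root merge height and the tree
is ultrametric; percent-similarity merge levels are 100 × (1 − height).

## Synthetic scenarios

The generator fabricates what the wet workflow would produce, with known
truth. Templates carry the 799f/1492R priming sites around a 650-750 bp
insert; one recognition site per enzyme is planted at a chosen offset and
the rest of the insert is scrubbed of recognition sites, so the planted
site is terminal and every taxon's T-RF is known by construction. T-RF
targets are drawn in 60-495 bp (inside the default sizing window),
pairwise ≥ 2 bp apart within an enzyme; an optional collision mode makes
taxon pairs share a fragment to exercise multi-taxon bin assignment.

Default design and noise, chosen once as a realistic greenhouse-comparison
setting: 3 genotype groups × 3 replicate samples, 2 instrument runs per
sample, 20 taxa, log-normal base abundances (log-SD 1.0 — a few dominants
and a long tail, as fingerprint heatmaps typically show), per-sample
biological log-noise 0.3, group effects as log-abundance shifts of scale
`effect_size` on a random half of the taxa, multiplicative mean-1
log-normal area noise with CV 0.3 (fluorescence scales multiplicatively),
Gaussian size jitter with SD 0.15 bp (sub-bp drift between runs), and a
detection floor of 50 area units on a 50,000-unit total signal. Everything
is deterministic given the scenario seed.

What the benchmarks show — and don't. The noiseless configuration
(area_cv = 0, jitter = 0, floor = 0) recovers true abundance vectors and
all diversity indices exactly through the full filter→bin→normalize path,
which validates the plumbing, not the biology. The null configuration
(effect_size = 0) calibrates the ANOSIM rejection rate; the large-effect
configuration (effect_size = 2) demonstrates power. Real electropherograms
additionally contain pseudo-T-RFs, partial digestion, size-standard
curvature and primer bias, none of which are simulated; passing these
benchmarks therefore says the analysis is correct for ideal-instrument
data, not that any biological conclusion is automatic.

## Benchmark sizes

The acceptance benchmarks use: 1,000 random templates (length ≤ 2,000 bp,
half with planted primer pairs) for the digest-vs-oracle comparison; n = 20
points and 100 starts for the NMDS stress check; 500 null scenarios at 199
permutations for calibration and 50 large-effect scenarios at 999
permutations for power; single-enzyme (DdeI) scenarios for the Monte-Carlo
loops. The routine unit suite re-runs the same checks at smaller sizes.
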