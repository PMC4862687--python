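# Methods

This note records the models, parameter choices and numerical decisions
behind each stage of the pipeline, what the synthetic generators do and
do not emulate, and the known limitations.

## Receptor mining

**ORF model.** Six reading frames are scanned; within a frame, maximal
ORFs run from the first ATG after a stop (or, for 5'-truncated
transcripts, from the contig edge) to a stop codon or the contig edge.
An edge-start ORF without an ATG is only called when it has a terminal
stop as its 3' anchor — a stretch with neither anchor is noise, not an
ORF. The minimum translated length defaults to 200 aa, a conservative
bound for a 7TM protein (7×21 helix residues plus loops and tails);
it is exposed in `MiningParams` because the appropriate bound depends on
assembly fragmentation.

**End-curation flags.** "Closely followed" for the upstream stop→ATG
rule is fixed at ≤ 90 nt in-frame (30 codons), configurable; the flag
indicates the transcript captured the true translation start. The
3' flag only requires a stop codon inside the contig. `orf_confident`
is their conjunction, and only confident ORFs face the topology filter:
a truncated protein cannot be expected to display all seven helices.

**Candidate choice is similarity-seeded.** Each transcript's candidate
is the ORF (among its three longest) with the most significant hit
against the seed database, not simply the longest ORF. This matters in
practice: compositionally biased coding sequence can leave a long
stop-free stretch on the opposite strand, and length alone would pick
that spurious frame. The true coding frame carries the seed similarity.

**E-values.** Local alignments (Biopython `PairwiseAligner`, BLOSUM62,
BLAST-style gap costs 11/1) are converted to bit scores with
Karlin–Altschul parameters (λ = 0.267, K = 0.041 for BLOSUM62 11/1) and
to E-values with effective search space = query length × total database
length. Admission requires a best hit at E ≤ 1e-3; this is the
threshold at which composition-matched shuffled queries produce no hits
(verified empirically in the test suite with 200 shuffles).

**Exclusion rule.** Among the top-50 hits (all hits if fewer, ties
broken by (E-value, target id)), a candidate is excluded when the
fraction that are non-receptor transmembrane proteins at E < 1e-10
reaches 1/2. The rule is deliberately a fraction of the *top hit list*,
so a receptor with many strong receptor hits is safe even if it also
weakly resembles transporters.

**Topology stand-in.** Transmembrane segments are maximal runs of
19-residue-window Kyte–Doolittle means above 1.6, merged when separated
by < 4 residues, then trimmed/padded toward the canonical 21-residue
helix length (non-overlap enforced by splitting at midpoints).
Orientation uses the positive-inside rule: of the two alternating
side assignments, the one placing more loop K+R residues inside wins;
ties default to an extracellular N-terminus. This hydropathy model is a
self-contained topology predictor adequate for the filter rule — it is
not an HMM and will misplace marginal helices in real proteins, which
is why `mine()` accepts externally computed per-candidate topology
overrides, and why manual helix rescues are represented as explicit
override entries rather than automated heuristics.

**Recursion.** Retained candidates join the seed database and mining
repeats until the retained set is stable (error after 10 rounds).
Status transitions are monotone within a pass: once excluded, a
candidate is not re-admitted.

## Network classification

Edges store p-values; attraction is −log₁₀(p) + log₁₀(threshold), so
every stored edge has positive attraction. The layout is a standard
force scheme — attraction along edges proportional to weight times
distance, all-pairs repulsion proportional to inverse distance, uniform
unit-cube initialization from the seed — with per-step displacement
capped by a linear cooling schedule (0.1 → 0.002 over the run). The
cap makes late steps small so the embedding settles; the energy
(attraction-weighted squared edge lengths minus log-repulsion) is
monitored and, in the tests, required not to rise between the midpoint
and the end of the run. Strict per-step monotonicity is not enforced:
that would require a line search and buys nothing for cluster
extraction, which is purely graph-based.

**Cluster extraction.** The attraction cutoff is mean + 0.5·SD computed
over the *full attraction matrix*, with absent pairs contributing zero.
This is the reading under which an edge's attraction is measured against
the typical pairwise attraction of the whole map; computing the
statistics over stored edges only would always discard a fixed upper
quantile of the within-family edges and can disconnect genuine families
regardless of how well separated they are. Components of ≥ 4 members
become clusters. Convexity (fraction of laid-out points inside a
cluster's hull that belong to it) is reported, never enforced; manual
merge/split directives are applied through `apply_curation` and logged,
mirroring how hand-adjusted cluster maps are documented rather than
automated.

## Phylogeny

The progressive aligner is minimal and deterministic: pairwise global
alignments (BLOSUM62, gap open 5 / extend 1) give identity distances, an
average-linkage guide tree fixes the merge order, and profiles are
merged by column-wise Needleman–Wunsch with a flat −4 gap-column score.
It is adequate for well-conserved receptor cores, not for twilight-zone
alignment.

Jukes–Cantor distances use the generalized k-state correction with
k = 20 and pairwise deletion (only columns ungapped in both rows).
Saturated pairs (p ≥ (k−1)/k, or no shared ungapped columns) are capped
at 10.0 and flagged rather than erroring: a bootstrap replicate may
transiently saturate a pair.

Neighbor joining follows the classic Q-matrix algorithm. Ties in Q are
broken by the lexicographic pair of cluster labels (a cluster is labeled
by its smallest leaf), making the topology independent of input order.
Negative branch lengths are clamped to zero with the deficit moved to
the sister edge, preserving the joined pair's path length — on additive
inputs the tree metric is reproduced to ≤ 1e-9 (property-tested on 100
random additive matrices).

Bootstrap supports resample alignment columns with replacement, rebuild
the NJ tree, and report the percentage of replicates containing each
internal bipartition of the full-data tree. Outgroup rooting requires
the outgroup to be monophyletic in the unrooted tree and places the root
at the midpoint of the separating edge. Bayesian tree inference is out
of scope; `write_bayesian_run_parameters` exports the run settings
(WAG, 200,000 generations, 25% burn-in) alongside the alignment for use
with external samplers.

## Expression screen

**Mapping.** k-mer-seeded (k = 15) ungapped alignment on the seed
diagonal; similarity = identities/aligned length, coverage = aligned
length/read length, both thresholds inclusive at 0.9 ("minimum" implies
attainable). Multi-mapping reads go to the best-similarity gene, exact
ties split fractionally. There is no spliced or gapped alignment: the
references are transcripts, and the generators produce substitution
noise only.

**Test statistic.** The two-group comparison is a weighted two-sample t
on per-replicate read proportions: group means are weighted by library
size (the inverse-variance weighting for binomial sampling), the
variance of each group mean is estimated from the between-replicate
scatter of the weighted residuals (so biological overdispersion is
respected), and degrees of freedom follow Satterthwaite. This is the
standard proportions-based test family for replicated count libraries;
it is validated in the tests against an exhaustive permutation oracle.
All-zero genes get p = 1 and a flag. BH correction is delegated to
statsmodels.

**Sentinel.** A fold-change denominator of zero is encoded as the ratio
10⁴ (log₂ = 13.2877, printed 13.29), the numerator case symmetrically
negative; both-zero genes are flagged undefined and excluded from
selection and trend fitting.

**Trend normalization.** The screen graphs log₂FC against
log₁₀(max-of-group RPKM) for significant (q < 0.05), defined,
non-sentinel genes, discards ⌊n·0.125⌋ points from each end of the
abundance order, and fits OLS on the middle 75% (376 points retain
exactly 282). The correction subtracts the fitted trend; the published
coefficients (slope 0.411, intercept 2.29) are available as a preset.
When fewer than three usable points exist the screen falls back to the
identity (no correction) rather than to the preset, since a preset
fitted on other data is not evidence about the table at hand. Selection
(q < alpha strict, fold ≥ threshold inclusive) applies to the normalized
fold change by default, with a switch for raw-fold selection.

## Assays

The 4PL is parameterized on log₁₀ concentration with variable Hill
slope; bottom is unconstrained (baselines drift), top is bounded by
1.5× the observed maximum. Initialization takes bottom/top from the
data extremes and the EC50 start from the concentration nearest the
half-range response, with three Hill starts (+1, −1, +3); the best-RSS
solution wins. Non-convergence sets a flag and never raises. A fit is
marked unreliable when |hill| < 0.05 or the fitted log-EC50 sits more
than three decades outside the tested range — the flat-series and
extrapolation failure modes. Replicates are fitted jointly by default
(a `fit_on_means` switch collapses them), and an EC50 confidence
interval is available by within-concentration bootstrap.

ΔΔCt follows the asymmetric-range convention: SEM is computed over the
test-condition ΔCt replicates only, and the reported range
[2^(−(ΔΔCt+SEM)), 2^(−(ΔΔCt−SEM))] therefore brackets RQ
asymmetrically on the linear scale.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic under their seed and serialize ground
truth sufficient to score any downstream stage.

- **Transcriptomes** (default 12 receptors, 8 decoys, 50 background;
  completeness mix 75% complete / 12.5% 5'-truncated / 12.5%
  3'-truncated). Receptors and the GPCR seed set are independently
  mutated copies of a 7TM consensus (21-residue hydrophobic helices,
  10-residue loops with K/R interleaved on the cytoplasmic side, 25/20
  residue tails); decoys and the non-receptor seed set derive from a
  9-helix consensus over disjoint TM and loop alphabets, so they trip
  the naive similarity search while their cross-family E-values stay
  orders of magnitude above the 1e-10 exclusion cutoff. Planted
  proteins avoid methionine so truncated ORFs carry no internal ATG.
  Realism is motif-level: composition and architecture, not
  evolutionary site-rate structure. Passing the mining tests shows the
  filter rules compose correctly on well-separated score
  distributions — not that the miner would resolve borderline real
  families.
- **Similarity blocks**: within-block p log-uniform on [1e-40, 1e-15],
  between-block on [1e-8, 1] at density 0.3 — fully separated at the
  1e-9 threshold, as the cluster-recovery contract assumes; sweeping the
  between-block law across the threshold degrades recovery monotonically
  (property-tested).
- **Count tables** (defaults: 200 genes, 6 vs 6, baseline expectation
  log-uniform over 0.5–3 decades, 10 genes enriched 8-fold, NB
  dispersion 0.05). Totals are 20× the reference-set expectation,
  reflecting that the receptor set is a small slice of each library.
  The abundance-correlated bias adds 0.411·log₁₀(RPKM) − 2.29 log₂
  units to every sexual-group mean — the composition signature the
  trend normalization exists to remove, with the published coefficients
  as the planted truth. With it, roughly three quarters of genes reach
  significance, the significant set is null-dominated, and the fitted
  trend re-centers null genes near zero.
- **Dose-response**: 4PL evaluations on the normalized-response scale
  over eight half-log concentration steps bracketing the EC50, plus
  additive Gaussian noise, clipped to [0, 1]. No plate effects or
  heteroscedasticity.

## Problem sizes

The test suite and the acceptance script run the studies at desk scale:
70-transcript mining runs, 15–23-node similarity graphs (20,000 layout
iterations where a layout is needed), ≤ 13-taxon NJ trees with 100–200
bootstrap replicates, 50 replicate count tables of 200 genes, and
20-seed dose-response recovery. These sizes make every stage's
statistical contract measurable in seconds while leaving the algorithms
identical to what larger inputs would use.

## Known limitations

- The topology predictor is a hydropathy heuristic; real marginal
  helices need external predictions via the override hook.
- The aligner has no iterative refinement; deep alignments should be
  produced externally and imported as FASTA.
- E-value calibration assumes the Karlin–Altschul parameter table;
  only BLOSUM62 gap systems with published parameters are accepted.
- `map_reads` is strand-aware only in the forward sense and ungapped;
  it quantifies transcript-level references, not genomes.
- The DE test assumes ≥ 2 replicates per group and near-binomial
  within-replicate sampling; single-replicate designs are rejected.
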