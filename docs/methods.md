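# Methods

This note documents the models, conventions and numerical choices
behind `ensimito`, and what the synthetic-data checks do and do not
demonstrate.

## Circular genome model and coordinates

A mitogenome is represented as the majority-strand ("J") sequence of a
circular molecule with 1-based inclusive coordinates; a feature whose
`end` is smaller than its `start` wraps through the origin.  Features
on the complementary strand ("N") keep majority-strand coordinate
intervals; their 5' terminus sits at `end`.  The adjacency ledger
records the signed spacer between consecutive features (positive =
intergenic gap, negative = overlap, 0 = abutting), computed on the
circle and mapped into (−L/2, L/2] so short overlaps across the origin
come out negative.  Over any complete circular annotation the ledger
satisfies the closure identity Σ gene lengths + Σ signed spacers =
genome length, exactly; this is asserted in tests on both the bundled
published table and every generated genome.

The bundled reference table transcribes the deposited annotation of
the *Tarragoilus diuturnus* mitogenome (GenBank JQ999995, 16 144 bp,
37 genes + control region in the ancestral arthropod gene order).
Only the printed coordinates are bundled, not the sequence, so
sequence-dependent statistics (A+T percentages, codon usage of the
real genome) require the user to supply the record; all
coordinate-derived statistics work without it.

## PCG boundary assignment

Protein-coding genes are re-bounded with the standard mitogenome
curation rules:

* **Initiation.** Candidate starts are in-frame codons from the ATN +
  NTG set (preference order ATG > ATA > ATT > ATC > GTG > TTG > CTG).
  Within a window of ±15 codons around the draft start, the chosen
  start minimizes the absolute spacer (gap or overlap) to the upstream
  neighbor; ties prefer a gap over an overlap, then the canonical
  start order, then the upstream-most position.  Start overlap into an
  upstream feature is admissible by default because published
  annotations contain such starts (cox1 begins 8 nt inside trnY in the
  reference table); a policy flag can forbid it.
* **Termination.** Scanning in frame for the first full stop (TAA or
  TAG — the only stops of the invertebrate mitochondrial code, table
  5, under which TGA is Trp and AGA/AGG are Ser), the gene keeps the
  full stop unless the stop's three bases would overlap a downstream
  tRNA.  In that case the gene is truncated at the tRNA boundary to
  the longest trailing T or TA (the incomplete stop completed to TAA
  by post-transcriptional polyadenylation); if the trailing bases are
  not T/TA the boundary is reported as unresolvable.  A full stop is
  kept when the downstream neighbor is another PCG (bicistronic pairs
  such as atp8/atp6 and nad4L/nad4 overlap by 7 nt with intact stops).
* tRNA and rRNA boundaries are taken as given and never refined; rRNA
  extents are positional (flanked by tRNAs) in real annotations.

The draft convention is that of ORF-finder output: each PCG's draft 5'
start lies *inside* the gene body in the correct reading frame
(refinement searches outward from there).  Refinement is idempotent,
and the planted-genome round trip (below) recovers truth exactly.

## Composition statistics

A+T content is 100·(A+T)/(A+C+G+T) over unambiguous bases only —
ambiguity codes are excluded from numerator and denominator — rounded
half-up to two decimals, the convention of printed tables.  The codon
census counts all complete codons of every PCG on its coding strand,
excluding full stops and the 1–2 trailing bases of incomplete stops;
start codons count as their encoded amino acid.  RSCU is count/mean
count within the synonymous family (stops excluded); each occupied
family sums to its size.  Note the published totals for this genome
(11 250 bp of PCGs; 3 741 codons) are not derivable from the printed
coordinates, which give 11 223 bp and 3 732 codons; the package
reports coordinate-derived values.

## tRNA cloverleaf folding

Folding is template-constrained combinatorial search, not
thermodynamic: the sequence is assigned to the four-arm cloverleaf by
enumerating arm placements within bounds (acceptor 6–7 bp, DHU 0–4,
anticodon 4–9 with an optional single bulged nucleotide in stems ≥ 8,
TψC 3–6; loops 3–9 nt, connectors 0–3 and 0–2, variable loop 0–9) and
maximizing the number of Watson-Crick + G-U wobble pairs.  The search
decomposes over interface coordinates (acceptor length, anticodon-arm
start and end) so the maximization of the pair count is exact; this is
verified against direct exhaustive enumeration in a test.  Ties are
broken deterministically: more WC pairs, then fewer mismatched rungs,
then no bulge, then canonical arm/connector/loop sizes (acceptor 7,
DHU 4, anticodon 5, T 5, connectors 2 and 1, variable loop 4), then
the smallest layout tuple.  T and U are synonyms throughout.

Two identifiability caveats follow from the scoring itself, and the
generator respects them: a *mismatch at a terminal stem rung* is
notation-equivalent to a shorter stem (the defect sampler therefore
plants mismatches at interior rungs only), and several defects
clustered in one short stem can make a different fold genuinely
higher-scoring (the sampler scatters defects across distinct arms, at
most one per stem, as in observed structures).  For mini DHU arms
(1–2 bp) the generator additionally scrubs accidental pairable
contacts in the DHU window, since a single lucky WC pair elsewhere in
the window would constitute an equally-scoring alternative arm.

Atypical-structure flags use canonical limits: anticodon stem > 5 bp
(`lengthened_anticodon_stem`), T stem > 5 (`extended_T_stem`), DHU ≤ 1
(`mini_DHU_arm`), both connectors absent (`no_connector`), any bulge
(`bulged_stem`) — the serine-AGN-style template triggers
{mini_DHU_arm, lengthened_anticodon_stem, extended_T_stem} plus the
latter two.

## Supermatrix

Per-gene alignments are concatenated with half-open column partitions
tiling the matrix.  Before concatenation the trailing codon triplet of
a codon alignment is removed when any ungapped row ends in a full
stop.  Missing taxa become all-gap rows with a warning.  Alignment
itself is out of scope (the package consumes aligned FASTA).

## GTR+I+Γ maximum likelihood

The substitution model is GTR with stationary frequencies π and six
exchangeabilities (GT fixed to 1), rate matrix scaled to mean rate 1.
Rate heterogeneity is the standard mixture p_inv·δ₀ +
(1−p_inv)·Γ_discrete with four equal-probability gamma categories
whose means come from the incomplete-gamma formula; the gamma rates
are rescaled by 1/(1−p_inv) so the mixture mean is exactly 1 and
branch lengths are expected substitutions per site.

The likelihood is Felsenstein pruning over compressed site patterns
with per-node rescaling; gaps and ambiguity codes are missing data
(partial likelihood 1 for compatible states), giving invariance under
re-rooting and taxon order (both tested).  A brute-force sum over
internal-node states serves as the independent oracle for trees of
≤ 5 taxa.

Branch lengths are optimized coordinate-wise on the exact
one-dimensional profile through each edge: with P(t) = U e^{Λrt} U⁻¹,
the per-site likelihood along one edge is a four-term exponential sum
whose coefficients come from the partials on either side, so a trial
length costs O(patterns × 4).  A sweep refreshes the two pruning
passes once and optimizes every edge on the (slightly stale) profile;
if the exact likelihood fails to improve, the sweep is redone with
per-edge refreshes, so the reported likelihood is monotone
non-decreasing.  Bounds are [10⁻⁸, 10] substitutions/site; the
convergence tolerance is ΔlnL < 10⁻⁴.  Model parameters
(exchangeabilities, α, p_inv, all transformed to unconstrained scale)
are optimized by Nelder-Mead on a fixed tree with a capped evaluation
budget; base frequencies stay empirical, the common practical choice
whose likelihood cost is negligible at these divergences.

Tree search follows the classical recipe: JC distances → BioNJ
(variance-weighted neighbor joining with the λ that minimizes reduced
variance, lowest-index tie-break) → branch/model optimization → greedy
NNI hill-climbing.  Each NNI candidate is scored after re-optimizing
only the rearranged edge — a cheap, tight bound — and the best
improving candidate is fully re-optimized before acceptance; the
search stops when no interchange improves lnL.  Bootstrap resampling
is column-wise by default (codon-blind), with a codon-block option;
model parameters are estimated once on the original matrix and held
fixed across replicates, and each replicate reruns BioNJ + NNI from
scratch.  Majority-rule consensus keeps splits above the threshold
(default 0.5) with percentage supports; RF distance is the symmetric
difference of split sets (both cross-checked against dendropy).
Bayesian inference is intentionally not implemented; the published
Bayesian topology is used only as a comparison point for the ML
result.

## Synthetic data: what it emulates, and what it does not

`generate_mitogenome` plants a complete annotated genome whose layout
(gene order, strands, lengths, signed spacers, start/stop codon
choices, anticodons) defaults to the published reference table, with
A+T fraction 0.70 — the orthopteran ballpark — random gene bodies free
of in-frame stops, cloverleaf-built tRNAs, low-complexity control
region with tandem repeats (55 bp unit × 8 copies by default), and a
deterministic constraint-repair pass guaranteeing that boundary
refinement recovers the planted truth: no decoy in-frame start codon
ties or beats the planted start's spacer, including inside overlapped
or fixed regions.  One global seed drives per-stage/per-gene sub-seeds
(`SeedSequence.spawn`), so regeneration is stable.

`simulate_alignment` evolves sites along a tree under GTR+I+Γ with
per-site category assignments recorded.  The recovery study simulates
17 taxa × 13 000 sites — the shape of a 13-PCG + 2-rRNA mitogenomic
supermatrix — under an AT-rich, transition-biased GTR (π = 0.35/0.17/
0.11/0.37; exchangeabilities 1.5, 6.0, 1.2, 1.0, 8.0, 1.0; α = 0.5,
p_inv = 0.2) on random topologies with internal branches 0.03–0.12 and
terminals 0.05–0.30 substitutions/site.  The four-superfamily check
simulates on (Grylloidea,(Tettigonioidea,(Hagloidea,
Rhaphidophoroidea))) with two outgroup taxa, internal branches 0.06,
at 3 000 sites — a deliberately scaled-down stand-in for the real
17-taxon analysis, chosen to keep the whole validation suite
single-CPU friendly.

What passing these checks shows: the implementation's arithmetic,
search and estimators are correct on data generated *by the model the
method assumes*.  What they do not show: robustness to alignment
error, compositional heterogeneity across lineages, selection, or
model misspecification — real mitogenome data violate all of these to
some degree, and the original 13 416-site ensiferan dataset rests on
undeposited alignments that cannot be reconstructed from public
records alone, which is why its likelihood score is not a reproduction
target here.

## Degenerate inputs and edge behavior

Saturated distance pairs (p ≥ 0.75) are capped at 5 substitutions/site
with a warning.  Zero-length branches and t = 0 transition matrices
are exact (identity).  Folding returns a failure flag (None) rather
than raising when no arm placement fits the bounds.  Feature-table
parse errors carry line numbers.  Empty tables, taxon-set mismatches,
duplicate names and malformed matrices raise typed errors.

## Known limitations

The annotation round trip guarantees recovery only for drafts that
preserve reading frame and overshoot inward, the normal failure mode
of ORF drafts; frame-shifted drafts are out of contract.  The
cloverleaf search is structural, not energetic, so it can differ from
hand-drawn structures in ways the atypical flags summarize; the
published totals of 30 G-U and 15 mismatches over the real 22 tRNAs
are treated as a qualitative cross-check, not an exact target.  The ML
engine is single-threaded and in-memory; it is sized for tens of taxa
and tens of thousands of sites, not genome-scale matrices.
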