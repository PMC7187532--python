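# Methods

This note records the models, conventions and design choices behind
circkit, in the order data flows through the pipeline.

## Coordinates and identity

All internal coordinates are 0-based half-open `[start, end)`. GTF input
(1-based closed) is converted on read; BED passes through. A circRNA's
identity is its back-splice junction: `(chrom, start, end, strand)`,
canonically `"chrom:start|end:strand"`. Strand `.` is rejected for BSJ
calls (strand is part of circRNA identity) but tolerated for repeats and
CLIP peaks, whose overlap tests are strand-agnostic.

## Consensus calling

A locus is retained when detected by at least `min_tools` (default 2)
distinct tools and supported by at least `min_reads` (default 2) BSJ
reads. Two interpretation choices are deliberate:

- **Within a sample, reads aggregate across tools by maximum, not sum.**
  Two detectors inspecting the same library see the same fragments;
  summing would double-count. The maximum is the largest set of distinct
  junction-spanning fragments any one detector evidenced, a conservative
  reading of "independent BSJ reads".
- **`min_reads` applies to the total over samples** (dataset-level
  phrasing); `per_sample_reads=True` switches to requiring one sample to
  reach the threshold alone.

`coordinate_slack` (default 0) optionally chains calls whose endpoints
each differ by ≤ slack bp into one locus before filtering; the default is
exact agreement because no slack convention is universal among detectors.

Expression is FPM = reads / (mapped fragments / 10⁶), linear in reads;
absent (locus, sample) pairs are 0.

## Classification

Host gene: the same-strand gene whose span contains both BSJ coordinates;
failing that, an opposite-strand containing gene (orientation antisense);
else intergenic. Ties go to the gene with the largest exonic overlap with
the circle, then lexicographic gene id — both tie-breaks are conventions,
chosen for determinism.

Subclass cascade: intergenic → antisense → 5utr → 3utr → exonic →
intronic. UTR classes outrank exonic so that UTR-derived circles are
counted separately from plain exonic ones. The exonic test is lenient by
default (both junction bases inside exons); strict mode additionally
requires both coordinates to coincide with annotated splice sites and is
surfaced as the `boundary_exact` flag — off-boundary exon circles keep
the exonic label either way, since every circle must receive exactly one
of the six labels. A circle spanning an exon/intron boundary that matches
no test is labeled exonic (it contains exonic sequence). Flanking introns
are taken from the transcript maximizing boundary agreement then exonic
overlap with the circle; `non_repeat` is defined only when both flanking
introns exist, and is true iff neither overlaps a repeat interval —
adding repeats can only flip it true → false.

IDs: `<species>-<symbol>_<NNNN>` with the ordinal ranking the gene's
circles by MCS descending (ties by coordinates); circles without a gene
symbol fall back to `<species>-<locus key>`.

Circular ORFs are scanned on the circularized sequence for up to three
laps (a rolling-circle translation bound); reported ORFs are maximal (one
per stop codon position, the earliest ATG after the previous stop), with
`spans_bsj` marking junction-crossing reads and `no_stop` marking
stop-free frames reported at the 3-lap cap.

## Ortholog detection

The search space is first restricted to orthologous host-gene pairs in
which both genes express circles; within each pair the full circle cross
product is considered. Each BSJ is represented by up to 50 nt of cirexon
sequence on each side of the junction, concatenated donor-side first in
mature-transcript 5′→3′ orientation (reverse-complemented for − strand
circles), i.e. exactly what a junction-spanning read shows. Flanks never
extend outside the circle or into introns; short terminal cirexons simply
yield shorter flanks (recorded per side, minimum total 2 nt).

Flank pairs are aligned with an optimal Smith–Waterman local aligner
(match +1, mismatch −1, gap open −2, extend −1; Biopython's
PairwiseAligner provides the DP). At ≤ 100 nt queries optimality is cheap
and removes any external aligner binary. Identity is matched columns over
alignment columns of one optimal alignment. A pair is a reciprocal best
hit when each side is the other's *unique* top-scoring candidate and the
hit passes `min_identity` 0.7 and `min_aln_len` 60 (defaults chosen to
demand most of the 100 nt flank aligns at high identity; both are
config-exposed since no published cutoffs exist). Ties for best are
disqualifying — ambiguity is treated as absence of evidence.

Pairwise RBH sets over ≥ 2 species are integrated on the RBH graph. Per
connected component the builder selects member sets with ≤ 1 circle per
species, every member supported by ≥ 1 retained edge, maximizing the
summed pairwise score; components of ≤ 10 nodes are solved exactly by
subset enumeration (so small components provably attain the maximum),
larger ones by greedy descending-score edge merging. Extracted groups are
removed and the remainder re-solved; leftover circles become singleton
groups. A member's species conservation count is N_s = group size − 1
(the number of orthologs); a config switch counts species (group size)
instead, since both readings of "ortholog number" appear in practice.

Advisory cirexon-boundary verification maps each circle through the
pairwise genome coordinate map (ungapped blocks, strand-aware endpoint
arithmetic); the boolean is recorded on the pair but does not reject it,
because no rejection rule is defensible when the map and the annotation
disagree for alignment-quality reasons.

## Multiple Conservation Score

MCS = N_s + N_t × N_i. The expression tree has one node per tissue and
one per (tissue, individual); an individual node is marked when any of
its samples exceeds the expression threshold (default FPM > 0 — any
supported junction read counts, since consensus already imposed the
evidence filter), and a tissue node when any of its individuals is
marked. N_t is the marked fraction of the tissue layer; N_i is
(marked tissue + marked individual nodes) / (2 × individuals belonging to
marked tissues). Both lie in [0, 1], so MCS ∈ [N_s, N_s + 1]; with k
individuals per tissue N_i is at most (1 + k)/(2k), reaching 1.0 only in
single-individual designs. The degenerate N_t × N_i = 1.0 case is not
clamped and components are always reported, keeping the integer/decimal
decomposition recoverable. N_i is undefined for an unexpressed circle;
the decimal part is set to 0 upstream in that case.

Tissue specificity uses Yanai's τ = Σ(1 − x_i/x_max)/(N − 1) over
per-tissue means — the field-standard index. The junction ratio is
2·BSJ/(2·BSJ + linear), the CIRI-family convention (a BSJ read evidences
two junction passages); linear junction reads are an input, not
recomputed.

## Annotation network

Co-expression is computed over **per-tissue mean** expression so the
≥ 3-expressed-tissues node filter and the correlation act on the same
axis. The r ≥ 0.5 filter is one-sided — the aim is removing weak
correlation, and anticorrelated partners are not co-expression evidence —
with `keep_anticorrelated` restoring |r| ≥ 0.5. Constant profiles have
undefined r and are skipped with a warning.

miRNA sites use the canonical seed classes: a 6mer core matching miRNA
positions 2–7, upgraded to 7mer-m8 by a position-8 match, to 7mer-A1 by
an A opposite position 1, and to 8mer by both; each position reports its
most specific class. The scan runs on the circular sequence extended by
its own first 8 nt so sites straddling the BSJ are found. External
target predictions import as TSV and combine with internal calls by
union (default, emulating a multi-tool ensemble) or intersection.

RBP edges connect a circle to an RBP when a CLIP peak overlaps the ±1 kb
window around either BSJ coordinate; peak count and minimum distance to
the nearer junction are recorded. Function propagation tests each
circle's neighbor gene set per term with the hypergeometric upper tail
P(X ≥ k) against the network's annotated gene universe, BH-corrected per
circle. Hypergeometric + BH is a choice — no statistic is canonical for
neighbor-based annotation transfer — picked for its exactness at the
small neighborhood sizes typical here.

## Synthetic fixtures

The generator emulates a multi-species, multi-tissue profiling study at
desk scale: 3 species (of a 6-species code table), 8 genes × 4 exons
each (120 nt exons, 90 nt introns), the 19-tissue panel of a typical
vertebrate atlas with 3 individuals per tissue, one sample per
individual, ~10⁶ mapped fragments per sample. The first genome is
random; the others derive from it by per-base substitution at the flank
divergence rate (default 5%, a plausible within-mammal exonic distance)
with identity-plus-offset coordinate maps, so ortholog truth is exact by
construction. Planted circles cover every subclass, a flanking-intron
repeat, an 8mer seed site, near- and far-BSJ CLIP peaks, housekeeping
(exactly uniform, τ = 0) and single-tissue (τ = 1) expression profiles,
and a co-expressed circle–mRNA pair sharing a latent tissue profile with
3% multiplicative noise (population r ≥ 0.9). Detector evidence is
simulated at the call level: per-tool sensitivities 0.95/0.90/0.90/0.85,
read counts 1 + Poisson(mean − 1) with mean 8, and decoy single-tool
single-read calls (the false-positive mode the two-tool filter targets)
at rate 0.05 per truth circle per sample. Every draw flows from one seed;
two runs produce byte-identical files.

The 19-tissue width is kept at full scale deliberately: the null
false-edge rate of an r ≥ 0.5 filter depends on the number of tissue
points (with 6 tissues the chance correlation of independent profiles
exceeds 10%; with 19 it is ~1–2%), so narrowing the tissue panel would
change the statistical regime the co-expression filter operates in.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level errors and coverage biases (evidence
is simulated at the call level), alternative splicing and overlapping
genes, indels and rearrangements between genomes (an indel-free map keeps
liftover truth exact; divergence is substitution-only), repeat-driven
false ortholog hits, and the heavy-tailed, batch-confounded expression
structure of real cohorts.

## Problem sizes and numerics

Test and acceptance runs use the bundle defaults above (10 planted
circles per species, ~500 calls per species, 57 samples per species),
200 random call sets for the consensus oracle, 200 random pairs ≤ 12 nt
for the aligner oracle, 100 replicates for the co-expression null, and
10⁵ draws for the Monte-Carlo hypergeometric check — sizes at which the
exhaustive oracles are exact and the whole suite runs in seconds.
Floating-point comparisons in tests use relative tolerance ~1e-6 except
the closed-form hypergeometric case (1e-12). Determinism relies on
sorted iteration everywhere a dict or set feeds output.

## Known limitations

- The ortholog group builder's greedy fallback (components > 10 nodes) is
  not guaranteed optimal; real atlas-scale components can exceed the
  exact solver's range.
- Flank extraction requires annotated cirexons; intronic and intergenic
  circles are excluded from conservation analysis by construction.
- IRES prediction, full-length isoform reconstruction, detector error
  modeling (FDR) and disease-database integration are out of scope.
- The seed-site scanner implements canonical seed pairing only; no
  thermodynamic or context scoring.
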