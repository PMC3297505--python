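# Methods

This note records the models, parameter choices and numerical decisions
behind `nlrscan`, and what the synthetic-data experiments do and do not
demonstrate.

## Motif scoring and the combined E-value

Each of the 20 packaged motif consensi becomes a position score matrix: the
BLOSUM62 substitution row of the consensus residue at each position (integer
log-odds against background frequencies).  Scanning slides the matrix along
the protein; a window's p-value is the exact tail probability of its total
score under i.i.d. background residues (Robinson–Robinson frequencies),
computed once per motif by dynamic-programming convolution over the integer
score support.  This replaces the position-specific probability models of a
motif-discovery tool, which are not recoverable from printed consensi; it is
exact, deterministic and needs no sampling.  Columns for the two
translation-specific symbols are fixed: `X` (unknown/ambiguous) scores 0 at
every position, `*` (stop codon in conceptual translations) scores the row
minimum.

Per-protein evidence combines the best hit of each of the 18 non-monocot
motifs (the two monocot-specific motifs are scanned and reported but carry
no weight in statistics or classification, since they are not diagnostic in
a dicot context).  Before combination, each best-window p-value is corrected
for the number of windows scanned, `p = min(1, p_window * n_windows)`, so an
unrelated protein scores approximately uniform per motif regardless of its
length — the behaviour a sequence-database search statistic needs.  The
combined probability is Fisher's method, `X = -2 * sum(ln p_m)` against a
chi-square with `2k` degrees of freedom, and `E = P_combined * N` with `N`
the number of sequences scored in the run.

Two numerical points.  First, genuine NB-LRRs combine 10+ near-exact motifs
and their combined probabilities underflow double precision; all threshold
comparisons therefore run on `log10 E`, computed from the chi-square
log-survival function, with a custom asymptotic tail expansion where scipy's
underflows.  The linear `e_value` field (which may underflow to exactly 0)
is kept because `E = P * N` is the reporting contract, and it makes the
"doubling the database doubles E" identity exact.  Second, the per-window
hit report cutoff (default `1e-4` on the raw window p-value) is distinct
from the presence cutoff used for classification and completeness decisions,
which applies `1e-4` on the *window-count-corrected* scale — presence calls
must have a per-sequence false rate near the cutoff, or a 600-residue
protein would accumulate roughly one spurious motif per scan.

## Calibration and triage

Thresholds are order statistics of training-set E-values: `t_strict` is the
largest positive E, `t_main` the smallest negative E, and the calibration is
"specific" when every positive falls below every negative.  Candidates with
`E >= 2` are rejected outright; below the cap, `E < t_main` accepts (below
`t_strict`, strictly); between `t_main` and the cap a candidate survives
only by the rescue rule — at least two distinct TIR/CC-class motifs
({13, 15, 18} ∪ {16, 17}) or three distinct NB-ARC-class motifs
({1, 2, 3, 4, 5, 6, 10, 12}) present at the corrected cutoff.  Distinct
motifs are counted, not hits, so tandem LRR repeats cannot trigger a rescue,
and motif order is ignored (truncated loci legitimately present partial,
shuffled-looking patterns).  Non-rejected transcripts collapse to genes via
GFF3 Parent attributes; proteins without a Parent count as single-transcript
genes.

## Re-annotation

Candidate models are clip-extended by 3 kb (configurable) on both sides and
conceptually translated in six frames (ambiguous codons to `X`, stops to
`*`).  Interpreting a six-frame scan of a multi-kilobase region needs two
guards, both biologically motivated:

* **ORF co-occurrence.** A hit only supports a gene structure if its open
  reading frame (stop-free stretch of one frame) carries a second distinct
  motif, or the hit alone is overwhelming (p <= 1e-8).  Genuine domains of
  one receptor co-occur within one ORF; scattered chance hits do not.
* **Strong-hit decisions.** Structural *decisions* — where to split a
  double model, whether adjacent models are complementary, whether a frame
  change is an intron — are taken on hits with p <= 1e-8 only.  Weaker hits
  ride along as supporting evidence but cannot create structure, because
  cross-matches between related motifs (e.g. two LRR motifs, or an NB-ARC
  motif against a TIR region) reach p ≈ 1e-5 routinely.

A model is split in two when the canonical motif series (N-terminal
anchors → P-loop → NB-ARC series → linker → LRR) restarts at an
N-terminal/P-loop anchor after a complete tail, and the remainder reaches a
tail again.  Two adjacent models (same scaffold and strand, gap <= 10 kb)
merge when their series are complementary: each canonically non-decreasing,
the upstream one ending no later in the series than the downstream one
begins, with at least four distinct motifs in the union.  Consecutive
same-frame hits with no intervening in-frame stop join one CDS segment; a
frame change across >= 60 bp (a minimal intron length; plant introns are
rarely shorter) counts an intron, a shorter frame change or an in-frame stop
a frameshift.  The re-annotated protein is read off the segment
translations, with the first/last segment extended to the bounding stop
codons so N-terminal domains upstream of the first motif (a coiled coil) are
recovered; for split models the extension stops at the partner's boundary.

Same-frame introns whose two exons happen to restore the reading frame are
not detectable by this rule and are undercounted — resolving them requires
homology evidence, which is out of scope.  Completeness requires the NB-ARC
core (P-loop, Kin-2, RNBS-B, RNBS-C, GLPL) plus an LRR motif (plus a TIR
motif for TNLs); with all present, a gene is full length when intron-free or
when it has at most two introns and no frameshift, otherwise potentially
full length; a missing requirement makes it partial.

Whether to trust the original protein or the rebuilt one is decided by
evidence: if the re-scan reveals no motifs beyond the original annotated
protein's, the original model and protein are kept unchanged.

## Classification

TIR-motif presence is the primary TNL/CNL rule; the residue aligned to the
final Kin-2 consensus column (aspartate in TNLs, tryptophan in CNLs)
cross-checks it, and disagreement flags the gene without changing the call.
We read "final position of Kin-2" as the last aligned column of the motif-4
hit; an alternative fixed-offset reading is possible but indistinguishable
here because the hit spans the full consensus.  A gene with no TIR motif, no
Kin-2 hit and none of the CNL-specific motifs {2, 6, 16, 17} is
`unresolved` (the atypical, ADR1-like situation).

Coiled-coil presence is scored by a heptad-register propensity scanner:
every 28-residue window (four heptads) is scored under all seven registers
from a fixed 7 x 20 propensity table (aliphatic hydrophobics rewarded at
core positions a/d, charged residues at flanks e/g, proline penalised
everywhere), and the best window among starts within the first 98 residues
is mapped to a p-score through a packaged empirical null — the best-window
scores of 4000 simulated background proteins of length 300 (frozen in
`data/cc_null.json`; regenerable with `classify.simulate_cc_null`).  The
published operating point (p <= 0.047, start <= 98) is applied to that
p-score.  This scanner is a deliberately simple stand-in for a
full coiled-coil predictor: it reproduces threshold semantics and separates
ideal heptad repeats from background by construction, but its p-scores are
not comparable to any external tool's, so a table of externally computed
predictions can be supplied and is then used verbatim.

Subtypes follow the class, the coiled-coil call and LRR-motif presence:
TIR-NB(-LRR) for TNLs; CC-NB(-LRR), NB-LRR or NB-ARC for CNLs.  Reference
R-gene homology uses local pairwise alignment (BLOSUM62, gap open -11,
extend -1); identity is matches over aligned columns, gaps excluded, and
labels require > 80 %.

## Phylogeny and subgroups

The NB-ARC region — first to last NB-ARC-class motif hit on the final
protein — is the alignable core.  Regions with ambiguity characters are
removed; the reference length is the median NB-ARC length among full-length
genes, and regions shorter than 50 % of it are excluded (boundary
inclusive).  The alignment fixes NB-ARC motifs hit in every sequence as
ungapped anchor blocks in canonical order and aligns inter-anchor segments
progressively (mafft); distances are Poisson-corrected mismatch proportions
under pairwise gap deletion, topology is neighbour joining, and supports are
the percentage of 100 column-bootstrap replicates containing each
bipartition.  Trees are midpoint-rooted before clade enumeration — NJ's
arbitrary rooting can otherwise land inside a clade of interest and hide it
from rooted traversal.

Subgroups are maximal clades with support >= 70 and patristic diameter
<= `max_diameter`, chosen greedily from the root down.  The diameter default
is 0.4 substitutions/site.  The notion being formalised is a "highly
conserved subgroup": a clade of recently duplicated genes, which under this
distance pipeline sits at diameters well below ~0.2, while distinct lineages
sit above ~0.6 — progressive alignment plus pairwise deletion compresses the
apparent divergence of unrelated inter-motif segments, so distances between
unrelated NB-ARCs saturate near 0.6–1.0 rather than the naive expectation.
0.4 splits that gap; anyone preferring a looser or stricter notion can set
the bound per run, and cluster-homogeneity fallback uses the same value.

## Physical clustering

Genes project to pseudomolecule coordinates through the placement table
(minus-oriented scaffolds reverse intra-scaffold coordinates and strands).
Two neighbouring NB-LRRs chain when their nearest-end distance is strictly
under 200 kb AND strictly fewer than 8 annotated non-NB-LRR genes lie fully
between their spans; both bounds are configurable, and the strict "<8"
reading is used where the sources of the rule disagree on "no more than"
versus "fewer than".  Nearest-end distance makes the rule invariant to gene
length; intervening genes are counted strand-blind.  Spacer sequence between
scaffolds contributes to distance, so genes on different scaffolds of one
pseudomolecule can, in principle, chain across a 50 kb spacer — a caveat
inherited from pseudomolecule-space analysis.  Singletons are not clusters;
cluster ids are C1..Cn in genome order.  A cluster is homogeneous when all
members share one subgroup label; members absent from the tree fall back to
pairwise patristic distances against the same diameter bound.

## Density landscape

Gene density is the count of gene midpoints in a 250 kb window centred on
the gene's midpoint, per Mb; repeat density is the fraction of the window
covered by the union of repeat intervals (a per-Mb feature-count alternative
is available via `repeat_measure="count"`).  Only the parent scaffold is
used and windows extending beyond it are omitted, because inter-scaffold
spacers are not real sequence.  The genome-wide landscape is binned
200 x 200 and a two-component Gaussian mixture is fitted by EM to the bin
centres weighted by counts (realised by count repetition; best of 10 seeded
restarts, tolerance 1e-6).  Outliers are NB-LRRs whose mixture density falls
below the density threshold enclosing 99 % of the mixture mass, computed as
a seeded Monte-Carlo quantile (100 000 draws); `mass_level >= 1` flags
nothing by convention.

## The synthetic genome

The generator is the package's experimental ground: it emulates the
structure of a draft annotation, not molecular evolution.  Default
conditions: six superscaffolds (0.6–1.4 Mb) split into gene-rich
(100 genes/Mb, 10 % repeat coverage) and gene-poor (30 genes/Mb, 45 %)
halves; ~350 background decoy genes (random background-frequency proteins,
150–450 aa); eight NB-LRR lineages (five CNL, three of them with an ideal
N-terminal coiled coil; three TNL) with 1–5 tandem copies at 20–40 kb
spacing and 0–3 intervening decoys; one deliberately heterogeneous
two-member cluster mixing a CNL and a TNL lineage; five scaffolds placed on
three pseudomolecules with 50 kb spacers (one scaffold left unplaced); and
the annotation defects the re-annotation stage exists for — three models
trimmed so that all but the first two N-terminal motifs lie outside the
model (within the 3 kb flank), two genuinely truncated receptors ending at
GLPL, one model containing two complete receptors in a single reading frame,
and one receptor split across two exactly adjacent models.

NLR proteins concatenate the packaged consensi in canonical order (the CNL
Kin-2 variant ends in W) with per-lineage random linkers (15–40 aa);
lineage founders mutate the class template at 0.20 per site, tandem copies
the founder at 0.04, training positives at 0.02.  Mutation never touches the
first and last position of each motif (two anchors per motif), so extreme
draws cannot erase identifiability under the default conditions; passing
`protect_anchors=False` gives a harder regime for stress testing.

Training negatives are kinase/PRR-like decoys: a Walker-A-like island (a
mutated P-loop consensus, mutation rate uniform on 0.10–0.40), half with an
additional Walker-B-like island, and two APAF-like sequences carrying three
*exact* NB-ARC-like islands (P-loop, Kin-2, RNBS-B).  The APAF-like pair
pins the negative minimum.  The regime was chosen once from the chi-square
tail arithmetic of the combined statistic: with ~600 database sequences,
random decoys score E ≈ 10^2, three exact islands E ≈ 10^-24, trimmed
two-motif models E ≈ 10^-24±3 … 10^-27, intact mutated receptors
E ≈ 10^-150, training positives E ≈ 10^-300.  This ordering reproduces the
operating regime the method was designed around — positives far below every
negative (100 % specificity), intact receptors accepted outright, trimmed
models above the negative minimum and recoverable only through rescue plus
extension, random decoys rejected by the E < 2 cap.

What passing tests show: under these conditions the pipeline attains
identification recall and precision 1.0, class accuracy 1.0, exact recovery
of all planted clusters, correct homogeneity labels, and loses exactly the
trimmed models when extension is disabled.  What they do not show: behaviour
under real splice structure (planted genes are intron-free), real repeat
families, real NLR sequence evolution (indels, domain swaps, pseudogene
decay), or transferability of the coiled-coil p-score to real predictors.
The per-copy completeness calls can occasionally miss a weakly matching
NB-ARC core motif in a heavily mutated copy and downgrade full length to
partial; completeness accuracy is therefore asserted at >= 0.85, not 1.0.

## Problem sizes and determinism

The default study runs ~380 gene models, ~520 scanned proteins, 26 planted
receptors, 100 bootstrap replicates on ~26 NB-ARC regions, and a 200 x 200
mixture fit on ~250 density points; a full pipeline run takes seconds on one
CPU, and the acceptance script regenerates its quantities from scratch in
under a minute.  All randomness flows from the single run seed; repeated
runs produce byte-identical output files (tables are written with fixed
float formatting, figures as templated SVG text).
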