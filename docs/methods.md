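# Methods

## The screen being modelled

An inducible-synthetic-promoter (iSynPro) library is built by blunt-end
ligation of a small vocabulary of transcription-factor response elements
(TREs) — here eleven elements, with the NF-κB element at a 3:1 molar
excess over each other element (weights 6 and 2) — followed by gel size
selection of 200–500 bp concatemers. The library rides through a plasmid
cloning bottleneck, lentiviral packaging, and a functional selection in
CAR T cells: GFP⁺ cells are sorted 24, 48 and 72 h after tumour
co-culture and once more after restimulation, and each sorted population
is sequenced as a 300 bp paired-end amplicon with ~30 nt invariant
flanks around the variable promoter.

The analysis problem is reference-free: templates vary in length and are
concatemers over a tiny alphabet. The pipeline therefore (1)
reconstructs each template from its read pair, (2) renders it as a
string over the TRE alphabet, and (3) treats the contig string as the
clone identity for all quantification, trajectory and enrichment
analysis.

## Template reconstruction (merge)

The reverse-complemented mate is slid against read 1 over every offset
with at least `min_overlap` (default 20) nt of geometric overlap,
including read-through offsets. Each offset scores matches − mismatches
in the overlap; the best offset is accepted if its overlap mismatch rate
is ≤ `max_mismatch_rate` (default 0.10). Exact score ties are rejected
(`tie`) rather than resolved arbitrarily: with a periodic concatemer an
arbitrary choice could create a chimeric clone and silently inflate
counts. When no admissible offset exists, or the best score is ≤ 0
(matches no better than mismatches, i.e. no evidence of a true overlap),
the pair is rejected as `no_overlap`; an overlap exceeding the mismatch
cap but with positive score is `too_many_mismatches`.

Consensus bases: agreement keeps the base with quality
min(q₁ + q₂, 41); disagreement keeps the higher-quality base with
quality |q₁ − q₂| (read 1 wins exact quality ties). The model is
gap-free — amplicon MiSeq data are substitution-dominated — and indels
are instead absorbed downstream by the edit-distance caller.

## TRE calling (segmentation)

Flanks are located by semi-global edit-distance search (edlib) within
`max_flank_edits` (default 3) near each end and removed; either side can
be skipped for libraries primed past the flank. The interior is then
segmented by a dynamic program over positions: each transition consumes
one whole TRE block in + or − orientation at cost equal to its edit
distance (capped at ⌈block length / 8⌉ per block, so a 10-mer tolerates
1 edit), or one unannotated base at cost 1.5. The per-block cap scales
with length so short elements are not over-permissive; the unannotated
penalty exceeds one block edit so the program prefers a slightly
imperfect block over a hole. The optimum is decoded left to right with
deterministic tie-breaking: fewer unresolved bases, then longer block,
then + orientation, then alphabetical code. Calls with more than
`max_unresolved_frac` (default 0.1) of the interior unannotated are
rejected.

Orientation is recorded per block but collapsed for counting (a contig
is its letter string); `keep_orientation` renders minus-strand blocks in
lowercase instead. Blocks tile without overlap, matching the abutting
geometry of blunt ligation.

The implementation prefilters candidate block ends with a vectorised
semi-global DP per oriented block (free start, one row per block base),
refines the sparse admissible (end, block) pairs with banded edit
distances, and only then runs the tiling DP — about 5 ms per 500 nt
template, and identical sequences in a sample are called once.

## Quantification

Identical contig strings aggregate into a contig × sample count matrix;
frequencies and CPM are per-column normalisations. Clonality uses the
Lorenz curve over distinct clones (ascending counts, clone share on x,
read share on y) and Gini = 1 − 2·AUC (trapezoidal); clones absent from
a sample are excluded. Library similarity is the Pearson correlation of
log₁₀ frequencies over contigs detected in either sample, with a
Haldane-style pseudo-frequency of 0.5 reads. TRE composition per sample
is the count-weighted letter fraction; its coefficient of variation
(sd/mean, ddof = 1) across the sorted-cell samples summarises
compositional stability. Length comparisons are count-weighted
Mann-Whitney U tests on contig length in TRE units.

## Trajectories, clusterability, clustering

Each contig's behaviour is log₂((CPM_t + c)/(CPM_virus + c)) at the four
post-stimulation timepoints, with pseudo-CPM c = 0.5; the lentiviral
library is the baseline. Contigs below 4 CPM at *every* post-stimulation
timepoint are discarded ("minimally detected"); the stricter
require-at-every-timepoint reading is available as `detect_mode="all"`.
Restimulation is part of the feature vector by default.

Clusterability uses the Hopkins statistic: m probe points uniform over
the data's bounding box and m data points sampled without replacement;
H = Σuᵈ/(Σuᵈ + Σwᵈ) with u the probe→nearest-data and w the
data→nearest-other-data distances, d the dimension, m defaulting to 10%
of n; one-sided p = P(Beta(m, m) ≥ H). Distances are computed on the
torus obtained by wrapping the bounding box (periodic boundary
conditions). This edge correction matters: in a bounded box the
truncation of nearest-neighbour balls makes d-th-power distances
non-exponential, and the Beta(m, m) null is visibly mis-calibrated at
n = 200, d = 4 (KS distance ≈ 0.11 against uniform p-values); on the
torus the null is exact to sampling error (KS ≈ 0.03) with no loss of
power on clustered data.

Clustering is Ward hierarchical agglomeration on Euclidean distances
between log₂ fold-change vectors (deterministic; seeded k-means as an
alternative), with k chosen by maximal mean silhouette over 2..15.
All-identical trajectories are reported as a degenerate single cluster.

## Enrichment and candidate selection

Features are single TREs (k = 1) or ordered contiguous k-letter motifs
(default k = 3), scored as presence/absence per contig; reverse-order
motifs are distinct and orientation is collapsed. For every cluster ×
feature with at least one in-cluster occurrence, a one-sided Fisher
exact test (alternative "greater") on the 2×2 presence table gives p;
Benjamini-Hochberg correction is applied within each feature family
across all cluster × feature tests. Note that with ~35-block contigs
single-TRE presence saturates (nearly every contig contains every
letter), so k = 1 enrichment has little power at these lengths — an
inherent property of presence-based testing on long concatemers.

Candidates must pass three rules: (i) baseline viral frequency ≥ 0.001;
(ii) linear fold change (CPM_t + c)/(CPM_virus + c) > 1.25 at ≥ 2
post-stimulation timepoints (log-scale thresholding available);
(iii) membership in the smallest descending-frequency prefix of the
pooled cell library reaching 90% cumulative frequency, with boundary
ties included. "Multiple time points" is read as ≥ 2 of 4, and the cell
library is pooled across all sorted samples; both are configurable.

## The synthetic-data generator

The generator is the stand-in for the screen's unreleased FASTQ data and
defines the study conditions used throughout the tests:

* **Ligation**: block codes i.i.d. proportional to ligation weight
  (6 : 2 × 10), orientations fair coins, block count geometric with mean
  35 (mean interior ≈ 350 nt over the fixture's ≈ 10 nt blocks),
  products outside 200–500 nt redrawn. NruI/XbaI linker blocks are not
  modelled: they carry no TRE information and the default treats them as
  terminal-only cloning scars outside the called interior.
* **Bottlenecks**: 2000 unique raw templates; a plasmid bottleneck keeps
  300 clones with Dirichlet(α = 0.7) abundance skew (the observed skew's
  law is not known; a single-α Dirichlet-multinomial is the simplest
  clonal-expansion model). Lentiviral packaging reweights by
  exp(−0.002 · nt length), an exponential form chosen because only the
  direction (shorter favoured) is known; it yields a ≈ 1.3 TRE-unit mean
  shortening of the virus library.
* **Selection dynamics**: per-clone per-timepoint multipliers applied to
  the viral frequencies, then multinomial sampling at 10⁵ reads/sample.
  Default planting: 15 inducible clones (multiplier 3–6 at all four cell
  timepoints, drawn preferentially from NF-κB-rich contigs with baseline
  ≥ 0.002) and 30% mildly depleted clones (×0.5–0.8 from 48 h on),
  mirroring a screen in which most promoters fade and a few are
  enriched.
* **Reads**: 300 bp pairs from the template ends (truncated to template
  length, emulating upstream adapter trimming), substitution-only errors
  at 0.5% (amplicon MiSeq regime; keeping indels out of the generator
  makes round-trip tests exact while the caller still tolerates indels),
  Gaussian Phred qualities (mean 35, sd 3, clipped to [2, 40]).
  Ground-truth template identity lives in a sidecar TSV, never in read
  names.

All randomness flows from one seed (per-stage seeds via
`numpy.random.SeedSequence.spawn`), and equal seeds give byte-identical
outputs.

What the generator does **not** emulate: PCR duplicates and chimeras,
quality-by-cycle decay, PhiX spike-ins, indel sequencing errors, the
custom asymmetric read-1 primer of the real protocol (handled instead by
configurable flank skipping), or any coupling between promoter length
and selection beyond what the NF-κB-preference planting induces. Passing
tests therefore demonstrate correctness of the algorithms under a
substitution-noise amplicon model with known ground truth — not
performance on the original instrument data.

## Degenerate inputs and numerical choices

Empty samples produce empty tables and zero-count reports; single-clone
samples give Gini 0; all-identical trajectories return one cluster;
zero-variance length comparisons report p = 1; contigs absent from the
baseline get finite fold changes through the pseudo-CPM. Merge costs and
DP costs are exact in binary floating point (edit costs are integers,
the gap penalty 1.5 is dyadic), so tie-breaking is reproducible across
platforms.

## Problem sizes

The bundled tests and the acceptance script run read-level checks on
1000-template corpora (one pair per template) and screen-level checks at
2000 templates × 10⁵ reads × 7 samples at the count level, with 10
independent screens for the selection-fidelity average — sizes at which
every planted effect is comfortably detectable on a single CPU.

## Known limitations

* Presence-based single-TRE enrichment is powerless on long concatemers
  (see above); motif (k ≥ 2) enrichment is the informative family.
* The caller's per-block edit caps assume block sequences are pairwise
  dissimilar at more than the cap distance; extremely similar elements
  in a user-supplied alphabet would make calls ambiguous (the alphabet
  validator rejects only exact and reverse-complement collisions).
* The merger is gap-free by design; data with real indels will merge at
  reduced rates and rely on the caller's edit tolerance.
* The three-rule filter operates on contig strings: distinct templates
  that collapse to the same TRE string are intentionally pooled.
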