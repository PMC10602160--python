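# isynpro

Analysis pipeline for screens of **inducible synthetic promoters
(iSynPros)** — promoters built by random blunt-end ligation of short
transcription-factor response elements (TREs) and selected for
activation-dependent transcription in CAR T cells.

Such a library has no alignment reference and its templates vary in
length, so standard amplicon tooling does not apply. This package
provides the full computational screen:

1. **Template reconstruction** (`isynpro.merge`) — each variable-length
   amplicon is rebuilt from its 300 bp read pair by sliding-overlap
   consensus with per-base quality recombination.
2. **TRE calling** (`isynpro.caller`) — the invariant ~30 nt flanks are
   trimmed by edit-distance search and the interior is segmented into an
   ordered string of TREs ("TRE contig") by a minimum-cost dynamic
   program that tolerates sequencing noise: each step consumes a whole
   block in either orientation at its edit-distance cost (cap
   ⌈len/8⌉ per block) or leaves a base unannotated at penalty 1.5.
3. **Quantification** (`isynpro.quantify`) — contig count matrices,
   CPM/frequencies, count-weighted TRE proportions and their coefficient
   of variation, clonality via Lorenz curves and the Gini coefficient,
   cross-library log-frequency correlation, and length comparisons in
   TRE units.
4. **Dynamics** (`isynpro.dynamics`) — per-contig log₂ fold-change
   trajectories versus the lentiviral baseline
   (log₂((CPM_t + 0.5)/(CPM_virus + 0.5))), a ≥ 4 CPM detection filter,
   clusterability testing with the Hopkins statistic (Beta(m, m) null,
   toroidal edge correction), and Ward clustering with
   silhouette-selected k.
5. **Enrichment & selection** (`isynpro.enrichment`) — one-sided Fisher
   exact tests of single TREs and ordered three-TRE motifs within
   behaviour clusters (Benjamini-Hochberg corrected), and the three-rule
   candidate filter: baseline viral frequency ≥ 0.001, fold change
   > 1.25 at ≥ 2 timepoints, and membership in the top 90% cumulative
   abundance of the pooled cell library.
6. **Synthetic screens** (`isynpro.simulate`) — a generative model of
   the whole experiment (weighted ligation, gel size selection, plasmid
   bottleneck with Dirichlet clonal skew, lentiviral length bias,
   planted per-timepoint enrichment/depletion, substitution-noise paired
   reads) that retains ground truth for every clone, used by the test
   suite and the acceptance script.

The bundled TRE alphabet (`isynpro/data/synthetic_tre_alphabet.fasta`)
is a clearly-labelled *synthetic* fixture of eleven consensus-style
elements (NF-κB at ligation weight 6, ten others at 2). Real analyses
should supply the element FASTA actually ligated, as
`>CODE name=<text> weight=<float>` records.

## Worked example

Simulate a screen and run the analysis at the count level:

```python
from isynpro import *

alphabet = load_alphabet()                      # synthetic fixture alphabet
templates = simulate_ligation(alphabet, LigationSpec(), 2000, seed=7)
spec = ScreenSimSpec(n_raw_templates=2000, plasmid_bottleneck_size=300, seed=7)
screen = simulate_screen(templates, spec)

counts = screen.counts.copy()
counts.index = screen.manifest["contig"]        # clone identity = TRE string
matrix = ContigCountMatrix(counts)

print("Gini raw/plasmid: %.3f / %.3f" % (
    lorenz_gini(matrix.counts["raw"]).gini,
    lorenz_gini(matrix.counts["plasmid"]).gini))
r, _ = library_correlation(matrix, "plasmid", "virus")
print("plasmid~virus log-freq r = %.3f" % r)

traj = build_trajectories(matrix, SelectionThresholds())
h = hopkins(traj.retained, seed=7)
print("Hopkins H = %.3f (p = %.2e, n = %d retained)" % (h.H, h.p_value, h.n))
clusters = cluster_trajectories(traj, seed=7)
print("clusters: k = %d" % clusters.k)

cand = select_candidates(matrix, traj, SelectionThresholds())
print("candidates selected:", int(cand["selected"].sum()))
```

prints

```
Gini raw/plasmid: 0.079 / 0.572
plasmid~virus log-freq r = 0.983
Hopkins H = 1.000 (p = 2.07e-91, n = 298 retained)
clusters: k = 3
candidates selected: 15
```

Reading the numbers: the raw ligation pool is nearly even (Gini 0.08 —
every molecule unique), the plasmid bottleneck skews clonality heavily
(Gini 0.57), and the skew carries into the virus library (r = 0.98).
The fold-change trajectories of the 298 detected clones are strongly
clusterable (H ≈ 1, far above the 0.5 of unstructured data), resolve
into three behaviour groups, and the three-rule filter recovers the 15
clones the simulation planted as antigen-inducible.

The same analysis runs from the shell on FASTQ input, stage by stage or
end to end:

```sh
isynpro run-all --out-dir run1 --seed 7
isynpro merge --fastq1 s_R1.fastq --fastq2 s_R2.fastq --out merged.fastq
isynpro call  --merged merged.fastq --out contigs.tsv
```

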