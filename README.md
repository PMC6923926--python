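# parscope

Sex-chromosome homology analysis for chromosome-scale mammalian assemblies:
calling the pseudoautosomal boundary, classifying X–Y gametologs, recovering
ampliconic gene-family copy numbers, and validating Y-scaffold order against
radiation-hybrid-style marker maps.

## The problem

The pseudoautosomal region (PAR) is the segment shared by the X and Y
chromosomes that still pairs and recombines at male meiosis; everything
distal of the pseudoautosomal boundary (PAB) on the Y is male-specific (MSY)
and degenerates independently. In a correctly assembled pair of sex
chromosomes the X–Y identity profile is diagnostic: ~99% identity across the
PAR, an abrupt collapse to background (~15% windowed identity) at the PAB,
single-copy X-degenerate relics at 60–96% identity scattered through the MSY,
and near-identical tandem ampliconic families. `parscope` turns that profile
into callable, testable statistics, aimed at assembly and comparative-genomics
groups working on non-model mammals.

## The method

**Windowed homology.** The X is partitioned into windows (1 Mb at chromosome
scale). For alignment blocks *b* intersecting window *w*:

- coverage(w) = |union of clipped block intervals| / |w|
- identity(w) = Σ_b cols_b·id_b / Σ_b cols_b  (alignment-column weighted)

Blocks come either from the internal seed–chain–extend aligner (exact k-mer
seeds, co-diagonal chaining, unit-cost edit-distance polishing) or from any
external aligner via BLAST tabular (outfmt 6) or PAF ingestion.

**Boundary calling.** The PAB is the start of the first window from the
proximal end with coverage < 0.80 **and** identity < 0.80 (a window with no
alignment counts as failing identity). The call is refined by re-binning the
interval around the failing window at 100 kb, 10 kb, then 1 kb, re-aligning
locally and re-applying the same rule.

**Gametolog classification.** X and Y genes are paired by reciprocal best
identity under global alignment; pairs with identity in [0.60, 0.96] are
gametologs, above the band PAR-grade, below it unpaired (candidate
Y-specific). Multi-copy families are single-linkage clusters at identity
≥ 0.70, just below the observed 74–91% within-family band.

**Scaffold QC.** Scaffolds < 50 kb with < 3 known Y genes are flagged;
flagged scaffolds binned at 50 kb and removed when < 90% of their bases align
to trusted references. Marker-map discordance is n − (longest monotone
subsequence) of assembly positions in map-rank order; a contig inversion is
proposed only when every map independently supports it.

All of this runs end-to-end on a seeded synthetic generator (2 Mb X, 684 kb
PAR — one-tenth chromosome scale) that emits full ground truth, so the whole
pipeline is scored without downloading anything.

## Worked example

```sh
parscope demo --seed 1 --out report.json
```

runs simulation → alignment → boundary call → classification → clustering →
segmentation → scaffold QC → gap counting and scores every stage against the
generator's truth. With seed 1 it prints `[demo] boundary error 1000 bp` and
writes (abridged):

```json
{
 "boundary":   {"called": 685000, "true": 684000, "error_bp": 1000, "resolution": 1000},
 "gametologs": {"predicted": 15, "true": 15, "precision": 1.0, "recall": 1.0},
 "families":   {"recovered_copy_numbers": {"OBP": 3, "BDA20": 4}, "exact": true},
 "segmentation": {"region_names": ["PAR", "X-d1", "ampliconic", "X-d2a", "ampliconic", "X-d2b"], "exact": true},
 "scaffold_qc": {"proposed_flips": ["Y.3"], "inversion_detection_correct": true,
                 "post_flip_discordance": {"RH1": 0, "RH2": 0}},
 "gaps":       {"y_par_gap_count": 2, "exact": true}
}
```

Reading: the boundary was recovered at the finest 1 kb resolution (the true
PAB sits at 684 kb; here a 3 bp chance seed extension rounded the call up one
bin — the median error across seeds is 0); all 15 gametolog pairs were
recovered with no false calls; the 3- and 4-copy families came back at
exactly their true sizes; the Y segmented into the expected
PAR / X-d1 / ampliconic / X-d2a / ampliconic / X-d2b layout; the one inverted
contig (`Y.3`) was identified from both marker maps and flipping it restores
full marker concordance; and both assembly gaps inside the called PAR were
counted.

Other subcommands (`simulate`, `align`, `callpar`, `classify`, `qc`, `gaps`)
expose the individual stages on FASTA/GFF3/TSV inputs; `--help` lists every
default.

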