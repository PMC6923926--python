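# Methods

This note documents the models, parameters, numerical choices and known
limitations of `parscope`. Empirical numbers quoted here are the ones the
test suite and `scripts/acceptance.py` themselves compute.

## Windowed homology statistics

An alignment block is the atomic evidence unit: query and target intervals
(0-based, half-open — the single internal convention, converted only at
format borders), strand, match count and alignment-column count. For a
window *w* and the blocks intersecting it:

- **coverage** is the union length of the clipped block query-intervals
  divided by the window length. Using the union makes coverage invariant to
  splitting a block into abutting pieces and to block overlap.
- **identity** is the alignment-column-weighted mean of block identities,
  with each block's columns scaled by the clipped fraction of its query
  span. Windows intersected by no block carry a `None` identity (the
  no-data flag) rather than 0, because "no alignment" and "alignment at 0%
  identity" are different observations.

Overlapping blocks double-count in the identity weighting. This is
deliberate: the per-base brute-force oracle (mark each covered base, average
identity base-wise over block multiplicity) agrees with the clipped-column
formula exactly when columns equal spans, and the union definition already
pins down coverage. The oracle equivalence is enforced to 1e-9 over
hundreds of random instances in the tests and the acceptance script.

## The internal aligner

A deliberately simple, fully documented seed–chain–extend procedure stands
in for a BLASTN-style local aligner, whose parameters in the original
analyses of this kind are typically unstated:

1. exact k-mer seeds (default k = 15), never placed on N; target k-mers
   occurring more than `max_seed_occ` (16) times are skipped as repeats;
2. co-diagonal seed runs merged, then runs chained greedily when query/target
   gaps ≤ `max_gap` (500 bp) and diagonal shift ≤ `diag_band` (100 bp);
3. each chain polished by a unit-cost global edit-distance alignment
   (edlib) of the chained substrings; matches and columns read off the
   extended CIGAR; chains spanning < `min_block` (100 bp) are dropped.

Both strands are searched (the query is reverse-complemented; coordinates
mapped back), and aligning revcomp(query) provably mirrors the block set
with strands flipped and identities unchanged — a tested invariant.

Consequences worth knowing: at 1% divergence the expected spacing between
intact 15-mers is a few bases, so the PAR is recovered as one chain; at
≥ ~30% divergence seeds effectively vanish, which is the desired behaviour —
deeply diverged sequence should register as background. Aligned N columns
count as mismatches; N-heavy windows simply score low coverage and are never
skipped. Any external aligner can be substituted through the BLAST outfmt 6
/ PAF readers, which normalise both conventions (1-based inclusive with
swapped subject coordinates on the minus strand; 0-based half-open with a
strand column) onto the internal one.

## Boundary calling

The first-failing-bin rule: scanning windows from the proximal end (the PAR
is anchored at coordinate 0 of the oriented X), the boundary is the start of
the first window with coverage < 0.80 AND identity < 0.80. Three conventions
are fixed and unit-tested:

- **conjunction** — a window must fail both criteria; failing only one
  (e.g. a sparse but high-identity gene relic) does not call a boundary;
- **strict inequality** — a window at exactly 0.80/0.80 passes;
- **no-data fails identity** — absence of alignment is the strongest
  evidence of non-homology.

Raising either threshold can only move the called boundary proximally
(property-tested), and on single-transition profiles the scan equals the
exhaustive transition finder.

**Refinement** is this package's own addition (base-precise boundary
procedures are rarely published): the interval between the nearest window
passing *both* criteria and the end of the failing window is re-binned at
each scheduled size (default 100 kb → 10 kb → 1 kb below the 1 Mb coarse
window), the X slice re-aligned against the full Y (the target k-mer index
is built once and reused), and the identical rule re-applied. Anchoring on
the nearest *both-passing* window rather than the immediately preceding one
matters: windows that fail only coverage are ambiguous under the conjunction
rule, and treating them as passing can push the refinement interval past the
true boundary entirely.

The call is quantized to the finest window: a chance seed extension of a few
bases beyond the true boundary can round the call up one bin (observed as
the occasional 1 kb error at 1 kb resolution; the median error across seeds
is 0). When no window ever fails, a sentinel call flags the whole sequence
as PAR rather than inventing a boundary.

## Gametolog classification and families

Gene-level identity is the match fraction of an optimal unit-cost global
alignment of the two gene sequences. Pairing is reciprocal best hit with a
deterministic tie-break (identity, then alignment columns, then
lexicographic id), which makes the pair set symmetric in the argument
order. Classification uses an inclusive band: identity in [0.60, 0.96] ⇒
gametolog; above ⇒ PAR-grade (still effectively recombining); below ⇒
unpaired. The band endpoints are configurable; the defaults follow the
observed X-degenerate range, and band membership is evaluated at gene level.
Note that optimal global alignment of *unrelated* DNA yields ~50% identity,
comfortably below the 0.60 floor — this is why below-band best hits are
treated as candidate Y-specific genes rather than weak gametologs.

Families are single-linkage clusters on pairwise gene identity at
≥ `family_cluster_min` = 0.70 — just below the 0.74 observed floor of
within-family identity — computed via scipy's hierarchical clustering and
cross-checked in the tests against an exhaustive union-find oracle. Family
ids are the lexicographically smallest member id, so clustering is invariant
to input order.

**Segmentation** turns labelled Y genes into regions: maximal runs of
same-label genes (broken when consecutive genes lie > `max_join` = 200 kb
apart) span from first gene start to last gene end; X-degenerate runs are
named X-d1, X-d2a, X-d2b, … proximal → distal. Region boundaries use gene
extents, not midpoints, so intergenic sequence between regions stays
unassigned — conservative and directly comparable to generator truth. The
PAR region always comes from the boundary call, never from gene labels; a
gametolog-labelled gene inside the PAR triggers a warning and is reassigned.

## Scaffold QC

- **Flagging**: length < 50 kb AND known-Y-gene hits < 3 (strict: exactly
  3 genes escapes).
- **Aligned fraction**: flagged scaffolds are cut into 50-kb bins, each bin
  aligned to every trusted reference; a base counts as aligned when covered
  by a block with identity ≥ 0.80 (the "alignment" in a coverage-style
  filter is ambiguous, so both the coverage reading and the identity floor
  are explicit, configurable parameters). Scaffolds with < 90% aligned
  bases are removed; exactly 90% is retained.
- **Concordance**: the discordant count is n − (longest strictly monotone
  subsequence) of assembly positions taken in map-rank order — the minimum
  number of markers to delete for order consistency, verified against an
  exhaustive subset oracle for n ≤ 8. The monotone direction is chosen per
  map, since map orientation is arbitrary. Kendall's tau is reported
  alongside.
- **Inversion resolution**: a contig flip is proposed only when mirroring
  that contig's marker positions strictly decreases the discordant count of
  *every* map, and applying the whole proposed flip set leaves no map worse
  than baseline; otherwise nothing is proposed and the assembly layout is
  retained. Unanimity encodes the conservative policy of trusting the
  assembly over conflicting external maps.

## The synthetic generator

The generator emulates, at one-tenth chromosome scale, the statistical
structure the analysis assumes; its defaults are the study conditions of
every test:

| parameter | default | meaning |
|---|---|---|
| x_length / par_length | 2 Mb / 684 kb | scaled X geometry; true PAB at 684 kb |
| par_sub_rate / par_indel_rate | 0.01 / 0 | PAR divergence ⇒ ~99% X–Y identity |
| xdeg_segments | 11 + 2 + 2 genes, divergence U(0.06, 0.38) | X-d1/X-d2a/X-d2b gametologs at ~62–94% identity |
| ampliconic_families | 3×3 kb and 4×3 kb, pairwise divergence U(0.09, 0.26) | OBP- and BDA20-like expansions at ~74–91% identity |
| gene_density / gene_length | 15 per Mb / 2 kb | ⇒ 10 PAR gene pairs |
| n_gap_runs | 5 kb @ 200 kb, 3 kb @ 452 kb | two assembly gaps in the Y PAR |
| marker_maps / marker_count | 2 / 30 | RH-style maps, ranks in true order |
| corruption_ops | fragment at 0.5/0.9/1.3 Mb; invert Y.3 | one 400 kb inverted contig (scaled mirror of a ~1.3 Mb real case) |

Design points:

- **PRNG**: every stochastic operation flows from one explicit seed through
  numpy's PCG64 — a named, documented algorithm — so a fixed config yields
  byte-identical FASTA/GFF3/TSV/JSON on any platform (tested).
- **Realized identities are recorded from the edit transcripts**, never
  re-estimated by alignment. Substitutions draw uniformly from the three
  alternative bases; indel events are single-base; N positions are never
  edited. Transcript identity (matches / columns, columns = length +
  insertions) agrees with an independent optimal global alignment on test
  instances.
- **Background is independent random sequence**, not a mutated copy: beyond
  the PAR, non-gene Y sequence shares only chance k-mers with the X, which
  reproduces the observed collapse of windowed identity to background. The
  short (~hundreds of bp) intermediate-identity transition zone sometimes
  seen immediately at a real PAB has no known generative model and is not
  simulated.
- Gametolog X loci are placed ≥ 100 kb distal of the PAB, reflecting the
  dispersal of X-degenerate homologues over a much larger X interval than
  their compact Y counterparts.
- N-gaps are overwritten in place (coordinates preserved) and placement
  avoiding genes is enforced; genes are single-exon intervals — intron
  structure, read-level error, repeat libraries and recombination are out
  of scope.

What passing tests on this generator do **not** show: robustness to real
repeat content (segmental duplications, satellite arrays), to biased base
composition, to assembly chimerism beyond the modelled corruption ops, or to
the unmodelled boundary transition zone. The generator controls repeat
content by construction, whereas real chromosomes would need masking or
repeat-aware seeding upstream.

## Problem sizes and determinism

Test and acceptance runs use the scaled geometry throughout: 2 Mb
chromosomes, 100 kb coarse windows with a 10 kb → 1 kb refinement schedule
(the same bin-count structure as 1 Mb windows on a 20 Mb chromosome), 20
seeded replicates for boundary recovery, 10 for families/inversions, 3 for
classification, and 200 random instances for the window-statistics oracle.
These sizes keep a full desk run in minutes while preserving every
structural feature the statistics depend on. All randomness is seeded; the
acceptance script derives per-replicate seeds from its single `--seed`
argument.

## Degenerate inputs and edge rules

- Empty window-statistics lists, empty sequences, rates outside [0, 1],
  invalid bands and non-monotone marker ranks are rejected with explicit
  errors; no homology at all yields an empty block list, not an error.
- `X == Y` propagates the no-boundary sentinel (whole sequence flagged PAR).
- All windows failing from the start yields boundary 0 and an empty PAR.
- A gene straddling the called boundary is reported as boundary-spanning
  and excluded from the PAR gene count.
- FASTA input is restricted to A/C/G/T/N (upper-cased); IUPAC ambiguity
  codes are rejected by design. Gaps are runs of literal N only; lowercase
  masking carries no meaning.
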