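# Methods

## The audit model

`draftaudit` treats a draft assembly the way a manual curator treats it:
gene by gene, using two independent sources of expectation — sequence
similarity to an ortholog annotation, and chromosome-level synteny. The
unit of evidence is the **exon chain**: the placements of one
transcript's exons on the draft, kept strictly in transcription order.
The central assumption is that vertebrate exon order and orientation are
conserved between closely related genomes, so any deviation of a chain
from "one chromosome, one strand, monotonic coordinates, intron-scale
gaps" is evidence about the assembly rather than about biology. A
second assumption is that the ortholog CDS translates cleanly, so
premature stops observed only on the draft side are draft defects (or
real pseudogenes — the audit reports, it does not adjudicate wet-lab
truth).

## Alignment

Exon placement is local Smith–Waterman with affine gaps, delegated to
Biopython's `PairwiseAligner` over the alphabet `ACGTN`:

* match +2, mismatch −3, gap of length L costs 5 + 2L (BLASTN-like
  defaults; the aligner is configured with open = −7, extend = −2 so the
  first gap base pays open+extend).
* N never matches anything (scored as mismatch), so placements shrink at
  assembly gaps instead of bridging them.
* identity is **substitution identity** — matches / (matches +
  mismatches), gap columns excluded. This is deliberate: an exon whose
  missing 30 nt were swallowed by a gap aligns perfectly around a
  structural deletion, and gap-inclusive identity would reject the
  placement and misroute the defect from "missing subsequence" to
  "missing exon". Coverage (aligned fraction of the exon) is thresholded
  separately.
* thresholds: min_identity 0.85, min_coverage 0.80. Chosen so one or two
  sequencing errors never unplace an exon while decoy intronic exons
  essentially never place. Exons shorter than 20 nt are not searched
  (too little signal) and are excluded from anomaly evidence.
* ambiguity: a runner-up within the tie margin (default: exact score
  equality) makes both placements *ambiguous*; ambiguous placements are
  excluded from anomaly evidence but are counted and can only ever make
  a gene `unclear`, never `wrong`.
* search: an exact 11-mer index prefilters candidate windows (merged
  diagonal bands, ±60 nt pad); windows supported by a single seed are
  aligned only when no multi-seed window exists; sequences under 2 kb
  are always scanned in full. Pure engineering — results are defined by
  the exact aligner, and a property test checks score agreement with an
  independent quadratic Gotoh reference.
* the traceback is the aligner's deterministic first optimal path; indel
  events are reported from the draft's perspective (`ins` = extra draft
  bases, `del` = query bases absent from the draft).

## Detection rules

* **FRAMESHIFT**: cumulative signed indel length within the CDS is ≠ 0
  (mod 3) at any point along the chain — so two compensating indels
  (+2, +1) still report, because the span between them is out of frame.
  Indel events ≥ 15 bp are excluded: they are assembly-gap-scale
  structural losses (routed to MISSING_SUBSEQUENCE), not the 1–2 bp
  sequencing errors this rule targets.
* **PREMATURE_STOP**: the draft CDS is reconstructed from placements
  (only when all CDS exons are placed on one sequence and strand —
  split genes are deferred to the misassembly detector), translated,
  and reported when an internal stop precedes the final codon while the
  ortholog codon is stop-free. When a single substitution explains the
  stop, the causative base is included in the evidence.
* **MISSING_EXON**: an unplaced exon; `gap_explained=true` when the
  flanking placed exons bracket an N-run ≥ 10 nt on the same target
  (10 avoids counting isolated ambiguous bases as gaps).
* **MISSING_SUBSEQUENCE**: a placed exon missing a contiguous block
  ≥ 15 nt — an unaligned terminus or a structural deletion inside the
  alignment. Block boundaries are alignment-dependent by ±5 nt, which is
  the slack tests allow.
* **SPURIOUS_EXON**: a draft-model exon whose best reciprocal overlap
  with any ortholog-supported placement is < 0.1 while a neighbouring
  model exon is supported (≥ 0.8) — the signature of an annotation
  pipeline anchoring a fabricated exon between real ones. Overlaps
  between 0.1 and 0.8 are reported as AMBIGUOUS_PLACEMENT instead.
* **MODEL_TRUNCATION**: supported placements on the model's own sequence
  entirely outside the model's genomic extent. (The survey category
  `incomplete` needs this converse of the spurious-exon check.)
* **SPLIT_CHROMOSOME / SPLIT_UNLOCALIZED / ORIENTATION_FLIP /
  ORDER_ANOMALY**: computed per chain. The primary target is the
  plurality target, ties broken by the synteny expectation, then
  lexicographically; the misplaced block of a split is the set of exons
  off the expected chromosome. Order checking requires monotonic target
  coordinates (ascending on +, descending on −) per (target, strand)
  group, tolerating backsteps up to one exon span (tandem
  near-duplicates); adjacent placed exons more than 1 Mb apart raise the
  "distance" variant. A single-contig unlocalized scaffold whose gene
  otherwise sits on the synteny-expected chromosome is additionally
  flagged as an unintegrated contig (evidence payload on the
  SPLIT_UNLOCALIZED finding).
* **CHIMERIC_CONTIG**: exon placements are projected through the
  placement table into contig coordinates and grouped by the chromosome
  each gene's chain expects under synteny. Two groups occupying disjoint
  contig intervals ⇒ chimeric, breakpoint interval = the gap between the
  innermost conflicting placements; interleaved groups are flagged
  ambiguous, never called.

## Classification

Precedence (most to least severe): `none_annotated` (no draft model) >
`no_protein_derived` (model CDS has an internal stop; partial models
without a terminal stop still count as protein-deriving, as automated
pipelines emit partial proteins) > `wrong` (spurious exons, splits,
flips, order anomalies, chimeric contigs, or a frameshift whose
downstream ORF survives) > `incomplete` (only missing-sequence or
truncation evidence) > `unclear` (only ambiguity) > `complete_correct`.
The precedence is this package's codification of the survey's implicit
severity ordering; published surveys of this kind were curated manually
without stated tie rules. Adding findings can never move a gene toward
`complete_correct` (a property test enforces this monotonicity).
Percentages in the summary are rounded half-up per category and are not
forced to sum to 100; counts are authoritative.

## The synthetic-data generator

The generator emulates the situation the audit is built for: a clean
"truth" genome standing in for the finished ortholog reference, and a
draft derived from it carrying known defects. Defaults (the study
conditions): 3 chromosomes, 50 genes, 5–9 exons of 90–180 bp, introns
1.5–4 kb, intergenic spacers 2–5 kb, GC 0.41 (primate-like), genes on
random strands. CDSs are built codon-wise from the 61 non-stop codons
(ATG start, one stop), so they are internal-stop-free by construction;
introns are GT..AG with otherwise unconstrained (stop-codon-agnostic)
sequence. Chromosomes are tiled into 5–15 kb contigs rejoined with 100-N
scaffold gaps; cut points avoid exons (±25 bp) so a clean draft maps
cleanly — with these sizes a typical gene (~15–20 kb) spans several
contigs, which is what gives the structural defect classes room to act.
The ortholog annotation used by the mapper is the truth annotation
itself, so the synteny map is the identity; real cross-species use only
swaps the inputs.

Defect classes and their realizations:

* STOP_SUBSTITUTION: one base of an interior codon (≥ 5 codons from
  either CDS end, wholly inside one exon) substituted to create an
  in-frame stop.
* FRAMESHIFT_INDEL: a 1–2 bp insertion or deletion at least 12 bp inside
  a CDS exon — interior placement keeps the local aligner opening a gap
  instead of trimming the exon terminus, which is also where real
  frameshift evidence is unambiguous.
* EXON_GAP: a middle exon ± 30 bp margin replaced by a same-length
  N-run. The draft model receives a **decoy exon** sampled from a
  flanking intron of the same gene, length within ±20% of the lost exon
  and congruent to it mod 3, searched (offsets × lengths) so the full
  model still translates stop-free — emulating an annotation pipeline
  that emits ORF-consistent models with invented exons. If no stop-free
  candidate exists the best one is used and flagged in the log.
* PARTIAL_EXON_GAP: the terminal 30 nt (transcript 3' side) of an exon
  ≥ 160 bp masked to N, plus a 20 bp margin — terminal rather than
  internal masking because an internal same-length N substitution is
  walked through by the aligner as mismatches and leaves no missing
  block, which is not what "sequence missing from the draft" means.
  The ≥160 bp eligibility keeps the placement above min_coverage.
* CONTIG_MISASSIGNMENT / UNLOCALIZED_SPLIT / ORIENTATION_FLIP: a contig
  carrying a middle exon (lowest middle index; never all of a gene's
  exons, and for flips fewer than half so the chain majority stays
  correct) is moved to another chromosome, moved to a new single-contig
  unlocalized scaffold, or reverse-complemented in place.
* CHIMERIC_FUSION: a prefix of one gene's contig (through its exons) is
  fused to the suffix of a partner gene's contig on another chromosome
  and placed at the partner's position; the fusion coordinate is logged
  for breakpoint scoring.
* ANNOTATION_DROP / MODEL_TRUNCATION: annotation-only defects — the
  model is removed, or loses its final exon (3'-terminal truncation, so
  the remaining CDS stays frame-intact and protein-deriving, which is
  what routes the gene to `incomplete` rather than
  `no_protein_derived`).

Draft gene models for genes whose exons left the home chromosome are cut
back to the longest transcription-contiguous run of surviving exons with
a frame-aligned CDS — a deliberate emulation of an annotator building a
partial but translatable model from what remains. One real-world mode is
*not* emulated: an annotator may fail entirely on such genes (no model
at all), which would classify them `none_annotated` instead of `wrong`.

Ground-truth records log each defect's draft-coordinate locus and a
payload including, for structural defects, the **collaterally affected
genes** (all genes with exons on the moved/fused/flipped contig).
Recovery scoring uses this: findings on collateral genes are neither
credited as true positives nor booked as false positives, because a
"clean" gene is one no defect touched at all. RNG is one root seed with
per-(gene, class) substreams, so logs are reproducible under spec
reordering.

### What the simulator does not model

Read-level error processes, repeats and segmental duplications,
heterozygosity, biased gap placement, and real intron/intergenic base
composition. Passing recovery tests therefore demonstrates that the
detectors respond correctly to each defect's footprint under
repeat-free, unambiguous mapping conditions; on real drafts, repeats and
paralogy will produce ambiguous placements (kept, not resolved) and the
thresholds may need loosening via `AlignmentParams`.

## Problem sizes

The validation suite and the reproduction script use 50-gene, ~1 Mb
genomes, 20 seeded replicates, and two genes per defect class per
replicate — sizes chosen so a full Monte Carlo completes in about two
minutes on one CPU while every defect class is exercised 40 times.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; GFF3 and the placement
  table are 1-based inclusive on disk, converted only in `draftaudit.io`.
* Codons containing N translate as `X`, never as a stop; a trailing
  partial codon is ignored with a warning; a stop in the final codon is
  the terminator, not an internal stop.
* Ambiguity codes other than N are rejected at FASTA read time.
* The genetic code is a data table (standard code shipped; swappable).
* A chain with zero placed exons yields an empty diagnosis with a status
  note, never an exception; unknown genes in defect specs, infeasible
  defects (e.g. contig misassignment on a one-chromosome genome) and
  over-subscribed defect counts raise `DefectError`.
* Contig-boundary-straddling placements (possible only in pathological
  inputs, since simulated cuts avoid exons) contribute no contig
  evidence.

## Known limitations

* Spliced alignment is exon-wise local alignment, not splice-site-aware
  one-shot alignment; micro-exons (< 20 nt) are deliberately skipped.
* Premature-stop calling is skipped for split genes, so a gene can carry
  both a stop-creating substitution and a split yet report only the
  split.
* The `unclear` category is operationalized as ambiguity-only evidence;
  a manual curator's notion of "unclear" is broader.
* Chimera detection needs at least one placed exon on each side of the
  fusion; a chimera joining two gene deserts is invisible to a
  gene-based audit by construction.
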