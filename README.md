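# draftaudit

Gene-based quality assessment of draft genome assemblies.

Draft vertebrate genomes (classically 5–6× Sanger coverage) carry
sequencing errors, assembly gaps and misassemblies that global quality
metrics hide but that corrupt gene models badly: a single inserted base
frameshifts a CDS, a substitution creates an in-frame stop that gets the
locus mislabelled a pseudogene, a gap swallows an exon and the annotation
pipeline "invents" a replacement from intronic sequence, and contigs
assigned to the wrong chromosome split genes apart. `draftaudit` detects
these defects gene by gene, the way a curator would: map the exons of
ortholog transcripts onto the draft and ask whether each gene's exons
land on one chromosome, on one strand, in transcription order, complete
and intact.

It is aimed at people producing or consuming draft assemblies — assembly
QC, annotation auditing, and comparative work that needs to know which
gene models can be trusted.

## Method

For each ortholog transcript with exons $e_1,\dots,e_n$ (transcription
order), every exon is aligned to both strands of the draft by local
Smith–Waterman alignment with affine gaps (match $+2$, mismatch $-3$, gap
of length $L$ costing $5 + 2L$; BLASTN-like). A placement is accepted at
substitution identity $\ge 0.85$ and exon coverage $\ge 0.80$; ties are
kept as *ambiguous* rather than resolved. The resulting **exon chain**
preserves transcription order, and the audit asks, in order:

* **integrity** — do the placements carry indels whose cumulative length
  is $\not\equiv 0 \pmod 3$ inside the CDS (frameshift)? does the
  reconstructed draft CDS translate with an internal stop (premature
  stop)? are exons unplaced, and if so do the flanking exons bracket an
  N-run (gap-explained missing exon)? are sub-exon blocks ($\ge 15$ nt)
  missing? does the draft's own annotation contain exons no ortholog
  evidence supports (spurious/invented exons) or omit exons the evidence
  supports (truncated models)?
* **misassembly** — exon order is highly conserved among vertebrates, so
  chains that span two chromosomes, land partly on unlocalized
  scaffolds, flip strand mid-gene, or violate coordinate monotonicity
  evidence misassembly. A chromosome-correspondence (synteny) table
  decides which side of a split is misplaced. Exon evidence is also
  projected through the contig placement table: a contig whose two sides
  host exons expected on different chromosomes is called **chimeric**,
  with a breakpoint interval bracketed by the innermost conflicting
  placements.

Each gene is then classified into one of six survey categories by
severity precedence: `none_annotated` > `no_protein_derived` > `wrong` >
`incomplete` > `unclear` > `complete_correct`.

A first-class synthetic-data module generates truth genomes (clean
ATG…stop ORFs, GT..AG introns) and derives corrupted drafts carrying ten
defect classes — stop-creating substitutions, frameshifting indels,
exon-swallowing N-gaps, partial-exon gaps, contig misassignments,
unlocalized splits, orientation flips, chimeric fusions, dropped
annotations and truncated models — with a machine-readable ground-truth
log, so the whole pipeline is validated end to end by recovery scoring.

## Worked example

Simulate a 30-gene draft carrying one defect of each class, audit it,
and score recovery against the ground-truth log:

```bash
draftaudit report --seed 4 --genes 30 --defects-per-class 1 --outdir audit_out
```

prints

```
          category  count  percent
  complete_correct     18       60
             wrong      7       23
        incomplete      2        7
no_protein_derived     2        7
    none_annotated      1        3
           unclear      0        0
CHIMERIC_CONTIG        sensitivity 1.00  precision 1.00
FRAMESHIFT             sensitivity 1.00  precision 1.00
MISSING_EXON           sensitivity 1.00  precision 1.00
...
SPURIOUS_EXON          sensitivity 1.00  precision 1.00
```

The table is the six-way survey of the 30 audited genes: the 10 injected
defects demote 12 genes out of `complete_correct` (structural defects
also damage neighbouring genes on the moved contigs), e.g. the
stop-substitution gene lands in `no_protein_derived` because its model
no longer translates, and the gene whose gapped exon was replaced by a
decoy intronic exon lands in `wrong`. The per-kind lines report
detection sensitivity (defects found on the right gene) and precision
(no findings on untouched genes); the command exits non-zero if either
drops below 0.95. `audit_out/` contains the FASTA/GFF3/TSV/JSONL bundle
(draft, placements, findings, per-gene verdicts, confusion table).

The same audit runs on real data via `draftaudit map` / `draftaudit qc`
with a reference FASTA+GFF3, a draft FASTA, an AGP-like placement table
and a two-column synteny TSV.

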