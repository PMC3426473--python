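"""Readers and writers for the standard formats the audit touches.

FASTA for sequences, GFF3 for gene models, and two tab-separated tables:
an AGP-like contig placement table (1-based inclusive coordinates, like
AGP) and a two-column synteny map. All paths may be plain or
gzip-compressed (detected by a ``.gz`` suffix).

GFF3 coordinates are 1-based inclusive on disk and converted to the
package's 0-based half-open convention on read (and back on write).
"""

from __future__ import annotations

import gzip
import os
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO

from .model import Assembly, ContigPlacement, SyntenyMap, TranscriptModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_placements",
    "write_placements",
    "read_synteny",
    "write_synteny",
]

_VALID_CHARS = frozenset("ACGTN")


def _open_text(path, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{name: sequence}``.

    Sequences are uppercased; duplicate record names and characters outside
    A/C/G/T/N are rejected with the offending record named. (Ambiguity
    codes other than N are out of scope for draft-assembly auditing.)
    """
    sequences: dict[str, str] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in sequences:
                raise ValueError(f"duplicate FASTA record name {record.id!r}")
            seq = str(record.seq).upper()
            bad = set(seq) - _VALID_CHARS
            if bad:
                raise ValueError(
                    f"record {record.id!r}: non-IUPAC/ambiguous characters "
                    f"{sorted(bad)} (only A/C/G/T/N accepted)"
                )
            sequences[record.id] = seq
    return sequences


def write_fasta(sequences: dict[str, str], path, line_width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> list[TranscriptModel]:
    """Read gene/mRNA/exon/CDS features into :class:`TranscriptModel` s.

    Every mRNA must have a gene parent; exons and CDS must lie within their
    mRNA span. Violations raise ``ValueError`` naming the feature.
    """
    path = os.fspath(path)
    if path.endswith(".gz"):
        with _open_text(path) as fh:
            data = fh.read()
        db = gffutils.create_db(
            data, ":memory:", from_string=True, keep_order=True,
            merge_strategy="error",
        )
    else:
        db = gffutils.create_db(
            path, ":memory:", keep_order=True, merge_strategy="error"
        )

    gene_ids = {f.id for f in db.features_of_type("gene")}
    models = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        parents = mrna.attributes.get("Parent", [])
        if not parents or parents[0] not in gene_ids:
            raise ValueError(
                f"mRNA {mrna.id!r} has no gene parent (Parent={parents})"
            )
        gene_id = parents[0]
        exons = []
        cds_parts = []
        for child in db.children(mrna, level=1):
            if child.start < mrna.start or child.end > mrna.end:
                raise ValueError(
                    f"feature {child.featuretype} at {child.start}-{child.end}"
                    f" outside parent mRNA {mrna.id!r} span "
                    f"{mrna.start}-{mrna.end}"
                )
            # GFF3 1-based inclusive -> 0-based half-open
            iv = (child.start - 1, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds_parts.append(iv)
        if not exons:
            raise ValueError(f"mRNA {mrna.id!r} has no exons")
        strand = mrna.strand
        exons.sort(reverse=strand == "-")
        model_no_cds = TranscriptModel(
            gene_id=gene_id,
            transcript_id=mrna.id,
            seq_name=mrna.seqid,
            strand=strand,
            exons=tuple(exons),
            cds_span=(0, sum(e - s for s, e in exons)),
        )
        cds_span = _cds_span_from_parts(model_no_cds, cds_parts)
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                seq_name=mrna.seqid,
                strand=strand,
                exons=tuple(exons),
                cds_span=cds_span,
            )
        )
    models.sort(key=lambda m: (m.seq_name, m.genomic_start, m.transcript_id))
    return models


def _cds_span_from_parts(
    model: TranscriptModel, cds_parts: list[tuple[int, int]]
) -> tuple[int, int]:
    if not cds_parts:
        return model.cds_span
    total = sum(e - s for s, e in cds_parts)
    if model.strand == "+":
        first = min(s for s, _ in cds_parts)
        start_off = _genomic_to_spliced(model, first)
    else:
        first = max(e for _, e in cds_parts) - 1
        start_off = _genomic_to_spliced(model, first)
    return (start_off, start_off + total)


def _genomic_to_spliced(model: TranscriptModel, pos: int) -> int:
    off = 0
    for s, e in model.exons:
        if s <= pos < e:
            return off + (pos - s if model.strand == "+" else e - 1 - pos)
        off += e - s
    raise ValueError(
        f"{model.transcript_id}: genomic position {pos} not in any exon"
    )


def _cds_genomic_parts(model: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic intervals of the CDS, in transcription order."""
    cs, ce = model.cds_span
    parts = []
    for (s, e), (o1, o2) in zip(model.exons, model.exon_spliced_offsets()):
        lo, hi = max(cs, o1), min(ce, o2)
        if lo >= hi:
            continue
        if model.strand == "+":
            parts.append((s + (lo - o1), s + (hi - o1)))
        else:
            parts.append((e - (hi - o1), e - (lo - o1)))
    return parts


def write_gff3(models: Iterable[TranscriptModel], path) -> None:
    """Write models as gene/mRNA/exon/CDS GFF3 (1-based inclusive)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, gms in by_gene.items():
            seq = gms[0].seq_name
            strand = gms[0].strand
            gs = min(m.genomic_start for m in gms)
            ge = max(m.genomic_end for m in gms)
            fh.write(
                f"{seq}\tdraftaudit\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for m in gms:
                fh.write(
                    f"{seq}\tdraftaudit\tmRNA\t{m.genomic_start + 1}\t"
                    f"{m.genomic_end}\t.\t{strand}\t.\t"
                    f"ID={m.transcript_id};Parent={gene_id}\n"
                )
                for s, e in sorted(m.exons):
                    fh.write(
                        f"{seq}\tdraftaudit\texon\t{s + 1}\t{e}\t.\t{strand}"
                        f"\t.\tParent={m.transcript_id}\n"
                    )
                phase = 0
                cds_lines = []
                for s, e in _cds_genomic_parts(m):
                    cds_lines.append((s, e, phase))
                    phase = (3 - ((e - s) - phase) % 3) % 3
                for s, e, ph in sorted(cds_lines):
                    fh.write(
                        f"{seq}\tdraftaudit\tCDS\t{s + 1}\t{e}\t.\t{strand}"
                        f"\t{ph}\tParent={m.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Tables

_PLACEMENT_COLS = ["contig_id", "target", "start", "end", "orientation"]


def read_placements(path) -> list[ContigPlacement]:
    """Read the AGP-like placement table (1-based inclusive on disk)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "target": str})
    missing = set(_PLACEMENT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"placement table missing columns {sorted(missing)}")
    return [
        ContigPlacement(
            contig_id=row.contig_id,
            target=row.target,
            target_start=int(row.start) - 1,
            target_end=int(row.end),
            orientation=row.orientation,
        )
        for row in df.itertuples()
    ]


def write_placements(placements: Iterable[ContigPlacement], path) -> None:
    df = pd.DataFrame(
        [
            {
                "contig_id": p.contig_id,
                "target": p.target,
                "start": p.target_start + 1,
                "end": p.target_end,
                "orientation": p.orientation,
            }
            for p in placements
        ],
        columns=_PLACEMENT_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_synteny(path) -> SyntenyMap:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["reference", "draft"], dtype=str,
        comment="#",
    )
    return SyntenyMap(dict(zip(df.reference, df.draft)))


def write_synteny(synteny: SyntenyMap, path) -> None:
    with _open_text(path, "wt") as fh:
        for ref, draft in synteny.pairs.items():
            fh.write(f"{ref}\t{draft}\n")


def load_assembly(
    fasta_path, placements_path=None, roles: dict[str, str] | None = None
) -> Assembly:
    """Convenience loader: FASTA plus optional placement table and roles."""
    sequences = read_fasta(fasta_path)
    placements = read_placements(placements_path) if placements_path else []
    asm = Assembly(
        sequences=sequences,
        sequence_role=dict(roles or {}),
        placements=placements,
    )
    asm.validate()
    return asm
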