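"""Core data model for assemblies, gene models and sequences.

All coordinates are 0-based half-open on the forward strand of the named
sequence. Conversion to/from the 1-based inclusive conventions of GFF3 and
the placement table happens only in :mod:`draftaudit.io`.

A draft assembly is represented as a set of named sequences (chromosomes
and unlocalized scaffolds) plus a table of contig placements describing how
contigs tile those sequences -- the object the audit interrogates. Gene
structure (both the ortholog evidence and a draft's own annotation) is a
:class:`TranscriptModel`: exons in transcription order plus a CDS span in
spliced-transcript coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "Assembly",
    "ContigPlacement",
    "TranscriptModel",
    "SyntenyMap",
    "GENETIC_CODE",
    "STOP_CODONS",
    "reverse_complement",
    "translate",
    "translate_full",
    "spliced_sequence",
    "cds_sequence",
    "CHROMOSOME",
    "UNLOCALIZED",
    "CONTIG",
]

CHROMOSOME = "chromosome"
UNLOCALIZED = "unlocalized_scaffold"
CONTIG = "contig"

_ROLES = (CHROMOSOME, UNLOCALIZED, CONTIG)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _build_standard_code() -> dict[str, str]:
    # Standard genetic code as a data table (swappable, not hard-coded logic).
    bases = "TCAG"
    amino = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    code = {}
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                code[b1 + b2 + b3] = amino[i]
                i += 1
    return code


GENETIC_CODE: dict[str, str] = _build_standard_code()
STOP_CODONS = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")


def translate_full(seq: str, code: dict[str, str] | None = None) -> str:
    """Translate every complete codon; stops are ``*``, ambiguous codons ``X``.

    No truncation at internal stops -- used where the full downstream
    translation matters (e.g. frameshift divergence checks).
    """
    code = GENETIC_CODE if code is None else code
    n = len(seq) // 3
    return "".join(code.get(seq[3 * i : 3 * i + 3], "X") for i in range(n))


def translate(
    cds_seq: str, code: dict[str, str] | None = None
) -> tuple[str, int | None]:
    """Translate a CDS, reporting the first *internal* stop codon.

    Returns ``(protein, first_internal_stop_index)``. The protein string is
    the translation up to (not including) the first internal stop; a stop in
    the final codon position is the normal terminator and is neither part of
    the protein nor reported as internal. A trailing partial codon is
    ignored with a warning. Codons containing N translate as ``X``.
    """
    if len(cds_seq) < 3:
        raise ValueError(f"CDS shorter than one codon: {len(cds_seq)} nt")
    if len(cds_seq) % 3 != 0:
        warnings.warn(
            f"CDS length {len(cds_seq)} not a multiple of 3; "
            "trailing partial codon ignored",
            stacklevel=2,
        )
    aas = translate_full(cds_seq, code)
    star = aas.find("*")
    if star == -1:
        return aas, None
    if star == len(aas) - 1:  # terminal stop
        return aas[:-1], None
    return aas[:star], star


@dataclass(frozen=True)
class ContigPlacement:
    """Placement of one contig on a target sequence (scaffold/chromosome)."""

    contig_id: str
    target: str
    target_start: int
    target_end: int
    orientation: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.target_start < self.target_end:
            raise ValueError(
                f"placement {self.contig_id}: bad span "
                f"[{self.target_start}, {self.target_end})"
            )
        if self.orientation not in ("+", "-"):
            raise ValueError(
                f"placement {self.contig_id}: orientation {self.orientation!r}"
            )

    @property
    def length(self) -> int:
        return self.target_end - self.target_start


@dataclass(frozen=True)
class TranscriptModel:
    """A gene model: exons in transcription order plus a spliced CDS span.

    ``exons`` are genomic 0-based half-open intervals, ordered by
    transcription: ascending genomic coordinates on ``+``, descending on
    ``-``. ``cds_span`` is ``(start, end)`` in spliced-transcript
    coordinates (offsets into the concatenated, strand-corrected exons).
    """

    gene_id: str
    transcript_id: str
    seq_name: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_span: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        for s, e in self.exons:
            if not 0 <= s < e:
                raise ValueError(f"{self.transcript_id}: bad exon ({s}, {e})")
        starts = [s for s, _ in self.exons]
        expect = sorted(starts, reverse=self.strand == "-")
        if starts != expect:
            raise ValueError(
                f"{self.transcript_id}: exons not in transcription order "
                f"for strand {self.strand}"
            )
        srt = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(srt, srt[1:]):
            if e1 > s2:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        cs, ce = self.cds_span
        if not 0 <= cs < ce <= self.spliced_length:
            raise ValueError(
                f"{self.transcript_id}: CDS span {self.cds_span} outside "
                f"spliced length {self.spliced_length}"
            )
        if ce - cs < 3:
            raise ValueError(f"{self.transcript_id}: CDS shorter than 3 nt")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def genomic_start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def genomic_end(self) -> int:
        return max(e for _, e in self.exons)

    def exon_spliced_offsets(self) -> list[tuple[int, int]]:
        """Spliced-coordinate interval of each exon, in transcription order."""
        out = []
        off = 0
        for s, e in self.exons:
            out.append((off, off + (e - s)))
            off += e - s
        return out

    def spliced_to_genomic(self, offset: int) -> int:
        """Genomic position of a spliced-transcript offset (base position)."""
        if not 0 <= offset < self.spliced_length:
            raise ValueError(f"spliced offset {offset} out of range")
        for (s, e), (o1, o2) in zip(self.exons, self.exon_spliced_offsets()):
            if o1 <= offset < o2:
                within = offset - o1
                if self.strand == "+":
                    return s + within
                return e - 1 - within
        raise AssertionError("unreachable")


@dataclass
class SyntenyMap:
    """Expected draft chromosome for each reference chromosome.

    The identity map is legal (and is what the simulator's truth-vs-draft
    setup uses); real cross-species use supplies each reference
    chromosome's syntenic counterpart in the audited species.
    """

    pairs: dict[str, str] = field(default_factory=dict)

    def expected(self, reference_chrom: str) -> str:
        try:
            return self.pairs[reference_chrom]
        except KeyError:
            raise KeyError(
                f"no synteny expectation for reference chromosome "
                f"{reference_chrom!r}"
            ) from None

    @classmethod
    def identity(cls, chrom_names) -> "SyntenyMap":
        return cls({c: c for c in chrom_names})


@dataclass
class Assembly:
    """Named sequences with roles plus the contig placement table.

    ``sequences`` maps name -> uppercase A/C/G/T/N string. ``sequence_role``
    assigns each name one of chromosome / unlocalized_scaffold / contig
    (missing entries default to chromosome). ``placements`` describe the
    contig tiling of the scaffolded sequences.
    """

    sequences: dict[str, str]
    sequence_role: dict[str, str] = field(default_factory=dict)
    placements: list[ContigPlacement] = field(default_factory=list)

    def role(self, name: str) -> str:
        return self.sequence_role.get(name, CHROMOSOME)

    def names_with_role(self, role: str) -> list[str]:
        return [n for n in self.sequences if self.role(n) == role]

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    def validate(self) -> None:
        for name, role in self.sequence_role.items():
            if role not in _ROLES:
                raise ValueError(f"sequence {name!r}: unknown role {role!r}")
        by_target: dict[str, list[ContigPlacement]] = {}
        for pl in self.placements:
            if pl.target not in self.sequences:
                raise ValueError(
                    f"placement {pl.contig_id}: unknown target {pl.target!r}"
                )
            if pl.target_end > len(self.sequences[pl.target]):
                raise ValueError(
                    f"placement {pl.contig_id}: span ends at {pl.target_end} "
                    f"beyond {pl.target!r} length "
                    f"{len(self.sequences[pl.target])}"
                )
            by_target.setdefault(pl.target, []).append(pl)
        for target, pls in by_target.items():
            pls = sorted(pls, key=lambda p: p.target_start)
            for a, b in zip(pls, pls[1:]):
                if a.target_end > b.target_start:
                    raise ValueError(
                        f"overlapping placements {a.contig_id} and "
                        f"{b.contig_id} on {target!r}"
                    )

    def placements_on(self, target: str) -> list[ContigPlacement]:
        return sorted(
            (p for p in self.placements if p.target == target),
            key=lambda p: p.target_start,
        )

    def placement_at(self, target: str, pos: int) -> ContigPlacement | None:
        """The contig placement covering position ``pos`` on ``target``."""
        for p in self.placements:
            if p.target == target and p.target_start <= pos < p.target_end:
                return p
        return None


def spliced_sequence(assembly: Assembly, model: TranscriptModel) -> str:
    """Concatenate a model's exon sequences in transcription order.

    On ``-`` each exon is reverse complemented, so the result reads 5'->3'
    in mRNA orientation.
    """
    try:
        chrom = assembly.sequences[model.seq_name]
    except KeyError:
        raise KeyError(
            f"{model.transcript_id}: sequence {model.seq_name!r} "
            "not in assembly"
        ) from None
    parts = []
    for s, e in model.exons:
        if e > len(chrom):
            raise ValueError(
                f"{model.transcript_id}: exon ({s},{e}) beyond end of "
                f"{model.seq_name!r} (length {len(chrom)})"
            )
        piece = chrom[s:e]
        parts.append(reverse_complement(piece) if model.strand == "-" else piece)
    return "".join(parts)


def cds_sequence(assembly: Assembly, model: TranscriptModel) -> str:
    """The model's CDS nucleotide sequence (spliced, strand-corrected)."""
    spliced = spliced_sequence(assembly, model)
    cs, ce = model.cds_span
    return spliced[cs:ce]
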