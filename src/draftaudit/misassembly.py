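"""Assembly-level anomalies from exon chains and contig placements.

Vertebrate exon order is highly conserved, so a transcript's exons should
land on one draft chromosome, on one strand, in transcription order, at
intron-scale spacings -- and that chromosome should be the one synteny
predicts. Deviations are the misassembly evidence: genes split across
chromosomes or onto unlocalized scaffolds, exons in inverted contigs,
exon-order violations, and contigs whose two ends belong to different
chromosomes (chimeras).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .integrity import (
    AMBIGUOUS_PLACEMENT,
    CHIMERIC_CONTIG,
    ORDER_ANOMALY,
    ORIENTATION_FLIP,
    SPLIT_CHROMOSOME,
    SPLIT_UNLOCALIZED,
    Finding,
)
from .mapping import PLACED, ExonChain, ExonPlacement
from .model import CHROMOSOME, UNLOCALIZED, Assembly, SyntenyMap

__all__ = [
    "ChainDiagnosis",
    "ContigDiagnosis",
    "diagnose_chain",
    "diagnose_contigs",
    "check_unintegrated",
    "MAX_INTRON_SPAN",
]

#: Adjacent placed exons farther apart than this on one target are an
#: exon-order anomaly of the "distance" variant. Real vertebrate introns
#: rarely approach this; draft chains need the bound to catch placements
#: scattered along a chromosome.
MAX_INTRON_SPAN = 1_000_000


@dataclass
class ChainDiagnosis:
    """Per-transcript misassembly anomalies plus the plurality target."""

    transcript_id: str
    gene_id: str
    anomalies: list[Finding] = field(default_factory=list)
    primary_target: str | None = None
    synteny_expected_target: str | None = None
    status: str = "ok"  # ok | no_placements


@dataclass
class ContigDiagnosis:
    """Chimera verdict for one contig, from the exon evidence it hosts."""

    contig_id: str
    verdict: str  # consistent | chimeric
    breakpoint_interval: tuple[int, int] | None = None
    groups: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    has_evidence: bool = True
    interleaved: bool = False


def _majority(items: list[str], prefer: str | None) -> str:
    counts: dict[str, int] = {}
    for it in items:
        counts[it] = counts.get(it, 0) + 1
    best = max(counts.values())
    tied = sorted(k for k, v in counts.items() if v == best)
    if prefer is not None and prefer in tied:
        return prefer
    return tied[0]


def diagnose_chain(
    chain: ExonChain,
    synteny: SyntenyMap,
    assembly: Assembly,
) -> ChainDiagnosis:
    """Split / orientation / order anomalies for one exon chain.

    The synteny-expected chromosome decides which side of a split is the
    misplaced block: exons on the expected chromosome are taken as
    correctly placed (very few genes are expected to change chromosome
    between close relatives), mirroring how a plurality target is chosen
    when counts tie.
    """
    expected = synteny.pairs.get(chain.ref_seq)
    diag = ChainDiagnosis(
        transcript_id=chain.transcript_id,
        gene_id=chain.gene_id,
        synteny_expected_target=expected,
    )
    placed = chain.placed()
    if not placed:
        diag.status = "no_placements"
        return diag

    targets = [p.target for p in placed]
    diag.primary_target = _majority(targets, expected)

    chrom_targets = sorted(
        {t for t in targets if assembly.role(t) == CHROMOSOME}
    )
    unloc_targets = sorted(
        {t for t in targets if assembly.role(t) == UNLOCALIZED}
    )
    misplaced = [
        p.exon_index
        for p in placed
        if expected is not None
        and p.target != expected
        and assembly.role(p.target) == CHROMOSOME
    ]
    if len(chrom_targets) > 1:
        diag.anomalies.append(
            Finding(
                gene_id=chain.gene_id,
                kind=SPLIT_CHROMOSOME,
                evidence={
                    "targets": chrom_targets,
                    "misplaced_exons": misplaced,
                },
                note="placed exons span multiple chromosomes",
            )
        )
    if unloc_targets and chrom_targets:
        diag.anomalies.append(
            Finding(
                gene_id=chain.gene_id,
                kind=SPLIT_UNLOCALIZED,
                evidence={
                    "scaffolds": unloc_targets,
                    "misplaced_exons": [
                        p.exon_index
                        for p in placed
                        if assembly.role(p.target) == UNLOCALIZED
                    ],
                },
                note="exon(s) on unlocalized scaffold(s) while the rest "
                "are chromosome-placed",
            )
        )

    strands = [p.strand for p in placed]
    majority_strand = _majority(strands, None)
    flipped = [
        p.exon_index for p in placed if p.strand != majority_strand
    ]
    if flipped:
        diag.anomalies.append(
            Finding(
                gene_id=chain.gene_id,
                kind=ORIENTATION_FLIP,
                evidence={
                    "exon_indices": flipped,
                    "majority_strand": majority_strand,
                },
                note="exon(s) on the opposite strand from the rest of "
                "the gene",
            )
        )

    diag.anomalies.extend(_order_anomalies(chain, placed, majority_strand))
    return diag


def _order_anomalies(
    chain: ExonChain, placed: list[ExonPlacement], majority_strand: str
) -> list[Finding]:
    """Monotonicity violations among same-target, same-strand exons.

    Transcription order must be ascending in target coordinate on '+',
    descending on '-'. Overlapping near-duplicate placements are
    tolerated: an inversion only counts when the backstep exceeds the
    larger of the two exon spans.
    """
    findings = []
    groups: dict[tuple[str, str], list[ExonPlacement]] = {}
    for p in placed:
        groups.setdefault((p.target, p.strand), []).append(p)
    for (target, strand), ps in sorted(groups.items()):
        if len(ps) < 2:
            continue
        sign = 1 if strand == "+" else -1
        for a, b in zip(ps, ps[1:]):
            step = sign * (b.target_start - a.target_start)
            span = max(
                a.target_end - a.target_start, b.target_end - b.target_start
            )
            if step < -span:
                findings.append(
                    Finding(
                        gene_id=chain.gene_id,
                        kind=ORDER_ANOMALY,
                        seq=target,
                        start=min(a.target_start, b.target_start),
                        end=max(a.target_end, b.target_end),
                        evidence={
                            "variant": "inversion",
                            "exon_indices": [a.exon_index, b.exon_index],
                        },
                        note="exons out of transcription order on "
                        f"{target}",
                    )
                )
            gap = abs(b.target_start - a.target_end)
            if gap > MAX_INTRON_SPAN:
                findings.append(
                    Finding(
                        gene_id=chain.gene_id,
                        kind=ORDER_ANOMALY,
                        seq=target,
                        start=min(a.target_start, b.target_start),
                        end=max(a.target_end, b.target_end),
                        evidence={
                            "variant": "distance",
                            "exon_indices": [a.exon_index, b.exon_index],
                            "gap": gap,
                        },
                        note="adjacent exons implausibly far apart",
                    )
                )
    return findings


def diagnose_contigs(
    chains: list[ExonChain],
    assembly: Assembly,
    synteny: SyntenyMap,
) -> list[ContigDiagnosis]:
    """Chimera calls per contig from the exon placements it hosts.

    Each placed exon is assigned to the contig covering it (via the
    placement table) and labelled with the chromosome its gene's chain
    expects under synteny. A contig hosting two expectation groups in
    disjoint contig intervals is chimeric, with the breakpoint bracketed
    by the innermost conflicting placements; interleaved groups are
    flagged ambiguous instead of called.
    """
    per_contig: dict[str, dict[str, list[tuple[int, int]]]] = {}
    contig_genes: dict[str, set[str]] = {}
    for chain in chains:
        expected = synteny.pairs.get(chain.ref_seq)
        if expected is None:
            continue
        for p in chain.placed():
            pl = assembly.placement_at(p.target, p.target_start)
            if pl is None or p.target_end > pl.target_end:
                continue  # in a gap or across a contig edge: no evidence
            if pl.orientation == "+":
                span = (
                    p.target_start - pl.target_start,
                    p.target_end - pl.target_start,
                )
            else:
                span = (
                    pl.target_end - p.target_end,
                    pl.target_end - p.target_start,
                )
            per_contig.setdefault(pl.contig_id, {}).setdefault(
                expected, []
            ).append(span)
            contig_genes.setdefault(pl.contig_id, set()).add(chain.gene_id)

    out = []
    for pl in assembly.placements:
        groups = per_contig.get(pl.contig_id)
        if not groups:
            out.append(
                ContigDiagnosis(
                    contig_id=pl.contig_id,
                    verdict="consistent",
                    has_evidence=False,
                )
            )
            continue
        diag = ContigDiagnosis(
            contig_id=pl.contig_id, verdict="consistent", groups=groups
        )
        if len(groups) >= 2:
            ranges = sorted(
                (min(s for s, _ in spans), max(e for _, e in spans), chrom)
                for chrom, spans in groups.items()
            )
            disjoint = all(
                a_end <= b_start
                for (_, a_end, _), (b_start, _, _) in zip(ranges, ranges[1:])
            )
            if disjoint:
                diag.verdict = "chimeric"
                diag.breakpoint_interval = (ranges[0][1], ranges[1][0])
            else:
                diag.interleaved = True
        out.append(diag)
    return out


def contig_findings(
    diagnoses: list[ContigDiagnosis],
    chains: list[ExonChain],
    assembly: Assembly,
) -> list[Finding]:
    """Per-gene findings derived from contig diagnoses."""
    chimeric = {
        d.contig_id: d for d in diagnoses if d.verdict == "chimeric"
    }
    interleaved = {
        d.contig_id for d in diagnoses if d.interleaved
    }
    findings = []
    for chain in chains:
        hit: dict[str, ContigDiagnosis] = {}
        soft: set[str] = set()
        for p in chain.placed():
            pl = assembly.placement_at(p.target, p.target_start)
            if pl is None:
                continue
            if pl.contig_id in chimeric:
                hit[pl.contig_id] = chimeric[pl.contig_id]
            if pl.contig_id in interleaved:
                soft.add(pl.contig_id)
        for cid, diag in sorted(hit.items()):
            findings.append(
                Finding(
                    gene_id=chain.gene_id,
                    kind=CHIMERIC_CONTIG,
                    seq=cid,
                    start=diag.breakpoint_interval[0],
                    end=diag.breakpoint_interval[1],
                    evidence={
                        "contig": cid,
                        "breakpoint_interval": list(
                            diag.breakpoint_interval
                        ),
                        "expected_chromosomes": sorted(diag.groups),
                    },
                    note="gene places on a contig whose two sides belong "
                    "to different chromosomes",
                )
            )
        for cid in sorted(soft):
            findings.append(
                Finding(
                    gene_id=chain.gene_id,
                    kind=AMBIGUOUS_PLACEMENT,
                    seq=cid,
                    evidence={"contig": cid, "interleaved": True},
                    note="conflicting expectations interleave on this "
                    "contig; no clean two-sided partition",
                )
            )
    return findings


def check_unintegrated(
    chain: ExonChain,
    diagnosis: ChainDiagnosis,
    assembly: Assembly,
) -> list[Finding]:
    """Failure to integrate a contig: part of the gene sits on a
    single-contig unlocalized scaffold although synteny says that contig
    belongs on the very chromosome hosting the rest of the gene."""
    expected = diagnosis.synteny_expected_target
    if expected is None or diagnosis.primary_target != expected:
        return []
    findings = []
    seen: set[str] = set()
    for p in chain.placed():
        t = p.target
        if t in seen or assembly.role(t) != UNLOCALIZED:
            continue
        seen.add(t)
        contigs = assembly.placements_on(t)
        if len(contigs) != 1:
            continue
        findings.append(
            Finding(
                gene_id=chain.gene_id,
                kind=SPLIT_UNLOCALIZED,
                seq=t,
                start=0,
                end=assembly.length(t),
                evidence={
                    "unintegrated_contig": True,
                    "contig": contigs[0].contig_id,
                    "belongs_on": expected,
                },
                note="single-contig scaffold left out of the chromosome "
                "its gene occupies",
            )
        )
    return findings
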