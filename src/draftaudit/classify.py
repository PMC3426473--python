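"""Six-way gene-annotation survey categories and recovery scoring.

Each audited gene ends in exactly one category, by severity precedence:

1. ``none_annotated``    -- the draft annotation has no model for the gene;
2. ``no_protein_derived``-- a model exists but its CDS does not translate
   cleanly (internal stop / broken frame), the pseudogene-mislabel mode;
3. ``wrong``             -- the model or locus is corrupted by spurious or
   misplaced sequence (invented exons, splits, flips, order anomalies,
   chimeric contigs, frameshifts with a surviving downstream ORF);
4. ``incomplete``        -- only truncation-type evidence (missing exons or
   sub-exon blocks, truncated models);
5. ``unclear``           -- nothing but ambiguous-placement evidence;
6. ``complete_correct``  -- otherwise.

The precedence codifies severity: categories higher in the list hide
lower ones, and adding findings can never move a gene toward
``complete_correct``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from . import integrity as K
from .integrity import Finding
from .simulate import DefectRecord

__all__ = [
    "CATEGORIES",
    "GeneVerdict",
    "SurveySummary",
    "RecoveryReport",
    "classify_gene",
    "summarize",
    "score_recovery",
    "PRIMARY_FINDING",
    "COMPATIBLE_FINDINGS",
    "EXPECTED_CATEGORIES",
]

CATEGORIES = (
    "complete_correct",
    "wrong",
    "incomplete",
    "no_protein_derived",
    "none_annotated",
    "unclear",
)

_WRONG_KINDS = frozenset(
    {
        K.SPURIOUS_EXON,
        K.SPLIT_CHROMOSOME,
        K.SPLIT_UNLOCALIZED,
        K.CHIMERIC_CONTIG,
        K.ORIENTATION_FLIP,
        K.ORDER_ANOMALY,
        K.FRAMESHIFT,
    }
)
_INCOMPLETE_KINDS = frozenset(
    {K.MISSING_EXON, K.MISSING_SUBSEQUENCE, K.MODEL_TRUNCATION}
)


@dataclass
class GeneVerdict:
    gene_id: str
    category: str
    findings: list[Finding] = field(default_factory=list)
    notes: str = ""


@dataclass
class SurveySummary:
    """Counts and integer percentages per category.

    Percentages are rounded half-up per category independently, so they
    need not sum to 100 (published surveys of this kind show the same
    behaviour); raw counts are authoritative.
    """

    counts: dict[str, int]
    total: int

    @property
    def percentages(self) -> dict[str, int]:
        return {
            c: int(
                (Decimal(n) * 100 / Decimal(self.total)).quantize(
                    Decimal(1), rounding=ROUND_HALF_UP
                )
            )
            for c, n in self.counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "count": [self.counts.get(c, 0) for c in CATEGORIES],
                "percent": [pct.get(c, 0) for c in CATEGORIES],
            }
        )


def classify_gene(
    gene_id: str,
    findings: list[Finding],
    model_present: bool,
    protein_derivable: bool,
) -> GeneVerdict:
    """Fold a gene's findings into its single survey category."""
    if not model_present and protein_derivable:
        raise ValueError(
            f"{gene_id}: protein cannot derive from an absent model"
        )
    kinds = {f.kind for f in findings}
    if not model_present:
        category = "none_annotated"
    elif not protein_derivable:
        category = "no_protein_derived"
    elif kinds & _WRONG_KINDS:
        category = "wrong"
    elif kinds & _INCOMPLETE_KINDS:
        category = "incomplete"
    elif K.AMBIGUOUS_PLACEMENT in kinds:
        category = "unclear"
    else:
        category = "complete_correct"
    return GeneVerdict(gene_id=gene_id, category=category, findings=findings)


def summarize(verdicts: list[GeneVerdict]) -> SurveySummary:
    if not verdicts:
        raise ValueError("no verdicts to summarize")
    counts = {c: 0 for c in CATEGORIES}
    for v in verdicts:
        counts[v.category] += 1
    return SurveySummary(counts=counts, total=len(verdicts))


# ---------------------------------------------------------------------------
# Recovery scoring (simulated runs only)

#: The finding kind each defect class should primarily produce. EXON_GAP
#: drives two: the missing real exon and the decoy spurious exon.
PRIMARY_FINDING: dict[str, tuple[str, ...]] = {
    "FRAMESHIFT_INDEL": (K.FRAMESHIFT,),
    "STOP_SUBSTITUTION": (K.PREMATURE_STOP,),
    "EXON_GAP": (K.MISSING_EXON, K.SPURIOUS_EXON),
    "PARTIAL_EXON_GAP": (K.MISSING_SUBSEQUENCE,),
    "CONTIG_MISASSIGNMENT": (K.SPLIT_CHROMOSOME,),
    "UNLOCALIZED_SPLIT": (K.SPLIT_UNLOCALIZED,),
    "ORIENTATION_FLIP": (K.ORIENTATION_FLIP,),
    "CHIMERIC_FUSION": (K.CHIMERIC_CONTIG,),
    "MODEL_TRUNCATION": (K.MODEL_TRUNCATION,),
    "ANNOTATION_DROP": (),
}

#: Finding kinds a defect class can legitimately explain on a gene it
#: touches (directly or via a moved contig); used for precision so that a
#: correct secondary detection is not booked as a false positive.
COMPATIBLE_FINDINGS: dict[str, frozenset] = {
    "STOP_SUBSTITUTION": frozenset({K.PREMATURE_STOP}),
    "FRAMESHIFT_INDEL": frozenset({K.FRAMESHIFT, K.PREMATURE_STOP}),
    "EXON_GAP": frozenset(
        {K.MISSING_EXON, K.SPURIOUS_EXON, K.AMBIGUOUS_PLACEMENT}
    ),
    "PARTIAL_EXON_GAP": frozenset({K.MISSING_SUBSEQUENCE, K.MISSING_EXON}),
    "CONTIG_MISASSIGNMENT": frozenset(
        {K.SPLIT_CHROMOSOME, K.ORDER_ANOMALY, K.MODEL_TRUNCATION}
    ),
    "UNLOCALIZED_SPLIT": frozenset(
        {K.SPLIT_UNLOCALIZED, K.MODEL_TRUNCATION}
    ),
    "ORIENTATION_FLIP": frozenset(
        {K.ORIENTATION_FLIP, K.ORDER_ANOMALY, K.MODEL_TRUNCATION}
    ),
    "CHIMERIC_FUSION": frozenset(
        {
            K.CHIMERIC_CONTIG,
            K.SPLIT_CHROMOSOME,
            K.SPLIT_UNLOCALIZED,
            K.MISSING_EXON,
            K.ORDER_ANOMALY,
            K.MODEL_TRUNCATION,
        }
    ),
    "ANNOTATION_DROP": frozenset(),
    "MODEL_TRUNCATION": frozenset({K.MODEL_TRUNCATION}),
}

#: Categories a defect class is expected to imply for its primary gene.
#: FRAMESHIFT_INDEL legitimately lands either way depending on whether an
#: ORF survives downstream of the indel.
EXPECTED_CATEGORIES: dict[str, frozenset] = {
    "ANNOTATION_DROP": frozenset({"none_annotated"}),
    "STOP_SUBSTITUTION": frozenset({"no_protein_derived"}),
    "FRAMESHIFT_INDEL": frozenset({"no_protein_derived", "wrong"}),
    "EXON_GAP": frozenset({"wrong"}),
    "PARTIAL_EXON_GAP": frozenset({"incomplete"}),
    "CONTIG_MISASSIGNMENT": frozenset({"wrong"}),
    "UNLOCALIZED_SPLIT": frozenset({"wrong"}),
    "ORIENTATION_FLIP": frozenset({"wrong"}),
    "CHIMERIC_FUSION": frozenset({"wrong"}),
    "MODEL_TRUNCATION": frozenset({"incomplete"}),
}


@dataclass
class RecoveryReport:
    """Ground-truth join: detection quality per finding kind plus the
    truth-category vs assigned-category confusion table."""

    sensitivity: dict[str, tuple[int, int]]  # kind -> (detected, total)
    precision: dict[str, tuple[int, int]]  # kind -> (tp, tp+fp)
    confusion: pd.DataFrame  # rows: defect class (or CLEAN); cols: category
    category_hits: tuple[int, int]  # defected genes in an expected category

    def sensitivity_rate(self, kind: str) -> float:
        d, t = self.sensitivity.get(kind, (0, 0))
        return d / t if t else 1.0

    def precision_rate(self, kind: str) -> float:
        tp, n = self.precision.get(kind, (0, 0))
        return tp / n if n else 1.0

    @staticmethod
    def merge(reports: list["RecoveryReport"]) -> "RecoveryReport":
        sens: dict[str, list[int]] = {}
        prec: dict[str, list[int]] = {}
        hits = [0, 0]
        for r in reports:
            for k, (d, t) in r.sensitivity.items():
                s = sens.setdefault(k, [0, 0])
                s[0] += d
                s[1] += t
            for k, (tp, n) in r.precision.items():
                p = prec.setdefault(k, [0, 0])
                p[0] += tp
                p[1] += n
            hits[0] += r.category_hits[0]
            hits[1] += r.category_hits[1]
        confusion = reports[0].confusion
        for r in reports[1:]:
            confusion = confusion.add(r.confusion, fill_value=0).astype(int)
        return RecoveryReport(
            sensitivity={k: tuple(v) for k, v in sens.items()},
            precision={k: tuple(v) for k, v in prec.items()},
            confusion=confusion,
            category_hits=tuple(hits),
        )


def score_recovery(
    verdicts: list[GeneVerdict],
    findings: list[Finding],
    defect_log: list[DefectRecord],
) -> RecoveryReport:
    """Join calls against the simulator's ground truth.

    Sensitivity per finding kind: the fraction of defect records whose
    primary kind(s) were found on the defected gene. Precision per kind:
    findings of that kind on genes no defect touches are false positives;
    genes a defect touches only collaterally (via its contig) count for
    neither. The confusion table tallies assigned categories per injected
    class, with untouched genes on a CLEAN row.
    """
    by_gene_kinds: dict[str, set[str]] = {}
    for f in findings:
        by_gene_kinds.setdefault(f.gene_id, set()).add(f.kind)

    primary: dict[str, str] = {}
    touched: dict[str, set[str]] = {}
    for rec in defect_log:
        primary[rec.gene_id] = rec.defect_class
        touched.setdefault(rec.gene_id, set()).add(rec.defect_class)
        for g in rec.payload.get("affected_genes", []):
            touched.setdefault(g, set()).add(rec.defect_class)

    sensitivity: dict[str, list[int]] = {}
    for rec in defect_log:
        for kind in PRIMARY_FINDING.get(rec.defect_class, ()):
            s = sensitivity.setdefault(kind, [0, 0])
            s[1] += 1
            if kind in by_gene_kinds.get(rec.gene_id, ()):
                s[0] += 1

    precision: dict[str, list[int]] = {}
    for f in findings:
        classes = touched.get(f.gene_id)
        p = precision.setdefault(f.kind, [0, 0])
        if classes is None:
            p[1] += 1  # finding on an untouched gene: false positive
        elif any(
            f.kind in COMPATIBLE_FINDINGS.get(c, frozenset())
            or f.kind in PRIMARY_FINDING.get(c, ())
            for c in classes
        ):
            p[0] += 1
            p[1] += 1
        # else: collateral gene, finding neither credited nor penalized

    rows = sorted(set(primary.values())) + ["CLEAN"]
    confusion = pd.DataFrame(0, index=rows, columns=list(CATEGORIES))
    hits = [0, 0]
    for v in verdicts:
        cls = primary.get(v.gene_id)
        if cls is None:
            row = "CLEAN" if v.gene_id not in touched else None
            if row:
                confusion.loc[row, v.category] += 1
            continue
        confusion.loc[cls, v.category] += 1
        hits[1] += 1
        if v.category in EXPECTED_CATEGORIES.get(cls, frozenset()):
            hits[0] += 1

    return RecoveryReport(
        sensitivity={k: tuple(v) for k, v in sensitivity.items()},
        precision={k: tuple(v) for k, v in precision.items()},
        confusion=confusion,
        category_hits=tuple(hits),
    )
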