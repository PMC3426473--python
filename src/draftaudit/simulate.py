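"""Synthetic truth genomes and derived corrupted draft assemblies.

:func:`generate_truth` emits a clean multi-chromosome genome whose
protein-coding genes have ATG-initiated, stop-terminated CDSs free of
internal stops and GT..AG introns. :func:`derive_draft` tiles the
chromosomes into contigs (rejoined with 100-N scaffold gaps), injects a
configurable mix of defect classes mirroring what low-coverage Sanger
drafts exhibit -- base substitutions creating stops, frameshifting
1-2 bp indels, assembly gaps swallowing exons or parts of exons, contigs
assigned to the wrong chromosome, left on unlocalized scaffolds, inverted
in place, or fused into chimeras -- plus annotation-level defects (dropped
or truncated gene models, and decoy "invented" exons drawn from intronic
sequence when a real exon was gapped out). Every applied defect is logged
as a machine-readable :class:`DefectRecord` for recovery scoring.

Determinism: one root seed; each defect draws from a substream keyed by
(seed, gene id, class) so a record is reproducible regardless of spec
order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    CHROMOSOME,
    STOP_CODONS,
    UNLOCALIZED,
    Assembly,
    ContigPlacement,
    SyntenyMap,
    TranscriptModel,
    cds_sequence,
    reverse_complement,
    spliced_sequence,
    translate_full,
)

__all__ = [
    "SimulationConfig",
    "TilingConfig",
    "DefectSpec",
    "DefectRecord",
    "DefectError",
    "DEFECT_CLASSES",
    "DEFAULT_DEFECT_MIX",
    "generate_truth",
    "derive_draft",
    "write_defect_log",
    "read_defect_log",
]

DEFECT_CLASSES = (
    "STOP_SUBSTITUTION",
    "FRAMESHIFT_INDEL",
    "EXON_GAP",
    "PARTIAL_EXON_GAP",
    "CONTIG_MISASSIGNMENT",
    "UNLOCALIZED_SPLIT",
    "ORIENTATION_FLIP",
    "CHIMERIC_FUSION",
    "ANNOTATION_DROP",
    "MODEL_TRUNCATION",
)

_SEQUENCE_CLASSES = (
    "STOP_SUBSTITUTION",
    "FRAMESHIFT_INDEL",
    "EXON_GAP",
    "PARTIAL_EXON_GAP",
    "ANNOTATION_DROP",
    "MODEL_TRUNCATION",
)
_STRUCTURAL_CLASSES = (
    "CONTIG_MISASSIGNMENT",
    "UNLOCALIZED_SPLIT",
    "ORIENTATION_FLIP",
    "CHIMERIC_FUSION",
)


class DefectError(ValueError):
    """A requested defect cannot be applied to the given genome."""


@dataclass
class SimulationConfig:
    """Truth-genome shape. Defaults give genes of ~15-20 kb spanning
    several 5-15 kb contigs, so structural defects have room to act."""

    n_chromosomes: int = 3
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (5, 9)
    exon_length: tuple[int, int] = (90, 180)
    intron_length: tuple[int, int] = (1500, 4000)
    intergenic_length: tuple[int, int] = (2000, 5000)
    gc_fraction: float = 0.41
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise ValueError("need at least one chromosome and one gene")
        for name in (
            "exons_per_gene",
            "exon_length",
            "intron_length",
            "intergenic_length",
        ):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name}: bad range ({lo}, {hi})")
        if self.exon_length[0] < 30:
            raise ValueError("exon_length minimum must be >= 30 bp")
        if self.exons_per_gene[0] < 1:
            raise ValueError("exons_per_gene minimum must be >= 1")
        if self.intron_length[0] < 40:
            raise ValueError("intron_length minimum must be >= 40 bp")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")


@dataclass
class TilingConfig:
    contig_length: tuple[int, int] = (5000, 15000)
    gap_length: int = 100
    exon_buffer: int = 25


@dataclass
class DefectSpec:
    """One defect class to inject, either at explicit genes or ``count``
    genes sampled from the eligible pool."""

    defect_class: str
    count: int | None = None
    genes: tuple[str, ...] | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.defect_class not in DEFECT_CLASSES:
            raise ValueError(f"unknown defect class {self.defect_class!r}")
        if (self.count is None) == (self.genes is None):
            raise ValueError("exactly one of count/genes must be given")


@dataclass
class DefectRecord:
    """Ground truth for one applied defect, in draft coordinates."""

    gene_id: str
    defect_class: str
    seq: str
    start: int
    end: int
    payload: dict = field(default_factory=dict)


#: Study-condition default: two genes per defect class.
DEFAULT_DEFECT_MIX = tuple(DefectSpec(c, count=2) for c in DEFECT_CLASSES)


# ---------------------------------------------------------------------------
# Truth genome

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_NONSTOP_CODONS = sorted(
    c for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in STOP_CODONS
)


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=n, p=p)
    return _NT[idx].tobytes().decode("ascii")


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    # ATG + non-stop codons + one stop: internal-stop-free by construction.
    if n_codons < 3:
        raise ValueError("CDS needs >= 3 codons")
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
    middle = "".join(_NONSTOP_CODONS[i] for i in idx)
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    return "ATG" + middle + stop


def _build_gene(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    gene_id: str,
    chrom: str,
    gene_start: int,
) -> tuple[str, TranscriptModel]:
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    ex_lens = rng.integers(
        cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_ex
    ).astype(int)
    total = int(ex_lens.sum())
    ex_lens[-1] += (3 - total % 3) % 3
    total = int(ex_lens.sum())
    cds = _random_cds(rng, total // 3)

    pieces = []
    off = 0
    for L in ex_lens:
        pieces.append(cds[off : off + int(L)])
        off += int(L)
    introns = [
        "GT" + _random_nt(rng, int(L) - 4, cfg.gc_fraction) + "AG"
        for L in rng.integers(
            cfg.intron_length[0], cfg.intron_length[1] + 1, size=n_ex - 1
        )
    ]
    cassette_parts = []
    exon_local = []  # transcript-orientation cassette coordinates
    pos = 0
    for i, piece in enumerate(pieces):
        exon_local.append((pos, pos + len(piece)))
        cassette_parts.append(piece)
        pos += len(piece)
        if i < n_ex - 1:
            cassette_parts.append(introns[i])
            pos += len(introns[i])
    cassette = "".join(cassette_parts)

    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "+":
        gseq = cassette
        exons = [(a + gene_start, b + gene_start) for a, b in exon_local]
    else:
        gseq = reverse_complement(cassette)
        L = len(cassette)
        exons = [
            (gene_start + L - b, gene_start + L - a) for a, b in exon_local
        ]
    model = TranscriptModel(
        gene_id=gene_id,
        transcript_id="t" + gene_id[1:],
        seq_name=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_span=(0, total),
    )
    return gseq, model


def generate_truth(
    config: SimulationConfig,
) -> tuple[Assembly, list[TranscriptModel]]:
    """Generate a clean genome and its annotation, deterministically."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    per_chrom: dict[str, list[str]] = {c: [] for c in chrom_names}
    for i, gid in enumerate(gene_ids):
        per_chrom[chrom_names[i % config.n_chromosomes]].append(gid)

    sequences: dict[str, str] = {}
    models: list[TranscriptModel] = []
    glo, ghi = config.intergenic_length
    for cname in chrom_names:
        parts: list[str] = []
        pos = 0
        for gid in per_chrom[cname]:
            spacer = _random_nt(
                rng, int(rng.integers(glo, ghi + 1)), config.gc_fraction
            )
            parts.append(spacer)
            pos += len(spacer)
            gseq, model = _build_gene(rng, config, gid, cname, pos)
            parts.append(gseq)
            pos += len(gseq)
            models.append(model)
        tail = _random_nt(
            rng, int(rng.integers(glo, ghi + 1)), config.gc_fraction
        )
        parts.append(tail)
        sequences[cname] = "".join(parts)

    models.sort(key=lambda m: m.gene_id)
    assembly = Assembly(
        sequences=sequences,
        sequence_role={c: CHROMOSOME for c in chrom_names},
    )
    return assembly, models


# ---------------------------------------------------------------------------
# Draft derivation


@dataclass
class _Edit:
    pos: int  # truth coordinate on its chromosome
    kind: str  # sub | ins | del | mask
    length: int = 0
    seq: str = ""


@dataclass
class _Contig:
    cid: str
    parts: list[tuple[str, int, int]]  # (source chrom, src_start, src_end)
    flipped: bool = False

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e in self.parts)


def _gene_rng(seed: int, gene_id: str, defect_class: str) -> np.random.Generator:
    return np.random.default_rng(
        [
            int(seed) & 0x7FFFFFFF,
            zlib.crc32(gene_id.encode()) & 0x7FFFFFFF,
            zlib.crc32(defect_class.encode()) & 0x7FFFFFFF,
        ]
    )


def _apply_edits(seq: str, edits: list[_Edit]) -> str:
    for ed in sorted(edits, key=lambda e: e.pos, reverse=True):
        if ed.kind == "sub":
            seq = seq[: ed.pos] + ed.seq + seq[ed.pos + 1 :]
        elif ed.kind == "ins":
            seq = seq[: ed.pos] + ed.seq + seq[ed.pos :]
        elif ed.kind == "del":
            seq = seq[: ed.pos] + seq[ed.pos + ed.length :]
        elif ed.kind == "mask":
            seq = seq[: ed.pos] + "N" * ed.length + seq[ed.pos + ed.length :]
        else:  # pragma: no cover
            raise AssertionError(ed.kind)
    return seq


def _make_lift(edits: list[_Edit]):
    events = sorted(
        [
            (e.pos, e.length if e.kind == "ins" else -e.length)
            for e in edits
            if e.kind in ("ins", "del")
        ]
    )

    def lift(p: int) -> int:
        out = p
        for q, d in events:
            if d > 0:
                if p >= q:
                    out += d
            else:
                dl = -d
                if p >= q + dl:
                    out -= dl
                elif p > q:
                    out -= p - q
        return out

    return lift


def _exon_neighbors(
    model: TranscriptModel, k: int
) -> tuple[int, int]:
    """Genomic (prev_end, next_start) around transcription-exon ``k``."""
    s, e = model.exons[k]
    others = sorted(model.exons)
    prev_end, next_start = 0, 10**12
    for os_, oe in others:
        if oe <= s:
            prev_end = max(prev_end, oe)
        if os_ >= e:
            next_start = min(next_start, os_)
    return prev_end, next_start


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _in_interval(ivals, pos):
    for s, e in ivals:
        if s <= pos < e:
            return (s, e)
        if s > pos:
            break
    return None


class _DraftBuilder:
    """Stateful helper that walks derive_draft's phases."""

    def __init__(self, truth, truth_models, specs, tiling, seed, annotate):
        self.truth = truth
        self.models = {m.gene_id: m for m in truth_models}
        self.model_list = sorted(truth_models, key=lambda m: m.gene_id)
        self.specs = list(specs)
        self.tiling = tiling or TilingConfig()
        self.seed = int(seed)
        self.annotate = annotate
        self.rng = np.random.default_rng([self.seed, 0xD2AF])
        self.assigned: dict[str, str] = {}  # gene -> class
        self.edits: dict[str, list[_Edit]] = {
            c: [] for c in truth.sequences
        }
        self.records: list[DefectRecord] = []
        self._pending: list[dict] = []  # records awaiting coordinate lift
        self.dropped_genes: set[str] = set()
        self.truncated_genes: set[str] = set()
        self.decoys: dict[str, tuple[int, tuple[int, int]]] = {}
        self.chrom_names = list(truth.sequences)

    # -- phase 1: assignment ------------------------------------------------

    def _eligible_sequence(self, gid: str, cls: str) -> bool:
        m = self.models[gid]
        if cls == "STOP_SUBSTITUTION":
            return m.spliced_length >= 45
        if cls == "FRAMESHIFT_INDEL":
            return any(e - s >= 40 for s, e in m.exons)
        if cls == "EXON_GAP":
            return m.n_exons >= 3
        if cls == "PARTIAL_EXON_GAP":
            return any(e - s >= 160 for s, e in m.exons)
        if cls == "ANNOTATION_DROP":
            return True
        if cls == "MODEL_TRUNCATION":
            return m.n_exons >= 2
        raise AssertionError(cls)

    def assign_sequence_defects(self) -> None:
        pool = [m.gene_id for m in self.model_list]
        self.rng.shuffle(pool)
        self.pool = pool
        for spec in self.specs:
            if spec.defect_class in _STRUCTURAL_CLASSES:
                continue
            self._assign(spec, self._eligible_sequence)

    def _assign(self, spec: DefectSpec, eligible) -> list[str]:
        chosen: list[str] = []
        if spec.genes is not None:
            for gid in spec.genes:
                if gid not in self.models:
                    raise DefectError(f"unknown gene {gid!r} in defect spec")
                if gid in self.assigned:
                    raise DefectError(
                        f"gene {gid} already carries {self.assigned[gid]}"
                    )
                if not eligible(gid, spec.defect_class):
                    raise DefectError(
                        f"gene {gid} not eligible for {spec.defect_class}"
                    )
                self.assigned[gid] = spec.defect_class
                chosen.append(gid)
            return chosen
        for gid in self.pool:
            if len(chosen) == spec.count:
                break
            if gid in self.assigned:
                continue
            if eligible(gid, spec.defect_class):
                self.assigned[gid] = spec.defect_class
                chosen.append(gid)
        if len(chosen) < (spec.count or 0):
            raise DefectError(
                f"only {len(chosen)} of {spec.count} eligible genes for "
                f"{spec.defect_class}"
            )
        return chosen

    # -- phase 2: sequence-level edits -------------------------------------

    def apply_sequence_defects(self) -> None:
        for gid in sorted(self.assigned):
            cls = self.assigned[gid]
            if cls in _STRUCTURAL_CLASSES:
                continue
            getattr(self, "_apply_" + cls.lower())(gid)

    def _record(self, gid, cls, chrom, start, end, payload, coords="truth"):
        self._pending.append(
            dict(
                gene_id=gid,
                defect_class=cls,
                chrom=chrom,
                start=start,
                end=end,
                payload=payload,
                coords=coords,
            )
        )

    def _apply_stop_substitution(self, gid: str) -> None:
        m = self.models[gid]
        rng = _gene_rng(self.seed, gid, "STOP_SUBSTITUTION")
        cds = cds_sequence(self.truth, m)
        n_codons = len(cds) // 3
        offsets = m.exon_spliced_offsets()
        candidates = [
            c
            for c in range(5, n_codons - 5)
            if any(o1 <= 3 * c and 3 * c + 3 <= o2 for o1, o2 in offsets)
            and cds[3 * c : 3 * c + 3] not in STOP_CODONS
        ]
        for c in rng.permutation(candidates):
            c = int(c)
            codon = cds[3 * c : 3 * c + 3]
            for stop in sorted(STOP_CODONS):
                diff = [j for j in range(3) if codon[j] != stop[j]]
                if len(diff) != 1:
                    continue
                j = diff[0]
                g = m.spliced_to_genomic(3 * c + j)
                base = stop[j]
                if m.strand == "-":
                    base = reverse_complement(base)
                self.edits[m.seq_name].append(_Edit(g, "sub", seq=base))
                exon_idx = next(
                    i
                    for i, (o1, o2) in enumerate(offsets)
                    if o1 <= 3 * c < o2
                )
                self._record(
                    gid,
                    "STOP_SUBSTITUTION",
                    m.seq_name,
                    g,
                    g + 1,
                    {
                        "codon_index": c,
                        "stop_codon": stop,
                        "exon_index": exon_idx,
                    },
                )
                return
        raise DefectError(f"no stop-creating substitution found for {gid}")

    def _apply_frameshift_indel(self, gid: str) -> None:
        m = self.models[gid]
        rng = _gene_rng(self.seed, gid, "FRAMESHIFT_INDEL")
        k = int(rng.choice([1, 2]))
        kind = str(rng.choice(["ins", "del"]))
        eligible = [i for i, (s, e) in enumerate(m.exons) if e - s >= 40]
        idx = int(rng.choice(eligible))
        s, e = m.exons[idx]
        g = s + int(rng.integers(12, (e - s) - 12 - k + 1))
        if kind == "ins":
            self.edits[m.seq_name].append(
                _Edit(g, "ins", length=k, seq=_random_nt(rng, k, 0.5))
            )
        else:
            self.edits[m.seq_name].append(_Edit(g, "del", length=k))
        self._record(
            gid,
            "FRAMESHIFT_INDEL",
            m.seq_name,
            g,
            g + (k if kind == "del" else 0),
            {"kind": kind, "length": k, "exon_index": idx},
        )

    def _apply_exon_gap(self, gid: str) -> None:
        m = self.models[gid]
        rng = _gene_rng(self.seed, gid, "EXON_GAP")
        k = int(rng.integers(1, m.n_exons - 1))
        s, e = m.exons[k]
        prev_end, next_start = _exon_neighbors(m, k)
        margin = int(self.specs_param("EXON_GAP", "margin", 30))
        ml = max(0, min(margin, s - prev_end - 10))
        mr = max(0, min(margin, next_start - e - 10))
        mask_s, mask_e = s - ml, e + mr
        self.edits[m.seq_name].append(
            _Edit(mask_s, "mask", length=mask_e - mask_s)
        )
        decoy, clean = self._pick_decoy(m, k, (mask_s, mask_e), rng)
        self.decoys[gid] = (k, decoy)
        self._record(
            gid,
            "EXON_GAP",
            m.seq_name,
            mask_s,
            mask_e,
            {
                "exon_index": k,
                "decoy_start": decoy[0],
                "decoy_end": decoy[1],
                "decoy_clean": clean,
            },
        )

    def _pick_decoy(self, m, k, mask, rng) -> tuple[tuple[int, int], bool]:
        """Intronic span standing in for lost exon ``k`` in the draft model.

        Searched so the resulting model still translates without internal
        stops (the annotation pipeline being emulated emits ORF-consistent
        models): lengths within ~20% of the lost exon, congruent mod 3.
        """
        s, e = m.exons[k]
        lost = e - s
        prev_end, next_start = _exon_neighbors(m, k)
        regions = [
            (prev_end + 10, mask[0] - 10),
            (mask[1] + 10, next_start - 10),
        ]
        maxt = max(1, int(0.2 * lost) // 3)
        lengths = [lost + 3 * t for t in range(-maxt, maxt + 1)]
        lengths = [L for L in lengths if L >= 30]
        order = rng.permutation(len(lengths))
        best = None
        best_stops = 10**9
        for li in order:
            L = lengths[int(li)]
            for a, b in regions:
                if b - a < L:
                    continue
                starts = rng.integers(a, b - L + 1, size=min(40, b - a - L + 1))
                for ds in sorted(set(int(x) for x in starts)):
                    cand_exons = list(m.exons)
                    cand_exons[k] = (ds, ds + L)
                    try:
                        cand = replace(m, exons=tuple(cand_exons))
                    except ValueError:
                        continue
                    aas = translate_full(spliced_sequence(self.truth, cand))
                    stops = aas[:-1].count("*")
                    if stops == 0:
                        return (ds, ds + L), True
                    if stops < best_stops:
                        best, best_stops = (ds, ds + L), stops
        if best is None:
            raise DefectError(f"no decoy span available for {m.gene_id}")
        return best, False

    def _apply_partial_exon_gap(self, gid: str) -> None:
        m = self.models[gid]
        rng = _gene_rng(self.seed, gid, "PARTIAL_EXON_GAP")
        L = int(self.specs_param("PARTIAL_EXON_GAP", "length", 30))
        eligible = [i for i, (s, e) in enumerate(m.exons) if e - s >= 160]
        idx = int(rng.choice(eligible))
        s, e = m.exons[idx]
        prev_end, next_start = _exon_neighbors(m, idx)
        margin = 20
        if m.strand == "+":  # transcript 3' end of the exon is genomic right
            mr = max(0, min(margin, next_start - e - 10))
            mask_s, mask_e = e - L, e + mr
        else:
            ml = max(0, min(margin, s - prev_end - 10))
            mask_s, mask_e = s - ml, s + L
        self.edits[m.seq_name].append(
            _Edit(mask_s, "mask", length=mask_e - mask_s)
        )
        self._record(
            gid,
            "PARTIAL_EXON_GAP",
            m.seq_name,
            mask_s,
            mask_e,
            {"exon_index": idx, "length": L},
        )

    def _apply_annotation_drop(self, gid: str) -> None:
        m = self.models[gid]
        self.dropped_genes.add(gid)
        self._record(
            gid,
            "ANNOTATION_DROP",
            m.seq_name,
            m.genomic_start,
            m.genomic_end,
            {},
        )

    def _apply_model_truncation(self, gid: str) -> None:
        m = self.models[gid]
        self.truncated_genes.add(gid)
        self._record(
            gid,
            "MODEL_TRUNCATION",
            m.seq_name,
            m.genomic_start,
            m.genomic_end,
            {"n_exons_removed": 1},
        )

    def specs_param(self, cls: str, key: str, default):
        for spec in self.specs:
            if spec.defect_class == cls and key in spec.params:
                return spec.params[key]
        return default

    # -- phase 3: edited sequences, lifted models ---------------------------

    def build_edited(self) -> None:
        self.edited = {
            c: _apply_edits(seq, self.edits[c])
            for c, seq in self.truth.sequences.items()
        }
        self.lifts = {c: _make_lift(self.edits[c]) for c in self.edits}

    def _lift_model(self, m: TranscriptModel) -> TranscriptModel:
        lift = self.lifts[m.seq_name]
        exons = tuple((lift(s), lift(e)) for s, e in m.exons)
        sl = sum(e - s for s, e in exons)
        return replace(m, exons=exons, cds_span=(0, 3 * (sl // 3)))

    def build_pre_models(self) -> None:
        """Draft annotation in pre-tiling coordinates."""
        self.lifted_truth = {
            gid: self._lift_model(m) for gid, m in self.models.items()
        }
        pre = {}
        for gid, m in self.lifted_truth.items():
            if gid in self.dropped_genes:
                continue
            if gid in self.truncated_genes:
                exons = m.exons[:-1]
                sl = sum(e - s for s, e in exons)
                m = replace(m, exons=exons, cds_span=(0, 3 * (sl // 3)))
            if gid in self.decoys:
                k, span = self.decoys[gid]
                lift = self.lifts[m.seq_name]
                exons = list(m.exons)
                exons[k] = (lift(span[0]), lift(span[1]))
                sl = sum(e - s for s, e in exons)
                m = replace(
                    m, exons=tuple(exons), cds_span=(0, 3 * (sl // 3))
                )
            pre[gid] = m
        self.pre_models = pre

    # -- phase 4: tiling ----------------------------------------------------

    def tile(self) -> None:
        t = self.tiling
        self.avoid: dict[str, list[tuple[int, int]]] = {}
        for c in self.chrom_names:
            ivals = []
            for m in list(self.lifted_truth.values()) + list(
                self.pre_models.values()
            ):
                if m.seq_name != c:
                    continue
                for s, e in m.exons:
                    ivals.append((s - t.exon_buffer, e + t.exon_buffer))
            self.avoid[c] = _merge_intervals(ivals)

        self.contigs: dict[str, _Contig] = {}
        self.layout: dict[str, list[str]] = {}
        for c in self.chrom_names:
            L = len(self.edited[c])
            cuts = [0]
            while cuts[-1] < L:
                cut = cuts[-1] + int(
                    self.rng.integers(t.contig_length[0], t.contig_length[1] + 1)
                )
                if cut < L:
                    hit = _in_interval(self.avoid[c], cut)
                    if hit is not None:
                        cut = hit[1]
                cuts.append(min(cut, L))
            ids = []
            for i, (a, b) in enumerate(zip(cuts, cuts[1:])):
                cid = f"{c}.c{i:04d}"
                self.contigs[cid] = _Contig(cid, [(c, a, b)])
                ids.append(cid)
            self.layout[c] = ids
        self.scaffolds: list[tuple[str, list[str]]] = []

    def _contig_of_span(self, chrom: str, s: int, e: int) -> str | None:
        for cid in self.layout.get(chrom, []):
            (_, a, b) = self.contigs[cid].parts[0]
            if a <= s and e <= b:
                return cid
        return None

    def _genes_on_span(self, chrom: str, s: int, e: int) -> list[str]:
        out = []
        for gid, m in self.lifted_truth.items():
            if m.seq_name != chrom:
                continue
            if any(es < e and s < ee for es, ee in m.exons):
                out.append(gid)
        return sorted(out)

    # -- phase 5: structural defects ----------------------------------------

    def _candidate_contig(self, gid: str, for_flip: bool) -> str | None:
        m = self.lifted_truth[gid]
        chrom = m.seq_name
        by_contig: dict[str, list[int]] = {}
        for i, (s, e) in enumerate(m.exons):
            cid = self._contig_of_span(chrom, s, e)
            if cid is None:
                return None
            by_contig.setdefault(cid, []).append(i)
        if len(by_contig) < 2:
            return None
        n = m.n_exons
        best = None
        best_key = None
        for cid, idxs in by_contig.items():
            middle = [i for i in idxs if 0 < i < n - 1]
            if not middle:
                continue
            if len(idxs) == n:
                continue
            if for_flip and 2 * len(idxs) >= n:
                continue
            if cid in self.used_contigs:
                continue
            (_, a, b) = self.contigs[cid].parts[0]
            others = [
                g
                for g in self._genes_on_span(chrom, a, b)
                if g != gid and g in self.assigned
            ]
            if others:
                continue
            key = min(middle)
            if best_key is None or key < best_key:
                best, best_key = cid, key
        return best

    def apply_structural_defects(self) -> None:
        self.used_contigs: set[str] = set()
        n_chrom = len(self.chrom_names)
        for spec in self.specs:
            cls = spec.defect_class
            if cls not in _STRUCTURAL_CLASSES:
                continue
            if cls in ("CONTIG_MISASSIGNMENT", "CHIMERIC_FUSION") and n_chrom < 2:
                raise DefectError(f"{cls} needs >= 2 chromosomes")
            if spec.genes is not None:
                for gid in spec.genes:
                    if not self._try_structural(gid, cls):
                        raise DefectError(f"gene {gid} not eligible for {cls}")
                continue
            done = 0
            for gid in self.pool:
                if done == spec.count:
                    break
                if self._try_structural(gid, cls):
                    done += 1
            if done < spec.count:
                raise DefectError(
                    f"only {done} of {spec.count} eligible genes for {cls}"
                )

    def _try_structural(self, gid: str, cls: str) -> bool:
        if gid in self.assigned:
            return False
        cid = self._candidate_contig(gid, for_flip=cls == "ORIENTATION_FLIP")
        if cid is None:
            return False
        rng = _gene_rng(self.seed, gid, cls)
        chrom = self.lifted_truth[gid].seq_name
        if cls == "CONTIG_MISASSIGNMENT":
            others = [c for c in self.chrom_names if c != chrom]
            dest = others[int(rng.integers(0, len(others)))]
            self.layout[chrom].remove(cid)
            self.layout[dest].append(cid)
            self._finish_structural(
                gid, cls, cid, {"moved_to": dest}
            )
            return True
        if cls == "UNLOCALIZED_SPLIT":
            self.layout[chrom].remove(cid)
            name = f"scaffold_un{len(self.scaffolds) + 1}"
            self.scaffolds.append((name, [cid]))
            self._finish_structural(
                gid, cls, cid, {"scaffold": name}
            )
            return True
        if cls == "ORIENTATION_FLIP":
            self.contigs[cid].flipped = True
            self._finish_structural(gid, cls, cid, {})
            return True
        if cls == "CHIMERIC_FUSION":
            return self._try_chimera(gid, cid, rng)
        raise AssertionError(cls)

    def _finish_structural(self, gid, cls, cid, extra) -> None:
        self.assigned[gid] = cls
        self.used_contigs.add(cid)
        (c, a, b) = self.contigs[cid].parts[0]
        payload = {
            "contig": cid,
            "affected_genes": [
                g for g in self._genes_on_span(c, a, b) if g != gid
            ],
        }
        payload.update(extra)
        self._record(gid, cls, cid, 0, b - a, payload, coords="contig")

    def _try_chimera(self, gid_a: str, cid_a: str, rng) -> bool:
        chrom_a = self.lifted_truth[gid_a].seq_name
        # partner gene on another chromosome with its own eligible contig
        partner = None
        for gid_b in self.pool:
            if gid_b in self.assigned or gid_b == gid_a:
                continue
            if self.lifted_truth[gid_b].seq_name == chrom_a:
                continue
            cid_b = self._candidate_contig(gid_b, for_flip=False)
            if cid_b is not None and cid_b != cid_a:
                partner = (gid_b, cid_b)
                break
        if partner is None:
            return False
        gid_b, cid_b = partner
        chrom_b = self.lifted_truth[gid_b].seq_name
        (_, a1, a2) = self.contigs[cid_a].parts[0]
        (_, b1, b2) = self.contigs[cid_b].parts[0]
        ma = self.lifted_truth[gid_a]
        mb = self.lifted_truth[gid_b]
        a_exons = [(s, e) for s, e in ma.exons if a1 <= s and e <= a2]
        b_exons = [(s, e) for s, e in mb.exons if b1 <= s and e <= b2]
        cut_a = max(e for _, e in a_exons) + 50
        hit = _in_interval(self.avoid[chrom_a], cut_a)
        if hit is not None:
            cut_a = hit[1]
        cut_a = min(cut_a, a2)
        cut_b = min(s for s, _ in b_exons) - 50
        hit = _in_interval(self.avoid[chrom_b], cut_b)
        if hit is not None:
            cut_b = hit[0]
        cut_b = max(cut_b, b1)
        # do not silently destroy another defected gene's evidence
        lost_prefix_genes = self._genes_on_span(chrom_b, b1, cut_b)
        if any(g in self.assigned for g in lost_prefix_genes):
            cut_b = b1
            lost_prefix_genes = []
        lost_suffix_genes = [
            g
            for g in self._genes_on_span(chrom_a, cut_a, a2)
            if g != gid_a
        ]
        if any(g in self.assigned for g in lost_suffix_genes):
            return False

        fusion_id = f"chim_{cid_a}_{cid_b}"
        fusion = _Contig(
            fusion_id,
            [(chrom_a, a1, cut_a), (chrom_b, cut_b, b2)],
        )
        self.contigs[fusion_id] = fusion
        self.layout[chrom_a].remove(cid_a)
        i = self.layout[chrom_b].index(cid_b)
        self.layout[chrom_b][i] = fusion_id
        self.assigned[gid_a] = "CHIMERIC_FUSION"
        self.used_contigs.update({cid_a, cid_b, fusion_id})
        affected = set(self._genes_on_span(chrom_a, a1, a2))
        affected |= set(lost_prefix_genes)
        affected |= set(self._genes_on_span(chrom_b, cut_b, b2))
        affected.discard(gid_a)
        self._record(
            gid_a,
            "CHIMERIC_FUSION",
            fusion_id,
            0,
            fusion.length,
            {
                "contig": fusion_id,
                "fusion_point": cut_a - a1,
                "partner_gene": gid_b,
                "source_contigs": [cid_a, cid_b],
                "affected_genes": sorted(affected),
            },
            coords="contig",
        )
        return True

    # -- phase 6: final assembly --------------------------------------------

    def _contig_seq(self, contig: _Contig) -> str:
        seq = "".join(self.edited[c][s:e] for c, s, e in contig.parts)
        return reverse_complement(seq) if contig.flipped else seq

    def build_final(self) -> None:
        t = self.tiling
        sequences: dict[str, str] = {}
        roles: dict[str, str] = {}
        placements: list[ContigPlacement] = []
        self.placement_by_cid: dict[str, ContigPlacement] = {}
        order = [(c, self.layout[c], CHROMOSOME) for c in self.chrom_names]
        order += [(n, ids, UNLOCALIZED) for n, ids in self.scaffolds]
        for name, ids, role in order:
            parts: list[str] = []
            pos = 0
            for cid in ids:
                if parts:
                    parts.append("N" * t.gap_length)
                    pos += t.gap_length
                seq = self._contig_seq(self.contigs[cid])
                pl = ContigPlacement(
                    cid,
                    name,
                    pos,
                    pos + len(seq),
                    "-" if self.contigs[cid].flipped else "+",
                )
                placements.append(pl)
                self.placement_by_cid[cid] = pl
                parts.append(seq)
                pos += len(seq)
            sequences[name] = "".join(parts)
            roles[name] = role
        self.draft = Assembly(
            sequences=sequences, sequence_role=roles, placements=placements
        )
        # part index for lifting pre-tiling coords to the final assembly
        self.part_index: dict[str, list[tuple[int, int, str, int]]] = {}
        for cid, contig in self.contigs.items():
            if cid not in self.placement_by_cid:
                continue
            local = 0
            for c, s, e in contig.parts:
                self.part_index.setdefault(c, []).append((s, e, cid, local))
                local += e - s
        for c in self.part_index:
            self.part_index[c].sort()

    def lift_final(
        self, chrom: str, s: int, e: int
    ) -> tuple[str, int, int, bool] | None:
        """Map a pre-tiling span to (target, start, end, flipped) or None if
        the span was dropped or straddles a contig boundary."""
        for ps, pe, cid, loc in self.part_index.get(chrom, []):
            if ps <= s and e <= pe:
                contig = self.contigs[cid]
                pl = self.placement_by_cid[cid]
                ls, le = loc + (s - ps), loc + (e - ps)
                if contig.flipped:
                    CL = contig.length
                    ls, le = CL - le, CL - ls
                return (
                    pl.target,
                    pl.target_start + ls,
                    pl.target_start + le,
                    contig.flipped,
                )
        return None

    def build_final_models(self) -> list[TranscriptModel] | None:
        """Draft annotation on the final assembly.

        Exons that left a gene's home chromosome (moved, fused or flipped
        contigs) are dropped and the model is cut back to its longest
        transcription-contiguous run of surviving exons with a
        frame-aligned CDS -- emulating an annotator that builds a partial
        but translatable model from the sequence that remains in place.
        """
        if not self.annotate:
            return None
        final = []
        for gid, m in sorted(self.pre_models.items()):
            home = m.seq_name
            mapped = [self.lift_final(home, s, e) for s, e in m.exons]
            ok = [
                mp is not None and mp[0] == home and not mp[3]
                for mp in mapped
            ]
            # longest contiguous run of in-place exons (earliest on ties)
            best = (0, 0)
            i = 0
            while i < len(ok):
                if not ok[i]:
                    i += 1
                    continue
                j = i
                while j < len(ok) and ok[j]:
                    j += 1
                if j - i > best[1] - best[0]:
                    best = (i, j)
                i = j
            i0, i1 = best
            if i1 - i0 == 0:
                continue
            exons = tuple((mp[1], mp[2]) for mp in mapped[i0:i1])
            lens = [e - s for s, e in m.exons]
            off = sum(lens[:i0])
            run_len = sum(lens[i0:i1])
            cds_start = (m.cds_span[0] - off) % 3
            cds_end = cds_start + 3 * ((run_len - cds_start) // 3)
            if cds_end - cds_start < 3:
                continue
            final.append(
                replace(
                    m,
                    seq_name=home,
                    exons=exons,
                    cds_span=(cds_start, cds_end),
                )
            )
        return final

    # -- phase 7: records ----------------------------------------------------

    def finalize_records(self) -> list[DefectRecord]:
        for p in self._pending:
            payload = dict(p["payload"])
            if p["coords"] == "contig":
                cid = payload["contig"]
                pl = self.placement_by_cid.get(cid)
                if pl is None:
                    seq, start, end = p["chrom"], p["start"], p["end"]
                else:
                    seq, start, end = pl.target, pl.target_start, pl.target_end
                    payload["contig_start"] = pl.target_start
                    payload["contig_end"] = pl.target_end
            else:
                lift = self.lifts[p["chrom"]]
                s1 = lift(p["start"])
                e1 = lift(p["end"]) if p["end"] > p["start"] else s1
                mp = self.lift_final(p["chrom"], s1, max(e1, s1 + 1))
                if mp is None:
                    seq, start, end = p["chrom"], s1, max(e1, s1)
                    payload["lifted"] = False
                else:
                    seq, start, end = mp[0], mp[1], mp[2]
                    if p["end"] == p["start"]:
                        end = start
                if "decoy_start" in payload:
                    lift2 = self.lift_final(
                        p["chrom"],
                        lift(payload["decoy_start"]),
                        lift(payload["decoy_end"]),
                    )
                    if lift2 is not None:
                        payload["decoy_start"] = lift2[1]
                        payload["decoy_end"] = lift2[2]
            self.records.append(
                DefectRecord(
                    gene_id=p["gene_id"],
                    defect_class=p["defect_class"],
                    seq=seq,
                    start=start,
                    end=end,
                    payload=payload,
                )
            )
        self.records.sort(key=lambda r: (r.gene_id, r.defect_class))
        return self.records


def derive_draft(
    truth_assembly: Assembly,
    truth_models: list[TranscriptModel],
    defect_specs=(),
    tiling: TilingConfig | None = None,
    seed: int = 0,
    annotate: bool = True,
) -> tuple[Assembly, list[TranscriptModel] | None, list[DefectRecord]]:
    """Derive a corrupted draft assembly from a truth genome.

    Returns the draft assembly (chromosome + unlocalized-scaffold
    sequences with the contig placement table filled in), the draft's own
    gene models (``None`` if ``annotate`` is false), and the ground-truth
    defect log.
    """
    b = _DraftBuilder(
        truth_assembly, truth_models, defect_specs, tiling, seed, annotate
    )
    b.assign_sequence_defects()
    b.apply_sequence_defects()
    b.build_edited()
    b.build_pre_models()
    b.tile()
    b.apply_structural_defects()
    b.build_final()
    draft_models = b.build_final_models()
    records = b.finalize_records()
    b.draft.validate()
    return b.draft, draft_models, records


# ---------------------------------------------------------------------------
# Defect log IO

_LOG_COLS = ["gene_id", "class", "seq", "start", "end", "payload"]


def write_defect_log(records: list[DefectRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "class": r.defect_class,
                "seq": r.seq,
                "start": r.start,
                "end": r.end,
                "payload": json.dumps(r.payload, sort_keys=True),
            }
            for r in records
        ],
        columns=_LOG_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_defect_log(path) -> list[DefectRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "seq": str})
    return [
        DefectRecord(
            gene_id=row["gene_id"],
            defect_class=row["class"],
            seq=row["seq"],
            start=int(row["start"]),
            end=int(row["end"]),
            payload=json.loads(row["payload"]),
        )
        for row in df.to_dict("records")
    ]


def identity_synteny(truth_assembly: Assembly) -> SyntenyMap:
    """The truth-vs-draft synteny expectation: each chromosome maps to
    itself (real cross-species use swaps in a two-column table)."""
    return SyntenyMap.identity(
        n for n in truth_assembly.sequences
        if truth_assembly.role(n) == CHROMOSOME
    )
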