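import pytest

from draftaudit.integrity import (
    AMBIGUOUS_PLACEMENT,
    FRAMESHIFT,
    MISSING_EXON,
    MISSING_SUBSEQUENCE,
    MODEL_TRUNCATION,
    PREMATURE_STOP,
    SPURIOUS_EXON,
    detect_frameshift,
    detect_missing_exon,
    detect_missing_subsequence,
    detect_model_truncation,
    detect_spurious_exon,
    find_gaps,
)
from draftaudit.mapping import ExonChain, ExonPlacement
from draftaudit.model import Assembly, TranscriptModel


def _placement(i, start, end, events=(), status="placed", qs=None, qe=None,
               target="chr1"):
    n = end - start
    return ExonPlacement(
        gene_id="g",
        exon_index=i,
        target=target,
        target_start=start,
        target_end=end,
        strand="+",
        score=2.0 * n,
        identity=1.0,
        coverage=1.0,
        indel_events=list(events),
        status=status,
        query_start=qs if qs is not None else 0,
        query_end=qe if qe is not None else n,
        exon_length=n,
    )


def _chain(placements):
    return ExonChain("g", "t", "chr1", "+", placements)


def _model(n_exons, exon_len=90, intron=200):
    exons = []
    pos = 0
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len))
        pos += exon_len + intron
    total = n_exons * exon_len
    return TranscriptModel(
        "g", "t", "chr1", "+", tuple(exons), (0, 3 * (total // 3))
    )


class TestFrameshift:
    def test_single_insertion_reports(self):
        model = _model(2)
        chain = _chain([
            _placement(0, 0, 91, events=[(40, 40, 1, "ins")]),
            _placement(1, 290, 380),
        ])
        (f,) = detect_frameshift(chain, model)
        assert f.kind == FRAMESHIFT
        assert f.evidence["net_indel"] == 1
        assert f.evidence["first_indel"]["exon_offset"] == 40

    def test_in_frame_deletion_silent(self):
        model = _model(2)
        chain = _chain([
            _placement(0, 0, 87, events=[(40, 40, 3, "del")]),
            _placement(1, 290, 380),
        ])
        assert detect_frameshift(chain, model) == []

    def test_compensating_indels_still_report_interior_span(self):
        # +2 then +1 nets to 3 at the exon end but the span between the
        # two indels is out of frame
        model = _model(1)
        chain = _chain([
            _placement(0, 0, 93, events=[(30, 30, 2, "ins"),
                                         (60, 62, 1, "ins")]),
        ])
        (f,) = detect_frameshift(chain, model)
        assert f.evidence["net_indel"] == 3
        assert "out-of-frame span" in f.note

    def test_structural_indels_excluded(self):
        model = _model(1)
        chain = _chain([
            _placement(0, 0, 60, events=[(30, 30, 31, "del")]),
        ])
        assert detect_frameshift(chain, model) == []

    def test_simulated_frameshift_found_on_right_gene(self, defected_run):
        rec = next(
            r for r in defected_run.defect_log
            if r.defect_class == "FRAMESHIFT_INDEL"
        )
        hits = [
            f for f in defected_run.findings
            if f.kind == FRAMESHIFT and f.gene_id == rec.gene_id
        ]
        assert len(hits) == 1

    def test_frameshift_oracle_divergence_within_one_codon(self, defected_run):
        # independent check: translating the reconstructed draft CDS, the
        # protein must diverge from the ortholog's no earlier than the
        # codon containing the reported indel
        from draftaudit.integrity import reconstruct_cds
        from draftaudit.model import cds_sequence, translate_full

        rec = next(
            r for r in defected_run.defect_log
            if r.defect_class == "FRAMESHIFT_INDEL"
        )
        f = next(
            f for f in defected_run.findings
            if f.kind == FRAMESHIFT and f.gene_id == rec.gene_id
        )
        chain = next(
            c for c in defected_run.chains if c.gene_id == rec.gene_id
        )
        model = next(
            m for m in defected_run.truth_models
            if m.gene_id == rec.gene_id
        )
        recon = reconstruct_cds(chain, defected_run.draft, model)
        truth_aas = translate_full(cds_sequence(defected_run.truth, model))
        draft_aas = translate_full(recon)
        diverge = next(
            i for i, (a, b) in enumerate(zip(truth_aas, draft_aas))
            if a != b
        )
        off = model.exon_spliced_offsets()[
            f.evidence["first_indel"]["exon_index"]
        ][0] + f.evidence["first_indel"]["exon_offset"]
        assert abs(diverge - off // 3) <= 1


class TestPrematureStop:
    def test_simulated_stop_at_logged_codon(self, defected_run):
        rec = next(
            r for r in defected_run.defect_log
            if r.defect_class == "STOP_SUBSTITUTION"
        )
        f = next(
            f for f in defected_run.findings
            if f.kind == PREMATURE_STOP and f.gene_id == rec.gene_id
        )
        assert f.evidence["codon_index"] == rec.payload["codon_index"]
        assert f.evidence["causative_base"]["draft_base"] in "ACGT"

    def test_clean_genes_never_called(self, clean_run):
        assert not [
            f for f in clean_run.findings if f.kind == PREMATURE_STOP
        ]

    def test_split_gene_deferred(self, defected_run):
        # genes split by contig moves must not get a stop call from the
        # unreconstructable CDS
        rec = next(
            r for r in defected_run.defect_log
            if r.defect_class == "CONTIG_MISASSIGNMENT"
        )
        assert not [
            f for f in defected_run.findings
            if f.kind == PREMATURE_STOP and f.gene_id == rec.gene_id
        ]


class TestMissingExon:
    def test_gap_explained_when_flanks_bracket_n_run(self, defected_run):
        rec = next(
            r for r in defected_run.defect_log
            if r.defect_class == "EXON_GAP"
        )
        f = next(
            f for f in defected_run.findings
            if f.kind == MISSING_EXON and f.gene_id == rec.gene_id
        )
        assert f.evidence["gap_explained"] is True
        assert f.evidence["exon_index"] == rec.payload["exon_index"]

    def test_clean_deletion_not_gap_explained(self):
        chain = _chain([
            _placement(0, 0, 90),
            _placement(1, 0, 0, status="unplaced"),
            _placement(2, 500, 590),
        ])
        (f,) = detect_missing_exon(chain, {"chr1": []})
        assert f.evidence["gap_explained"] is False

    def test_clean_draft_has_none(self, clean_run):
        assert not [
            f for f in clean_run.findings if f.kind == MISSING_EXON
        ]


class TestMissingSubsequence:
    def test_simulated_partial_gap_length_recovered(self, defected_run):
        rec = next(
            r for r in defected_run.defect_log
            if r.defect_class == "PARTIAL_EXON_GAP"
        )
        f = next(
            f for f in defected_run.findings
            if f.kind == MISSING_SUBSEQUENCE and f.gene_id == rec.gene_id
        )
        lo, hi = f.evidence["missing_block"]
        assert abs((hi - lo) - rec.payload["length"]) <= 5

    def test_full_coverage_silent(self):
        chain = _chain([_placement(0, 0, 90)])
        assert detect_missing_subsequence(chain) == []

    def test_small_shortfall_below_threshold_silent(self):
        chain = _chain([_placement(0, 0, 80, qs=0, qe=80)])
        chain.placements[0].exon_length = 90  # 10 nt missing < 15
        assert detect_missing_subsequence(chain) == []

    def test_internal_structural_deletion_reported(self):
        chain = _chain([
            _placement(0, 0, 60, events=[(30, 30, 30, "del")],
                       qs=0, qe=90),
        ])
        chain.placements[0].exon_length = 90
        (f,) = detect_missing_subsequence(chain)
        assert f.evidence["where"] == "internal"
        assert f.evidence["missing_block"] == [30, 60]


class TestSpuriousExon:
    def _chain_for(self, spans):
        return _chain([
            _placement(i, s, e) for i, (s, e) in enumerate(spans)
        ])

    def test_unsupported_anchored_exon_is_spurious(self):
        chains = [self._chain_for([(0, 90), (400, 490)])]
        model = TranscriptModel(
            "g", "t", "chr1", "+", ((0, 90), (200, 290), (400, 490)), (0, 270)
        )
        (f,) = detect_spurious_exon([model], chains)
        assert f.kind == SPURIOUS_EXON and f.evidence["exon_index"] == 1

    def test_half_overlap_routed_to_ambiguous(self):
        chains = [self._chain_for([(0, 90), (245, 335), (400, 490)])]
        model = TranscriptModel(
            "g", "t", "chr1", "+", ((0, 90), (200, 290), (400, 490)), (0, 270)
        )
        (f,) = detect_spurious_exon([model], chains)
        assert f.kind == AMBIGUOUS_PLACEMENT

    def test_simulated_decoy_exon_detected(self, defected_run):
        rec = next(
            r for r in defected_run.defect_log
            if r.defect_class == "EXON_GAP"
        )
        hits = [
            f for f in defected_run.findings
            if f.kind == SPURIOUS_EXON and f.gene_id == rec.gene_id
        ]
        assert len(hits) == 1
        assert hits[0].start == rec.payload["decoy_start"]

    def test_faithful_model_silent(self, clean_run):
        assert not [
            f for f in clean_run.findings if f.kind == SPURIOUS_EXON
        ]


class TestModelTruncation:
    def test_supported_exons_beyond_model_reported(self, defected_run):
        rec = next(
            r for r in defected_run.defect_log
            if r.defect_class == "MODEL_TRUNCATION"
        )
        f = next(
            f for f in defected_run.findings
            if f.kind == MODEL_TRUNCATION and f.gene_id == rec.gene_id
        )
        assert len(f.evidence["missing_exon_indices"]) == 1

    def test_complete_model_silent(self):
        model = _model(2, exon_len=90, intron=200)
        chain = _chain([_placement(0, 0, 90), _placement(1, 290, 380)])
        assert detect_model_truncation([model], [chain]) == []


def test_find_gaps_reports_maximal_runs():
    asm = Assembly({"c": "ACGT" + "N" * 12 + "ACGT" + "N" * 5 + "AC"})
    gaps = find_gaps(asm)
    assert gaps["c"] == [(4, 16)]  # the 5-run is below min_gap_len
    assert find_gaps(asm, min_gap_len=5)["c"] == [(4, 16), (20, 25)]
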