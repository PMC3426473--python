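import pytest

from draftaudit.integrity import (
    CHIMERIC_CONTIG,
    ORDER_ANOMALY,
    ORIENTATION_FLIP,
    SPLIT_CHROMOSOME,
    SPLIT_UNLOCALIZED,
)
from draftaudit.mapping import ExonChain, ExonPlacement
from draftaudit.misassembly import (
    check_unintegrated,
    diagnose_chain,
    diagnose_contigs,
)
from draftaudit.model import (
    Assembly,
    ContigPlacement,
    SyntenyMap,
    reverse_complement,
)

SYNTENY = SyntenyMap({"chr4": "chr4", "chrX": "chrX"})


def _asm(roles=None, placements=()):
    names = ["chr4", "chrX", "un1", "un2"]
    return Assembly(
        {n: "A" * 200_000 for n in names},
        sequence_role=roles
        or {
            "chr4": "chromosome",
            "chrX": "chromosome",
            "un1": "unlocalized_scaffold",
            "un2": "unlocalized_scaffold",
        },
        placements=list(placements),
    )


def _p(i, target, start, end, strand="+"):
    return ExonPlacement(
        gene_id="g",
        exon_index=i,
        target=target,
        target_start=start,
        target_end=end,
        strand=strand,
        score=100.0,
        identity=1.0,
        coverage=1.0,
        status="placed",
        query_start=0,
        query_end=end - start,
        exon_length=end - start,
    )


def _chain(placements, ref="chr4"):
    return ExonChain("g", "t", ref, "+", placements)


class TestDiagnoseChain:
    def test_split_chromosome_and_unlocalized_together(self):
        # exons 3-5 on the wrong chromosome, 6-8 on two unlocalized
        # scaffolds of the right chromosome: both split kinds, and the
        # synteny expectation marks exons 3-5 as the misplaced block
        placements = (
            [_p(i, "chr4", 1000 * i, 1000 * i + 100) for i in range(3)]
            + [_p(i, "chrX", 5000 + 1000 * i, 5000 + 1000 * i + 100)
               for i in (3, 4, 5)]
            + [_p(6, "un1", 970, 1112), _p(7, "un2", 2910, 3400),
               _p(8, "un2", 3500, 3818)]
        )
        diag = diagnose_chain(_chain(placements), SYNTENY, _asm())
        kinds = {f.kind for f in diag.anomalies}
        assert kinds == {SPLIT_CHROMOSOME, SPLIT_UNLOCALIZED}
        split = next(
            f for f in diag.anomalies if f.kind == SPLIT_CHROMOSOME
        )
        assert split.evidence["misplaced_exons"] == [3, 4, 5]
        assert diag.primary_target == "chr4"
        assert diag.synteny_expected_target == "chr4"

    def test_single_opposite_strand_exon_flagged(self):
        placements = [
            _p(i, "chr4", 1000 * i, 1000 * i + 100) for i in range(5)
        ]
        placements[2] = _p(2, "chr4", 2000, 2100, strand="-")
        diag = diagnose_chain(_chain(placements), SYNTENY, _asm())
        (f,) = [a for a in diag.anomalies if a.kind == ORIENTATION_FLIP]
        assert f.evidence["exon_indices"] == [2]
        assert f.evidence["majority_strand"] == "+"

    def test_consistent_chain_has_no_anomalies(self):
        placements = [
            _p(i, "chr4", 1000 * i, 1000 * i + 100) for i in range(5)
        ]
        diag = diagnose_chain(_chain(placements), SYNTENY, _asm())
        assert diag.anomalies == []

    def test_minus_strand_descending_is_consistent(self):
        placements = [
            _p(i, "chr4", 1000 * (5 - i), 1000 * (5 - i) + 100, strand="-")
            for i in range(5)
        ]
        diag = diagnose_chain(_chain(placements), SYNTENY, _asm())
        assert diag.anomalies == []

    def test_order_inversion_beyond_one_exon_span(self):
        placements = [
            _p(0, "chr4", 0, 100),
            _p(1, "chr4", 5000, 5100),
            _p(2, "chr4", 2000, 2100),  # backstep of 3000 >> exon span
            _p(3, "chr4", 8000, 8100),
        ]
        diag = diagnose_chain(_chain(placements), SYNTENY, _asm())
        hits = [a for a in diag.anomalies if a.kind == ORDER_ANOMALY]
        assert hits and hits[0].evidence["variant"] == "inversion"

    def test_overlapping_near_duplicates_tolerated(self):
        placements = [
            _p(0, "chr4", 0, 100),
            _p(1, "chr4", 1000, 1100),
            _p(2, "chr4", 980, 1080),  # backstep within one exon span
        ]
        diag = diagnose_chain(_chain(placements), SYNTENY, _asm())
        assert [a for a in diag.anomalies if a.kind == ORDER_ANOMALY] == []

    def test_distance_variant_beyond_intron_bound(self):
        placements = [
            _p(0, "chr4", 0, 100),
            _p(1, "chr4", 1_500_000, 1_500_100),
        ]
        asm = Assembly(
            {"chr4": "A" * 2_000_000},
            sequence_role={"chr4": "chromosome"},
        )
        diag = diagnose_chain(_chain(placements), SYNTENY, asm)
        (f,) = diag.anomalies
        assert f.kind == ORDER_ANOMALY
        assert f.evidence["variant"] == "distance"

    def test_all_unplaced_yields_status_note(self):
        empty = ExonPlacement(gene_id="g", exon_index=0, status="unplaced")
        diag = diagnose_chain(_chain([empty]), SYNTENY, _asm())
        assert diag.status == "no_placements"
        assert diag.anomalies == []


class TestDiagnoseContigs:
    def _contig_asm(self):
        return _asm(
            placements=[
                ContigPlacement("ctgA", "chrX", 0, 10_000),
                ContigPlacement("ctgB", "chrX", 10_100, 20_000),
            ]
        )

    def test_two_sided_conflict_is_chimeric_with_breakpoint(self):
        asm = self._contig_asm()
        chains = [
            _chain([_p(0, "chrX", 1000, 1100), _p(1, "chrX", 2000, 2100)],
                   ref="chr4"),
            _chain([_p(0, "chrX", 6000, 6100), _p(1, "chrX", 8000, 8100)],
                   ref="chrX"),
        ]
        diags = {d.contig_id: d for d in diagnose_contigs(chains, asm, SYNTENY)}
        d = diags["ctgA"]
        assert d.verdict == "chimeric"
        lo, hi = d.breakpoint_interval
        assert (lo, hi) == (2100, 6000)
        assert diags["ctgB"].verdict == "consistent"
        assert diags["ctgB"].has_evidence is False

    def test_single_expectation_contig_consistent(self):
        asm = self._contig_asm()
        chains = [
            _chain([_p(0, "chrX", 1000, 1100), _p(1, "chrX", 6000, 6100)],
                   ref="chrX"),
        ]
        diags = {d.contig_id: d for d in diagnose_contigs(chains, asm, SYNTENY)}
        assert diags["ctgA"].verdict == "consistent"

    def test_interleaved_conflict_flagged_not_called(self):
        asm = self._contig_asm()
        chains = [
            _chain([_p(0, "chrX", 1000, 1100), _p(1, "chrX", 6000, 6100)],
                   ref="chr4"),
            _chain([_p(0, "chrX", 3000, 3100), _p(1, "chrX", 8000, 8100)],
                   ref="chrX"),
        ]
        diags = {d.contig_id: d for d in diagnose_contigs(chains, asm, SYNTENY)}
        assert diags["ctgA"].verdict == "consistent"
        assert diags["ctgA"].interleaved is True

    def test_simulated_chimera_breakpoint_contains_fusion(self, defected_run):
        rec = next(
            r for r in defected_run.defect_log
            if r.defect_class == "CHIMERIC_FUSION"
        )
        d = next(
            d for d in defected_run.contig_diagnoses
            if d.contig_id == rec.payload["contig"]
        )
        assert d.verdict == "chimeric"
        lo, hi = d.breakpoint_interval
        assert lo <= rec.payload["fusion_point"] <= hi
        hits = [
            f for f in defected_run.findings
            if f.kind == CHIMERIC_CONTIG and f.gene_id == rec.gene_id
        ]
        assert hits


class TestCheckUnintegrated:
    def _diag(self, chain, asm):
        return diagnose_chain(chain, SYNTENY, asm)

    def test_single_contig_scaffold_expected_on_primary(self):
        asm = _asm(placements=[ContigPlacement("c9", "un1", 0, 5000)])
        chain = _chain(
            [_p(0, "chr4", 0, 100), _p(1, "chr4", 1000, 1100),
             _p(2, "un1", 200, 300)]
        )
        (f,) = check_unintegrated(chain, self._diag(chain, asm), asm)
        assert f.kind == SPLIT_UNLOCALIZED
        assert f.evidence["unintegrated_contig"] is True
        assert f.evidence["contig"] == "c9"

    def test_multi_contig_scaffold_not_this_finding(self):
        asm = _asm(
            placements=[
                ContigPlacement("c9", "un1", 0, 2000),
                ContigPlacement("c10", "un1", 2100, 5000),
            ]
        )
        chain = _chain(
            [_p(0, "chr4", 0, 100), _p(1, "un1", 200, 300)]
        )
        assert check_unintegrated(chain, self._diag(chain, asm), asm) == []

    def test_clean_chain_silent(self):
        asm = _asm()
        chain = _chain([_p(0, "chr4", 0, 100), _p(1, "chr4", 500, 600)])
        assert check_unintegrated(chain, self._diag(chain, asm), asm) == []

    def test_simulated_unintegrated_contig_found(self, defected_run):
        rec = next(
            r for r in defected_run.defect_log
            if r.defect_class == "UNLOCALIZED_SPLIT"
        )
        hits = [
            f for f in defected_run.findings
            if f.kind == SPLIT_UNLOCALIZED
            and f.gene_id == rec.gene_id
            and f.evidence.get("unintegrated_contig")
        ]
        assert hits


class TestGlobalReverseComplementInvariance:
    def test_anomaly_kinds_stable_under_revcomp(self, small_truth):
        # reverse complementing every draft sequence must not change
        # which anomaly kinds are reported per gene
        from draftaudit.mapping import KmerIndex, map_transcript
        from draftaudit.simulate import (
            DefectSpec,
            derive_draft,
            identity_synteny,
        )

        truth, models = small_truth
        specs = (
            DefectSpec("CONTIG_MISASSIGNMENT", count=1),
            DefectSpec("ORIENTATION_FLIP", count=1),
        )
        draft, _, log = derive_draft(truth, models, specs, seed=7)
        synteny = identity_synteny(truth)
        sub = [
            m for m in models
            if m.gene_id in {r.gene_id for r in log}
        ]

        def kinds_for(asm):
            idx = KmerIndex(asm)
            out = {}
            for m in sub:
                chain = map_transcript(m, truth, idx)
                diag = diagnose_chain(chain, synteny, asm)
                out[m.gene_id] = {f.kind for f in diag.anomalies}
            return out

        fwd = kinds_for(draft)
        rc = Assembly(
            {n: reverse_complement(s) for n, s in draft.sequences.items()},
            sequence_role=dict(draft.sequence_role),
        )
        assert kinds_for(rc) == fwd
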