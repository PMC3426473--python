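import numpy as np
import pytest

from draftaudit.model import (
    cds_sequence,
    reverse_complement,
    translate,
    translate_full,
)
from draftaudit.pipeline import protein_derivable
from draftaudit.simulate import (
    DEFECT_CLASSES,
    DefectError,
    DefectRecord,
    DefectSpec,
    SimulationConfig,
    derive_draft,
    generate_truth,
    read_defect_log,
    write_defect_log,
)


class TestGenerateTruth:
    def test_every_cds_is_clean_orf(self, small_truth):
        truth, models = small_truth
        for m in models:
            cds = cds_sequence(truth, m)
            assert cds.startswith("ATG")
            assert cds[-3:] in ("TAA", "TAG", "TGA")
            _, stop = translate(cds)
            assert stop is None

    def test_all_splice_sites_are_gt_ag(self, small_truth):
        # scan every intron directly on the genomic strings
        truth, models = small_truth
        checked = 0
        for m in models:
            seq = truth.sequences[m.seq_name]
            exons = sorted(m.exons)
            for (_, e1), (s2, _) in zip(exons, exons[1:]):
                intron = seq[e1:s2]
                donor, acceptor = intron[:2], intron[-2:]
                if m.strand == "+":
                    assert (donor, acceptor) == ("GT", "AG")
                else:
                    assert (donor, acceptor) == ("CT", "AC")
                checked += 1
        assert checked > 10

    def test_single_exon_single_gene(self):
        cfg = SimulationConfig(
            n_chromosomes=1, n_genes=1, exons_per_gene=(1, 1), seed=5
        )
        truth, (m,) = generate_truth(cfg)
        _, stop = translate(cds_sequence(truth, m))
        assert stop is None

    def test_same_seed_reproduces_genome(self):
        cfg = SimulationConfig(n_chromosomes=2, n_genes=6, seed=33)
        t1, m1 = generate_truth(cfg)
        t2, m2 = generate_truth(cfg)
        assert t1.sequences == t2.sequences
        assert m1 == m2

    @pytest.mark.parametrize(
        "field,value",
        [
            ("gc_fraction", 1.5),
            ("exon_length", (10, 20)),
            ("n_genes", 0),
            ("intron_length", (0, 10)),
        ],
    )
    def test_invalid_config_rejected(self, field, value):
        cfg = SimulationConfig(**{field: value})
        with pytest.raises(ValueError):
            cfg.validate()


class TestIdentityDraft:
    def test_reassembly_recovers_truth(self, small_truth):
        truth, models = small_truth
        draft, dmodels, log = derive_draft(truth, models, (), seed=7)
        assert log == []
        for c in truth.sequences:
            rebuilt = "".join(
                draft.sequences[c][p.target_start : p.target_end]
                for p in draft.placements_on(c)
            )
            assert rebuilt == truth.sequences[c]

    def test_draft_models_splice_to_truth_cds(self, small_truth):
        truth, models = small_truth
        draft, dmodels, _ = derive_draft(truth, models, (), seed=7)
        by_gene = {m.gene_id: m for m in dmodels}
        for m in models:
            dm = by_gene[m.gene_id]
            assert cds_sequence(draft, dm) == cds_sequence(truth, m)


@pytest.fixture(scope="module")
def defected():
    cfg = SimulationConfig(n_chromosomes=2, n_genes=20, seed=9)
    truth, models = generate_truth(cfg)
    specs = tuple(DefectSpec(c, count=1) for c in DEFECT_CLASSES)
    draft, dmodels, log = derive_draft(truth, models, specs, seed=9)
    return truth, models, draft, dmodels, log


class TestDeriveDraft:
    def test_one_record_per_defect_and_deterministic(self, defected):
        truth, models, draft, dmodels, log = defected
        assert len(log) == len(DEFECT_CLASSES)
        specs = tuple(DefectSpec(c, count=1) for c in DEFECT_CLASSES)
        draft2, dmodels2, log2 = derive_draft(truth, models, specs, seed=9)
        assert draft2.sequences == draft.sequences
        assert dmodels2 == dmodels
        assert log2 == log

    def test_frameshift_translation_diverges_downstream(self, defected):
        truth, models, draft, dmodels, log = defected
        rec = next(r for r in log if r.defect_class == "FRAMESHIFT_INDEL")
        dm = next(m for m in dmodels if m.gene_id == rec.gene_id)
        tm = next(m for m in models if m.gene_id == rec.gene_id)
        aas_draft = translate_full(cds_sequence(draft, dm))
        aas_truth = translate_full(cds_sequence(truth, tm))
        assert aas_draft != aas_truth[: len(aas_draft)]

    def test_stop_substitution_creates_logged_stop_codon(self, defected):
        truth, models, draft, dmodels, log = defected
        rec = next(r for r in log if r.defect_class == "STOP_SUBSTITUTION")
        dm = next(m for m in dmodels if m.gene_id == rec.gene_id)
        aas = translate_full(cds_sequence(draft, dm))
        assert aas[rec.payload["codon_index"]] == "*"

    def test_exon_gap_masks_span_and_decoy_model_translates(self, defected):
        truth, models, draft, dmodels, log = defected
        rec = next(r for r in log if r.defect_class == "EXON_GAP")
        span = draft.sequences[rec.seq][rec.start : rec.end]
        assert set(span) == {"N"}
        dm = next(m for m in dmodels if m.gene_id == rec.gene_id)
        assert protein_derivable(draft, dm)

    def test_annotation_drop_removes_model_only(self, defected):
        truth, models, draft, dmodels, log = defected
        rec = next(r for r in log if r.defect_class == "ANNOTATION_DROP")
        assert rec.gene_id not in {m.gene_id for m in dmodels}

    def test_model_truncation_loses_terminal_exon(self, defected):
        truth, models, draft, dmodels, log = defected
        rec = next(r for r in log if r.defect_class == "MODEL_TRUNCATION")
        dm = next(m for m in dmodels if m.gene_id == rec.gene_id)
        tm = next(m for m in models if m.gene_id == rec.gene_id)
        assert dm.n_exons == tm.n_exons - 1

    def test_orientation_flip_reverse_complements_contig(self, defected):
        truth, models, draft, dmodels, log = defected
        rec = next(r for r in log if r.defect_class == "ORIENTATION_FLIP")
        pl = next(
            p
            for p in draft.placements
            if p.contig_id == rec.payload["contig"]
        )
        assert pl.orientation == "-"

    def test_unlocalized_scaffold_created_with_role(self, defected):
        truth, models, draft, dmodels, log = defected
        rec = next(r for r in log if r.defect_class == "UNLOCALIZED_SPLIT")
        assert draft.role(rec.payload["scaffold"]) == "unlocalized_scaffold"

    def test_conservation_of_non_n_sequence(self):
        # total non-N draft bases = truth - masked - chimera-dropped
        # + insertions - deletions; check without chimeras where the
        # dropped spans are not directly logged
        cfg = SimulationConfig(n_chromosomes=2, n_genes=20, seed=13)
        truth, models = generate_truth(cfg)
        classes = [c for c in DEFECT_CLASSES if c != "CHIMERIC_FUSION"]
        specs = tuple(DefectSpec(c, count=1) for c in classes)
        draft, _, log = derive_draft(truth, models, specs, seed=13)
        nonN = lambda seqs: sum(
            len(s) - s.count("N") for s in seqs.values()
        )
        delta = 0
        for r in log:
            if r.defect_class in ("EXON_GAP", "PARTIAL_EXON_GAP"):
                delta -= r.end - r.start
            elif r.defect_class == "FRAMESHIFT_INDEL":
                k = r.payload["length"]
                delta += k if r.payload["kind"] == "ins" else -k
        assert nonN(draft.sequences) == nonN(truth.sequences) + delta

    def test_point_defects_touch_only_their_logged_loci(self, small_truth):
        # same seed with and without the defect: tiling is identical, so
        # the whole-genome diff must be confined to the logged spans
        truth, models = small_truth
        base, _, _ = derive_draft(truth, models, (), seed=7)
        specs = (
            DefectSpec("STOP_SUBSTITUTION", count=1),
            DefectSpec("PARTIAL_EXON_GAP", count=1),
        )
        draft, _, log = derive_draft(truth, models, specs, seed=7)
        allowed = {
            (r.seq, i) for r in log for i in range(r.start, r.end)
        }
        for name in base.sequences:
            a, b = base.sequences[name], draft.sequences[name]
            assert len(a) == len(b)
            diffs = {
                (name, i) for i, (x, y) in enumerate(zip(a, b)) if x != y
            }
            assert diffs <= allowed

    def test_misassignment_infeasible_on_one_chromosome(self):
        cfg = SimulationConfig(n_chromosomes=1, n_genes=4, seed=3)
        truth, models = generate_truth(cfg)
        with pytest.raises(DefectError):
            derive_draft(
                truth,
                models,
                (DefectSpec("CONTIG_MISASSIGNMENT", count=1),),
                seed=3,
            )

    def test_too_many_defects_rejected(self, small_truth):
        truth, models = small_truth
        with pytest.raises(DefectError):
            derive_draft(
                truth,
                models,
                (DefectSpec("STOP_SUBSTITUTION", count=99),),
                seed=7,
            )


class TestDefectLog:
    def test_empty_log_is_header_only(self, tmp_path):
        p = tmp_path / "d.tsv"
        write_defect_log([], p)
        assert p.read_text().strip() == "gene_id\tclass\tseq\tstart\tend\tpayload"

    def test_roundtrip(self, tmp_path, defected):
        *_, log = defected
        p = tmp_path / "d.tsv"
        write_defect_log(log, p)
        assert read_defect_log(p) == log

    def test_three_record_roundtrip(self, tmp_path):
        recs = [
            DefectRecord("g1", "EXON_GAP", "chr1", 5, 50, {"exon_index": 2}),
            DefectRecord("g2", "ANNOTATION_DROP", "chr2", 0, 10, {}),
            DefectRecord(
                "g3", "CHIMERIC_FUSION", "chim", 0, 99, {"fusion_point": 42}
            ),
        ]
        p = tmp_path / "d.tsv"
        write_defect_log(recs, p)
        assert read_defect_log(p) == recs
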