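"""Annotation I/O, event classification, start inference, event filters."""

import numpy as np
import pytest

from mirrorpg.mirror_analysis import NovelPeptideEvidence
from mirrorpg.reannotation import (
    AnnotationRecord,
    FilterThresholds,
    NovelEvent,
    PipelineConfig,
    classify_peptides,
    filter_events,
    infer_start_codon,
    read_annotation,
    run_pipeline,
    write_annotation_gff3,
)
from mirrorpg.sixframe_db import Genome, map_protein_to_genome, six_frame_orfs


def build_single_orf_genome(codon_string):
    """A genome holding one stop-bounded ORF made of the given codons."""
    genome = Genome("toy", "AT" + "TAA" + codon_string + "TAA" + "CC")
    db = six_frame_orfs(genome, min_len=5)
    orf = next(e for e in db.entries if e.strand == "+" and e.start == 6)
    return genome, db, orf


def evidence_at(orf, aa_start, aa_end, sequence=None, protease="trypsin",
                **flags):
    seq = sequence or orf.aa_sequence[aa_start - 1 : aa_end]
    rec = NovelPeptideEvidence(
        sequence=seq,
        protease=protease,
        orf_id=orf.orf_id,
        aa_start=aa_start,
        aa_end=aa_end,
        interval=map_protein_to_genome(orf, aa_start, aa_end),
        q_best=0.0,
        raw_score_best=10.0,
    )
    for k, v in flags.items():
        setattr(rec, k, v)
    return rec


CODONS_MKR = "ATGAAACGTGACACCGAACTGGGTCACTGGAAGGATATC"  # MKRDTELGHWKDI


class TestAnnotationIo:
    def test_gff_and_tsv_parse_identically(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr\tsrc\tCDS\t10\t39\t.\t+\t0\tID=geneA;product=thing\n"
        )
        tsv = tmp_path / "a.tsv"
        tsv.write_text("gene_id\tstrand\tcds_start\tcds_end\tproduct\n"
                       "geneA\t+\t10\t39\tthing\n")
        assert read_annotation(gff) == read_annotation(tsv)

    def test_roundtrip_through_writer(self, tmp_path):
        records = [
            AnnotationRecord("g1", "+", 10, 39, "alpha"),
            AnnotationRecord("g2", "-", 100, 129, "beta"),
        ]
        p = tmp_path / "out.gff3"
        write_annotation_gff3(records, p, "chr")
        assert read_annotation(p) == records

    def test_frame_inconsistent_length_warns_but_keeps(self, tmp_path):
        tsv = tmp_path / "bad.tsv"
        tsv.write_text("gene_id\tstrand\tcds_start\tcds_end\n" "g\t+\t1\t5\n")
        with pytest.warns(UserWarning):
            records = read_annotation(tsv)
        assert len(records) == 1


class TestClassification:
    def setup_method(self):
        self.genome, self.db, self.orf = build_single_orf_genome(CODONS_MKR)
        assert self.orf.aa_sequence == "MKRDTELGHWKDI"
        # CDS including its stop codon
        self.cds = AnnotationRecord("geneA", "+", self.orf.start, self.orf.end + 3)

    def test_interior_peptide_is_annotated(self):
        ev = evidence_at(self.orf, 4, 11)
        events, annotated = classify_peptides([ev], self.db, [self.cds])
        assert events == [] and annotated == [ev]

    def test_upstream_peptide_makes_extension(self):
        shifted = AnnotationRecord(
            "geneA", "+", self.cds.cds_start + 9, self.cds.cds_end
        )
        ev = evidence_at(self.orf, 1, 8)
        events, annotated = classify_peptides([ev], self.db, [shifted])
        assert annotated == []
        (event,) = events
        assert event.event_type == "n_term_extension"
        assert event.gene_id == "geneA"

    def test_unannotated_orf_makes_novel_event(self):
        ev = evidence_at(self.orf, 4, 11)
        events, annotated = classify_peptides([ev], self.db, [])
        (event,) = events
        assert event.event_type == "novel_orf"
        assert event.orf_id == self.orf.orf_id

    def test_each_peptide_in_exactly_one_bucket(self):
        shifted = AnnotationRecord(
            "geneA", "+", self.cds.cds_start + 9, self.cds.cds_end
        )
        records = [evidence_at(self.orf, 1, 8), evidence_at(self.orf, 4, 11),
                   evidence_at(self.orf, 5, 13)]
        events, annotated = classify_peptides(records, self.db, [shifted])
        n_in_events = sum(len(e.peptides) for e in events)
        assert n_in_events + len(annotated) == len(records)


class TestStartInference:
    def test_ctg_start_before_dimethyl_serine(self):
        """A dimethyl N-terminus at S with CTG immediately upstream: the
        initiator L was removed and CTG is the (canonical-set) start."""
        genome, db, orf = build_single_orf_genome(
            "CTG" "AGC" "GTC" "GAC" "ACC" "GAA" "CTC" "GGT"
        )
        assert orf.aa_sequence == "LSVDTELG"
        event = NovelEvent("n_term_extension", orf.orf_id, "g")
        start = infer_start_codon(event, [2], orf, genome)
        assert (start.codon, start.aa_pos) == ("CTG", 1)
        assert start.initiator_removed and not start.non_canonical
        assert start.confidence == "high"

    def test_gtc_noncanonical_start_accepted_with_dimethyl(self):
        genome, db, orf = build_single_orf_genome(
            "GTC" "GCT" "GCA" "GCC" "GGT" "CTC" "GCC" "TGG"
        )
        assert orf.aa_sequence == "VAAAGLAW"
        event = NovelEvent("novel_orf", orf.orf_id)
        start = infer_start_codon(event, [2], orf, genome)
        assert (start.codon, start.aa_pos) == ("GTC", 1)
        assert start.initiator_removed and start.non_canonical

    def test_atg_start_retained_initiator(self):
        genome, db, orf = build_single_orf_genome(
            "ATG" "AAC" "GAT" "GAA" "CTC" "GGT" "TGG"
        )
        assert orf.aa_sequence == "MNDELGW"
        event = NovelEvent("novel_orf", orf.orf_id)
        start = infer_start_codon(event, [1], orf, genome)
        assert (start.codon, start.aa_pos) == ("ATG", 1)
        assert not start.initiator_removed and not start.non_canonical

    def test_upstream_scan_without_nterm_evidence(self):
        genome, db, orf = build_single_orf_genome(
            "TTG" "CGT" "GCA" "GAC" "ACC" "GAA" "GGT" "CAC"
        )
        assert orf.aa_sequence == "LRADTEGH"
        event = NovelEvent("n_term_extension", orf.orf_id, "g",
                           peptides=[evidence_at(orf, 4, 8)])
        start = infer_start_codon(event, [], orf, genome)
        assert (start.codon, start.aa_pos) == ("TTG", 1)
        assert start.confidence == "low"

    def test_never_proposes_downstream_of_supporting_peptides(self):
        genome, db, orf = build_single_orf_genome(
            "TTG" "CGT" "GCA" "GAC" "ACC" "GAA" "GGT" "CAC"
        )
        for aa_start in (2, 3, 4, 5):
            event = NovelEvent("novel_orf", orf.orf_id,
                               peptides=[evidence_at(orf, aa_start, 8)])
            start = infer_start_codon(event, [], orf, genome)
            if start is not None:
                assert start.aa_pos <= aa_start

    def test_unresolved_when_no_candidate(self):
        genome, db, orf = build_single_orf_genome(
            "GCA" "CGT" "GCA" "GAC" "ACC" "GAA" "GGT" "CAC"
        )
        event = NovelEvent("novel_orf", orf.orf_id,
                           peptides=[evidence_at(orf, 1, 8)])
        assert infer_start_codon(event, [], orf, genome) is None


class TestFilterEvents:
    def _event(self, n_peptides=2, mirror=True, n15=True, pairs=5,
               two_proteases=True):
        peps = []
        for i in range(n_peptides):
            protease = "trypsin" if (i == 0 or not two_proteases) else "lysarginase"
            peps.append(
                NovelPeptideEvidence(
                    sequence=f"PEPTIDE{'ACDEFGHIKLMN'[i]}K",
                    protease=protease,
                    orf_id="orf|0|+|1-60",
                    aa_start=1 + i,
                    aa_end=9 + i,
                    interval=(1, 27, "+"),
                    q_best=0.001,
                    raw_score_best=10.0,
                    is_mirror=mirror,
                    n15_validated=n15,
                    pair_count=pairs,
                )
            )
        return NovelEvent("novel_orf", "orf|0|+|1-60", peptides=peps)

    def test_single_peptide_fails_unique_filter(self):
        (event,) = filter_events([self._event(n_peptides=1)])
        assert not event.filters_passed["unique_peptides"]
        assert not event.reportable

    def test_full_evidence_passes_all(self):
        (event,) = filter_events([self._event()])
        assert all(event.filters_passed.values())
        assert event.reportable

    def test_no_15n_data_relaxes_cosine_filter(self):
        (event,) = filter_events([self._event(n15=False)], n15_present=False)
        assert event.filters_passed["n15_cosine"]

    def test_pair_threshold(self):
        (event,) = filter_events([self._event(pairs=2)])
        assert not event.filters_passed["by_pairs"]

    def test_enumeration_matches_hand_count(self):
        events = [
            self._event(),                          # passes
            self._event(n_peptides=1),              # fails unique
            self._event(pairs=1),                   # fails pairs
            self._event(n15=False),                 # fails cosine
            self._event(mirror=False, two_proteases=False),  # fails products
            self._event(mirror=False),              # two proteases: passes
        ]
        filtered = filter_events(events, FilterThresholds())
        assert sum(e.reportable for e in filtered) == 2


class TestPipeline:
    def test_clean_run_recovers_all_planted_events(self, clean_dataset, clean_report):
        truth = clean_dataset.truth
        reportable = clean_report.reportable_events
        mis = {g.gene_id: g for g in truth.genes if g.mis_start}
        extensions = {
            e.gene_id: e for e in reportable if e.event_type == "n_term_extension"
        }
        assert set(extensions) == set(mis)
        for gene_id, event in extensions.items():
            g = mis[gene_id]
            assert event.inferred_start is not None
            assert event.inferred_start.codon == g.start_codon
        hidden = [g for g in truth.genes if g.hidden]
        novel = [e for e in reportable if e.event_type == "novel_orf"]
        assert len(novel) == len(hidden)

    def test_extension_events_share_stop_with_gene(self, clean_dataset, clean_report):
        annotation = {
            g.gene_id: g for g in clean_dataset.truth.genes if not g.hidden
        }
        orfs = clean_report.db.by_id()
        for event in clean_report.events:
            if event.event_type != "n_term_extension":
                continue
            orf = orfs[event.orf_id]
            g = annotation[event.gene_id]
            if g.strand == "+":
                assert g.annotated_cds[1] == orf.end + 3
            else:
                assert g.annotated_cds[0] == orf.start - 3

    def test_rerun_is_byte_identical(self, clean_dataset, tmp_path):
        cfg = PipelineConfig.from_yaml(clean_dataset.config_yaml)
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        for out in (out_a, out_b):
            cfg2 = PipelineConfig(**{**cfg.__dict__, "out_dir": str(out)})
            run_pipeline(cfg2)
        for name in ("events.tsv", "corrected.gff3", "novel_orfs.gff3"):
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()

    def test_outputs_written(self, clean_dataset, clean_report):
        out = clean_dataset.root / "results"
        for name in ("events.tsv", "corrected.gff3", "novel_orfs.gff3", "run.log"):
            assert (out / name).exists()

    def test_missing_input_rejected_before_compute(self, tmp_path):
        cfg = PipelineConfig(
            genome=str(tmp_path / "nope.fa"),
            annotation=str(tmp_path / "nope.gff3"),
            mgf_trypsin_14n=str(tmp_path / "nope.mgf"),
            mgf_lysarginase_14n=str(tmp_path / "nope.mgf"),
        )
        with pytest.raises(FileNotFoundError):
            run_pipeline(cfg)
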