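"""HMMER tabular parsing, best-hit selection and threshold behavior."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flavimine.annotation_ingest import (
    AnnotationConfig,
    annotate_proteins,
    assign_best_ko,
    collect_pfam_domains,
    parse_hmmsearch_tbl,
    parse_localization,
    read_annotation_tsv,
    write_annotation_tsv,
)
from flavimine.genome_model import DomainHit, FormatError

# Realistic hmmsearch --tblout / --domtblout data lines (column layout is what
# matters; descriptions at the end are free text).
TBLOUT_LINE = (
    "p1  -  FMN_bind  PF04205.18  1e-10  55.3  0.0  1.2e-10  54.9  0.0  "
    "1.1  1  0  0  1  1  1  1  some description\n"
)
DOMTBLOUT_LINE = (
    "p1  -  320  FMN_bind  PF04205.18  140  1e-10  55.3  0.0  1  2  "
    "2e-11  2.4e-11  54.9  0.0  3  138  21  158  20  160  0.95  desc here\n"
)


class TestHmmerParsing:
    def test_domtblout_field_mapping(self, tmp_path):
        path = tmp_path / "hits.domtblout"
        path.write_text("# comment\n" + DOMTBLOUT_LINE)
        (hit,) = parse_hmmsearch_tbl(path, "pfam")
        assert hit.protein_id == "p1"
        assert hit.accession == "PF04205"  # version suffix stripped
        assert hit.evalue == 1e-10
        assert hit.bitscore == 55.3
        assert (hit.ali_from, hit.ali_to) == (21, 158)

    def test_tblout_has_no_coordinates(self, tmp_path):
        path = tmp_path / "hits.tbl"
        path.write_text(TBLOUT_LINE)
        (hit,) = parse_hmmsearch_tbl(path, "pfam")
        assert hit.accession == "PF04205"
        assert hit.ali_from is None and hit.ali_to is None

    def test_kofam_accession_from_query_name(self, tmp_path):
        path = tmp_path / "hits.tbl"
        path.write_text(TBLOUT_LINE.replace("FMN_bind", "K00351").replace("PF04205.18", "-"))
        (hit,) = parse_hmmsearch_tbl(path, "kofam")
        assert hit.accession == "K00351"

    def test_comment_only_file_is_empty(self, tmp_path):
        path = tmp_path / "hits.tbl"
        path.write_text("# one\n# two\n")
        assert parse_hmmsearch_tbl(path, "pfam") == []

    def test_non_finite_score_is_parse_error(self, tmp_path):
        path = tmp_path / "hits.tbl"
        path.write_text(TBLOUT_LINE.replace("55.3", "inf", 1))
        with pytest.raises(FormatError, match="non-finite"):
            parse_hmmsearch_tbl(path, "pfam")

    def test_truncated_line_reports_line_number(self, tmp_path):
        path = tmp_path / "hits.tbl"
        path.write_text("p1 - PF04205\n")
        with pytest.raises(FormatError, match=":1"):
            parse_hmmsearch_tbl(path, "pfam")


def _ko(pid, acc, evalue, score=100.0):
    return DomainHit(pid, "kofam", acc, evalue, score)


def _pf(pid, acc, evalue, score=100.0):
    return DomainHit(pid, "pfam", acc, evalue, score)


class TestBestKo:
    def test_minimum_evalue_wins(self):
        hits = [_ko("p1", "K00001", 1e-5), _ko("p1", "K00002", 1e-8)]
        assert assign_best_ko(hits) == {"p1": "K00002"}

    def test_hit_above_cutoff_is_dropped(self):
        assert assign_best_ko([_ko("p1", "K00001", 0.01)]) == {}

    def test_tie_broken_by_bitscore_then_accession(self):
        hits = [
            _ko("p1", "K00001", 1e-6, score=50),
            _ko("p1", "K00002", 1e-6, score=60),
        ]
        assert assign_best_ko(hits) == {"p1": "K00002"}
        hits = [
            _ko("p1", "K00009", 1e-6, score=60),
            _ko("p1", "K00002", 1e-6, score=60),
        ]
        assert assign_best_ko(hits) == {"p1": "K00002"}

    def test_order_independence(self):
        hits = [
            _ko("p1", "K00003", 1e-7, 80),
            _ko("p1", "K00001", 1e-9, 30),
            _ko("p2", "K00004", 1e-4, 10),
        ]
        forward = assign_best_ko(hits)
        backward = assign_best_ko(list(reversed(hits)))
        assert forward == backward == {"p1": "K00001", "p2": "K00004"}

    def test_brute_force_oracle_on_random_hit_tables(self):
        rng = random.Random(7)
        accs = [f"K{i:05d}" for i in range(1, 30)]
        hits = [
            _ko(
                f"p{rng.randrange(1000)}",
                rng.choice(accs),
                10.0 ** rng.uniform(-20, 1),
                round(rng.uniform(5, 300), 1),
            )
            for _ in range(5000)
        ]
        cfg = AnnotationConfig()
        # oracle: sort the full per-protein hit list and filter explicitly
        expected = {}
        by_protein = {}
        for h in hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        for pid, group in by_protein.items():
            passing = [h for h in group if h.evalue <= cfg.evalue_cutoff]
            if passing:
                best = sorted(passing, key=lambda h: (h.evalue, -h.bitscore, h.accession))[0]
                expected[pid] = best.accession
        assert assign_best_ko(hits, cfg) == expected


class TestPfamDomains:
    def test_multiplicity_preserved(self):
        hits = [_pf("p1", "PF04205", 1e-9), _pf("p1", "PF04205", 1e-7)]
        got = collect_pfam_domains(hits)
        assert len(got["p1"]) == 2

    def test_cutoff_excludes_weak_hit(self):
        assert collect_pfam_domains([_pf("p1", "PF04205", 0.5)]) == {}

    def test_distinct_accessions_both_retained(self):
        hits = [_pf("p1", "PF02424", 1e-9), _pf("p1", "PF04205", 1e-7)]
        accs = {h.accession for h in collect_pfam_domains(hits)["p1"]}
        assert accs == {"PF02424", "PF04205"}

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 20),
                st.sampled_from(["PF00001", "PF00002", "PF00003"]),
                st.floats(1e-30, 1.0),
            ),
            max_size=60,
        ),
        st.floats(1e-6, 1e-1),
    )
    def test_tightening_cutoff_never_adds_annotations(self, raw, cutoff):
        hits = [_pf(f"p{i}", acc, ev) for i, acc, ev in raw]
        loose = collect_pfam_domains(hits, AnnotationConfig(evalue_cutoff=cutoff))
        tight = collect_pfam_domains(hits, AnnotationConfig(evalue_cutoff=cutoff / 10))
        for pid, group in tight.items():
            assert len(group) <= len(loose.get(pid, []))
        kos = [DomainHit(h.protein_id, "kofam", h.accession, h.evalue, h.bitscore) for h in hits]
        loose_ko = set(assign_best_ko(kos, AnnotationConfig(evalue_cutoff=cutoff)))
        tight_ko = set(assign_best_ko(kos, AnnotationConfig(evalue_cutoff=cutoff / 10)))
        assert tight_ko <= loose_ko


class TestLocalization:
    def test_signalp_token_mapping(self, tmp_path):
        path = tmp_path / "sp.tsv"
        path.write_text(
            "# header\np1\tSP(Sec/SPI)\np2\tLIPO(Sec/SPII)\np3\tTAT(Tat/SPI)\np4\tOTHER\n"
        )
        calls = parse_localization(path)
        assert [calls[p].call for p in ("p1", "p2", "p3", "p4")] == [
            "SP", "LIPO", "TAT", "OTHER",
        ]
        assert calls["p2"].extracytosolic and not calls["p4"].extracytosolic

    def test_tmhmm_helix_counts_joined(self, tmp_path):
        sp = tmp_path / "sp.tsv"
        sp.write_text("p1\tOTHER\n")
        tm = tmp_path / "tm.tsv"
        tm.write_text("p1\tlen=300\tExpAA=66\tFirst60=0\tPredHel=3\tTopology=o\n")
        calls = parse_localization(sp, tm)
        assert calls["p1"].tm_helix_count == 3

    def test_unknown_prediction_token_is_error(self, tmp_path):
        path = tmp_path / "sp.tsv"
        path.write_text("p1\tMAYBE\n")
        with pytest.raises(FormatError, match="MAYBE"):
            parse_localization(path)


class TestAnnotationTsv:
    def test_round_trip(self, tmp_path):
        hits = [
            DomainHit("p1", "pfam", "PF04205", 1e-10, 55.3, 21, 158),
            DomainHit("p1", "kofam", "K00351", 2.5e-7, 80.0),
            DomainHit("p2", "pfam", "PF02424", 3e-12, 120.1, 5, 330),
        ]
        path = tmp_path / "ann.tsv"
        write_annotation_tsv(hits, path)
        assert sorted(read_annotation_tsv(path), key=str) == sorted(hits, key=str)


def test_annotate_proteins_consolidates(micro_genome_factory):
    genome = micro_genome_factory(
        [
            {"pfams": ["PF04205", "PF04205"], "ko": "K00351", "loc": "SP"},
            {},
        ]
    )
    anns = annotate_proteins(genome)
    first, second = anns.values()
    assert first.ko == "K00351"
    assert first.pfam_count("PF04205") == 2
    assert first.extracytosolic
    assert second.ko is None and second.pfam_hits == []
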