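"""Key-gene rule matching, domain-architecture checks, and the genome-level
analyses (orphan ApbE, multi-flavinylation, fumarate-reductase and P19
co-occurrence)."""

import pytest

from flavimine.annotation_ingest import annotate_proteins
from flavimine.cluster_mining import mine_genome
from flavimine.genome_model import DomainHit
from flavimine.system_classification import (
    SUBSTRATES_EXTENDED,
    SUBSTRATES_FMN_ONLY,
    RuleConfigError,
    analyze_frd,
    check_nqr_rnf_like,
    classify_clusters,
    detect_dsbd_independent_duf3570,
    detect_p19_clusters,
    find_multiflavinylated,
    find_orphan_apbe,
    load_rules,
)


def classify(genome):
    anns = annotate_proteins(genome)
    _, kept = mine_genome(genome, annotations=anns)
    return classify_clusters(kept, anns), kept, anns


class TestRules:
    def test_rnf_key_gene_assigns_rnf(self, micro_genome_factory):
        genome = micro_genome_factory(
            [{"pfams": ["PF04205"], "loc": "SP"}, {"ko": "K03616"}]
        )
        (assignment,), _, _ = classify(genome)
        assert assignment.systems == frozenset({"RNF"})

    def test_eet_requires_transmembrane_helix(self, micro_genome_factory):
        base = [{"pfams": ["PF04205"], "loc": "SP"}]
        without_tm = micro_genome_factory(base + [{"ko": "K03885", "tm": 0}])
        with_tm = micro_genome_factory(base + [{"ko": "K03885", "tm": 1}])
        (a1,), _, _ = classify(without_tm)
        (a2,), _, _ = classify(with_tm)
        assert "EET" not in a1.systems
        assert a2.systems == frozenset({"EET"})

    def test_pepsy_and_msrq_can_cooccur(self, micro_genome_factory):
        genome = micro_genome_factory(
            [
                {"pfams": ["PF04205"], "loc": "SP"},
                {"pfams": ["PF03929"]},
                {"pfams": ["PF01794"]},
            ]
        )
        (assignment,), _, _ = classify(genome)
        assert assignment.systems == frozenset({"PEPSY", "MSRQ_LIKE"})

    @pytest.mark.parametrize("key,system", [
        ({"ko": "K00376"}, "NOS"),
        ({"pfams": ["PF13486"]}, "PCE"),
        ({"ko": "K00351"}, "NQR"),
        ({"pfams": ["PF12801"]}, "NAPH_LIKE"),
        ({"ko": "K19339"}, "NAPH_LIKE"),
        ({"pfams": ["PF16357"]}, "PEPSY"),
        ({"pfams": ["PF02683"]}, "DSBD"),
    ])
    def test_each_key_gene_assigns_its_system(self, micro_genome_factory, key, system):
        genome = micro_genome_factory([{"pfams": ["PF04205"], "loc": "SP"}, key])
        (assignment,), _, _ = classify(genome)
        assert assignment.systems == frozenset({system})

    def test_unclassified_cluster_gets_empty_set(self, micro_genome_factory):
        genome = micro_genome_factory([{"pfams": ["PF02424"], "loc": "SP"}])
        (assignment,), _, _ = classify(genome)
        assert assignment.systems == frozenset()

    def test_adding_annotation_never_removes_labels(self, micro_genome_factory):
        genome = micro_genome_factory(
            [{"pfams": ["PF04205"], "loc": "SP"}, {"ko": "K03616"}]
        )
        (before,), kept, anns = classify(genome)
        # add an MsrQ-like hit to the second gene
        pid = kept[0].member_genes[1].protein_id
        anns[pid].pfam_hits.append(
            DomainHit(pid, "pfam", "PF01794", 1e-15, 200.0, 1, 100)
        )
        (after,) = classify_clusters(kept, anns)
        assert before.systems <= after.systems

    def test_naph_fmn_partition_recorded(self, micro_genome_factory):
        fused = micro_genome_factory(
            [{"pfams": ["PF12801", "PF04205"], "loc": "SP"}]
        )
        separate = micro_genome_factory(
            [{"pfams": ["PF12801"]}, {"pfams": ["PF04205"], "loc": "SP"}]
        )
        (a1,), _, _ = classify(fused)
        (a2,), _, _ = classify(separate)
        assert a1.naph_fmn_mode == "fused"
        assert a2.naph_fmn_mode == "separate"

    def test_accessory_features_with_fused_flag(self, micro_genome_factory):
        genome = micro_genome_factory(
            [
                {"pfams": ["PF01794", "PF00175"]},   # NAD-binding fused to MsrQ-like
                {"pfams": ["PF04205"], "loc": "SP"},
                {"pfams": ["PF01988"]},              # VIT1 elsewhere in cluster
            ]
        )
        (assignment,), _, _ = classify(genome)
        features = {f.feature: f.fused for f in assignment.accessories}
        assert features["NAD_BINDING"] is True
        assert features["VIT1"] is False

    def test_rule_table_rejects_unknown_namespace(self, tmp_path):
        bad = tmp_path / "rules.yaml"
        bad.write_text(
            "systems:\n  X:\n    any:\n      - {namespace: tigrfam, accession: T1}\n"
        )
        with pytest.raises(RuleConfigError, match="tigrfam"):
            load_rules(bad)


class TestNqrRnfLikeArchitecture:
    def _hit(self, acc, start, end):
        return DomainHit("p1", "pfam", acc, 1e-10, 100.0, start, end)

    def test_correct_order_and_nterminal_start(self):
        hits = [self._hit("PF03116", 20, 350), self._hit("PF00175", 400, 580)]
        assert check_nqr_rnf_like(600, hits) is True

    def test_membrane_domain_alone_is_false(self):
        assert check_nqr_rnf_like(600, [self._hit("PF03116", 20, 350)]) is False

    def test_reversed_domain_order_is_false(self):
        hits = [self._hit("PF00175", 10, 150), self._hit("PF03116", 300, 550)]
        assert check_nqr_rnf_like(600, hits) is False

    def test_membrane_domain_in_cterminal_half_is_false(self):
        hits = [self._hit("PF03116", 400, 450), self._hit("PF00175", 460, 580)]
        assert check_nqr_rnf_like(600, hits) is False

    def test_missing_coordinates_warn_and_return_false(self):
        hits = [
            DomainHit("p1", "pfam", "PF03116", 1e-10, 100.0),
            DomainHit("p1", "pfam", "PF00175", 1e-10, 100.0),
        ]
        with pytest.warns(UserWarning, match="indeterminate"):
            assert check_nqr_rnf_like(600, hits) is False

    def test_full_genome_assignment(self, micro_genome_factory):
        genome = micro_genome_factory(
            [
                {
                    "pfams": [("PF03116", 20, 250), ("PF00175", 380, 560)],
                    "length": 600,
                },
                {"pfams": ["PF04205"], "loc": "SP"},
            ]
        )
        (assignment,), _, _ = classify(genome)
        assert assignment.systems == frozenset({"NQR_RNF_LIKE"})


class TestOrphanApbe:
    def test_lone_apbe_is_orphan_under_both_definitions(self, micro_genome_factory):
        genome = micro_genome_factory([{"pfams": ["PF02424"], "loc": "SP"}])
        assert find_orphan_apbe(genome, substrate_set=SUBSTRATES_FMN_ONLY)
        assert find_orphan_apbe(genome, substrate_set=SUBSTRATES_EXTENDED)

    def test_duf2271_resolves_orphan_only_under_extended_set(self, micro_genome_factory):
        genome = micro_genome_factory(
            [
                {"pfams": ["PF02424"], "loc": "SP"},
                {"pfams": ["PF10029"], "loc": "SP"},
            ]
        )
        assert find_orphan_apbe(genome, substrate_set=SUBSTRATES_FMN_ONLY) is True
        assert find_orphan_apbe(genome, substrate_set=SUBSTRATES_EXTENDED) is False

    def test_genome_without_apbe_is_not_orphan(self, micro_genome_factory):
        genome = micro_genome_factory([{"pfams": ["PF04205"], "loc": "SP"}])
        assert find_orphan_apbe(genome) is False

    def test_cytosolic_apbe_does_not_count(self, micro_genome_factory):
        genome = micro_genome_factory([{"pfams": ["PF02424"], "loc": "OTHER"}])
        assert find_orphan_apbe(genome) is False


class TestMultiflavinylated:
    def test_counts_multiple_fmn_domains(self, micro_genome_factory):
        genome = micro_genome_factory(
            [
                {
                    "pfams": [("PF04205", 10, 110), ("PF04205", 130, 230),
                              ("PF04205", 250, 350)],
                    "loc": "SP",
                    "length": 400,
                }
            ]
        )
        pid = genome.contigs["c1"][0].protein_id
        assert find_multiflavinylated(genome) == [(pid, 3)]

    def test_single_domain_protein_excluded(self, micro_genome_factory):
        genome = micro_genome_factory([{"pfams": ["PF04205"], "loc": "SP"}])
        assert find_multiflavinylated(genome) == []

    def test_cytosolic_protein_excluded_unless_requested(self, micro_genome_factory):
        genome = micro_genome_factory(
            [{"pfams": [("PF04205", 10, 110), ("PF04205", 130, 230)], "length": 300}]
        )
        assert find_multiflavinylated(genome) == []
        assert len(find_multiflavinylated(genome, extracytosolic_only=False)) == 1


class TestFrdCooccurrence:
    def test_fused_fmn_domain(self, micro_genome_factory):
        genome = micro_genome_factory([{"pfams": ["PF00890", "PF04205"]}])
        (rec,) = analyze_frd(genome)
        assert rec["fmn_fused"] and not rec["fmn_nearby"]

    def test_fmn_two_genes_away_is_nearby(self, micro_genome_factory):
        genome = micro_genome_factory(
            [{"pfams": ["PF00890"]}, {}, {"pfams": ["PF04205"]}]
        )
        (rec,) = analyze_frd(genome)
        assert rec["fmn_nearby"] and not rec["fmn_fused"]

    def test_cytochrome_three_genes_away_is_not_nearby(self, micro_genome_factory):
        genome = micro_genome_factory(
            [{"pfams": ["PF00890"]}, {}, {}, {"pfams": ["PF14537"]}]
        )
        (rec,) = analyze_frd(genome)
        assert rec["cytochrome_nearby"] is False


class TestP19:
    def test_flavinylation_type_cluster(self, micro_genome_factory):
        genome = micro_genome_factory(
            [
                {"pfams": ["PF10634"], "loc": "SP"},
                {"pfams": ["PF03239"]},
                {"pfams": ["PF04205"], "loc": "SP"},
            ]
        )
        (rec,) = detect_p19_clusters(genome)
        assert rec["ftr1"] and rec["fmn_binding"] and not rec["thioredoxin_like"]

    def test_thioredoxin_type_cluster(self, micro_genome_factory):
        genome = micro_genome_factory(
            [
                {"pfams": ["PF10634"], "loc": "SP"},
                {"pfams": ["PF03239"]},
                {"pfams": ["PF13899"], "loc": "SP"},
            ]
        )
        (rec,) = detect_p19_clusters(genome)
        assert rec["thioredoxin_like"] and not rec["fmn_binding"]

    def test_lone_p19_has_all_flags_false(self, micro_genome_factory):
        genome = micro_genome_factory([{"pfams": ["PF10634"]}])
        (rec,) = detect_p19_clusters(genome)
        assert not (rec["ftr1"] or rec["fmn_binding"] or rec["thioredoxin_like"])


class TestDsbdIndependentDuf3570:
    def _genome(self, factory, with_dsbd=False, drop_one=False):
        specs = [
            {"pfams": ["PF02424"], "loc": "LIPO"},
            {"pfams": ["PF12094"], "loc": "SP"},
            {"pfams": ["PF13899"], "loc": "SP"},
            {"pfams": ["PF14086"], "loc": "SP"},
        ]
        if drop_one:
            specs = specs[:-1]
        if with_dsbd:
            specs.append({"pfams": ["PF02683"]})
        return factory(specs)

    def test_all_four_without_dsbd_flagged(self, micro_genome_factory):
        genome = self._genome(micro_genome_factory)
        anns = annotate_proteins(genome)
        _, kept = mine_genome(genome, annotations=anns)
        flags = detect_dsbd_independent_duf3570(kept, anns)
        assert list(flags.values()) == [True]

    def test_with_dsbd_counted_as_dsbd_system_instead(self, micro_genome_factory):
        genome = self._genome(micro_genome_factory, with_dsbd=True)
        anns = annotate_proteins(genome)
        _, kept = mine_genome(genome, annotations=anns)
        assert list(detect_dsbd_independent_duf3570(kept, anns).values()) == [False]
        (assignment,) = classify_clusters(kept, anns)
        assert "DSBD" in assignment.systems

    def test_three_of_four_is_not_flagged(self, micro_genome_factory):
        genome = self._genome(micro_genome_factory, drop_one=True)
        anns = annotate_proteins(genome)
        _, kept = mine_genome(genome, annotations=anns)
        assert list(detect_dsbd_independent_duf3570(kept, anns).values()) == [False]
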