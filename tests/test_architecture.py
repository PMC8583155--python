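import pytest

from srfam.architecture import (
    Architecture,
    ClassifierConfig,
    build_architecture,
    classify_subfamily,
    detect_n_terminal_extension,
    detect_signature_motif,
    detect_sp_rich_region,
    identify_sr_proteins,
    merge_regions,
)
from srfam.io_formats import DomainHit, ProteinRecord
from srfam.rs_domain import RSDomain


def _arch(pid="p", rrm=(), zf=(), rs=1, swqdlkd=False, sp=False, next_=False):
    rs_domains = tuple(
        RSDomain(pid, 100 + 70 * i, 160 + 70 * i, 30) for i in range(rs)
    )
    return Architecture(pid, tuple(rrm), tuple(zf), rs_domains,
                        swqdlkd, sp, next_)


class TestDetectors:
    def test_signature_in_second_rrm(self):
        seq = "A" * 80 + "AAASWQDLKDAAA" + "A" * 20
        assert detect_signature_motif(seq, ((0, 70), (80, 93 + 20)))
        # motif outside RRM2 does not count
        seq2 = "SWQDLKD" + "A" * 100
        assert not detect_signature_motif(seq2, ((10, 40), (50, 100)))

    def test_signature_needs_two_rrms(self):
        assert not detect_signature_motif("SWQDLKD" + "A" * 50, ((0, 30),))

    def test_signature_mismatch_budget(self):
        seq = "A" * 80 + "SWQDLKA" + "A" * 20  # one substitution
        regions = ((0, 70), (80, 107))
        assert not detect_signature_motif(seq, regions)
        assert detect_signature_motif(
            seq, regions, ClassifierConfig(swqdlkd_max_mismatch=1)
        )

    def test_sp_rich_saturated_tail(self):
        seq = "A" * 60 + "SP" * 10
        rs = (RSDomain("p", 10, 60, 20),)
        assert detect_sp_rich_region(seq, rs)

    def test_sp_rich_absent(self):
        assert not detect_sp_rich_region("A" * 60 + "A" * 20, (RSDomain("p", 0, 60, 20),))

    def test_sp_rich_low_coverage(self):
        # "SP" + 18 A repeated: coverage 0.1 < 0.2
        seq = "A" * 60 + ("SP" + "A" * 18) * 3
        assert not detect_sp_rich_region(seq, (RSDomain("p", 10, 60, 20),))

    def test_sp_rich_without_rs_domain_scans_whole_sequence(self):
        assert detect_sp_rich_region("SPSP" * 10 + "A" * 40, ())

    def test_n_terminal_extension_greedy_count(self):
        # prefix "MRSAASPA": RS then SP -> 2 overlap-free dipeptides
        assert detect_n_terminal_extension("MRSAASPA" + "W" * 80, ((8, 80),))
        assert not detect_n_terminal_extension("MAAA" + "W" * 80, ((4, 60),))
        assert not detect_n_terminal_extension("W" * 80, ((0, 60),))


class TestMergeRegions:
    def test_split_envelopes_merged(self):
        # overlap 30 >= 50% of shorter (40) -> one region
        assert merge_regions([(0, 40), (10, 80)]) == ((0, 80),)

    def test_distinct_regions_kept(self):
        assert merge_regions([(0, 40), (35, 120)]) == ((0, 40), (35, 120))

    def test_disjoint_untouched(self):
        assert merge_regions([(50, 90), (0, 40)]) == ((0, 40), (50, 90))


class TestClassifier:
    @pytest.mark.parametrize(
        "arch, expected",
        [
            (_arch(rrm=[(5, 80), (90, 170)], swqdlkd=True), "SR"),
            (_arch(rrm=[(5, 80), (90, 170)], swqdlkd=False), "RS"),
            (_arch(rrm=[(5, 80)], zf=[(85, 98), (100, 113)]), "RS2Z"),
            (_arch(rrm=[(5, 80)], zf=[(85, 98)]), "RSZ"),
            (_arch(rrm=[(5, 80)], next_=True), "SCL"),
            (_arch(rrm=[(5, 80)], next_=False), "SC"),
            (_arch(rrm=[(5, 80), (90, 170), (180, 260)]), "UNCLASSIFIED"),
            (_arch(rrm=[(5, 80)], rs=0), "UNCLASSIFIED"),
            (_arch(rrm=[]), "UNCLASSIFIED"),
        ],
    )
    def test_rule_table(self, arch, expected):
        call = classify_subfamily(arch)
        assert call.subfamily == expected
        if expected == "UNCLASSIFIED":
            assert call.rule_trace == ()
        else:
            assert call.rule_trace

    def test_classifier_total_on_synthetic_archs(self, proteome_bundle):
        from srfam.rs_domain import find_rs_domains

        by_protein = {}
        for h in proteome_bundle.hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        for rec in proteome_bundle.records:
            arch = build_architecture(rec, by_protein.get(rec.id, []))
            call = classify_subfamily(arch)
            assert call.subfamily in {
                "SR", "SC", "RSZ", "RS", "SCL", "RS2Z", "UNCLASSIFIED"
            }


class TestBuildArchitecture:
    def test_assembly_and_kinds(self):
        rec = ProteinRecord("p", "M" + "A" * 79 + "RS" * 30 + "A" * 40)
        hits = [DomainHit("p", "RRM", 1, 75), DomainHit("p", "ZF_CCHC", 76, 80)]
        arch = build_architecture(rec, hits)
        assert arch.n_rrm == 1 and arch.n_zf == 1 and arch.n_rs == 1

    def test_hit_beyond_sequence_rejected(self):
        rec = ProteinRecord("p", "MA" * 30)
        with pytest.raises(ValueError, match="exceeds"):
            build_architecture(rec, [DomainHit("p", "RRM", 0, 100)])

    def test_foreign_hit_rejected(self):
        rec = ProteinRecord("p", "MA" * 30)
        with pytest.raises(ValueError, match="q"):
            build_architecture(rec, [DomainHit("q", "RRM", 0, 10)])


class TestIdentify:
    def test_truth_recovery(self, proteome_bundle):
        catalogue = identify_sr_proteins(proteome_bundle.records, proteome_bundle.hits)
        truth = dict(
            zip(proteome_bundle.truth.protein_id, proteome_bundle.truth.label)
        )
        assert len(catalogue.entries) == 36
        for _, _, call in catalogue.entries:
            assert call.subfamily == truth[call.protein_id]

    def test_reject_reason_codes(self, proteome_bundle):
        catalogue = identify_sr_proteins(proteome_bundle.records, proteome_bundle.hits)
        truth = dict(
            zip(proteome_bundle.truth.protein_id, proteome_bundle.truth.label)
        )
        expected = {"RRM_only": ("NO_RS_DOMAIN",), "RS_only": ("NO_RRM",),
                    "random": ("NO_RRM", "NO_RS_DOMAIN")}
        assert len(catalogue.rejects) == 5
        for reject in catalogue.rejects:
            assert reject.reasons == expected[truth[reject.protein_id]]

    def test_input_order_invariance(self, proteome_bundle):
        records = list(proteome_bundle.records)
        hits = list(proteome_bundle.hits)
        base = identify_sr_proteins(records, hits)
        shuffled = identify_sr_proteins(records[::-1], hits[::-1])
        assert [c.subfamily for _, _, c in base.entries] == [
            c.subfamily for _, _, c in shuffled.entries
        ]

    def test_empty_proteome(self):
        catalogue = identify_sr_proteins([], [])
        assert catalogue.entries == [] and catalogue.rejects == []
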