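"""NG86 counting against brute-force oracles and Biopython's implementation."""

import itertools
import math
import warnings

import numpy as np
import pytest

from srfam.ks_dating import (
    CODON_TO_AA,
    NUCLEOTIDES,
    STOP_CODONS,
    CodonAlignmentPair,
    EventThresholds,
    KsEstimate,
    TooShortError,
    classify_duplication_event,
    estimate_ka_ks,
    filter_codons,
    jukes_cantor,
    ks_histogram,
    ng86_differences,
    ng86_sites,
)
from srfam.synthetic import generate_codon_pair


def oracle_sites(codon):
    """Independent per-codon site count via explicit neighbor enumeration."""
    s = 0.0
    for pos, nt in itertools.product(range(3), NUCLEOTIDES):
        if nt == codon[pos]:
            continue
        mutant = codon[:pos] + nt + codon[pos + 1:]
        if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == CODON_TO_AA[codon]:
            s += 1 / 3
    return s, 3 - s


def oracle_differences(ca, cb):
    """Exhaustive pathway enumeration, averaging over valid orderings."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return (0.0, 0.0)
    results = []
    for order in itertools.permutations(diff):
        current, sd, nd, valid = ca, 0, 0, True
        for pos in order:
            nxt = current[:pos] + cb[pos] + current[pos + 1:]
            if nxt in STOP_CODONS or current in STOP_CODONS:
                valid = False
                nd += 1
            elif CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        results.append((sd, nd, valid))
    usable = [r for r in results if r[2]] or results
    return (
        sum(r[0] for r in usable) / len(usable),
        sum(r[1] for r in usable) / len(usable),
    )


NONSTOP = sorted(CODON_TO_AA)


class TestSites:
    def test_phenylalanine_codon(self):
        # TTT: only TTT->TTC is synonymous among the 9 one-step neighbors
        assert ng86_sites("TTT") == pytest.approx((1 / 3, 8 / 3))

    def test_tryptophan_codon(self):
        # TGG: every neighbor is nonsynonymous or a stop
        assert ng86_sites("TGG") == pytest.approx((0.0, 3.0))

    def test_sites_sum_to_three_per_codon(self):
        for codon in NONSTOP:
            s, n = ng86_sites(codon)
            assert s + n == pytest.approx(3.0)
            assert (s, n) == pytest.approx(oracle_sites(codon))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_sites("TAA")


class TestDifferences:
    def test_identity_and_single_synonymous(self):
        pair = CodonAlignmentPair("a", "b", "TTT", "TTT")
        assert ng86_differences(pair) == (0.0, 0.0)
        pair = CodonAlignmentPair("a", "b", "TTT", "TTC")
        assert ng86_differences(pair) == pytest.approx((1.0, 0.0))

    def test_pathway_average_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            ca, cb = rng.choice(NONSTOP, size=2)
            got = ng86_differences(CodonAlignmentPair("a", "b", ca, cb))
            assert got == pytest.approx(oracle_differences(ca, cb))

    def test_total_changes_conserved(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            ca, cb = rng.choice(NONSTOP, size=2)
            sd, nd = ng86_differences(CodonAlignmentPair("a", "b", ca, cb))
            n_diff = sum(x != y for x, y in zip(ca, cb))
            assert sd + nd == pytest.approx(n_diff)


class TestJukesCantor:
    def test_values(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.3) == pytest.approx(0.3831, abs=5e-5)
        assert math.isnan(jukes_cantor(0.75))
        with pytest.raises(ValueError):
            jukes_cantor(-0.1)


class TestFilterCodons:
    def test_gapped_codon_dropped(self):
        a = "ATG" * 49 + "A-G" + "ATG" * 50
        b = "ATG" * 100
        pair = filter_codons(CodonAlignmentPair("a", "b", a, b))
        assert pair.n_codons == 99

    def test_stop_codon_column_dropped(self):
        a = "TAA" + "ATG" * 20
        b = "ATG" * 21
        pair = filter_codons(CodonAlignmentPair("a", "b", a, b))
        assert pair.n_codons == 20

    def test_too_short_refused(self):
        with pytest.raises(TooShortError, match="TOO_SHORT"):
            filter_codons(CodonAlignmentPair("a", "b", "-" * 300, "-" * 300))

    def test_clean_pair_unchanged(self):
        a = "ATGGCT" * 10
        pair = filter_codons(CodonAlignmentPair("a", "b", a, a))
        assert pair.seq_a == a


class TestEstimate:
    def test_identical_pair_zero(self):
        a = "".join(np.random.default_rng(2).choice(NONSTOP, size=100))
        est = estimate_ka_ks(CodonAlignmentPair("a", "b", a, a))
        assert est.ks == 0.0 and est.ka == 0.0 and not est.saturated

    def test_hand_computed_single_substitution(self):
        # 100 TTT codons, one synonymous change: S = 100/3, ps = 0.03
        a = "TTT" * 100
        b = "TTC" + "TTT" * 99
        est = estimate_ka_ks(CodonAlignmentPair("a", "b", a, b))
        assert est.s_sites == pytest.approx(100 / 3)
        assert est.ks == pytest.approx(jukes_cantor(0.03))
        assert est.ks == pytest.approx(0.0306, abs=2e-4)

    def test_sites_partition_total(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(NONSTOP, size=50))
        est = estimate_ka_ks(CodonAlignmentPair("a", "b", a, a))
        assert est.s_sites + est.n_sites == pytest.approx(3 * 50)

    def test_symmetry(self, rng):
        pair, _ = generate_codon_pair(0.4, 120, rng, ka_true=0.1)
        fwd = estimate_ka_ks(pair)
        rev = estimate_ka_ks(
            CodonAlignmentPair(pair.id_b, pair.id_a, pair.seq_b, pair.seq_a)
        )
        assert fwd.ks == pytest.approx(rev.ks)
        assert fwd.ka == pytest.approx(rev.ka)

    def test_agrees_with_biopython_ng86(self, rng):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        for _ in range(10):
            pair, _ = generate_codon_pair(0.4, 150, rng, ka_true=0.1)
            est = estimate_ka_ks(pair)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dn, ds = cal_dn_ds(
                    CodonSeq(pair.seq_a), CodonSeq(pair.seq_b), method="NG86"
                )
            # small differences come from stop-pathway handling
            assert est.ks == pytest.approx(ds, abs=0.03)
            assert est.ka == pytest.approx(dn, abs=0.03)

    @pytest.mark.parametrize("ks_true", [0.1, 0.3, 0.6])
    def test_low_ks_bias_below_ten_percent(self, ks_true):
        rng = np.random.default_rng(int(ks_true * 1000))
        estimates = [
            estimate_ka_ks(generate_codon_pair(ks_true, 300, rng)[0]).ks
            for _ in range(60)
        ]
        assert abs(np.mean(estimates) - ks_true) < 0.1 * ks_true


class TestEventCalls:
    def _est(self, ks):
        return KsEstimate("p", ks, 0.1, 100, 200, 10, 10, math.isnan(ks))

    @pytest.mark.parametrize(
        "ks, category",
        [(0.3, "RECENT_WGD"), (1.0, "RECENT_WGD"), (1.8, "GAMMA"),
         (1.1, "AMBIGUOUS"), (5.0, "AMBIGUOUS"), (math.nan, "AMBIGUOUS")],
    )
    def test_threshold_windows(self, ks, category):
        assert classify_duplication_event(self._est(ks)).category == category

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            EventThresholds(recent_max=2.0, gamma_min=1.2, gamma_max=2.8)

    def test_histogram_conservation(self):
        ests = [self._est(k) for k in (0.05, 0.25, 0.25, 1.8, math.nan)]
        bins, n_saturated = ks_histogram(ests, 0.1)
        assert sum(bins.values()) + n_saturated == len(ests)
        assert any(
            lo == pytest.approx(0.2) and c == 2 for (lo, hi), c in bins.items()
        )

    def test_histogram_empty_and_validation(self):
        assert ks_histogram([], 0.1) == ({}, 0)
        with pytest.raises(ValueError):
            ks_histogram([], 0.0)
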