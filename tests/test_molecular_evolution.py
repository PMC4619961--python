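"""NG86 counting, clock dating and sliding windows vs independent oracles."""

import itertools
import math

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from microsynteny.homology import AlignmentResult, align_global
from microsynteny.molecular_evolution import (
    SENSE_CODONS,
    CodonAlignment,
    back_translate,
    date_block,
    date_from_ks,
    jukes_cantor,
    ng86_diff_count,
    ng86_kaks,
    ng86_site_count,
    sliding_window,
)

# -- independent oracle: direct transcription of the counting definitions --

CODE = dict(standard_dna_table.forward_table)
for stop in standard_dna_table.stop_codons:
    CODE[stop] = "*"


def oracle_sites(codon):
    syn = 0.0
    for pos in range(3):
        changes = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in "ACGT"
            if b != codon[pos]
        ]
        ok = [m for m in changes if CODE[m] != "*"]
        if ok:
            syn += sum(CODE[m] == CODE[codon] for m in ok) / len(ok)
    return syn, 3.0 - syn


def oracle_diffs(a, b):
    pos = [i for i in range(3) if a[i] != b[i]]
    if not pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(pos):
        cur, syn, nonsyn, ok = a, 0, 0, True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if CODE[nxt] == "*":
                ok = False
                break
            if CODE[nxt] == CODE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            results.append((syn, nonsyn))
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def oracle_kaks(codons_a, codons_b):
    """Naive re-implementation of the whole NG86 + Jukes-Cantor estimate."""
    S = sum((oracle_sites(a)[0] + oracle_sites(b)[0]) / 2
            for a, b in zip(codons_a, codons_b))
    N = 3 * len(codons_a) - S
    Sd = sum(oracle_diffs(a, b)[0] for a, b in zip(codons_a, codons_b))
    Nd = sum(oracle_diffs(a, b)[1] for a, b in zip(codons_a, codons_b))

    def jc(p):
        return math.inf if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return jc(Sd / S), jc(Nd / N)


class TestSiteCounts:
    @pytest.mark.parametrize(
        "codon,S", [("TTT", 1 / 3), ("GGG", 1.0), ("ATG", 0.0)]
    )
    def test_hand_derived_examples(self, codon, S):
        s, n = ng86_site_count(codon)
        assert s == pytest.approx(S)
        assert s + n == pytest.approx(3.0)

    def test_all_sense_codons_match_enumeration_oracle(self):
        for codon in SENSE_CODONS:
            assert ng86_site_count(codon) == pytest.approx(oracle_sites(codon))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_count("TAA")


class TestDiffCounts:
    def test_identity(self):
        assert ng86_diff_count("TTT", "TTT") == (0.0, 0.0)

    def test_single_difference(self):
        assert ng86_diff_count("TTT", "TTC") == (1.0, 0.0)

    def test_all_sense_pairs_match_path_oracle(self):
        rng = np.random.default_rng(13)
        idx = rng.integers(0, len(SENSE_CODONS), size=(500, 2))
        for i, j in idx:
            a, b = SENSE_CODONS[i], SENSE_CODONS[j]
            got = ng86_diff_count(a, b)
            want = oracle_diffs(a, b)
            assert got == pytest.approx(want), (a, b)
            # differences always sum to the number of differing positions
            assert sum(got) == pytest.approx(sum(x != y for x, y in zip(a, b)))

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b = rng.choice(SENSE_CODONS, size=2)
            assert ng86_diff_count(a, b) == pytest.approx(ng86_diff_count(b, a))


def random_alignment(rng, n):
    a = tuple(rng.choice(SENSE_CODONS, size=n))
    b = tuple(rng.choice(SENSE_CODONS, size=n))
    return CodonAlignment(a, b)


class TestKaKs:
    def test_identical_sequences(self):
        ca = CodonAlignment(("ATG", "GCC"), ("ATG", "GCC"))
        est = ng86_kaks(ca)
        assert est.Ka == est.Ks == 0.0
        assert est.ratio is None

    def test_site_conservation_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ca = random_alignment(rng, int(rng.integers(1, 50)))
            est = ng86_kaks(ca)
            assert est.S + est.N == pytest.approx(3 * len(ca))

    def test_matches_naive_reimplementation(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            ca = random_alignment(rng, 40)
            est = ng86_kaks(ca)
            ks, ka = oracle_kaks(ca.codons_a, ca.codons_b)
            if math.isinf(ks):
                assert est.saturated
            else:
                assert est.Ks == pytest.approx(ks)
                assert est.Ka == pytest.approx(ka)

    def test_symmetry(self):
        rng = np.random.default_rng(23)
        ca = random_alignment(rng, 60)
        swapped = CodonAlignment(ca.codons_b, ca.codons_a)
        assert ng86_kaks(ca) == ng86_kaks(swapped)

    def test_saturation_flag(self):
        assert jukes_cantor(0.75) == math.inf
        assert jukes_cantor(0.0) == 0.0

    def test_simulated_divergence_recovered(self):
        # generate ~Ks 0.2 with omega 0.2 and check the estimator lands nearby
        from microsynteny.synthetic_data import _random_cds, evolve_sequence

        rng = np.random.default_rng(8)
        ks_vals = []
        for _ in range(25):
            cds = _random_cds(300, rng)
            a = evolve_sequence(cds, 15.4e6, rng=rng)
            b = evolve_sequence(cds, 15.4e6, rng=rng)
            ca = CodonAlignment(
                tuple(a[i : i + 3] for i in range(0, len(a), 3)),
                tuple(b[i : i + 3] for i in range(0, len(b), 3)),
            )
            ks_vals.append(ng86_kaks(ca).Ks)
        mean = np.mean(ks_vals)
        se = np.std(ks_vals) / math.sqrt(len(ks_vals))
        assert abs(mean - 0.2) < 3 * se + 0.01


class TestBackTranslate:
    def test_identity_pair(self):
        cds = "ATGGCCGCCAAAGGG" * 2
        prot = "MAAKG" * 2
        aln = AlignmentResult(prot, prot, 100.0, 1.0)
        ca = back_translate(aln, cds, cds)
        assert len(ca) == 10

    def test_gap_columns_dropped(self):
        aln = align_global("MAAKGMAAKG", "MAAKMAAKG")
        ca = back_translate(
            aln, "ATGGCCGCCAAAGGGATGGCCGCCAAAGGG", "ATGGCCGCCAAAATGGCCGCCAAAGGG"
        )
        assert len(ca) == 9  # one aligned gap column removed

    def test_ambiguous_codon_dropped(self):
        cds_a = "ATGGCCGCC"
        cds_b = "ATGGNCGCC"
        aln = AlignmentResult("MAA", "MXA", 10.0, 1.0)
        ca = back_translate(aln, cds_a, cds_b)
        assert len(ca) == 2

    def test_translation_mismatch_reported_with_position(self):
        aln = AlignmentResult("MAA", "MWA", 10.0, 1.0)
        with pytest.raises(ValueError, match="codon 1"):
            back_translate(aln, "ATGGCCGCC", "ATGGCCGCC")


class TestClock:
    @pytest.mark.parametrize(
        "ks,expected",
        [
            (1.0927, 84.0538),
            (0.5470, 42.0769),
            (0.8338, 64.1385),
            (0.1816, 13.9692),
            (0.2567, 19.7462),
            (0.0157, 1.2077),
            (0.0, 0.0),
            (0.13, 10.0),
        ],
    )
    def test_published_dates_reproduced(self, ks, expected):
        assert date_from_ks(ks) == pytest.approx(expected, abs=5e-5)

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            date_from_ks(-0.1)

    def test_clock_consistency(self):
        rate = 6.5e-9
        for t in (0.0, 1.0, 15.0, 84.0538):
            ks = 2 * rate * t * 1e6
            assert date_from_ks(ks, rate) == pytest.approx(t, abs=5e-5)


def _est(ks):
    from microsynteny.molecular_evolution import KaKsEstimate

    return KaKsEstimate(
        S=100, N=200, Sd=1, Nd=1, pS=0.01, pN=0.005, Ks=ks, Ka=ks / 2,
        ratio=0.5, saturated=ks > 2.0, n_codons=100,
    )


class TestDateBlock:
    def test_mean_and_date(self):
        d = date_block([_est(0.18), _est(0.20), _est(0.16)])
        assert d.mean_ks == pytest.approx(0.18)
        assert d.date_mya == pytest.approx(13.8462, abs=5e-5)
        assert d.sd_ks == pytest.approx(np.std([0.18, 0.2, 0.16], ddof=1))

    def test_saturated_pairs_excluded(self):
        d = date_block([_est(0.5), _est(2.5)])
        assert d.mean_ks == pytest.approx(0.5)
        assert d.n_saturated == 1

    def test_single_pair_degenerate(self):
        d = date_block([_est(0.3)])
        assert d.sd_ks == 0.0
        assert d.degenerate

    def test_all_saturated_undatable(self):
        d = date_block([_est(2.5), _est(3.0)])
        assert d.mean_ks is None and d.date_mya is None


class TestSlidingWindow:
    def _alignment(self, n_codons, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        return random_alignment(rng, n_codons)

    def test_300bp_alignment_gives_17_windows(self):
        prof = sliding_window(self._alignment(100), window=150, step=9)
        assert len(prof.windows) == 17
        assert prof.windows[0].start == 1 and prof.windows[0].end == 150
        assert prof.windows[-1].end <= 300

    def test_divisibility_enforced(self):
        with pytest.raises(ValueError):
            sliding_window(self._alignment(100), window=151, step=9)
        with pytest.raises(ValueError):
            sliding_window(self._alignment(100), window=150, step=10)

    def test_short_alignment_flagged(self):
        prof = sliding_window(self._alignment(20), window=150, step=9)
        (w,) = prof.windows
        assert w.short and w.end == 60

    def test_zero_ks_window_has_undefined_ratio(self):
        ca = CodonAlignment(("ATG",) * 60, ("ATG",) * 60)
        prof = sliding_window(ca, window=150, step=9)
        assert all(w.ratio is None for w in prof.windows)

    def test_window_means_track_global_ratio(self):
        from microsynteny.synthetic_data import _random_cds, evolve_sequence

        rng = np.random.default_rng(2)
        cds = _random_cds(3000, rng)
        a = evolve_sequence(cds, 40e6, rng=rng)
        b = evolve_sequence(cds, 40e6, rng=rng)
        ca = CodonAlignment(
            tuple(a[i : i + 3] for i in range(0, len(a), 3)),
            tuple(b[i : i + 3] for i in range(0, len(b), 3)),
        )
        global_ratio = ng86_kaks(ca).ratio
        prof = sliding_window(ca, window=900, step=900)
        ratios = [w.ratio for w in prof.windows if w.ratio is not None]
        assert np.mean(ratios) == pytest.approx(global_ratio, rel=0.25)
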