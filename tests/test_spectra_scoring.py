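"""Peak matching, raw score, target-decoy q-values, coverage, cosine."""

import numpy as np
import pytest

from mirrorpg.digestion import DigestPeptide
from mirrorpg.mass_model import FragmentIon, fragment_ions
from mirrorpg.spectra_scoring import (
    CoverageMetrics,
    Psm,
    Spectrum,
    cosine_similarity,
    coverage_from_positions,
    filter_qvalue,
    ion_coverage,
    match_peaks,
    raw_score,
    read_mgf,
    target_decoy_qvalues,
    write_mgf,
)


def frag(series, index, mz, charge=1):
    return FragmentIon(series, index, charge, mz, 0)


def make_spectrum(mz, intensity, sid="s1", precursor=500.0, charge=2, label=None):
    return Spectrum(sid, precursor, charge, np.asarray(mz), np.asarray(intensity), label)


def make_psm(seq, matched_keys, score=0.0, decoy=False, sid="s", parent="orf|0|+|1-30"):
    pep = DigestPeptide(seq, parent, 1, len(seq), 0, "-", "-", "trypsin")
    matched = {
        k: None for k in matched_keys
    }  # coverage only needs the keys
    psm = Psm(spectrum_id=sid, peptide=pep, matched=matched, raw_score=score,
              is_decoy=decoy)
    return psm


class TestMgfIo:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.mgf"
        p.write_text("")
        assert read_mgf(p) == []

    def test_single_spectrum_roundtrip(self, tmp_path):
        s = make_spectrum([100.1, 200.2], [1.0, 2.0], label="14N")
        p = tmp_path / "one.mgf"
        write_mgf([s], p)
        (back,) = read_mgf(p)
        assert back.spectrum_id == "s1"
        assert back.precursor_charge == 2
        assert back.label == "14N"
        np.testing.assert_allclose(back.mz, s.mz, atol=1e-5)
        np.testing.assert_allclose(back.intensity, s.intensity, atol=1e-5)

    def test_random_roundtrip(self, tmp_path):
        rng = np.random.default_rng(20)
        spectra = [
            make_spectrum(
                np.sort(rng.uniform(100, 1500, 25)),
                rng.lognormal(0, 0.5, 25),
                sid=f"s{i}",
                precursor=float(rng.uniform(300, 1200)),
            )
            for i in range(100)
        ]
        p = tmp_path / "many.mgf"
        write_mgf(spectra, p)
        back = read_mgf(p)
        assert len(back) == 100
        for a, b in zip(spectra, back):
            np.testing.assert_allclose(a.mz, b.mz, atol=1e-5)

    def test_peaks_sorted_and_deduplicated(self):
        s = make_spectrum([300.0, 100.0, 100.0], [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(s.mz, [100.0, 300.0])
        np.testing.assert_array_equal(s.intensity, [5.0, 1.0])


class TestMatchPeaks:
    def test_exact_match_zero_ppm(self):
        s = make_spectrum([500.0], [1.0])
        matched = match_peaks(s, [frag("b", 1, 500.0)], 20.0)
        assert matched[("b", 1, 1)].ppm_error == pytest.approx(0.0, abs=1e-9)

    def test_boundary_inclusive(self):
        f = frag("b", 1, 500.0)
        inside = make_spectrum([500.0 * (1 + 20.0e-6)], [1.0])
        outside = make_spectrum([500.0 * (1 + 20.1e-6)], [1.0])
        assert ("b", 1, 1) in match_peaks(inside, [f], 20.0)
        assert match_peaks(outside, [f], 20.0) == {}

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            peaks = np.sort(rng.uniform(100, 2000, 40))
            frags = [frag("b", i + 1, float(m))
                     for i, m in enumerate(rng.uniform(100, 2000, 30))]
            s = make_spectrum(peaks, np.ones(40))
            got = set(match_peaks(s, frags, 20.0))
            oracle = {
                f.key
                for f in frags
                if any(abs(p - f.mz) / f.mz * 1e6 <= 20.0 for p in peaks)
            }
            assert got == oracle


class TestRawScore:
    def test_no_matches_zero(self):
        s = make_spectrum([100.0], [1.0])
        assert raw_score(s, {}) == 0.0

    def test_hand_example(self):
        # 5 peaks, 3 matched carrying 60% of total intensity, 3 fragments
        s = make_spectrum([100, 200, 300, 400, 500], [30, 15, 15, 20, 20])
        frags = [frag("b", 1, 100.0), frag("b", 2, 200.0), frag("b", 3, 300.0)]
        matched = match_peaks(s, frags, 20.0)
        assert raw_score(s, matched) == pytest.approx(3.6)

    def test_saturation(self):
        seq = "PEPTIDEK"
        frags = fragment_ions(seq)
        s = make_spectrum([f.mz for f in frags], np.ones(len(frags)))
        matched = match_peaks(s, frags, 20.0)
        assert raw_score(s, matched) == pytest.approx(2 * (len(seq) - 1) + 1)


class TestTargetDecoyQvalues:
    def test_targets_only_all_zero(self):
        psms = [make_psm("PEPK", [], score=s) for s in (5, 3, 1)]
        for p in target_decoy_qvalues(psms):
            assert p.q_value == 0.0

    def test_hand_example(self):
        """Scores [T10, T9, D8, T7, D6] give q(T10)=q(T9)=0, q(T7)=1/3."""
        psms = [
            make_psm("AAAK", [], 10.0, sid="a"),
            make_psm("CCCK", [], 9.0, sid="b"),
            make_psm("DDDK", [], 8.0, decoy=True, sid="c"),
            make_psm("EEEK", [], 7.0, sid="d"),
            make_psm("FFFK", [], 6.0, decoy=True, sid="e"),
        ]
        by_id = {p.spectrum_id: p for p in target_decoy_qvalues(psms)}
        assert by_id["a"].q_value == pytest.approx(0.0)
        assert by_id["b"].q_value == pytest.approx(0.0)
        assert by_id["d"].q_value == pytest.approx(1 / 3)

    def test_monotone_nonincreasing_with_score(self):
        rng = np.random.default_rng(22)
        psms = [
            make_psm("PEPK", [], float(rng.uniform(0, 10)),
                     decoy=bool(rng.random() < 0.4), sid=f"s{i}")
            for i in range(200)
        ]
        ranked = target_decoy_qvalues(psms)
        qs = [p.q_value for p in ranked]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_tie_permutation_invariance(self):
        def build():
            return [
                make_psm("AAAK", [], 5.0, sid="a"),
                make_psm("CCCK", [], 5.0, decoy=True, sid="b"),
                make_psm("DDDK", [], 5.0, sid="c"),
                make_psm("EEEK", [], 2.0, sid="d"),
            ]

        base = sorted(p.q_value for p in target_decoy_qvalues(build()))
        for perm in ([1, 0, 3, 2], [3, 2, 1, 0]):
            psms = build()
            shuffled = [psms[i] for i in perm]
            assert sorted(p.q_value for p in target_decoy_qvalues(shuffled)) == base

    def test_filter_never_keeps_below_rejected(self):
        rng = np.random.default_rng(23)
        psms = [
            make_psm("PEPK", [], float(rng.uniform(0, 10)),
                     decoy=bool(rng.random() < 0.3), sid=f"s{i}")
            for i in range(300)
        ]
        ranked = target_decoy_qvalues(psms)
        kept = filter_qvalue(ranked, 0.01)
        if kept:
            min_kept = min(p.raw_score for p in kept)
            rejected_above = [
                p for p in ranked
                if not p.is_decoy and p.q_value >= 0.01 and p.raw_score > min_kept
            ]
            assert rejected_above == []


class TestIonCoverage:
    def test_all_fragments_matched(self):
        seq = "PEPTIDEK"
        keys = [f.key for f in fragment_ions(seq)]
        cov = ion_coverage(make_psm(seq, keys))
        assert cov.b_coverage == 1.0 and cov.y_coverage == 1.0
        assert cov.pair_count == len(seq) - 1
        assert cov.max_continuous_pairs == len(seq) - 1

    def test_hand_example_8mer(self):
        cov = ion_coverage(
            make_psm(
                "ACDEFGHI",
                [("b", 1, 1), ("b", 2, 1), ("b", 3, 1), ("y", 7, 1)],
            )
        )
        assert cov.b_coverage == pytest.approx(3 / 7)
        assert cov.y_coverage == pytest.approx(1 / 7)
        assert cov.by_pair_positions == frozenset({1})
        assert cov.max_continuous_pairs == 1

    def test_empty_match_set(self):
        cov = ion_coverage(make_psm("PEPTIDEK", []))
        assert cov.b_coverage == 0.0 and cov.y_coverage == 0.0
        assert cov.pair_count == 0 and cov.max_continuous_pairs == 0

    def test_run_computation(self):
        cov = coverage_from_positions(10, {1, 2, 3, 5, 6, 9}, {2, 3, 5, 6, 7, 9})
        assert cov.by_pair_positions == frozenset({2, 3, 5, 6, 9})
        assert cov.max_continuous_pairs == 2

    def test_short_peptide_rejected(self):
        with pytest.raises(ValueError):
            ion_coverage(make_psm("G", []))


class TestCosine:
    def test_identical(self):
        v = {("b", 1, 1): 2.0, ("y", 1, 1): 3.0}
        assert cosine_similarity(v, dict(v)) == pytest.approx(1.0)

    def test_disjoint(self):
        a = {("b", 1, 1): 1.0}
        b = {("y", 1, 1): 1.0}
        assert cosine_similarity(a, b) == pytest.approx(0.0)

    def test_hand_example(self):
        a = {("b", 1, 1): 1.0, ("b", 2, 1): 0.5}
        b = {("b", 1, 1): 0.5, ("b", 2, 1): 1.0}
        assert cosine_similarity(a, b) == pytest.approx(0.8)

    def test_symmetric_and_scale_invariant(self):
        rng = np.random.default_rng(24)
        a = {("b", i, 1): float(v) for i, v in enumerate(rng.lognormal(0, 1, 10), 1)}
        b = {("b", i, 1): float(v) for i, v in enumerate(rng.lognormal(0, 1, 10), 1)}
        assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, a))
        scaled = {k: 7.3 * v for k, v in a.items()}
        assert cosine_similarity(scaled, b) == pytest.approx(cosine_similarity(a, b))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity({}, {})
        with pytest.raises(ValueError):
            cosine_similarity({("b", 1, 1): 0.0}, {("b", 1, 1): 0.0})
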