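import functools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tesrna import synthetic_data as sd
from tesrna import te_annotation as ta


def exhaustive_score(a, b, match=1, mismatch=-1, gap_open=-4, gap_extend=-1):
    """Independent oracle: best global affine-gap score by exhaustive
    recursion over all alignments (memoised on (i, j, last state))."""

    @functools.cache
    def go(i, j, last):
        if i == len(a) and j == len(b):
            return 0
        best = -np.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + go(i + 1, j + 1, "M"))
        if i < len(a):
            g = gap_extend if last == "A" else gap_open
            best = max(best, g + go(i + 1, j, "A"))
        if j < len(b):
            g = gap_extend if last == "B" else gap_open
            best = max(best, g + go(i, j + 1, "B"))
        return best

    return go(0, 0, "M")


class TestLengthPeaks:
    def test_single_dominant_peak(self):
        lengths = [100] * 10 + [200] * 50 + [300] * 12
        peaks = ta.length_peaks(lengths, bin_width=10)
        assert len(peaks) >= 1
        best = max(peaks, key=lambda p: p.count)
        assert best.window[0] <= 200 <= best.window[1] and best.count == 50

    def test_uniform_lengths_single_occupied_bin(self):
        peaks = ta.length_peaks([500] * 20, bin_width=100)
        assert len(peaks) == 1 and peaks[0].count == 20

    def test_bimodal_mixture_two_peaks(self, rng):
        """Two full-length modes (7.3 kb and 9.4 kb) are both recovered."""
        lengths = np.concatenate([
            rng.normal(7300, 80, 300), rng.normal(9400, 80, 200),
            rng.uniform(2000, 12000, 150),  # fragmented background
        ]).astype(int)
        peaks = ta.length_peaks(lengths, bin_width=200, min_prominence=10)
        modes = [p.mode_length for p in peaks]
        assert any(abs(m - 7300) <= 400 for m in modes)
        assert any(abs(m - 9400) <= 400 for m in modes)


class TestSelectFullLength:
    def test_planted_in_window_count(self, rng):
        lengths = list(rng.integers(20_000, 30_000, 63)) + \
            list(rng.integers(13_300, 14_101, 37))
        picked = ta.select_fulllength_candidates(lengths, (13_300, 14_100))
        assert len(picked) == 37

    def test_empty_overlap(self):
        assert ta.select_fulllength_candidates([100, 200], (300, 400)) == []

    def test_all_inside_is_identity(self):
        assert ta.select_fulllength_candidates([350, 360], (300, 400)) == [350, 360]


class TestAlignment:
    def test_identical_sequences_no_edits(self):
        a, b = ta.align_ltr_pair("ACGTACGT", "ACGTACGT")
        assert a == b == "ACGTACGT"

    def test_single_gap_toy(self):
        a, b = ta.align_ltr_pair("ACGT", "ACT")
        assert len(a) == len(b) == 4
        assert a.count("-") + b.count("-") == 1
        matches = sum(x == y for x, y in zip(a, b) if x != "-" and y != "-")
        assert matches == 3

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=8),
           st.text(alphabet="ACGT", min_size=1, max_size=8))
    def test_score_matches_exhaustive_enumeration(self, a, b):
        assert ta.alignment_score(a, b) == exhaustive_score(a, b)


class TestDivergence:
    def test_zero_distance_all_models(self):
        for model in ("p", "JC69", "K2P"):
            est = ta.ltr_divergence("ACGT" * 25, "ACGT" * 25, model=model)
            assert est.K == 0 and est.T == 0

    def test_jc69_closed_form(self):
        # p = 0.1 over 100 sites: K = -0.75 ln(1 - 4*0.1/3)
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        est = ta.ltr_divergence(a, b, model="JC69")
        assert est.p_distance == pytest.approx(0.1)
        assert est.K == pytest.approx(-0.75 * np.log(1 - 0.4 / 3), abs=1e-12)
        assert est.K == pytest.approx(0.10733, abs=1e-5)

    def test_k2p_closed_form(self):
        # P = 0.06 (A<->G transitions), Q = 0.04 (A<->C transversions)
        a = "A" * 100
        b = "G" * 6 + "C" * 4 + "A" * 90
        est = ta.ltr_divergence(a, b, model="K2P")
        assert est.K == pytest.approx(0.10802, abs=5e-6)

    def test_gap_columns_excluded(self):
        est = ta.ltr_divergence("AC-GT", "ACCGT", model="p")
        assert est.n_sites == 4 and est.p_distance == 0

    def test_saturation_reported_not_clamped(self):
        a = "A" * 100
        b = "G" * 80 + "A" * 20  # p = 0.8 >= 0.75
        est = ta.ltr_divergence(a, b, model="JC69")
        assert est.K is None and est.T is None

    def test_k_monotone_in_p_and_at_least_p(self):
        for model in ("JC69", "K2P"):
            prev = -1.0
            for ndiff in range(0, 60, 5):
                a = "A" * 100
                # alternate transitions and transversions
                b = ("G" * (ndiff // 2) + "C" * (ndiff - ndiff // 2)
                     + "A" * (100 - ndiff))
                est = ta.ltr_divergence(a, b, model=model)
                assert est.K >= est.p_distance - 1e-12
                assert est.K > prev
                prev = est.K


class TestAge:
    def test_linear_formula(self):
        assert ta.estimate_age(0.0, 1.3e-8) == 0.0
        assert ta.estimate_age(0.0026, 1.3e-8) == pytest.approx(100_000)

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            ta.estimate_age(0.01, 0.0)
        with pytest.raises(ValueError):
            ta.estimate_age(-0.1, 1.3e-8)

    def test_recovery_on_clock_simulation(self):
        """Known insertion age T = 1e6 y, 1 kb LTRs, uniform clock: the
        median relative age error over 200 elements stays within 15%."""
        spec = sd.FamilySpec("f", 200, ltr_length=1000, int_length=60,
                             age_law="uniform", age_params=(1e6, 1e6),
                             hotspot_rate_factor=1.0,
                             hotspot_variant_divergence=0.0)
        els = sd.simulate_family(spec, seed=77)
        errs = []
        for el in els:
            est = ta.age_ltr_pair(el.sequence[slice(*el.ltr5)],
                                  el.sequence[slice(*el.ltr3)], model="JC69")
            errs.append(abs(est.T - el.age) / el.age)
        assert np.median(errs) <= 0.15


class TestContaminationScreen:
    def test_planted_verbatim_fragment_found(self, rng):
        donor = "".join(rng.choice(list("ACGT"), 1500))
        frag = donor[400:589]  # 189 nt
        host = "".join(rng.choice(list("ACGT"), 2000))
        host = host[:900] + frag + host[900:]
        hits = ta.contamination_screen({"h": host}, {"d": donor})
        assert len(hits) == 1
        (hit,) = hits
        assert hit.match_length >= 189 and hit.identity == pytest.approx(1.0)
        s, e = hit.host_interval
        assert s <= 900 and e >= 900 + 189

    def test_reverse_strand_fragment_found(self, rng):
        from tesrna.mapping import revcomp

        donor = "".join(rng.choice(list("ACGT"), 1000))
        host = "".join(rng.choice(list("ACGT"), 800)) + revcomp(donor[100:300])
        hits = ta.contamination_screen({"h": host}, {"d": donor})
        assert len(hits) == 1 and hits[0].match_length >= 200

    def test_no_shared_seed_no_hits(self):
        assert ta.contamination_screen({"h": "ACGT" * 100}, {"d": "AACC" * 100}) == []

    def test_short_fragment_below_min_match(self, rng):
        donor = "".join(rng.choice(list("ACGT"), 500))
        host = "".join(rng.choice(list("ACGT"), 500)) + donor[100:150]
        hits = ta.contamination_screen({"h": host}, {"d": donor}, min_match=100)
        assert hits == []

    def test_blast_tabular_import_filters_evalue(self, tmp_path):
        rows = [
            "don1\thost1\t98.5\t210\t3\t0\t1\t210\t501\t710\t1e-50\t380",
            "don2\thost1\t90.0\t120\t12\t0\t1\t120\t100\t219\t1e-10\t80",
        ]
        p = tmp_path / "hits.tsv"
        p.write_text("\n".join(rows) + "\n")
        hits = ta.import_blast_hits(p)
        assert len(hits) == 1
        assert hits[0].host_id == "host1" and hits[0].donor_id == "don1"
        assert hits[0].host_interval == (500, 710)
        assert hits[0].identity == pytest.approx(0.985)
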