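import numpy as np
import pytest

from tesrna import quantification as qt
from tesrna.mapping import ExactIndex, Hit, HitSet, map_table
from tesrna.quantification import UNWEIGHTED, WeightingScheme

GW = WeightingScheme("weighted", "genome")


def hitset(seq, hits, label="genome"):
    return HitSet(species=seq, reference_set=label, hits=hits)


class TestWeights:
    def test_inverse_location_count(self):
        hs = hitset("ACGT", [Hit("g", i, "sense") for i in range(4)])
        assert qt.weight_hits(hs, GW, {"ACGT": hs}) == pytest.approx(0.25)

    def test_unique_species_weight_one(self):
        hs = hitset("ACGT", [Hit("g", 0, "sense")])
        assert qt.weight_hits(hs, GW, {"ACGT": hs}) == 1.0
        assert qt.weight_hits(hs, UNWEIGHTED) == 1.0

    def test_denominator_set_vs_tally_set(self):
        """10 genome locations, 2 inside the population: genome-weighted
        in-population tally 0.2; population(dataset)-weighted tally 1.0."""
        seq = "A" * 21
        genome_hs = hitset(seq, [Hit("g", 100 * i, "sense") for i in range(10)])
        pop_hs = hitset(seq, [Hit("el1", 5, "sense"), Hit("el2", 9, "sense")],
                        label="population")
        w_genome = qt.weight_hits(pop_hs, GW, {seq: genome_hs})
        w_dataset = qt.weight_hits(pop_hs, WeightingScheme("weighted", "population"),
                                   {seq: pop_hs})
        assert 2 * w_genome == pytest.approx(0.2)
        assert 2 * w_dataset == pytest.approx(1.0)

    def test_unmapped_in_denominator_is_error(self):
        pop_hs = hitset("ACGT", [Hit("el1", 0, "sense")], label="population")
        empty = hitset("ACGT", [])
        with pytest.raises(ValueError, match="unmapped in denominator"):
            qt.weight_hits(pop_hs, GW, {"ACGT": empty})

    def test_genome_weight_conservation(self, small_study):
        """Under genome weighting, each mapped species' weights sum to 1, so
        the total weighted genome tally equals the number of mapped species."""
        total = 0.0
        n_mapped = 0
        for seq, hs in small_study.genome_hits.items():
            if hs.x == 0:
                continue
            n_mapped += 1
            w = qt.weight_hits(hs, GW, small_study.genome_hits)
            per_species = w * hs.x
            assert per_species == pytest.approx(1.0, abs=1e-9)
            total += per_species
        assert total == pytest.approx(n_mapped, abs=1e-6)
        assert n_mapped > 100


class TestLocusMetrics:
    def test_unweighted_division(self):
        hitsets = {
            f"SP{i}" + "A" * 19: hitset(f"SP{i}" + "A" * 19, [Hit("g", 10 * i, "sense")])
            for i in range(5)
        }
        expr = {seq: 10 for seq in hitsets}
        m = qt.locus_metrics("el", "full", "g", (0, 1000), hitsets, expr)
        assert m.species_count == 5
        assert m.species_per_nt == pytest.approx(0.005)
        assert m.expression_per_nt == pytest.approx(0.05)

    def test_no_hits_all_zero(self):
        m = qt.locus_metrics("el", "full", "g", (0, 100), {}, {})
        assert (m.species_count, m.species_per_nt, m.expression_per_nt) == (0, 0, 0)

    def test_zero_length_locus_is_error(self):
        with pytest.raises(ValueError):
            qt.locus_metrics("el", "full", "g", (5, 5), {}, {})

    def test_full_span_rule_excludes_boundary_hits(self):
        seq = "A" * 10
        hs = {seq: hitset(seq, [Hit("g", 95, "sense")])}
        inside = qt.locus_metrics("el", "full", "g", (0, 105), hs, {seq: 1})
        outside = qt.locus_metrics("el", "full", "g", (0, 100), hs, {seq: 1})
        assert inside.species_count == 1 and outside.species_count == 0

    def test_weighted_species_density_matches_hand_sum(self):
        """Five species with known x and in-locus hit counts: the weighted
        species density is sum over in-locus hits of 1/x, divided by length."""
        specs = {  # seq -> (x total, hits inside locus)
            "S1": (1, 1), "S2": (4, 2), "S3": (5, 5), "S4": (2, 1), "S5": (10, 3),
        }
        hitsets, denom = {}, {}
        for i, (name, (x, inside)) in enumerate(specs.items()):
            seq = name + "A" * 8
            hits = [Hit("g", 10 + 20 * j, "sense") for j in range(inside)]
            hits += [Hit("other", 30 * j, "sense") for j in range(x - inside)]
            hitsets[seq] = hitset(seq, hits)
            denom[seq] = hitsets[seq]
        expr = {s: 1 for s in hitsets}
        m = qt.locus_metrics("el", "full", "g", (0, 500), hitsets, expr,
                             scheme=GW, denominator_hitsets=denom)
        expected = (1 / 1 + 2 / 4 + 5 / 5 + 1 / 2 + 3 / 10) / 500
        assert m.species_per_nt == pytest.approx(expected)

    def test_species_metric_ignores_expression_and_expression_scales(self, small_study):
        a = small_study.annotations[0]
        base = qt.locus_metrics(a.element_id, "full", a.reference_id, a.interval,
                                small_study.genome_hits, small_study.species)
        doubled = {s: 2 * e for s, e in small_study.species.items()}
        scaled = qt.locus_metrics(a.element_id, "full", a.reference_id, a.interval,
                                  small_study.genome_hits, doubled)
        assert scaled.species_per_nt == base.species_per_nt
        assert scaled.expression_per_nt == pytest.approx(2 * base.expression_per_nt)

    def test_unweighted_at_least_weighted(self, small_study):
        for a in small_study.annotations[:5]:
            un = qt.locus_metrics(a.element_id, "full", a.reference_id, a.interval,
                                  small_study.genome_hits, small_study.species)
            wt = qt.locus_metrics(a.element_id, "full", a.reference_id, a.interval,
                                  small_study.genome_hits, small_study.species,
                                  scheme=GW, denominator_hitsets=small_study.genome_hits)
            assert un.expression_per_nt >= wt.expression_per_nt - 1e-12
            assert un.species_count / un.length >= wt.species_per_nt - 1e-12


class TestWindowProfile:
    def test_equal_windows(self):
        p = qt.window_profile("el", "full", "g", (0, 200), {}, {}, n_windows=100)
        assert (p.window_lengths == 2).all()

    def test_window_assignment_by_five_prime(self):
        seq = "ACGTACGTAC"
        hs = {seq: hitset(seq, [Hit("g", 10, "sense")])}
        p = qt.window_profile("el", "full", "g", (0, 200), hs, {seq: 1}, n_windows=100)
        assert p.density["sense"][5] > 0
        assert p.density["sense"].sum() == p.density["sense"][5]
        assert p.density["antisense"].sum() == 0

    def test_antisense_five_prime_is_read_end(self):
        seq = "ACGTACGTAC"
        hs = {seq: hitset(seq, [Hit("g", 10, "antisense")])}
        p = qt.window_profile("el", "full", "g", (0, 200), hs, {seq: 1}, n_windows=100)
        assert p.density["antisense"][9] > 0  # 5' end at 19 -> window 9

    def test_locus_shorter_than_windows_is_error(self):
        with pytest.raises(ValueError, match="smaller n_windows"):
            qt.window_profile("el", "full", "g", (0, 50), {}, {}, n_windows=100)

    @pytest.mark.parametrize("metric", ["species", "expression"])
    @pytest.mark.parametrize("weighted", [False, True])
    def test_profile_conservation(self, small_study, metric, weighted):
        """Window densities x window lengths sum to the locus total."""
        scheme = GW if weighted else UNWEIGHTED
        a = small_study.annotations[1]
        p = qt.window_profile(a.element_id, "full", a.reference_id, a.interval,
                              small_study.genome_hits, small_study.species,
                              n_windows=100, metric=metric, scheme=scheme,
                              denominator_hitsets=small_study.genome_hits)
        total = sum((p.density[s] * p.window_lengths).sum() for s in p.density)
        # independent locus-level total
        expected = 0.0
        for seq, hs in small_study.genome_hits.items():
            inside = qt.hits_in_locus(hs.hits, a.reference_id, a.interval, len(seq))
            if not inside:
                continue
            w = qt.weight_hits(hs, scheme, small_study.genome_hits)
            v = w if metric == "species" else w * small_study.species[seq]
            expected += v * len(inside)
        assert total == pytest.approx(expected, rel=1e-9)
        assert p.window_lengths.sum() == a.length
        assert np.ptp(p.window_lengths) <= 1


class TestUmRatio:
    def test_proportions(self):
        hitsets = [hitset(f"s{i}", [Hit("g", i, "sense")]) for i in range(2)]
        hitsets += [hitset(f"m{i}", [Hit("g", i, "sense"), Hit("g", 50 + i, "sense")])
                    for i in range(8)]
        r = qt.um_ratio(hitsets)
        assert r["U"] == 2 and r["M"] == 8
        assert r["U_proportion"] == pytest.approx(0.2)

    def test_all_unique(self):
        r = qt.um_ratio([hitset("s", [Hit("g", 0, "sense")])])
        assert r["U_proportion"] == 1.0

    def test_unmapped_excluded_and_empty_is_missing(self):
        r = qt.um_ratio([hitset("s", [])])
        assert r["mapped"] == 0 and r["U_proportion"] is None
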