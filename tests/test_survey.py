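"""Top-oligomer tables, HIP summaries, palindrome classes, HIP-subtracted O/E."""

import math

import pytest

from hipscan.sequence import GenomeSeq, OligoPattern, count_occurrences
from hipscan.survey import (
    HIP1,
    best_in_class,
    degenerate_palindromic_hexamers,
    hip_summary,
    oe_excluding_hip,
    overlaps_reference,
    palindromic_hexamers,
    palindromic_pentamers_ws,
    top_oligomers,
    within_hip1,
)
from hipscan.synthetic import generate_genome, plant_pattern


@pytest.fixture(scope="module")
def planted_genome():
    g = generate_genome(1_000_000, 0.45, seed=101)
    g, truth = plant_pattern(g, HIP1, 1000, min_spacing=10, seed=102)
    return g, truth


class TestTopOligomers:
    def test_planted_hip_ranks_first_with_overlaps_elevated(self, planted_genome):
        g, _ = planted_genome
        top = top_oligomers(g, k=8, n=12)
        assert top[0].pattern == HIP1
        assert top[0].is_palindromic
        assert top[0].contained_in == HIP1
        # several of the next entries overlap the planted palindrome
        overlapping = [t for t in top[1:] if t.contained_in == HIP1]
        assert len(overlapping) >= 4

    def test_unplanted_uniform_genome_has_modest_oe(self):
        g = generate_genome(2_000_000, 0.5, seed=55)
        top = top_oligomers(g, k=8, n=1)
        assert top[0].oe < 5

    def test_triplet_repeat_genome(self):
        g = GenomeSeq.from_string("ACG" * 40_000)
        top = top_oligomers(g, k=8, n=3, rank_by="count_per_m")
        # the only 8-mers present are the three phases of the repeat
        assert {t.pattern for t in top} == {"ACGACGAC", "CGACGACG", "GACGACGA"}
        assert all(t.count_per_m > 100_000 for t in top)

    def test_collapsed_list_invariant_under_rc(self, planted_genome):
        g, _ = planted_genome
        top_f = top_oligomers(g, k=6, n=8)
        top_r = top_oligomers(g.reverse_complement(), k=6, n=8)
        # representatives and counts agree pairwise
        assert [(t.pattern, t.count_collapsed) for t in top_f] == [
            (t.pattern, t.count_collapsed) for t in top_r
        ]

    def test_stats_internal_consistency(self, planted_genome):
        g, _ = planted_genome
        for t in top_oligomers(g, k=8, n=5):
            assert t.oe == pytest.approx(t.count_collapsed / t.expected)
            assert t.count_per_m == pytest.approx(t.count_collapsed * 1e6 / g.length)


class TestOverlapAnnotation:
    @pytest.mark.parametrize(
        "pattern,overlaps",
        [
            ("CGATCGCA", True),   # suffix overlap with HIP1
            ("AGCGATCG", True),   # prefix overlap
            ("GCGATCGC", True),   # identity
            ("TTTTTTTT", False),
            ("GGGATCCC", False),  # shares GATC core but no 4-nt aligned window
        ],
    )
    def test_overlaps_reference(self, pattern, overlaps):
        assert overlaps_reference(pattern, HIP1) is overlaps


class TestHipSummary:
    def test_echoes_generator_parameters(self, planted_genome):
        g, truth = planted_genome
        s = hip_summary(g)
        assert s["hip1_count_per_m"] == pytest.approx(
            truth["total_forward"] * 1e6 / g.length, rel=1e-9
        )
        assert s["hip1_oe_order0"] > 50
        assert s["top8_pattern"] is None  # HIP1 itself ranks first
        assert s["hip1_oe_markov1"] > 10 and s["hip1_oe_markov2"] > 10

    def test_zero_hip_genome(self):
        g = GenomeSeq.from_string("AT" * 10_000)
        s = hip_summary(g)
        assert s["hip1_count_per_m"] == 0.0
        assert s["hip1_oe_order0"] == 0.0

    def test_non_hip_top8_reported(self):
        g = generate_genome(500_000, 0.5, seed=77)
        g, _ = plant_pattern(g, "GGGATCCC", 400, min_spacing=10, seed=78)
        s = hip_summary(g)
        assert s["top8_pattern"] == "GGGATCCC"
        assert s["top8_oe"] > 10

    def test_small_genome_rejected(self):
        with pytest.raises(ValueError):
            hip_summary(GenomeSeq.from_string("ACGT" * 100))


class TestClasses:
    def test_memberships(self):
        hexes = palindromic_hexamers()
        assert len(hexes) == 64
        assert all(OligoPattern(str(p)).is_palindromic for p in hexes)
        pents = palindromic_pentamers_ws()
        assert len(pents) == 32
        assert all(p.pattern[2] in "WS" for p in pents)
        assert all(p.is_palindromic for p in pents)
        degs = degenerate_palindromic_hexamers()
        assert len(degs) == 288
        assert all(p.is_palindromic for p in degs)
        assert all(sum(c in "RYSWKM" for c in p.pattern) == 2 for p in degs)
        assert "RCCGGY" in {p.pattern for p in degs}

    def test_within_hip1(self):
        assert within_hip1("CGATCG")
        assert within_hip1("GATC")
        assert not within_hip1("GGCGCC")
        assert not within_hip1("RCCGGY")

    def test_best_in_class_planted_alternate(self):
        g = generate_genome(800_000, 0.5, seed=31)
        g, _ = plant_pattern(g, "GGCGCC", 800, min_spacing=10, seed=32)
        best = best_in_class(g, "palindromic6")
        assert best["pattern"] == "GGCGCC"
        assert best["within_hip1"] is False

    def test_best_in_class_planted_hip(self, planted_genome):
        g, _ = planted_genome
        best = best_in_class(g, "palindromic6")
        assert best["within_hip1"] is True
        assert best["pattern"] == "CGATCG"

    def test_degenerate_class_finds_planted_rccggy(self):
        g = generate_genome(800_000, 0.5, seed=33)
        g, _ = plant_pattern(g, "RCCGGY", 900, min_spacing=10, seed=34)
        best = best_in_class(g, "degenerate_palindromic6")
        assert best["pattern"] == "RCCGGY"


class TestOEExcludingHip:
    def test_no_hip_equals_plain_oe(self):
        from hipscan.expectation import expected_count, oe_ratio
        from hipscan.sequence import strand_collapsed_count

        g = GenomeSeq.from_string("AT" * 5000 + "GATCAT" * 500)
        plain = oe_ratio(
            strand_collapsed_count(g, "GATC"), expected_count(g, "GATC")
        )
        assert oe_excluding_hip(g, "GATC") == pytest.approx(plain)

    def test_full_subtraction_reaches_zero(self):
        # every GATC lies inside a planted HIP1 copy
        spacer = "TTTTAATT"
        g = GenomeSeq.from_string((HIP1 + spacer) * 1000)
        assert oe_excluding_hip(g, "GATC") == 0.0
        assert oe_excluding_hip(g, "CGATCG") == 0.0

    def test_mixed_genome_position_level_oracle(self):
        from hipscan.expectation import expected_count, oe_ratio
        from hipscan.sequence import find_occurrences

        g = generate_genome(200_000, 0.5, seed=41)
        g, _ = plant_pattern(g, HIP1, 200, min_spacing=12, seed=42)
        # oracle: classify every GATC occurrence by whether a HIP1 window covers it
        hip_pos = set(find_occurrences(g, HIP1))
        inner = find_occurrences(g, "GATC")
        # GATC sits at offset 2 of GCGATCGC, once per copy
        outside = sum(1 for p in inner if (p - 2) not in hip_pos)
        want = oe_ratio(float(outside), expected_count(g, "GATC"))
        assert oe_excluding_hip(g, "GATC") == pytest.approx(want, rel=1e-6)

    def test_never_exceeds_plain_oe(self, planted_genome):
        from hipscan.expectation import expected_count, oe_ratio
        from hipscan.sequence import strand_collapsed_count

        g, _ = planted_genome
        for inner in ("GATC", "CGATCG", "ATCG"):
            plain = oe_ratio(
                strand_collapsed_count(g, inner), expected_count(g, inner)
            )
            assert oe_excluding_hip(g, inner) <= plain + 1e-12

    def test_non_substring_rejected(self):
        g = generate_genome(50_000, 0.5, seed=43)
        with pytest.raises(ValueError):
            oe_excluding_hip(g, "GGGCCC")
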