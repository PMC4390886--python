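"""Mismatch-repair ratchet simulator: rule table, conservation, dynamics."""

import numpy as np
import pytest

from hipscan import _kmers
from hipscan.ratchet import (
    RatchetParams,
    classify_mismatch,
    init_state,
    run,
    step,
    trajectory_deviation_spectrum,
)
from hipscan.sequence import GenomeSeq, count_occurrences, find_occurrences


def encode(s: str) -> np.ndarray:
    return _kmers.encode(s)


def oracle_classify(seq: np.ndarray, methylated, params, p, alt):
    """Independent rule table built from whole-sequence string scans."""
    L = params.length
    k = len(params.mtase_pattern)
    # rule (a): circular distance from the mutation to any methylated start
    for s in methylated:
        d = abs(p - s)
        if params.circular:
            d = min(d, L - d)
        if d <= params.repair_radius:
            return "parental"
    # rule (b): scan the full daughter string for qualifying occurrences
    daughter = seq.copy()
    daughter[p] = alt
    text = "".join("ACGT"[c] for c in daughter)
    doubled = text + text if params.circular else text
    pat = params.mtase_pattern
    rc = "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[c] for c in pat)[::-1]
    off = params.meth_offset
    for s in range(L if params.circular else L - k + 1):
        window = doubled[s : s + k]
        spans = []
        if window == pat and doubled[(s + off - 1) % len(doubled)] == "G" and (
            params.circular or s > 0
        ):
            spans.append((s - 1, s + k - 1))
        if window == rc and (params.circular or s + k < L):
            if doubled[s + k - off] == "C" if s + k - off < len(doubled) else False:
                spans.append((s, s + k))
        for lo, hi in spans:
            for pp in (p, p + L) if params.circular else (p,):
                if lo - 1 <= pp <= hi + 1:
                    return "methylation"
    return "random"


class TestRuleTable:
    def test_exhaustive_enumeration_matches_oracle(self):
        """Every single mismatch on a 60-nt genome resolves identically."""
        rng = np.random.default_rng(7)
        base = "".join(rng.choice(list("ACGT"), 60))
        # embed a near-site (one off from G+CGATCG) and a methylated site
        base = base[:10] + "GCGATCG" + base[17:40] + "ACGATCG" + base[47:]
        params = RatchetParams(length=60, repair_radius=5, generations=1, seed=0)
        seq = encode(base)
        methylated = [11]  # the planted GCGATCG pattern start
        agree = 0
        for p in range(60):
            for alt in range(4):
                if alt == seq[p]:
                    continue
                got, _ = classify_mismatch(seq, methylated, params, p, alt)
                want = oracle_classify(seq, methylated, params, p, alt)
                assert got == want, f"p={p} alt={alt}: {got} != {want}"
                agree += 1
        assert agree == 180

    def test_forced_methylation_fix(self):
        """A mutation creating G^meC context before the pattern is rule (b)."""
        text = "A" * 15 + "A" + "CGATCG" + "A" * 18
        params = RatchetParams(length=40, generations=1, seed=0, circular=True)
        seq = encode(text)
        rule, start = classify_mismatch(seq, [], params, 15, 2)  # A->G at 15
        assert rule == "methylation"
        assert start == 16

    def test_parental_repair_wins_over_methylation(self):
        text = "A" * 15 + "A" + "CGATCG" + "A" * 18
        params = RatchetParams(length=40, repair_radius=20, generations=1, seed=0)
        seq = encode(text)
        rule, _ = classify_mismatch(seq, [30], params, 15, 2)
        assert rule == "parental"

    def test_distant_mutation_is_random(self):
        text = "A" * 60
        params = RatchetParams(length=60, repair_radius=5, generations=1, seed=0)
        rule, _ = classify_mismatch(encode(text), [], params, 30, 1)
        assert rule == "random"


class TestInitState:
    def test_zero_density_zero_sites(self):
        params = RatchetParams(length=10_000, init_site_per_nt=0.0, generations=1, seed=3)
        assert init_state(params).site_count() == 0

    def test_planted_density_and_verification(self):
        params = RatchetParams(length=100_000, init_site_per_nt=1e-4, generations=1, seed=4)
        state = init_state(params)
        assert state.site_count() == 10
        genome = state.to_genome()
        qualifying = set(find_occurrences(genome, "GCGATCG"))
        for s in state.methylated:
            assert (s - 1) in qualifying  # planted as G + CGATCG

    def test_unachievable_density_rejected(self):
        with pytest.raises(ValueError, match="unachievable"):
            init_state(RatchetParams(length=1000, init_site_per_nt=0.2, generations=1))


class TestStep:
    def test_mu_zero_changes_nothing_but_generation(self):
        params = RatchetParams(length=5000, mu=0.0, generations=1, seed=5)
        state = init_state(params)
        before = state.seq.copy()
        rng = np.random.default_rng(0)
        state, stats = step(state, params, rng)
        assert np.array_equal(state.seq, before)
        assert stats.mismatches == 0
        assert state.generation == 1

    def test_conservation_fixed_plus_lost(self):
        params = RatchetParams(length=20_000, mu=5e-3, generations=30, seed=6)
        traj = run(params)
        for s in traj.stats:
            assert (
                s.lost_parental + s.fixed_methylation + s.fixed_random + s.lost_random
                == s.mismatches
            )

    def test_determinism(self):
        params = RatchetParams(length=10_000, mu=1e-3, generations=50, seed=11)
        t1, t2 = run(params), run(params)
        assert np.array_equal(t1.final_state.seq, t2.final_state.seq)
        assert t1.final_state.methylated == t2.final_state.methylated
        assert [s.site_count for s in t1.stats] == [s.site_count for s in t2.stats]

    def test_registry_entries_stay_qualifying(self):
        params = RatchetParams(length=20_000, mu=2e-3, generations=100, seed=12)
        traj = run(params)
        state = traj.final_state
        genome = state.to_genome()
        text = genome.residues
        L = params.length
        k = len(params.mtase_pattern)
        for s in state.methylated:
            # CGATCG is its own reverse complement: the window must read the
            # pattern, with G^meC context on one strand (G before or C after)
            window = "".join(text[(s + j) % L] for j in range(k))
            assert window == params.mtase_pattern
            assert text[(s - 1) % L] == "G" or text[(s + k) % L] == "C"


class TestDynamics:
    def test_random_only_resolution_is_balanced(self):
        """Without sites or methylation the fixed:lost ratio is 1:1."""
        params = RatchetParams(
            length=50_000, mu=5e-3, p_meth=0.0, init_site_per_nt=0.0,
            generations=60, seed=13,
        )
        traj = run(params)
        t = traj.totals()
        assert t["fixed_methylation"] == 0
        total_random = t["fixed_random"] + t["lost_random"]
        assert total_random > 10_000
        ratio = t["fixed_random"] / total_random
        assert abs(ratio - 0.5) < 0.02

    def test_sites_protected_and_nondecreasing(self):
        params = RatchetParams(length=50_000, mu=1e-3, generations=300, seed=14)
        traj = run(params)
        counts = traj.site_counts()
        assert np.all(np.diff(counts) >= 0)
        assert counts[-1] >= counts[0]

    def test_rule_a_dominance_blocks_site_destruction(self):
        """With dense methylated sites and p_meth 1, destroying mutations are lost."""
        params = RatchetParams(
            length=20_000, mu=2e-3, init_site_per_nt=1e-3, repair_radius=2000,
            generations=50, seed=15,
        )
        traj = run(params)
        t = traj.totals()
        # every mismatch lies within R of a site: all lost to parental repair
        assert t["fixed_methylation"] == 0 and t["fixed_random"] == 0
        assert t["lost_parental"] == t["mismatches"]
        assert traj.stats[-1].site_count == traj.stats[0].site_count


class TestDeviationSpectrum:
    def test_zero_generation_profile_matches_init_genome(self):
        params = RatchetParams(length=50_000, generations=1, seed=16)
        state = init_state(params)
        prof = trajectory_deviation_spectrum(state)
        from hipscan.deviation import deviation_profile

        direct = deviation_profile(state.to_genome(), "GCGATCGC")
        assert prof.fractions == direct.fractions

    def test_pre_ratchet_profile_roughly_flat(self):
        params = RatchetParams(length=200_000, init_site_per_nt=0.0, generations=1, seed=17)
        prof = trajectory_deviation_spectrum(init_state(params))
        fr = np.array(prof.fractions)
        assert np.nanmax(fr) - np.nanmin(fr) < 0.35  # small-count noise only
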