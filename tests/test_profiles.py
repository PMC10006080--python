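"""Variant-design operations: window means, deltas, classes, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mef2dyn.profiles import (BETA_DOMAIN, DISORDER_THRESHOLD, DomainWindow,
                              DynamicsSummary, ResidueProfile, VariantSpec,
                              average_window, classify_disorder,
                              classify_variant, delta_dynamics,
                              droplet_landscape, full_to_peptide,
                              peptide_to_full, rank_candidates,
                              read_profile_table, summarize_variant,
                              toy_profile, write_summary_table)


def make_profile(p_d, start=286, name="p", p_dd=None, p_dp=None):
    p_d = np.asarray(p_d, dtype=float)
    n = p_d.size
    return ResidueProfile(
        sequence="A" * n, positions=np.arange(start, start + n),
        p_D=p_d, p_DD=p_dd if p_dd is not None else np.full(n, 0.5),
        p_DP=p_dp if p_dp is not None else np.full(n, 0.5), name=name)


class TestAverageWindow:
    @pytest.mark.parametrize("values, expected", [
        (np.full(7, 0.4), 0.4),                      # constant profile
        (np.array([0.2, 0.3, 0.4]), 0.3),            # plain arithmetic
    ])
    def test_mean(self, values, expected):
        prof = make_profile(values)
        win = DomainWindow(286, 286 + values.size - 1)
        assert average_window(prof, win)[0] == pytest.approx(expected)

    def test_singleton_window(self):
        prof = make_profile([0.1, 0.7, 0.9])
        assert average_window(prof, DomainWindow(287, 287)) == (0.7, 0.5, 0.5)

    def test_window_outside_profile_raises(self):
        prof = make_profile([0.5] * 3)
        with pytest.raises(IndexError):
            average_window(prof, DomainWindow(280, 295))

    @given(scale=st.floats(0.05, 1.0), seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_linearity_under_scaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.1, 0.9, 7)
        win = DomainWindow(286, 292)
        m0 = average_window(make_profile(base), win)[0]
        m1 = average_window(make_profile(base * scale), win)[0]
        assert m1 == pytest.approx(scale * m0)


class TestClassifyDisorder:
    def test_threshold_inclusive(self):
        assert classify_disorder(DISORDER_THRESHOLD) == "disordered"
        assert classify_disorder(DISORDER_THRESHOLD - 1e-9) == "ordered"

    @pytest.mark.parametrize("value, expected", [
        (0.0, "ordered"), (1.0, "disordered")])
    def test_extremes(self, value, expected):
        assert classify_disorder(value) == expected

    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, a, b):
        lo, hi = min(a, b), max(a, b)
        order = {"ordered": 0, "disordered": 1}
        assert order[classify_disorder(lo)] <= order[classify_disorder(hi)]


class TestDeltaDynamics:
    def test_identity_is_zero(self):
        p = make_profile(np.linspace(0.1, 0.7, 7))
        assert delta_dynamics(p, p) == (0.0, 0.0, 0.0)

    def test_arithmetic(self):
        wt = make_profile(np.full(7, 0.3))
        mut = make_profile(np.full(7, 0.5))
        assert delta_dynamics(mut, wt)[0] == pytest.approx(0.2)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_antisymmetry(self, seed):
        r = np.random.default_rng(seed)
        a = make_profile(r.uniform(0, 1, 7), p_dd=r.uniform(0, 1, 7),
                         p_dp=r.uniform(0, 1, 7))
        b = make_profile(r.uniform(0, 1, 7), p_dd=r.uniform(0, 1, 7),
                         p_dp=r.uniform(0, 1, 7))
        fwd = delta_dynamics(a, b)
        rev = delta_dynamics(b, a)
        assert np.allclose(fwd, [-x for x in rev])

    def test_mismatched_numbering_raises(self):
        with pytest.raises(ValueError):
            delta_dynamics(make_profile([0.5] * 7),
                           make_profile([0.5] * 7, start=300))


class TestClassifyVariant:
    @pytest.mark.parametrize("delta, expected", [
        (0.0, "similar"), (0.2, "mobile"), (-0.2, "rigid"),
        (0.05, "mobile"), (-0.05, "rigid"), (0.049, "similar")])
    def test_rule(self, delta, expected):
        assert classify_variant(delta, epsilon=0.05) == expected

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_variant(0.1, epsilon=0)


class TestDropletLandscape:
    def test_far_from_diagonal(self):
        assert droplet_landscape((0.9, 0.1))[0] == "liquid-favoring"
        assert droplet_landscape((0.1, 0.9))[0] == "solid-favoring"

    @pytest.mark.parametrize("x", [0.0, 0.3, 0.77, 1.0])
    def test_diagonal_is_boundary(self, x):
        label, dist = droplet_landscape((x, x))
        assert label == "boundary" and dist == 0.0

    def test_range_check(self):
        with pytest.raises(ValueError):
            droplet_landscape((1.2, 0.5))


class TestRankCandidates:
    @staticmethod
    def cand(name, d_pd, d_pdp, pos=290):
        spec = VariantSpec(name, ((pos, "A", "W"),))
        summ = DynamicsSummary(name=name, mean_p_D=0.3, mean_p_DD=0.5,
                               mean_p_DP=0.5, delta_p_D=d_pd,
                               delta_p_DP=d_pdp)
        return spec, summ

    def test_single_candidate(self):
        c = [self.cand("a", 0.1, 0.0)]
        assert rank_candidates(c) == c

    def test_sorted_by_abs_delta(self):
        cs = [self.cand("a", 0.3, 0), self.cand("b", 0.1, 0),
              self.cand("c", -0.2, 0)]
        assert [c[0].name for c in rank_candidates(cs)] == ["a", "c", "b"]

    def test_tie_broken_by_delta_pdp(self):
        cs = [self.cand("a", 0.2, 0.1), self.cand("b", -0.2, 0.3)]
        assert [c[0].name for c in rank_candidates(cs)] == ["b", "a"]

    def test_permutation_and_shuffle_invariance(self, rng):
        cs = [self.cand(f"v{i}", rng.uniform(-0.4, 0.4),
                        rng.uniform(-0.3, 0.3), pos=286 + i)
              for i in range(10)]
        ranked = rank_candidates(cs)
        assert sorted(c[0].name for c in ranked) == sorted(
            c[0].name for c in cs)
        shuffled = [cs[i] for i in rng.permutation(len(cs))]
        assert [c[0].name for c in rank_candidates(shuffled)] == \
            [c[0].name for c in ranked]

    def test_empty(self):
        assert rank_candidates([]) == []


class TestNumbering:
    def test_full_peptide_round_trip(self):
        assert full_to_peptide(265) == 1
        assert full_to_peptide(286) == 22
        assert peptide_to_full(full_to_peptide(292)) == 292

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            full_to_peptide(264)


class TestSummaryAndIO:
    def test_summary_fields_consistent(self):
        wt = make_profile(np.full(7, 0.30))
        mut = make_profile(np.full(7, 0.55), name="mut")
        s = summarize_variant(mut, wt)
        assert s.delta_p_D == pytest.approx(0.25)
        assert s.dynamics_class == "mobile"
        assert s.disorder_class == "disordered"

    def test_profile_table_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame({
            "position": np.arange(286, 293), "residue": list("EEDDLEL"),
            "p_D": np.linspace(0.1, 0.7, 7), "p_DD": np.full(7, 0.4),
            "p_DP": np.full(7, 0.6), "mbm_flag": [0, 1, 1, 0, 0, 1, 0]})
        path = tmp_path / "prof.tsv"
        df.to_csv(path, sep="\t", index=False)
        prof = read_profile_table(path)
        assert prof.sequence == "EEDDLEL"
        assert prof.mbm_regions == ((287, 288), (291, 291))
        assert np.allclose(prof.p_D, df["p_D"])
        assert prof.mbm_fraction(DomainWindow(286, 292)) == pytest.approx(3 / 7)

    def test_write_summary_table(self, tmp_path):
        import pandas as pd

        wt = make_profile(np.full(7, 0.3))
        s = summarize_variant(make_profile(np.full(7, 0.4), name="v"), wt)
        out = tmp_path / "summary.tsv"
        write_summary_table([s], out)
        back = pd.read_csv(out, sep="\t")
        assert back.loc[0, "name"] == "v"
        assert back.loc[0, "delta_p_D"] == pytest.approx(0.1, abs=1e-12)


class TestToySurrogate:
    def test_charged_more_disordered_than_hydrophobic(self):
        charged = toy_profile("EDEDKEDEDKEDEDK")
        greasy = toy_profile("LVLIVLLVILVLIVL")
        assert charged.p_D.mean() > greasy.p_D.mean()

    def test_probabilities_bounded(self):
        prof = toy_profile("SRKPDLRVITSQAGKGLMHHLTEDHLDLNNAQRLGVS",
                           start_position=265)
        for arr in (prof.p_D, prof.p_DD, prof.p_DP):
            assert np.all((arr >= 0) & (arr <= 1))


class TestInvariants:
    def test_profile_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            make_profile([1.2] * 7)

    def test_positions_strictly_increasing(self):
        with pytest.raises(ValueError):
            ResidueProfile(sequence="AA", positions=np.array([5, 5]),
                           p_D=np.array([0.1, 0.2]),
                           p_DD=np.array([0.1, 0.2]),
                           p_DP=np.array([0.1, 0.2]))

    def test_mutation_wt_mismatch(self):
        prof = make_profile([0.5] * 7)
        with pytest.raises(ValueError):
            prof.apply_mutations(VariantSpec("v", ((288, "W", "K"),)))
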