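"""Kruskal-Wallis, Dunn post hoc and the normality gate."""

import numpy as np
import pytest
from scipy import stats as sps

from prmkit.group_stats import (
    GroupedRatios,
    compare_peptide,
    dunn_posthoc,
    kruskal_wallis,
    shapiro_wilk_gate,
    stars_for,
)


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        # ranks 1..9, mean ranks 2/5/8 -> H = 7.2 exactly
        h, p = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert h == pytest.approx(7.2, abs=1e-12)

    def test_identical_observations_give_zero(self):
        h, p = kruskal_wallis({"a": [1, 1], "b": [1, 1]})
        assert (h, p) == (0.0, 1.0)

    def test_matches_reference_implementation(self):
        """Tie-corrected H and p agree with scipy.stats.kruskal to 1e-10
        on 100 random datasets (with and without ties)."""
        rng = np.random.default_rng(42)
        for k in range(100):
            n_groups = int(rng.integers(2, 5))
            groups = {}
            for g in range(n_groups):
                n = int(rng.integers(3, 12))
                vals = rng.normal(size=n)
                if k % 2:  # force ties half the time
                    vals = np.round(vals, 1)
                groups[str(g)] = vals.tolist()
            h, p = kruskal_wallis(groups)
            h_ref, p_ref = sps.kruskal(*groups.values())
            assert h == pytest.approx(h_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        groups = {g: rng.lognormal(0, 1, size=8).tolist() for g in "abc"}
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis({g: np.log(v).tolist() for g, v in groups.items()})
        h3, _ = kruskal_wallis({g: (np.asarray(v) ** 3).tolist() for g, v in groups.items()})
        assert h1 == pytest.approx(h2, abs=1e-12)
        assert h1 == pytest.approx(h3, abs=1e-12)

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1.0, 2.0, 3.0], "b": []})


class TestDunn:
    def test_hand_formula_oracle(self):
        # design {1,2,3},{4,5,6},{7,8,9}: no ties, var base N(N+1)/12 = 7.5,
        # z(a,c) = (2 - 8) / sqrt(7.5 * (1/3 + 1/3)) = -6/sqrt(5)
        pairs = {
            (r.group_a, r.group_b): r
            for r in dunn_posthoc(
                {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}, adjustment="none"
            )
        }
        z = pairs[("a", "c")].z
        assert z == pytest.approx(-6 / np.sqrt(5), abs=1e-12)
        assert pairs[("a", "c")].raw_p == pytest.approx(
            2 * sps.norm.sf(6 / np.sqrt(5)), abs=1e-12
        )

    def test_identical_groups_give_zero_z(self):
        pairs = dunn_posthoc({"a": [1, 2, 3], "b": [1, 2, 3]}, adjustment="none")
        (r,) = pairs
        assert r.z == pytest.approx(0.0, abs=1e-12)
        assert r.raw_p == pytest.approx(1.0, abs=1e-12)

    def test_swapping_groups_negates_z(self):
        g1 = {"a": [1, 2, 3], "b": [7, 8, 9]}
        g2 = {"b": [7, 8, 9], "a": [1, 2, 3]}
        (r1,) = dunn_posthoc(g1, adjustment="none")
        (r2,) = dunn_posthoc(g2, adjustment="none")
        assert r1.z == pytest.approx(-r2.z, abs=1e-12)
        assert r1.raw_p == pytest.approx(r2.raw_p, abs=1e-12)

    @pytest.mark.parametrize("adjustment", ["bonferroni", "holm"])
    def test_adjusted_p_at_least_raw(self, adjustment):
        rng = np.random.default_rng(3)
        groups = {g: rng.normal(loc=i, size=10).tolist() for i, g in enumerate("abc")}
        for r in dunn_posthoc(groups, adjustment=adjustment):
            assert r.adjusted_p >= r.raw_p - 1e-15

    def test_empty_group_pair_skipped_and_flagged(self):
        results = dunn_posthoc({"a": [1, 2, 3], "b": [], "c": [4, 5, 6]})
        flagged = [r for r in results if r.skipped]
        assert {(r.group_a, r.group_b) for r in flagged} == {("a", "b"), ("b", "c")}
        assert all("insufficient" in r.note for r in flagged)
        tested = [r for r in results if not r.skipped]
        assert len(tested) == 1


class TestShapiroGate:
    def test_skewed_sample_routes_nonparametric(self):
        rng = np.random.default_rng(123)
        groups = {"a": rng.lognormal(0, 1.5, size=50).tolist(),
                  "b": rng.normal(size=50).tolist()}
        report, route = shapiro_wilk_gate(groups, alpha=0.05)
        assert report["a"] < 0.05
        assert route == "nonparametric"

    def test_tiny_group_untestable_forces_nonparametric(self):
        report, route = shapiro_wilk_gate({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0, 2.5]})
        assert report["a"] is None
        assert route == "nonparametric"

    def test_route_deterministic(self):
        rng = np.random.default_rng(5)
        groups = {g: rng.normal(size=20).tolist() for g in "ab"}
        assert shapiro_wilk_gate(groups) == shapiro_wilk_gate(groups)


class TestCompare:
    def test_stars_thresholds(self):
        assert stars_for(0.2) == ""
        assert stars_for(0.04) == "*"
        assert stars_for(0.009) == "**"
        assert stars_for(0.0009) == "***"

    def test_sparse_group_cannot_claim_significance(self):
        grouped = GroupedRatios(
            "PEP", {"GP": [0.1, 0.2], "SGR": list(np.linspace(5, 6, 15)),
                    "AGR": list(np.linspace(1, 2, 15))}
        )
        comp = compare_peptide(grouped, min_detections=3)
        gp_pairs = [
            r for r in comp.pairwise if "GP" in (r.group_a, r.group_b)
        ]
        assert all(r.skipped for r in gp_pairs)
        assert ("SGR", "AGR") in comp.significant_pairs()

    def test_bar_plot_renders_stars(self, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        from prmkit.group_stats import plot_group_comparison

        grouped = GroupedRatios(
            "GADVWFK",
            {"GP": [0.1, 0.2, 0.15, 0.12], "SGR": [5.0, 5.5, 6.0, 5.2],
             "AGR": [1.0, 1.1, 0.9, 1.2]},
        )
        comp = compare_peptide(grouped)
        ax = plot_group_comparison(grouped, comp)
        assert len(ax.patches) == 3  # one bar per group
        assert any(t.get_text() in ("*", "**", "***") for t in ax.texts)
        ax.figure.savefig(tmp_path / "plot.png")

    def test_type_i_error_near_alpha(self):
        """Null calibration: three identical lognormal groups, n = 15,
        2000 reps -> rejection rate at alpha 0.05 lies in [0.04, 0.06]."""
        rng = np.random.default_rng(2021)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            groups = {g: rng.lognormal(0.0, 1.0, size=15) for g in "abc"}
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        rate = rejections / reps
        assert 0.04 <= rate <= 0.06
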