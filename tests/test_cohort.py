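"""Data-generating process: responder rule, marginals, randomisation,
outcome model, noisy-variable recipes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenosim import (
    NoiseSpec,
    OutcomeModel,
    ResponseRule,
    add_noise_variables,
    draw_phenotypes,
    is_responsive,
    remove_variable,
    responsive_mask,
    simulate_trial,
)


def rule_oracle(x: int, y: int, z: int) -> int:
    """Independent brute-force restatement of the responder rule."""
    if x >= 95:
        return 1
    if z == 1 and 50 <= y <= 90:
        return 1
    if z == 0 and 90 <= x <= 94 and 50 <= y <= 90:
        return 1
    return 0


GRID = [(x, y, z) for z in (0, 1) for x in range(50, 101) for y in range(40, 101)]
EXACT_FRACTION = sum(rule_oracle(*c) for c in GRID) / len(GRID)  # 2782 / 6222


class TestResponderRule:
    def test_matches_enumeration_oracle_on_full_grid(self):
        xs, ys, zs = map(np.array, zip(*GRID))
        got = responsive_mask(xs, ys, zs)
        want = np.array([rule_oracle(*c) for c in GRID])
        assert np.array_equal(got, want)
        assert got.mean() == pytest.approx(2782 / 6222)

    @pytest.mark.parametrize(
        "x, y, z, expected",
        [
            (96, 45, 0, 1),  # high x responds regardless of y and z
            (95, 40, 1, 1),  # the x floor is inclusive
            (80, 70, 1, 1),  # z present opens the y band at any x
            (80, 70, 0, 0),  # same phenotype without z does not respond
            (92, 60, 0, 1),  # conditional x window when z absent
            (92, 49, 0, 0),  # y band is inclusive: 49 just misses
            (92, 91, 0, 0),
        ],
    )
    def test_known_cases(self, x, y, z, expected):
        assert is_responsive(x, y, z) == expected

    @given(
        x=st.integers(50, 100),
        y=st.integers(40, 100),
        z=st.integers(0, 1),
    )
    @settings(max_examples=200, derandomize=True)
    def test_agrees_with_oracle_everywhere(self, x, y, z):
        assert is_responsive(x, y, z) == rule_oracle(x, y, z)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            is_responsive(101, 50, 0)
        with pytest.raises(ValueError):
            is_responsive(80, 39, 0)
        with pytest.raises(ValueError):
            is_responsive(80, 50, 2)

    def test_invalid_rule_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ResponseRule(x_high=90, x_mid_low=95)
        with pytest.raises(ValueError):
            ResponseRule(y_low=90, y_high=50)


class TestPhenotypes:
    def test_ranges_and_shape(self):
        df = draw_phenotypes(1000, seed=3)
        assert len(df) == 1000
        assert df["x"].between(50, 100).all()
        assert df["y"].between(40, 100).all()
        assert df["age"].between(18, 100).all()
        assert set(np.unique(df[["sex", "v1", "z"]])) <= {0, 1}

    def test_mean_of_x_matches_discrete_uniform(self):
        # mean of uniform integers 50..100 is exactly 75, sd^2=(51^2-1)/12
        df = draw_phenotypes(100_000, seed=11)
        se = np.sqrt((51**2 - 1) / 12 / 100_000)
        assert abs(df["x"].mean() - 75.0) < 3 * se

    def test_variables_mutually_independent(self):
        df = draw_phenotypes(50_000, seed=5)
        corr = df.corr().to_numpy()
        off_diag = corr[~np.eye(len(corr), dtype=bool)]
        assert np.abs(off_diag).max() < 0.02

    def test_deterministic_and_seed_sensitive(self):
        a = draw_phenotypes(50, seed=42)
        b = draw_phenotypes(50, seed=42)
        c = draw_phenotypes(50, seed=43)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            draw_phenotypes(0, seed=1)


class TestTrial:
    def test_monte_carlo_fraction_matches_enumeration(self):
        df = draw_phenotypes(1_000_000, seed=99)
        frac = responsive_mask(df["x"], df["y"], df["z"]).mean()
        se = np.sqrt(EXACT_FRACTION * (1 - EXACT_FRACTION) / 1_000_000)
        assert abs(frac - EXACT_FRACTION) < 3 * se

    def test_simple_randomisation_arm_sizes(self):
        # Binomial(1000, 1/2): 99% of realisations fall within [440, 560]
        counts = [
            (simulate_trial(1000, seed=s)["arm"] == "treatment").sum() for s in range(20)
        ]
        assert all(440 <= c <= 560 for c in counts)
        assert len(set(counts)) > 1  # simple, not forced 500/500

    def test_outcome_means_by_responsiveness(self):
        trial = simulate_trial(20_000, seed=21)
        treated_resp = (trial["arm"] == "treatment") & (trial["responsive_truth"] == 1)
        others = ~treated_resp
        k = treated_resp.sum()
        assert abs(trial.loc[treated_resp, "outcome_change"].mean() - 10) < 3 * 3 / np.sqrt(k)
        m = others.sum()
        assert abs(trial.loc[others, "outcome_change"].mean() - 0) < 3 * 3 / np.sqrt(m)

    def test_degenerate_noise_free_outcomes(self):
        trial = simulate_trial(500, model=OutcomeModel(sigma=0.0), seed=2)
        treated_resp = (trial["arm"] == "treatment") & (trial["responsive_truth"] == 1)
        assert (trial.loc[treated_resp, "outcome_change"] == 10.0).all()
        assert (trial.loc[~treated_resp, "outcome_change"] == 0.0).all()

    def test_trial_determinism(self):
        pd.testing.assert_frame_equal(simulate_trial(200, seed=8), simulate_trial(200, seed=8))

    def test_rejects_tiny_trial(self):
        with pytest.raises(ValueError):
            simulate_trial(1, seed=0)


class TestNoiseVariables:
    def test_zero_noise_is_identity(self):
        df = draw_phenotypes(100, seed=1)
        out = add_noise_variables(df, NoiseSpec(n_noisy=0), seed=2)
        pd.testing.assert_frame_equal(out, df)
        assert out is not df

    def test_class_split_for_six_variables(self):
        df = draw_phenotypes(400, seed=1)
        out = add_noise_variables(df, NoiseSpec(n_noisy=6), seed=2)
        noise = out.iloc[:, 7:]
        assert noise.shape[1] == 6
        # fixed ordering: x-linked, y-linked, z-linked, then 3 independents
        assert noise.iloc[:, 0].corr(df["x"]) > 0.5
        assert noise.iloc[:, 1].corr(df["y"]) > 0.5
        assert (noise.iloc[:, 2] == df["z"]).mean() == pytest.approx(
            round(2 / 3 * 400) / 400
        )
        assert set(np.unique(noise.iloc[:, 3])) <= {0.0, 1.0}
        assert noise.iloc[:, 4].between(18, 100).all()

    def test_x_linked_correlation_matches_closed_form(self):
        # corr = sd_x / sqrt(sd_x^2 + 10^2) with sd_x^2 = (51^2 - 1)/12
        df = draw_phenotypes(20_000, seed=4)
        out = add_noise_variables(df, NoiseSpec(n_noisy=6), seed=5)
        var_x = (51**2 - 1) / 12
        expected = np.sqrt(var_x / (var_x + 100.0))
        assert out.iloc[:, 7].corr(df["x"]) == pytest.approx(expected, abs=0.02)

    def test_independent_variables_uncorrelated_with_signal(self):
        df = draw_phenotypes(1000, seed=6)
        out = add_noise_variables(df, NoiseSpec(n_noisy=60), seed=7)
        indep = out.iloc[:, 7 + 30 :]  # last 30 columns are the independents
        r = np.array(
            [abs(indep.iloc[:, j].corr(df[v])) for j in range(30) for v in ("x", "y", "z")]
        )
        assert (r < 0.1).mean() >= 0.95

    def test_z_match_fraction_exact_and_flip_default(self):
        df = draw_phenotypes(300, seed=8)
        out = add_noise_variables(df, NoiseSpec(n_noisy=18), seed=9)
        z = df["z"].to_numpy()
        for j in range(6, 9):  # the three z-linked columns
            col = out.iloc[:, 7 + j].to_numpy()
            assert (col == z).sum() == round(2 / 3 * 300)
            assert ((col == z) | (col == 1 - z)).all()

    def test_independent_binary_prevalence(self):
        df = draw_phenotypes(5000, seed=10)
        out = add_noise_variables(df, NoiseSpec(n_noisy=12), seed=11)
        binaries = out.iloc[:, 7 + 6 :: 2]  # alternating: even independents binary
        assert binaries.to_numpy().mean() == pytest.approx(0.10, abs=0.02)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(n_noisy=-1)


class TestRemoveVariable:
    def test_remove_and_roundtrip(self):
        df = draw_phenotypes(50, seed=1)
        kept = df["z"].copy()
        reduced = remove_variable(df, "z")
        assert "z" not in reduced.columns
        assert len(reduced) == 50
        assert "z" in df.columns  # original untouched
        restored = reduced.assign(z=kept)[df.columns]
        pd.testing.assert_frame_equal(restored, df)

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            remove_variable(draw_phenotypes(5, seed=1), "q")
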