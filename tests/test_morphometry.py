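"""ANCOVA, reaction-norm and character-coding behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from normevol.morphometry import (
    NEGATIVE,
    NO_PLASTICITY,
    POSITIVE,
    AncovaResult,
    InsufficientReplicationError,
    code_character,
    fit_ancova,
    reaction_norm,
    species_summary,
)
from normevol.synth import SimulationConfig, simulate_specimens


def _table(species, temps, wings, spots, sex="female"):
    return pd.DataFrame(
        dict(species=species, sex=sex, temperature=temps,
             wing_area=wings, eyespot_area=spots)
    )


class TestAncova:
    def test_matches_normal_equation_oracle(self):
        # 6-row toy table solved by explicit least squares
        wings = np.array([80.0, 95.0, 110.0, 85.0, 100.0, 120.0])
        spots = np.array([1.0, 1.3, 1.6, 1.5, 1.9, 2.5])
        temps = [17, 17, 17, 27, 27, 27]
        df = _table(["sp"] * 6, temps, wings, spots)
        res = fit_ancova(df, "sp")

        y = np.log10(spots)
        X_full = np.column_stack(
            [np.ones(6), np.log10(wings), np.array([0, 0, 0, 1, 1, 1.0])]
        )
        X_red = X_full[:, :2]
        b_full, *_ = np.linalg.lstsq(X_full, y, rcond=None)
        b_red, *_ = np.linalg.lstsq(X_red, y, rcond=None)
        rss_f = np.sum((y - X_full @ b_full) ** 2)
        rss_r = np.sum((y - X_red @ b_red) ** 2)
        F = (rss_r - rss_f) / 1 / (rss_f / 3)
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.df == (1, 3)
        assert res.coefficients["temperature_high"] == pytest.approx(
            b_full[2], rel=1e-10
        )

    def test_perfect_separation_overflow_safe(self):
        # constant offset in log eyespot, zero residual noise
        wings = np.array([100.0, 110, 121, 100, 110, 121])
        temps = [17, 17, 17, 27, 27, 27]
        spots = 0.01 * wings * np.where(np.array(temps) == 27, 10.0, 1.0)
        res = fit_ancova(_table(["sp"] * 6, temps, wings, spots), "sp")
        assert np.isinf(res.F) or res.F > 1e12
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_type_one_error_rate_small(self):
        # small null calibration here; the full 2000-rep run lives in the
        # acceptance suite
        hits = 0
        n = 300
        for i in range(n):
            df = simulate_specimens(
                SimulationConfig(seed=i, n_species=1, n_per_group=10)
            )
            hits += fit_ancova(df, "sp01").p_value < 0.05
        assert hits / n == pytest.approx(0.05, abs=0.03)

    def test_f_invariant_under_covariate_rescaling(self):
        df = simulate_specimens(
            SimulationConfig(seed=5, n_species=1, temp_effect=0.05)
        )
        res = fit_ancova(df, "sp01")
        df2 = df.assign(wing_area=df.wing_area * 7.3)
        res2 = fit_ancova(df2, "sp01")
        assert res2.F == pytest.approx(res.F, rel=1e-9)

    def test_insufficient_replication(self):
        df = _table(["sp"] * 3, [17, 17, 27], [100, 100, 100], [1, 1, 1])
        with pytest.raises(InsufficientReplicationError):
            fit_ancova(df, "sp")

    def test_zero_eyespots_excluded_with_warning(self):
        df = _table(
            ["sp"] * 6, [17, 17, 17, 27, 27, 27],
            [100.0] * 6, [1.0, 1.1, 0.0, 1.2, 1.3, 1.25],
        )
        with pytest.warns(UserWarning, match="zero"):
            res = fit_ancova(df, "sp")
        assert res.n == 5

    def test_males_excluded_by_default(self):
        df = pd.concat(
            [
                _table(["sp"] * 4, [17, 17, 27, 27], [100.0] * 4,
                       [1.0, 1.1, 1.2, 1.3]),
                _table(["sp"] * 2, [17, 27], [100.0] * 2, [9.0, 9.0],
                       sex="male"),
            ]
        )
        res = fit_ancova(df, "sp")
        assert res.n == 4


class TestReactionNorm:
    def test_direct_formula(self):
        df = _table(["sp"] * 4, [17, 17, 27, 27], [100.0] * 4,
                    [4.0, 4.0, 8.0, 8.0])
        norm = reaction_norm(df, "sp")
        assert norm.slope == pytest.approx(0.4)
        assert (norm.value_low, norm.value_high) == (4.0, 8.0)

    def test_equal_means_zero_slope(self):
        df = _table(["sp"] * 4, [17, 17, 27, 27], [100.0] * 4, [5.0] * 4)
        assert reaction_norm(df, "sp").slope == 0.0

    def test_literature_delta_t_correction(self):
        # species reared at 21/27 C: slope expressed over the 6 C spanned
        df = _table(["sp"] * 4, [21, 21, 27, 27], [100.0] * 4,
                    [3.0, 3.0, 6.0, 6.0])
        norm = reaction_norm(df, "sp", delta_T=6.0)
        assert norm.slope == pytest.approx(0.5)
        # and the default uses the observed difference (also 6 here)
        assert reaction_norm(df, "sp").slope == pytest.approx(0.5)

    def test_single_temperature_errors(self):
        df = _table(["sp"] * 4, [17] * 4, [100.0] * 4, [1.0] * 4)
        with pytest.raises(InsufficientReplicationError):
            reaction_norm(df, "sp")


class TestCoding:
    def _norm(self, slope):
        df = _table(["sp"] * 4, [17, 17, 27, 27], [100.0] * 4,
                    [1.0, 1.0, 1.0 + slope * 10, 1.0 + slope * 10])
        return reaction_norm(df, "sp")

    def _res(self, p):
        return AncovaResult("sp", F=1.0, df=(1, 10), p_value=p)

    @pytest.mark.parametrize(
        "slope,p,expected",
        [
            (+0.03, 0.001, POSITIVE),
            (-0.03, 0.40, NO_PLASTICITY),
            (-0.03, 0.001, NEGATIVE),
            (+0.03, 0.051, NO_PLASTICITY),
        ],
    )
    def test_rule(self, slope, p, expected):
        assert code_character(self._norm(slope), self._res(p)) == expected

    @given(
        slope=st.floats(-1, 1, allow_nan=False).filter(lambda s: abs(s) > 1e-6),
        p=st.floats(0, 1, allow_nan=False),
        alpha=st.floats(0.001, 0.5),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_coding_pure_function_of_sign_p_alpha(self, slope, p, alpha):
        state = code_character(self._norm(slope), self._res(p), alpha)
        if p >= alpha:
            assert state == NO_PLASTICITY
        else:
            assert state == (POSITIVE if slope > 0 else NEGATIVE)
        # binary collapse round-trips through the documented mapping
        b = code_character(
            self._norm(slope), self._res(p), alpha, scheme="binary"
        )
        assert b == int(state != NO_PLASTICITY)

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            code_character(self._norm(0.1), self._res(0.5), alpha=1.5)


class TestPower:
    def test_power_monotone_in_effect_size(self):
        effects = [0.0, 0.02, 0.05, 0.1]
        reps = 60
        power = []
        for e in effects:
            hits = 0
            for i in range(reps):
                df = simulate_specimens(
                    SimulationConfig(seed=1000 + i, n_species=1,
                                     n_per_group=10, temp_effect=e)
                )
                hits += fit_ancova(df, "sp01").p_value < 0.05
            power.append(hits / reps)
        assert all(b >= a for a, b in zip(power, power[1:]))
        assert power[-1] > 0.9

    def test_strong_effect_codes_positive(self):
        df = simulate_specimens(
            SimulationConfig(seed=3, n_species=1, n_per_group=20,
                             temp_effect=0.2, residual_sd=0.01)
        )
        res = fit_ancova(df, "sp01")
        norm = reaction_norm(df, "sp01")
        assert code_character(norm, res) == POSITIVE


def test_species_summary_table(fixture_data):
    cfg = SimulationConfig(
        seed=11, n_species=3, temp_effect=[0.1, -0.1, 0.0], residual_sd=0.02
    )
    df = simulate_specimens(cfg)
    tab = species_summary(df)
    assert list(tab["state"]) == [POSITIVE, NEGATIVE, NO_PLASTICITY]
    assert np.sign(tab["slope"]).tolist() == [1.0, -1.0, np.sign(tab["slope"][2])]


def test_fixture_coding_matches_reported_pattern(fixture_data):
    """Among reared species exactly one is positive and five non-plastic."""
    fx = fixture_data
    states = fx.characters.loc[fx.reared_species, "size_plasticity"].astype(int)
    assert (states == POSITIVE).sum() == 1
    assert states.idxmax() == "Bicyclus_anynana"
    assert (states == NO_PLASTICITY).sum() == 5
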