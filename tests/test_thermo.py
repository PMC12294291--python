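"""Hyperchromicity fits: slope/intercept oracle, published-table checks, units."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copigmentation.thermo import (
    REFERENCE_LADDER,
    FitSettings,
    ThermoFitResult,
    TitrationSeries,
    build_thermo_table,
    fit_copigmentation,
    gibbs_free_energy,
    hyperchromic_shift,
    rank_copigments,
    reference_series,
)


def ols_oracle(x, y):
    """Independent two-moment least-squares formulas (Sxy/Sxx, ybar - m xbar)."""
    x, y = np.asarray(x), np.asarray(y)
    sxx = np.mean(x * x) - np.mean(x) ** 2
    sxy = np.mean(x * y) - np.mean(x) * np.mean(y)
    slope = sxy / sxx
    return slope, np.mean(y) - slope * np.mean(x)


def series_from_shifts(shifts, conc=REFERENCE_LADDER, **kw):
    return TitrationSeries.from_shifts(shifts, conc, **kw)


class TestHyperchromicShift:
    def test_identity_and_arithmetic(self):
        assert hyperchromic_shift(0.40, 0.40) == 0.0
        assert hyperchromic_shift(0.4974, 0.400) == pytest.approx(0.2435)

    def test_negative_reference_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            hyperchromic_shift(0.5, 0.0)

    def test_hypochromic_allowed(self):
        assert hyperchromic_shift(0.3, 0.4) < 0


class TestFitCopigmentation:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_independent_ols_oracle(self, seed):
        r = np.random.default_rng(seed)
        conc = np.sort(r.uniform(1e-5, 1e-2, size=5))
        while np.any(np.diff(conc) == 0):
            conc = np.sort(r.uniform(1e-5, 1e-2, size=5))
        shifts = r.uniform(0.01, 0.5, size=5)
        fit = fit_copigmentation(series_from_shifts(shifts, conc))
        slope, intercept = ols_oracle(np.log(conc), np.log(shifts))
        assert fit.n == pytest.approx(slope, abs=1e-10)
        assert fit.lnKeq == pytest.approx(intercept, abs=1e-10)

    def test_published_ca_ph36_stoichiometry(self):
        fit = fit_copigmentation(
            series_from_shifts([0.0435, 0.1304, 0.2043, 0.2826], copigment="CA", pH=3.6)
        )
        assert round(fit.n, 2) == 0.64

    def test_published_caf_ph28_r2(self):
        fit = fit_copigmentation(
            series_from_shifts([0.0097, 0.0326, 0.0568, 0.0906], copigment="CAF", pH=2.8)
        )
        assert round(fit.r2, 3) == 0.999

    def test_noiseless_isotherm_recovered_exactly(self):
        conc = np.array(REFERENCE_LADDER)
        A0 = 0.4
        obs = tuple((c, A0 * (1 + 50.0 * c)) for c in conc)
        fit = fit_copigmentation(TitrationSeries(A0=A0, observations=obs))
        assert fit.n == pytest.approx(1.0, rel=1e-6)
        assert fit.Keq == pytest.approx(50.0, rel=1e-6)

    def test_keq_invariant_to_ladder_choice_noiseless(self):
        A0, Keq = 0.4, 50.0
        fits = []
        for conc in ([1e-5, 1e-4, 1e-3], [5e-5, 2e-4, 8e-4, 2e-3]):
            obs = tuple((c, A0 * (1 + Keq * c)) for c in conc)
            fits.append(fit_copigmentation(TitrationSeries(A0=A0, observations=obs)))
        assert fits[0].Keq == pytest.approx(fits[1].Keq, rel=1e-9)

    def test_concentration_rescale_shifts_intercept_only(self):
        shifts = [0.02, 0.07, 0.13, 0.24]
        base = fit_copigmentation(series_from_shifts(shifts))
        scaled = fit_copigmentation(
            series_from_shifts(shifts, conc=[2 * c for c in REFERENCE_LADDER])
        )
        assert scaled.n == pytest.approx(base.n, abs=1e-12)
        assert scaled.r2 == pytest.approx(base.r2, abs=1e-12)
        assert scaled.lnKeq == pytest.approx(
            base.lnKeq - base.n * math.log(2), abs=1e-10
        )

    def test_hypochromic_points_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_copigmentation(
                series_from_shifts([-0.01, 0.07, 0.13, 0.24])
            )
        assert fit.points_used == 3
        assert any("non-positive" in f for f in fit.flags)

    def test_too_few_positive_shifts(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match=">= 3 positive"):
                fit_copigmentation(series_from_shifts([-0.01, -0.02, 0.13, 0.24]))

    def test_stoichiometry_flag(self):
        # shifts rising ~ [Cp]^0.2: slope far below the 0.5-2 window
        conc = np.array(REFERENCE_LADDER)
        shifts = 0.5 * (conc / conc[0]) ** 0.2
        fit = fit_copigmentation(series_from_shifts(shifts))
        assert any("outside" in f for f in fit.flags)

    def test_series_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TitrationSeries(A0=0.4, observations=((1e-3, 0.5), (1e-4, 0.45)))
        with pytest.raises(ValueError, match="positive"):
            TitrationSeries(A0=-0.1, observations=((1e-4, 0.45),))


class TestGibbsFreeEnergy:
    def test_unit_equilibrium_is_zero(self):
        assert gibbs_free_energy(0.0) == 0.0

    def test_si_ph36_intercept(self):
        assert gibbs_free_energy(3.859455) == pytest.approx(-9.56, abs=5e-3)

    def test_keq_65(self):
        assert gibbs_free_energy(math.log(65.0)) == pytest.approx(-10.34, abs=5e-3)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(-20, 20))
    def test_roundtrip_identity(self, x):
        s = FitSettings()
        expected = -s.R * s.T * x / 1000.0
        assert gibbs_free_energy(math.log(math.exp(x))) == pytest.approx(
            expected, abs=1e-12 + 1e-12 * abs(expected)
        )

    def test_sign_iff_keq_above_unity(self):
        for keq in (0.1, 0.99, 1.0, 1.01, 65.0):
            dg = gibbs_free_energy(math.log(keq))
            assert (dg < 0) == (keq > 1)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            gibbs_free_energy(float("nan"))


class TestThermoTable:
    def test_reference_table_all_spontaneous(self):
        table = build_thermo_table(reference_series())
        assert len(table) == 12
        assert (table["dG0_kJ_mol"] < 0).all()
        assert (table["Keq"] > 1).all()

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            table = build_thermo_table([])
        assert table.empty

    def test_failed_fit_becomes_flagged_row(self):
        bad = series_from_shifts([-0.01, -0.02, 0.13, 0.24])
        good = series_from_shifts([0.02, 0.07, 0.13, 0.24])
        with pytest.warns(UserWarning):
            table = build_thermo_table([bad, good])
        assert len(table) == 2
        assert table["flags"].str.contains("fit failed").sum() == 1
        assert np.isnan(table.loc[0, "Keq"])


class TestRankCopigments:
    def fit_with_keq(self, keq, copigment, pH=3.6):
        return ThermoFitResult(
            n=1.0, lnKeq=math.log(keq), Keq=keq,
            delta_G0=gibbs_free_energy(math.log(keq)), r2=1.0, rmse=0.0,
            residuals=(), points_used=4, copigment=copigment, pH=pH,
        )

    def test_published_ranking(self):
        fits = [self.fit_with_keq(k, c) for c, k in
                [("CAF", 65.0), ("SI", 48.5), ("CA", 26.6)]]
        ranked = rank_copigments(fits)
        assert [(r, f.copigment) for r, f in ranked] == [
            (1, "CAF"), (2, "SI"), (3, "CA")]

    def test_near_tie_shares_rank(self):
        ranked = rank_copigments(
            [self.fit_with_keq(30.5, "A"), self.fit_with_keq(30.0, "B")]
        )
        assert [r for r, _ in ranked] == [1, 1]

    def test_singleton_and_mixed_ph(self):
        single = rank_copigments([self.fit_with_keq(10.0, "A")])
        assert len(single) == 1
        with pytest.raises(ValueError, match="multiple pH"):
            rank_copigments(
                [self.fit_with_keq(10, "A", 2.8), self.fit_with_keq(20, "B", 3.6)]
            )
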