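"""Single-site isotherm simulation, fitting, and derived thermodynamics."""

import numpy as np
import pytest

from helixread.itc import (
    DEFAULT_SCHEDULE_UL, Titration, derive_thermo, fit_single_site, fold_change,
    load_thermo_table, simulate_titration, subtract_blank, validate_table,
    _running_concentrations,
)


def bisection_oracle(kd_uM, n_sites, dh_kcal, cell_uM, syringe_uM,
                     volumes_ul, cell_ul=200.0):
    """Independent heats: solve the binding polynomial by bisection per step."""
    kd = kd_uM * 1e-6
    volumes = np.asarray(volumes_ul, dtype=float)
    _, m, x = _running_concentrations(cell_ul, cell_uM, syringe_uM, volumes)
    q = np.empty_like(volumes)
    for k in range(len(volumes)):
        sites = n_sites * m[k]

        def f(b):
            return (x[k] - b) * (sites - b) - kd * b

        lo, hi = 0.0, min(sites, x[k])
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
        q[k] = n_sites * ((lo + hi) / 2 / sites) * m[k] * dh_kcal * cell_ul * 1e-6 * 1e9
    qp = np.concatenate([[0.0], q[:-1]])
    return q - qp + (volumes / cell_ul) * (q + qp) / 2


class TestSimulate:
    def test_zero_enthalpy_zero_heats(self):
        t = simulate_titration(51, 1.35, 0.0, 100, 1500)
        assert np.allclose(t.heats_ucal, 0.0)

    def test_matches_bisection_oracle(self):
        t = simulate_titration(51, 1.35, -5.8, 100, 1500)
        ref = bisection_oracle(51, 1.35, -5.8, 100, 1500, DEFAULT_SCHEDULE_UL)
        assert np.allclose(t.heats_ucal, ref, rtol=1e-9)

    def test_stoichiometric_limit(self):
        # K_D -> 0: every early injection binds completely, so its heat is
        # dH x moles injected; past the equivalence point heats vanish.
        t = simulate_titration(1e-6, 1.0, -5.8, 100, 1500)
        moles_inj = 2e-6 * 1500e-6  # 2 ul of 1500 uM, in mol
        expected = -5.8 * moles_inj * 1e9  # ucal
        assert t.heats_ucal[1] == pytest.approx(expected, rel=1e-2)
        assert abs(t.heats_ucal[-1]) < abs(expected) * 1e-3

    def test_heat_conservation_at_saturation(self):
        # cumulative heat approaches N * M0 * V0 * dH as ligand -> infinity
        # (tight binding so every site is filled before it can be displaced)
        kd, n, dh, m0 = 0.1, 1.35, -5.8, 100.0
        t = simulate_titration(kd, n, dh, m0, 50 * 1500.0)
        total_expected = n * m0 * 1e-6 * dh * 200e-6 * 1e9
        assert t.heats_ucal.sum() == pytest.approx(total_expected, rel=5e-3)

    def test_monotone_after_equivalence(self):
        t = simulate_titration(10, 1.0, -5.8, 100, 1500)
        ratios = t.molar_ratios()
        post = np.abs(t.heats_ucal[1:])[ratios[1:] > 1.0]
        assert np.all(np.diff(post) <= 1e-9)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            simulate_titration(0.0, 1.0, -5.8, 100, 1500)


class TestSubtractBlank:
    def _tit(self, heats):
        return Titration(298.15, 200, 100, 1500,
                         np.asarray(DEFAULT_SCHEDULE_UL), np.asarray(heats))

    def test_zero_blank_identity(self):
        s = simulate_titration(51, 1.0, -5.8, 100, 1500)
        out = subtract_blank(s, self._tit(np.zeros(20)))
        assert np.allclose(out.heats_ucal, s.heats_ucal)
        assert out.meta["blank_subtracted"]

    def test_constant_blank_shifts(self):
        s = self._tit(np.ones(20) * 3.0)
        out = subtract_blank(s, self._tit(np.ones(20) * 0.5))
        assert np.allclose(out.heats_ucal, 2.5)

    def test_schedule_mismatch_rejected(self):
        s = simulate_titration(51, 1.0, -5.8, 100, 1500)
        blank = Titration(298.15, 200, 100, 1500, np.ones(5), np.zeros(5))
        with pytest.raises(ValueError):
            subtract_blank(s, blank)


class TestFit:
    def test_noiseless_round_trip(self):
        t = simulate_titration(51, 1.35, -5.8, 100, 1500)
        fit = fit_single_site(t)
        assert fit.kd_uM == pytest.approx(51, rel=1e-3)
        assert fit.n == pytest.approx(1.35, rel=1e-3)
        assert fit.dh_kcal == pytest.approx(-5.8, rel=1e-3)
        assert fit.converged and not fit.low_c_warning

    def test_fix_n_semantics(self):
        t = simulate_titration(51, 1.0, -5.8, 100, 1500)
        fit = fit_single_site(t, fix_n=1.0)
        assert fit.n == 1.0 and fit.n_err == 0.0 and fit.n_fixed
        assert fit.kd_uM == pytest.approx(51, rel=1e-3)

    def test_weak_binder_reported_as_bound(self):
        t = simulate_titration(5000, 1.0, -5.8, 100, 1500)
        fit = fit_single_site(t, fix_n=1.0)
        assert fit.low_c_warning
        assert fit.kd_is_bound
        assert fit.kd_display().startswith(">")

    def test_all_zero_heats_rejected(self):
        t = simulate_titration(51, 1.0, 0.0, 100, 1500)
        with pytest.raises(ValueError):
            fit_single_site(t)

    def test_csv_round_trip(self, tmp_path):
        t = simulate_titration(51, 1.35, -5.8, 100, 1500)
        path = tmp_path / "t.csv"
        t.to_csv(path)
        back = Titration.from_csv(path)
        assert np.allclose(back.heats_ucal, t.heats_ucal)
        assert back.cell_uM == t.cell_uM


class TestDeriveThermo:
    def test_h3_10mer_row(self):
        row = derive_thermo(51, 2, -5.8, 0.1, 298.15)
        r = row.rounded()
        assert r["dG"] == -5.86 and r["dG_err"] == 0.02
        assert r["TdS"] == 0.1 and r["TdS_err"] == 0.1

    def test_gg_mutant_row(self):
        row = derive_thermo(143, 7, -7.4, 0.3, 298.15)
        assert row.rounded()["dG"] == -5.25
        assert row.rounded()["TdS"] == -2.2

    def test_molar_kd_gives_zero_dg(self):
        row = derive_thermo(1e6, 0, -5.0, 0.0)  # K_D = 1 M
        assert row.dg_kcal == pytest.approx(0.0, abs=1e-12)
        assert row.tds_kcal == pytest.approx(-5.0)

    def test_identity_dg_dh_tds_exact(self):
        row = derive_thermo(37.2, 1.1, -6.43, 0.21)
        assert row.dg_kcal == pytest.approx(row.dh_kcal - row.tds_kcal, abs=1e-12)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            derive_thermo(0, 0, -5, 0)


class TestFoldChange:
    def test_examples(self):
        assert fold_change(51, 210).one_decimal == 4.1
        assert fold_change(51, 210).nearest_int == 4
        assert fold_change(48, 810).one_decimal == 16.9
        assert fold_change(48, 810).nearest_int == 17
        assert fold_change(48, 48).ratio == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0, 48)


class TestValidateTable:
    @pytest.mark.parametrize("which,n_rows,n_skip", [
        ("wt_peptides", 16, 4), ("wall_mutants", 6, 1),
    ])
    def test_packaged_tables_consistent(self, which, n_rows, n_skip):
        v = validate_table(which)
        assert v.n_checked == n_rows and v.n_skipped == n_skip
        assert v.all_consistent
        assert v.max_dg_dev <= 0.03 and v.max_tds_dev <= 0.1

    def test_corrupted_row_flagged(self):
        df = load_thermo_table("wt_peptides").copy()
        df.loc[0, "dg_kcal"] = "-6.46"  # 1 kcal/mol off
        v = validate_table(df)
        assert not v.all_consistent
        bad = v.report[v.report["ok"] == False]  # noqa: E712
        assert len(bad) == 1 and "ARTK" in bad.iloc[0]["row"]

    def test_bound_rows_skipped_with_note(self):
        v = validate_table("wall_mutants")
        skipped = v.report[~v.report["checked"].astype(bool)]
        assert len(skipped) == 1
        assert "skipped" in skipped.iloc[0]["note"]

    def test_malformed_row_named(self):
        df = load_thermo_table("wt_peptides").copy()
        df.loc[2, "kd_uM"] = "-5"
        with pytest.raises(ValueError, match="ARTKQ"):
            validate_table(df)
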