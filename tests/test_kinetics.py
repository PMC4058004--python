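"""Core engine properties: closed-form oracles, linearity, CYP2D6 scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tamoxsim import (
    ANALYTES,
    SubjectParameters,
    build_system,
    combine,
    once_daily,
    phenotype_activity,
    simulate,
    trough_css,
)
from tamoxsim.kinetics import effective_rate, periodic_trough
from tamoxsim.network import PhenotypeActivity
from tamoxsim.regimen import Regimen


@pytest.fixture(scope="module")
def em_system(template):
    return build_system(template, phenotype_activity("EM"))


class TestEdgeScaling:
    def test_em_typical_is_identity(self):
        assert effective_rate(0.2, 0.95, 1.0, 1.0) == pytest.approx(0.2)

    def test_pm_keeps_non_cyp2d6_residual(self):
        # endoxifen formation persists in PMs through the residual pathway
        assert effective_rate(0.2, 0.95, 0.0) == pytest.approx(0.2 * 0.05)

    def test_im_interpolates_linearly(self):
        lo = effective_rate(0.2, 0.95, 0.0)
        hi = effective_rate(0.2, 0.95, 1.0)
        assert effective_rate(0.2, 0.95, 0.5) == pytest.approx((lo + hi) / 2)

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            effective_rate(0.2, 0.95, -0.1)


class TestSimulate:
    def test_zero_dose_gives_zero_series(self, em_system):
        df = simulate(em_system, once_daily("TAM", 0.0, 10), 10)
        assert (df[list(ANALYTES)].to_numpy() == 0).all()

    def test_single_dose_matches_bateman_closed_form(self, template):
        """One-compartment sub-system (formation shut off) must match the
        absorption/elimination closed form to < 1e-6 relative."""
        net = (template.with_edge_rate("TAM", "NDM", 0.0)
               .with_edge_rate("TAM", "4OH", 0.0))
        ka = net.absorption["TAM"].ka
        ke = net.edge("TAM", "sink").rate
        F, V = net.absorption["TAM"].bioavailability, net.volumes["TAM"]
        system = build_system(net, phenotype_activity("EM"))
        df = simulate(system, once_daily("TAM", 20.0, 1), horizon_days=7,
                      output_grid_h=0.5)
        t = df.time_h.to_numpy()
        expected = (20.0 * F * ka / (V * (ka - ke))
                    * (np.exp(-ke * t) - np.exp(-ka * t)) * 1000.0)
        mask = expected > expected.max() * 1e-6
        np.testing.assert_allclose(df.TAM.to_numpy()[mask], expected[mask],
                                   rtol=1e-6)

    def test_dose_doubling_doubles_every_concentration(self, em_system):
        d20 = simulate(em_system, once_daily("TAM", 20.0, 30), 30, 6.0)
        d40 = simulate(em_system, once_daily("TAM", 40.0, 30), 30, 6.0)
        np.testing.assert_allclose(d40[list(ANALYTES)].to_numpy(),
                                   2.0 * d20[list(ANALYTES)].to_numpy(),
                                   rtol=1e-12, atol=1e-12)

    def test_ode_integrator_agrees_with_exact_stepping(self, em_system):
        expm = simulate(em_system, once_daily("TAM", 20.0, 20), 20, 12.0)
        ivp = simulate(em_system, once_daily("TAM", 20.0, 20), 20, 12.0,
                       method="ivp")
        for a in ANALYTES:
            x, y = expm[a].to_numpy(), ivp[a].to_numpy()
            m = x > x.max() * 1e-3
            np.testing.assert_allclose(y[m], x[m], rtol=1e-6)


class TestTroughs:
    def test_zero_dose_trough_is_zero(self, em_system):
        tr = trough_css(em_system, once_daily("TAM", 0.0, 150), 120)
        assert all(v == 0.0 for v in tr.values())

    def test_steady_state_attained_by_day_120(self, em_system):
        """Successive daily troughs at steady state differ by < 0.5%."""
        t119 = trough_css(em_system, once_daily("TAM", 20.0, 150), 119)
        t120 = trough_css(em_system, once_daily("TAM", 20.0, 150), 120)
        for a in ANALYTES:
            assert t120[a] == pytest.approx(t119[a], rel=5e-3)

    def test_day_outside_blocks_rejected(self, em_system):
        with pytest.raises(ValueError, match="outside"):
            trough_css(em_system, once_daily("TAM", 20.0, 30), 45)

    def test_matrix_exponential_periodic_steady_state_oracle(self, em_system):
        """Day-360 stepping vs the closed-form periodic steady state of the
        full cascade: < 0.1% at the trough time."""
        stepped = trough_css(em_system, once_daily("TAM", 20.0, 360), 360)
        closed = periodic_trough(em_system, {"TAM": 20.0}, 24.0)
        for a in ANALYTES:
            assert stepped[a] == pytest.approx(closed[a], rel=1e-3)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(dose=st.floats(1.0, 100.0))
    def test_trough_homogeneous_of_degree_one_in_dose(self, template, dose):
        system = build_system(template, phenotype_activity("EM"))
        ref = trough_css(system, once_daily("TAM", 20.0, 120), 120)
        scaled = trough_css(system, once_daily("TAM", dose, 120), 120)
        for a in ANALYTES:
            assert scaled[a] == pytest.approx(ref[a] * dose / 20.0, rel=1e-9)

    def test_superposition_of_concurrent_compounds(self, em_system):
        """TAM + END co-administration equals the sum of the single-compound
        troughs (linear system; 1e-8 relative)."""
        tam = trough_css(em_system, once_daily("TAM", 20.0, 120), 120)
        end = trough_css(em_system, once_daily("END", 3.0, 120), 120)
        both = trough_css(
            em_system,
            combine(once_daily("TAM", 20.0, 120), once_daily("END", 3.0, 120)),
            120)
        for a in ANALYTES:
            assert both[a] == pytest.approx(tam[a] + end[a], rel=1e-8, abs=1e-12)


class TestCyp2d6Monotonicity:
    def test_end_increases_tam_ndm_decrease_with_activity(self, template):
        regimen = once_daily("TAM", 20.0, 240)
        activities = [
            PhenotypeActivity("PM", 0.0),
            PhenotypeActivity("IM", 0.25),
            PhenotypeActivity("IM", 0.5),
            PhenotypeActivity("IM", 0.75),
            PhenotypeActivity("EM", 1.0),
        ]
        troughs = [
            trough_css(build_system(template, p), regimen, 240)
            for p in activities
        ]
        ends = [t["END"] for t in troughs]
        assert ends == sorted(ends)
        for a in ("TAM", "NDM"):
            vals = [t[a] for t in troughs]
            assert vals == sorted(vals, reverse=True)

    def test_pm_endoxifen_stays_positive(self, template):
        system = build_system(template, phenotype_activity("PM"))
        tr = trough_css(system, once_daily("TAM", 20.0, 240), 240)
        assert tr["END"] > 0.0


def test_series_csv_export(tmp_path, em_system):
    import pandas as pd
    from tamoxsim.kinetics import export_series_csv
    df = simulate(em_system, once_daily("TAM", 20.0, 2), 2, 12.0)
    out = tmp_path / "series.csv"
    export_series_csv(df, subject_id=7, path=out)
    tidy = pd.read_csv(out)
    assert list(tidy.columns) == ["subject_id", "analyte", "time_h", "conc_ugL"]
    assert set(tidy.analyte) == set(ANALYTES)
    assert (tidy.subject_id == 7).all()


def test_eta_abs_scales_all_troughs_exactly(template):
    phen = phenotype_activity("EM")
    base = trough_css(build_system(template, phen),
                      once_daily("TAM", 20.0, 120), 120)
    subject = SubjectParameters(1, eta_abs=1.7, eta_2d6=1.0)
    scaled = trough_css(build_system(template, phen, subject),
                        once_daily("TAM", 20.0, 120), 120)
    for a in ANALYTES:
        assert scaled[a] == pytest.approx(1.7 * base[a], rel=1e-12)
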