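"""JIP-test engine: cardinal extraction, derived parameters, connectivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phycotox.ojip import (
    FluorescenceTransient,
    OjipConfig,
    compute_jip,
    estimate_grouping,
    extract_cardinal_points,
)
from phycotox.synthetic import SimulationConfig, connectivity_transient, generate_ojip

from conftest import piecewise_transient, random_cardinal_values


def plateau_transient(f0=500.0, fm=2500.0):
    """Flat at f0 through the O step, monotone rise to a plateau at fm."""
    t = np.unique(np.concatenate([np.geomspace(10, 300000, 60),
                                  [50.0, 300.0, 2000.0, 30000.0]]))
    rise = 1.0 - np.exp(-np.maximum(t - 50.0, 0.0) / 2000.0)
    return FluorescenceTransient("p", "0", t, f0 + (fm - f0) * rise)


class TestCardinalExtraction:
    def test_plateau_curve_recovers_f0_fm_fv(self):
        pts = extract_cardinal_points(plateau_transient())
        assert pts.F0 == pytest.approx(500.0)
        assert pts.FM == pytest.approx(2500.0, rel=1e-3)
        assert pts.FV == pytest.approx(pts.FM - 500.0)

    def test_exact_sampling_at_step_times_needs_no_interpolation(self):
        tr = piecewise_transient(500, 740, 1500, 2100, 2500)
        pts = extract_cardinal_points(tr)
        assert (pts.F0, pts.F300, pts.FJ, pts.FI, pts.FM) == (500, 740, 1500, 2100, 2500)

    def test_generator_round_trip_within_interpolation_tolerance(self, noiseless_ojip_config):
        transients, truth = generate_ojip(noiseless_ojip_config)
        for tr, (_, row) in zip(transients[:12], truth.iterrows()):
            pts = extract_cardinal_points(tr)
            assert pts.F0 == pytest.approx(row["F0"], rel=5e-3)
            assert pts.FM == pytest.approx(row["FM_protocol"], rel=5e-3)

    def test_uncovered_step_raises_naming_the_step(self):
        t = np.linspace(100, 400000, 50)
        tr = FluorescenceTransient("x", "0", t, np.linspace(500, 2500, 50))
        with pytest.raises(ValueError, match="O step"):
            extract_cardinal_points(tr)

    def test_no_variable_fluorescence_raises(self):
        t = np.unique(np.concatenate([np.geomspace(10, 300000, 50),
                                      [50.0, 300.0, 2000.0, 30000.0]]))
        tr = FluorescenceTransient("x", "0", t, np.full(t.size, 500.0))
        with pytest.raises(ValueError, match="no variable fluorescence"):
            extract_cardinal_points(tr)


class TestJipDerivation:
    def test_worked_arithmetic_example(self):
        """F0=500, F300=740, FJ=1500, FI=2100, FM=2500 by hand."""
        tr = piecewise_transient(500, 740, 1500, 2100, 2500)
        pts = extract_cardinal_points(tr)
        r = compute_jip(pts, tr)
        assert r.VJ == pytest.approx(0.5)
        assert r.VI == pytest.approx(0.8)
        assert r.M0 == pytest.approx(0.48)
        assert r.phiP0 == pytest.approx(0.8)
        assert r.psi0 == pytest.approx(0.5)
        assert r.trDi == pytest.approx(4.0)
        assert r.psiRatio == pytest.approx(1.0)
        assert r.deltaRatio == pytest.approx(0.2 / 0.3)
        assert r.re0RC == pytest.approx(0.48 * 2.0 * 0.2)

    def test_oec_fraction_is_one_for_reference_identical_to_sample(self):
        tr = piecewise_transient(500, 740, 1500, 2100, 2500)
        pts = extract_cardinal_points(tr)
        r = compute_jip(pts, tr, reference=pts)
        assert r.oecFraction == pytest.approx(1.0)

    def test_cross_section_switch_propagates_to_all_per_cs_fluxes(self):
        tr = piecewise_transient(500, 740, 1500, 2100, 2500)
        pts = extract_cardinal_points(tr)
        r0 = compute_jip(pts, tr, config=OjipConfig(cross_section="F0"))
        rm = compute_jip(pts, tr, config=OjipConfig(cross_section="FM"))
        assert r0.absCS == pytest.approx(pts.F0)
        assert rm.absCS == pytest.approx(pts.FM)
        for f in ("trCS", "etCS", "diCS", "rcCS"):
            assert getattr(rm, f) == pytest.approx(
                getattr(r0, f) * pts.FM / pts.F0)

    def test_degenerate_vj_yields_nan_not_infinity(self):
        # FJ == FM makes VJ = 1: psiRatio denominator fine but deltaRatio
        # and deltaR0-family degenerate (VI == VJ)
        tr = piecewise_transient(500, 740, 2500, 2500, 2500.0001)
        pts = extract_cardinal_points(tr)
        with pytest.warns(UserWarning):
            r = compute_jip(pts, tr, with_grouping=False)
        assert np.isnan(r.deltaRatio)
        assert np.isfinite(r.VJ)

    def test_mean_recovered_phi_p0_close_to_generator_target(self):
        cfg = SimulationConfig(seed=5)
        cfg.ojip.phi_p0 = 0.75
        cfg.ojip.phi_p0_effect = {t: 1.0 for t in cfg.treatments}
        transients, _ = generate_ojip(cfg)
        controls = [t for t in transients]
        vals = []
        for tr in controls[:50]:
            pts = extract_cardinal_points(tr)
            vals.append(compute_jip(pts, tr, with_grouping=False).phiP0)
        assert np.mean(vals) == pytest.approx(0.75, rel=0.02)


class TestAlgebraicInvariants:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_identities_hold_on_random_cardinal_sets(self, seed):
        rng = np.random.default_rng(seed)
        f0, f300, fj, fi, fm = random_cardinal_values(rng)
        tr = piecewise_transient(f0, f300, fj, fi, fm)
        pts = extract_cardinal_points(tr)
        r = compute_jip(pts, tr, with_grouping=False)
        assert r.diCS == pytest.approx(r.absCS - r.trCS, abs=1e-12 * r.absCS)
        assert r.N * r.SS == pytest.approx(r.SM, rel=1e-10)
        assert r.gammaRC / (1 - r.gammaRC) == pytest.approx(r.rcABS, rel=1e-10)
        assert r.trDi * (1 - r.phiP0) == pytest.approx(r.phiP0, rel=1e-10)

    def test_increasing_fj_decreases_psi0_and_etcs(self):
        lo = piecewise_transient(500, 740, 1400, 2100, 2500)
        hi = piecewise_transient(500, 740, 1800, 2100, 2500)
        r_lo = compute_jip(extract_cardinal_points(lo), lo, with_grouping=False)
        r_hi = compute_jip(extract_cardinal_points(hi), hi, with_grouping=False)
        assert r_hi.psi0 < r_lo.psi0
        assert r_hi.etCS < r_lo.etCS

    def test_trapezoid_area_matches_dense_integration_of_closed_form(self):
        cfg = SimulationConfig(seed=3)
        for f in ("cv_amplitude", "cv_phi_p0", "cv_vj", "cv_point"):
            setattr(cfg.ojip, f, 0.0)
        cfg.ojip.n_points = 200
        cfg.n_ojip = 2
        transients, truth = generate_ojip(cfg)
        for tr, (_, row) in zip(transients, truth.iterrows()):
            pts = extract_cardinal_points(tr)
            r = compute_jip(pts, tr, with_grouping=False)
            assert r.SM == pytest.approx(row["SM"], rel=0.01)

    def test_imposed_trapping_ordering_recovered_in_mean_trcs(self):
        """Clearly separated trapping-efficiency multipliers must reproduce
        their rank order in per-treatment mean TR/CS (>= 95% over seeds)."""
        matches = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, n_ojip=18)
            cfg.ojip.phi_p0_effect = {"0": 1.0, "10": 0.95, "50": 0.90,
                                      "100": 0.85, "250": 0.75, "500": 0.80}
            cfg.ojip.amplitude_effect = {t: 1.0 for t in cfg.treatments}
            transients, _ = generate_ojip(cfg)
            means = {}
            for trt in cfg.treatments:
                vals = []
                for tr in transients:
                    if tr.treatment != trt:
                        continue
                    pts = extract_cardinal_points(tr)
                    vals.append(compute_jip(pts, tr, with_grouping=False).trCS)
                means[trt] = np.mean(vals)
            imposed = sorted(cfg.treatments,
                             key=lambda t: -cfg.ojip.phi_p0_effect[t])
            observed = sorted(cfg.treatments, key=lambda t: -means[t])
            matches += imposed == observed
        assert matches / n_seeds >= 0.95


class TestGrouping:
    def test_exponential_rise_gives_zero_connectivity(self):
        tr = connectivity_transient(0.0)
        pg = estimate_grouping(tr, extract_cardinal_points(tr))
        assert pg == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize("C", [0.25, 1.0])
    def test_hyperbolic_rise_recovers_connectivity(self, C):
        tr = connectivity_transient(C)
        pg = estimate_grouping(tr, extract_cardinal_points(tr))
        assert pg == pytest.approx(C / (1 + C), abs=0.01)

    def test_full_transient_connectivity_nearly_unbiased(self, noiseless_ojip_config):
        """On complete transients the slower I/P phases overlap the O-J window;
        the drift nuisance term must keep the p_G bias small."""
        transients, truth = generate_ojip(noiseless_ojip_config)
        errs = []
        for tr, (_, row) in list(zip(transients, truth.iterrows()))[:12]:
            pg = estimate_grouping(tr, extract_cardinal_points(tr))
            errs.append(abs(pg - row["pG"]))
        assert max(errs) < 0.05

    def test_too_few_oj_points_raises(self):
        t = np.unique(np.concatenate([
            [10.0, 50.0, 300.0, 2000.0], np.geomspace(3000, 300000, 40)]))
        f = 500 + 2000 * (1 - np.exp(-np.maximum(t - 50, 0) / 300.0))
        tr = FluorescenceTransient("x", "0", t, f)
        with pytest.raises(ValueError, match="at least 5"):
            estimate_grouping(tr, extract_cardinal_points(tr))
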