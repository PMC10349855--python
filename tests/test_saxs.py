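"""Debye curves, Guinier analysis, p(r) and chi-square fitting."""

import math

import numpy as np
import pytest

from prelink.exceptions import EmptyInputError, GuinierError
from prelink.saxs import (
    PairDistribution,
    ScatteringCurve,
    debye_curve,
    fit_chi2,
    guinier_rg,
    pofr_from_curve,
    pofr_from_model,
    read_curve,
    write_curve,
)

Q = np.linspace(0.005, 0.35, 150)


def sphere_beads(radius, n=600, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-1, 1, (4 * n, 3))
    pts = pts[np.linalg.norm(pts, axis=1) <= 1.0][:n] * radius
    return pts


class TestDebye:
    def test_single_bead_flat(self):
        curve = debye_curve(np.zeros((1, 3)), Q, weights=np.array([3.0]))
        np.testing.assert_allclose(curve.intensity, 9.0)

    def test_two_bead_closed_form(self):
        d = 20.0
        beads = np.array([[0, 0, 0], [d, 0, 0]])
        curve = debye_curve(beads, Q)
        x = Q * d
        expected = (1 + np.sin(x) / x) / 2
        np.testing.assert_allclose(curve.intensity / curve.intensity[0] *
                                   (1 + np.sin(Q[0] * d) / (Q[0] * d)) / 2,
                                   expected, rtol=1e-9)

    def test_i0_equals_total_weight_squared(self):
        beads = sphere_beads(15.0, n=100)
        w = np.linspace(1, 2, 100)
        curve = debye_curve(beads, np.array([0.0, 0.01]), weights=w)
        assert curve.intensity[0] == pytest.approx(np.sum(w) ** 2, rel=1e-12)

    def test_sphere_guinier_radius(self):
        """Uniform ball of radius R has Rg = sqrt(3/5) R."""
        R = 20.0
        curve = debye_curve(sphere_beads(R, n=800), np.linspace(0.004, 0.12, 80))
        rg, i0, _ = guinier_rg(ScatteringCurve(curve.q, curve.intensity, 0.001 * curve.intensity))
        assert rg == pytest.approx(math.sqrt(3.0 / 5.0) * R, rel=0.03)

    def test_empty_errors(self):
        with pytest.raises(EmptyInputError):
            debye_curve(np.zeros((0, 3)), Q)


class TestGuinier:
    def test_exact_recovery(self):
        rg_true, i0_true = 15.0, 100.0
        q = np.linspace(0.005, 0.2, 120)
        intensity = i0_true * np.exp(-(q**2) * rg_true**2 / 3)
        curve = ScatteringCurve(q, intensity, 0.01 * intensity)
        rg, i0, (lo, hi) = guinier_rg(curve)
        assert rg == pytest.approx(rg_true, abs=1e-6)
        assert i0 == pytest.approx(i0_true, rel=1e-6)
        assert q[hi] * rg < 1.3

    def test_noisy_mean_within_two_percent(self):
        rng = np.random.default_rng(21)
        rg_true = 15.0
        q = np.linspace(0.005, 0.2, 120)
        base = 100.0 * np.exp(-(q**2) * rg_true**2 / 3)
        estimates = []
        for _ in range(100):
            noisy = base * (1 + rng.normal(0, 0.01, len(q)))
            curve = ScatteringCurve(q, noisy, 0.01 * base)
            estimates.append(guinier_rg(curve)[0])
        assert np.mean(estimates) == pytest.approx(rg_true, rel=0.02)

    def test_no_valid_window_raises(self):
        # all points far beyond the Guinier regime of a large particle
        q = np.linspace(0.2, 0.5, 30)
        intensity = 100.0 * np.exp(-(q**2) * 80.0**2 / 3)
        curve = ScatteringCurve(q, intensity, 0.01 * intensity)
        with pytest.raises(GuinierError):
            guinier_rg(curve)


class TestPofrFromModel:
    def test_two_beads_single_bin(self):
        beads = np.array([[0, 0, 0], [10.0, 0, 0]])
        dist = pofr_from_model(beads, bin_width=0.5)
        assert dist.dmax == pytest.approx(10.0)
        occupied = dist.r[dist.p > 0]
        assert len(occupied) == 1
        assert occupied[0] == pytest.approx(10.0, abs=0.25)

    def test_rg_matches_coordinate_oracle(self):
        beads = sphere_beads(18.0, n=300, seed=3)
        dist = pofr_from_model(beads, bin_width=0.5)
        center = beads.mean(axis=0)
        rg_coord = math.sqrt(np.mean(np.sum((beads - center) ** 2, axis=1)))
        assert dist.rg == pytest.approx(rg_coord, rel=0.01)

    def test_similarity_scaling(self):
        beads = sphere_beads(10.0, n=200, seed=4)
        d1 = pofr_from_model(beads)
        d2 = pofr_from_model(beads * 2.0)
        assert d2.dmax == pytest.approx(2 * d1.dmax, rel=1e-9)
        assert d2.rg == pytest.approx(2 * d1.rg, rel=1e-9)


class TestPofrFromCurve:
    def _curve_from_pofr(self, r, p, q):
        intensity = np.array(
            [4 * math.pi * np.trapezoid(p * np.sinc(qi * r / math.pi), r) for qi in q]
        )
        return ScatteringCurve(q, intensity, 0.005 * np.abs(intensity) + 1e-9)

    def test_two_gaussian_mixture_recovery(self):
        r = np.linspace(0, 60, 400)
        p = np.exp(-((r - 18) ** 2) / 30) + 0.6 * np.exp(-((r - 35) ** 2) / 40)
        p[0] = 0.0
        curve = self._curve_from_pofr(r, p, np.linspace(0.008, 0.35, 160))
        dist, diag = pofr_from_curve(curve, dmax_trial=60.0, nbins=90)
        p_interp = np.interp(dist.r, r, p)
        corr = np.corrcoef(dist.p, p_interp)[0, 1]
        assert corr > 0.99

    def test_sphere_peak_position(self):
        R = 20.0
        beads = sphere_beads(R, n=800)
        model = debye_curve(beads, np.linspace(0.008, 0.35, 160))
        curve = ScatteringCurve(model.q, model.intensity, 0.01 * model.intensity)
        dist, diag = pofr_from_curve(curve, dmax_trial=2 * R, nbins=80)
        peak_r = dist.r[np.argmax(dist.p)]
        assert peak_r == pytest.approx(1.05 * R, rel=0.10)

    def test_grossly_small_dmax_flagged(self):
        R = 20.0
        beads = sphere_beads(R, n=600)
        model = debye_curve(beads, np.linspace(0.008, 0.35, 160))
        curve = ScatteringCurve(model.q, model.intensity, 0.005 * model.intensity)
        _, diag = pofr_from_curve(curve, dmax_trial=R / 2, nbins=40)
        assert diag["dmax_flagged_small"]


class TestChi2:
    def test_model_vs_itself_zero(self):
        model = ScatteringCurve(Q, 100 * np.exp(-(Q**2) * 75), None)
        experiment = ScatteringCurve(Q, model.intensity.copy(), 0.5 * np.ones_like(Q))
        chi2, c, b = fit_chi2(model, experiment)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance(self):
        model = ScatteringCurve(Q, 100 * np.exp(-(Q**2) * 75), None)
        experiment = ScatteringCurve(
            Q, 2.0 * model.intensity + 5.0, np.ones_like(Q)
        )
        chi2, c, b = fit_chi2(model, experiment)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert c == pytest.approx(2.0, rel=1e-9)
        assert b == pytest.approx(5.0, rel=1e-6)

    def test_unit_noise_gives_chi2_one(self):
        rng = np.random.default_rng(8)
        q = np.linspace(0.005, 0.3, 200)
        base = 1000 * np.exp(-(q**2) * 120)
        model = ScatteringCurve(q, base, None)
        experiment = ScatteringCurve(q, base + rng.normal(0, 1.0, len(q)), np.ones_like(q))
        chi2, _, _ = fit_chi2(model, experiment)
        assert chi2 == pytest.approx(1.0, abs=0.2)

    def test_too_little_overlap(self):
        model = ScatteringCurve(np.array([0.0, 0.01]), np.array([1.0, 0.9]), None)
        experiment = ScatteringCurve(np.array([0.5, 0.6]), np.array([1.0, 0.9]), None)
        with pytest.raises(EmptyInputError):
            fit_chi2(model, experiment)


class TestConsistency:
    def test_debye_matches_pofr_transform(self, bound_complex):
        """I(q) from the histogapplied p(r) agrees with the Debye sum within
        1% for q < 0.3 at 0.5 A bins."""
        conf, _, _ = bound_complex
        curve = debye_curve(conf, np.linspace(0.01, 0.29, 40))
        dist = pofr_from_model(conf, bin_width=0.5)
        from prelink.saxs import bead_model

        _, w = bead_model(conf)
        self_term = float(np.sum(w**2))
        # the histogram stores unordered pairs once -> factor 2 for the
        # Debye cross term
        recon = np.array(
            [
                self_term
                + 2.0 * np.sum(dist.p * 0.5 * np.sinc(qi * dist.r / math.pi))
                for qi in curve.q
            ]
        )
        np.testing.assert_allclose(recon, curve.intensity, rtol=0.01)

    def test_rg_triple_agreement(self, bound_complex):
        """Guinier Rg, p(r) Rg and coordinate Rg agree within 3%."""
        conf, _, _ = bound_complex
        from prelink.saxs import bead_model

        beads, w = bead_model(conf)
        center = np.average(beads, weights=w, axis=0)
        rg_coord = math.sqrt(
            np.average(np.sum((beads - center) ** 2, axis=1), weights=w)
        )
        dist = pofr_from_model(conf, bin_width=0.5)
        q = np.linspace(0.004, 0.08, 60)
        model = debye_curve(conf, q)
        curve = ScatteringCurve(q, model.intensity, 0.001 * model.intensity)
        # anisometric particle: use the tighter q*Rg < 1.0 Guinier window
        rg_guinier, _, _ = guinier_rg(curve, qrg_max=1.0)
        assert dist.rg == pytest.approx(rg_coord, rel=0.03)
        assert rg_guinier == pytest.approx(rg_coord, rel=0.03)


def test_curve_io_roundtrip(tmp_path):
    curve = ScatteringCurve(Q, 100 * np.exp(-(Q**2) * 75), 0.01 * np.ones_like(Q))
    p = tmp_path / "curve.dat"
    write_curve(curve, p, header="toy curve")
    back = read_curve(p)
    np.testing.assert_allclose(back.q, curve.q, rtol=1e-6)
    np.testing.assert_allclose(back.intensity, curve.intensity, rtol=1e-5)
    assert back.sigma is not None
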