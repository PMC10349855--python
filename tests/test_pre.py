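"""PRE ratio arithmetic, Gamma2/distance conversion and restraint building."""

import math

import numpy as np
import pandas as pd
import pytest

from prelink.exceptions import EmptyOverlapError, OutOfRegimeError
from prelink.pre import (
    PREParams,
    SpinLabelSite,
    backcalculate_pre,
    classify_and_build_restraints,
    distance_to_gamma2,
    forward_ratio,
    gamma2_to_distance,
    intensity_ratio,
    ratio_to_gamma2,
    read_restraints_table,
    write_restraints_table,
)

PARAMS = PREParams(tauc_ns=8.4, field_1h_mhz=600.13, t_evol_s=0.010, r2_dia=15.0)


def peaks(residues, intensities):
    return pd.DataFrame(
        {
            "residue_number": residues,
            "residue_name": ["ALA"] * len(residues),
            "dH_ppm": [8.0] * len(residues),
            "dN_ppm": [115.0] * len(residues),
            "intensity": intensities,
        }
    )


class TestIntensityRatio:
    def test_identity_and_zero(self):
        para = peaks([1, 2, 3], [1.0, 0.0, 2.0])
        dia = peaks([1, 2, 3], [1.0, 5.0, 4.0])
        prof = intensity_ratio(para, dia)
        np.testing.assert_allclose(prof["ratio"], [1.0, 0.0, 0.5])

    def test_elementwise_division_oracle(self, rng):
        ip = rng.uniform(0.1, 2.0, 20)
        idia = rng.uniform(0.5, 3.0, 20)
        prof = intensity_ratio(peaks(range(20), ip), peaks(range(20), idia))
        np.testing.assert_allclose(prof["ratio"], ip / idia, rtol=1e-12)

    def test_nonpositive_dia_skipped(self):
        prof = intensity_ratio(peaks([1, 2], [1.0, 1.0]), peaks([1, 2], [2.0, 0.0]))
        assert list(prof["residue"]) == [1]

    def test_anomalous_flag(self):
        prof = intensity_ratio(peaks([1], [2.0]), peaks([1], [1.0]))
        assert bool(prof["anomalous"].iloc[0])

    def test_no_overlap(self):
        with pytest.raises(EmptyOverlapError):
            intensity_ratio(peaks([1], [1.0]), peaks([2], [1.0]))


class TestGamma2:
    def test_ratio_one_no_effect(self):
        g, flag = ratio_to_gamma2(1.0, 15.0, 0.010)
        assert g == 0.0 and flag == "no-effect"

    def test_ratio_zero_lower_bound_only(self):
        g, flag = ratio_to_gamma2(0.0, 15.0, 0.010)
        assert math.isinf(g) and flag == "lower-bound-only"

    def test_forward_then_invert(self):
        ratio = forward_ratio(20.0, 15.0, 0.010)
        assert ratio == pytest.approx(0.3509, abs=2e-4)
        g, flag = ratio_to_gamma2(ratio, 15.0, 0.010)
        assert flag == ""
        assert g == pytest.approx(20.0, rel=1e-8)

    def test_monotone_smaller_ratio_larger_gamma(self):
        gs = [ratio_to_gamma2(r, 15.0, 0.010)[0] for r in (0.8, 0.5, 0.2, 0.05)]
        assert all(b > a for a, b in zip(gs, gs[1:]))


class TestDistanceConversion:
    def test_direct_formula_oracle(self):
        """r(Gamma2=50, tau_c=8.4 ns, 600.13 MHz) ~ 14.2 A, from the
        Solomon-Bloembergen expression evaluated independently."""
        k = 1.23e-32  # cm^6 s^-2
        tau = 8.4e-9
        omega_h = 2 * math.pi * 600.13e6
        spectral = 4 * tau + 3 * tau / (1 + (omega_h * tau) ** 2)
        expected_cm = (k / 50.0 * spectral) ** (1 / 6)
        assert gamma2_to_distance(50.0, 8.4, 600.13) == pytest.approx(
            expected_cm * 1e8, rel=1e-12
        )
        assert gamma2_to_distance(50.0, 8.4, 600.13) == pytest.approx(14.2, abs=0.05)

    def test_sixth_root_scaling(self):
        r = gamma2_to_distance(5.0, 8.4, 600.13)
        assert gamma2_to_distance(64 * 5.0, 8.4, 600.13) == pytest.approx(r / 2, rel=1e-12)

    def test_round_trip(self):
        for r in (8.0, 14.2, 22.0):
            g = distance_to_gamma2(r, 8.4, 600.13)
            assert gamma2_to_distance(g, 8.4, 600.13) == pytest.approx(r, abs=1e-6)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(OutOfRegimeError):
            gamma2_to_distance(0.0, 8.4, 600.13)


class TestClassification:
    def profile(self, ratios):
        return pd.DataFrame({"residue": range(1, len(ratios) + 1), "ratio": ratios})

    def test_all_ones_all_lower(self):
        restraints = classify_and_build_restraints(
            self.profile([1.0, 1.0, 1.0]), SpinLabelSite(5), PARAMS
        )
        assert all(r.klass == "lower" for r in restraints)
        assert all(math.isinf(r.upper) for r in restraints)

    def test_three_way_split(self):
        restraints = classify_and_build_restraints(
            self.profile([0.05, 0.5, 0.95]), SpinLabelSite(5), PARAMS
        )
        assert [r.klass for r in restraints] == ["upper", "quantitative", "lower"]

    def test_exhaustive_and_exclusive(self):
        ratios = np.concatenate([np.linspace(0, 1.2, 49), [PARAMS.low_cut, PARAMS.high_cut]])
        restraints = classify_and_build_restraints(
            self.profile(ratios), SpinLabelSite(5), PARAMS
        )
        assert len(restraints) == len(ratios)
        for r, ratio in zip(restraints, ratios):
            if ratio < PARAMS.low_cut:
                assert r.klass == "upper"
            elif ratio <= PARAMS.high_cut:
                assert r.klass == "quantitative"
            else:
                assert r.klass == "lower"

    def test_quantitative_bounds_bracket_target(self):
        restraints = classify_and_build_restraints(
            self.profile([0.3, 0.6]), SpinLabelSite(5), PARAMS
        )
        for r in restraints:
            assert r.lower <= r.target <= r.upper
            assert r.upper - r.target == pytest.approx(PARAMS.quantitative_tol)


class TestBackCalculation:
    def test_long_distance_limit(self, bound_complex):
        conf, _, _ = bound_complex
        site = SpinLabelSite(residue_number=1)
        label = site.effective_position(conf)
        prof = backcalculate_pre(conf, site, 8.4, 600.13, 0.010, 15.0)
        far = prof[prof["distance"] > 60.0]
        assert (far["ratio"] > 0.995).all()

    def test_composition_identity(self):
        r = 14.22
        g = distance_to_gamma2(r, 8.4, 600.13)
        ratio = forward_ratio(g, 15.0, 0.010)
        g2, _ = ratio_to_gamma2(ratio, 15.0, 0.010)
        assert gamma2_to_distance(g2, 8.4, 600.13) == pytest.approx(r, abs=1e-6)

    def test_monotone_with_distance(self, bound_complex):
        conf, _, _ = bound_complex
        site = SpinLabelSite(residue_number=12)
        prof = backcalculate_pre(conf, site, 8.4, 600.13, 0.010, 15.0)
        order = prof.sort_values("distance")
        assert order["ratio"].is_monotonic_increasing


class TestInversionProperties:
    def test_full_inversion_below_tenth_angstrom(self):
        """Distances regenerate to < 0.1 A across the informative ratio band."""
        for ratio in np.linspace(0.051, 0.949, 25):
            g, _ = ratio_to_gamma2(ratio, PARAMS.r2_dia, PARAMS.t_evol_s)
            r = gamma2_to_distance(g, PARAMS.tauc_ns, PARAMS.field_1h_mhz)
            ratio_back = forward_ratio(
                distance_to_gamma2(r, PARAMS.tauc_ns, PARAMS.field_1h_mhz),
                PARAMS.r2_dia,
                PARAMS.t_evol_s,
            )
            g2, _ = ratio_to_gamma2(ratio_back, PARAMS.r2_dia, PARAMS.t_evol_s)
            r2 = gamma2_to_distance(g2, PARAMS.tauc_ns, PARAMS.field_1h_mhz)
            assert abs(r2 - r) < 0.1

    def test_noisy_quantitative_recovery_rmse(self):
        """5% ratio noise -> quantitative distances back within 1.5 A RMSE
        (50-residue toy, 200 replicates)."""
        rng = np.random.default_rng(11)
        true_r = rng.uniform(15.0, 23.0, 50)
        true_ratio = np.array(
            [
                forward_ratio(
                    distance_to_gamma2(r, PARAMS.tauc_ns, PARAMS.field_1h_mhz),
                    PARAMS.r2_dia,
                    PARAMS.t_evol_s,
                )
                for r in true_r
            ]
        )
        errs = []
        for _ in range(200):
            noisy = np.clip(true_ratio + rng.normal(0, 0.05, 50), 1e-3, 0.999)
            for i, ratio in enumerate(noisy):
                if not (PARAMS.low_cut <= ratio <= PARAMS.high_cut):
                    continue
                g, _ = ratio_to_gamma2(ratio, PARAMS.r2_dia, PARAMS.t_evol_s)
                r = gamma2_to_distance(g, PARAMS.tauc_ns, PARAMS.field_1h_mhz)
                errs.append(r - true_r[i])
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse < 1.5


def test_restraint_table_roundtrip(tmp_path):
    restraints = classify_and_build_restraints(
        pd.DataFrame({"residue": [1, 2, 3], "ratio": [0.05, 0.5, 0.95]}),
        SpinLabelSite(7),
        PARAMS,
    )
    p = tmp_path / "restraints.tsv"
    write_restraints_table(restraints, p)
    back = read_restraints_table(p)
    assert [r.klass for r in back] == [r.klass for r in restraints]
    assert [r.target for r in back] == pytest.approx([r.target for r in restraints])
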