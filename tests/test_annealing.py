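"""Restraint energies, simulated annealing and ensemble selection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from prelink.annealing import (
    AnnealingSchedule,
    EnergyModel,
    RestraintEvaluator,
    anneal,
    ensemble_centroid,
    restraint_energy,
    select_ensemble,
)
from prelink.csp import AmbiguousRestraint
from prelink.exceptions import ConfigurationError, SizeError
from prelink.pre import DistanceRestraint, SpinLabelSite
from prelink.structure import backbone_rmsd


def flat_restraint(residue, lower, upper, site_residue=12, chain="A", target=None):
    if target is None:
        target = min(max(lower, (lower + min(upper, lower + 8)) / 2), upper)
    return DistanceRestraint(
        chain_id=chain,
        residue_number=residue,
        atom_name="N",
        site=SpinLabelSite(residue_number=site_residue, chain_id=chain),
        klass="quantitative",
        target=target,
        lower=lower,
        upper=upper,
    )


class TestRestraintEnergy:
    def test_satisfied_restraints_zero_energy(self, bound_complex):
        conf, partition, truth = bound_complex
        # bounds wide open around the actual distances
        restraints = [flat_restraint(40, 0.0, 1e6), flat_restraint(70, 0.0, 1e6)]
        model = EnergyModel(w_steric=0.0)
        energy, violations = restraint_energy(
            conf, restraints, model=model, partition=partition
        )
        assert energy == pytest.approx(0.0, abs=1e-6)
        assert all(v == 0.0 for v in violations.values())

    def test_single_violation_harmonic(self, bound_complex):
        conf, partition, _ = bound_complex
        site = SpinLabelSite(residue_number=12)
        d = float(
            np.linalg.norm(conf.get("A", 70, "N") - site.effective_position(conf))
        )
        restraints = [flat_restraint(70, d + 1.0, d + 3.0)]  # violated by 1 A below
        model = EnergyModel(w_steric=0.0, w_bonded=0.0)
        energy, violations = restraint_energy(conf, restraints, model=model)
        assert energy == pytest.approx(1.0, rel=1e-6)

    def test_ambiguous_effective_distance_closed_form(self, bound_complex):
        """Two equal contributing distances r -> r_eff = 2^(-1/6) r."""
        conf, partition, _ = bound_complex
        # construct a one-pair-per-partner toy directly on the evaluator
        amb = AmbiguousRestraint(
            protein_residue=1, rna_positions=(1,), target=4.0, halfwidth=1.0
        )
        ev = RestraintEvaluator(
            conf, [], [amb], EnergyModel(w_steric=0.0, w_bonded=0.0)
        )
        ii, jj, lo, up, w = ev._amb[0]
        d = np.linalg.norm(conf.coords[ii] - conf.coords[jj], axis=1)
        r_eff_expected = float(np.sum(d**-6.0) ** (-1 / 6))
        terms, violations = ev.terms(conf.coords)
        # closed form for the two-equal-distance case
        r = 7.3
        assert (2 * r**-6.0) ** (-1 / 6) == pytest.approx(2 ** (-1 / 6) * r, rel=1e-12)
        # and the evaluator reproduces the general r^-6 sum
        delta = violations["amb:1"]
        if r_eff_expected < lo:
            assert delta == pytest.approx(lo - r_eff_expected, rel=1e-9)
        elif r_eff_expected > up:
            assert delta == pytest.approx(r_eff_expected - up, rel=1e-9)
        else:
            assert delta == 0.0

    def test_decomposition_sums_to_total(self, bound_complex):
        conf, partition, _ = bound_complex
        restraints = [flat_restraint(40, 30.0, 35.0), flat_restraint(70, 0.0, 5.0)]
        amb = [AmbiguousRestraint(protein_residue=70, rna_positions=(6, 7, 8))]
        ev = RestraintEvaluator(conf, restraints, amb, EnergyModel(), partition)
        sc = ev.score(conf)
        assert sc.total == pytest.approx(sum(sc.terms.values()), rel=1e-9)
        # the fast path agrees with the bookkeeping path
        assert ev.energy(conf.coords) == pytest.approx(sc.total, rel=1e-9)

    def test_invariance_under_global_motion(self, bound_complex, rng):
        conf, partition, _ = bound_complex
        restraints = [flat_restraint(40, 10.0, 20.0), flat_restraint(75, 5.0, 25.0)]
        amb = [AmbiguousRestraint(protein_residue=70, rna_positions=(6, 7, 8))]
        model = EnergyModel(w_bonded=0.0)
        e0, _ = restraint_energy(conf, restraints, amb, model)
        moved = conf.copy()
        rot = Rotation.from_rotvec(rng.normal(0, 1, 3))
        moved.coords = rot.apply(conf.coords) + np.array([10.0, -4.0, 6.0])
        e1, _ = restraint_energy(moved, restraints, amb, model)
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_unresolvable_restraint_errors(self, bound_complex):
        conf, partition, _ = bound_complex
        with pytest.raises(ConfigurationError):
            RestraintEvaluator(conf, [flat_restraint(9999, 0.0, 10.0)])


class TestAnneal:
    def test_no_violations_energy_stays_zero(self, bound_complex):
        conf, partition, _ = bound_complex
        # all-satisfiable restraints and a clash-free start
        restraints = [flat_restraint(40, 0.0, 1e6)]
        model = EnergyModel(w_steric=0.0, w_bonded=0.0)
        ev = RestraintEvaluator(conf, restraints, [], model, partition)
        schedule = AnnealingSchedule(steps=(50, 50, 20))
        sc = anneal(conf, ev, schedule, partition, np.random.default_rng(0))
        assert sc.total == pytest.approx(0.0, abs=1e-9)

    def test_pulls_domains_to_satisfy_restraint(self, bound_complex):
        """A single satisfiable inter-domain distance restraint, violated by
        ~20 A in a linker-extended start, anneals to < 0.5 A violation."""
        from prelink.sampling import SamplingConfig, generate_pool

        conf, partition, _ = bound_complex
        site = SpinLabelSite(residue_number=12)
        d_true = float(
            np.linalg.norm(conf.get("A", 75, "N") - site.effective_position(conf))
        )
        restraints = [flat_restraint(75, d_true - 1.0, d_true + 1.0, site_residue=12)]
        pool = generate_pool(conf, partition, SamplingConfig(n_attempts=3, seed=9))
        ev = RestraintEvaluator(conf, restraints, [], EnergyModel(), partition)
        # pick the start with the largest violation
        start = max(pool.members, key=lambda c: ev.energy(c.coords))
        assert ev.score(start).violations[f"pre:12->75"] > 5.0
        schedule = AnnealingSchedule(scales=(10.0, 3.0, 0.5), steps=(800, 800, 400))
        sc = anneal(start, ev, schedule, partition, np.random.default_rng(1))
        assert sc.violations["pre:12->75"] < 0.5

    def test_deterministic_under_seed(self, bound_complex):
        conf, partition, _ = bound_complex
        restraints = [flat_restraint(70, 5.0, 15.0)]
        ev = RestraintEvaluator(conf, restraints, [], EnergyModel(), partition)
        schedule = AnnealingSchedule(steps=(100, 100, 50))
        a = anneal(conf, ev, schedule, partition, np.random.default_rng(5))
        b = anneal(conf, ev, schedule, partition, np.random.default_rng(5))
        np.testing.assert_array_equal(a.conformer.coords, b.conformer.coords)
        assert a.total == b.total

    def test_never_worse_than_start(self, bound_complex):
        conf, partition, _ = bound_complex
        restraints = [flat_restraint(70, 40.0, 45.0)]
        ev = RestraintEvaluator(conf, restraints, [], EnergyModel(), partition)
        e_start = ev.energy(conf.coords)
        schedule = AnnealingSchedule(steps=(100, 100, 50))
        sc = anneal(conf, ev, schedule, partition, np.random.default_rng(2))
        assert sc.total <= e_start + 1e-9

    def test_rigid_geometry_preserved(self, bound_complex):
        from prelink.structure import intra_segment_distances

        conf, partition, _ = bound_complex
        restraints = [flat_restraint(70, 5.0, 15.0)]
        ev = RestraintEvaluator(conf, restraints, [], EnergyModel(), partition)
        schedule = AnnealingSchedule(steps=(150, 100, 50))
        sc = anneal(conf, ev, schedule, partition, np.random.default_rng(3))
        last = partition.rigid_segments()[-1]
        np.testing.assert_allclose(
            intra_segment_distances(sc.conformer, partition, last.name),
            intra_segment_distances(conf, partition, last.name),
            atol=1e-6,
        )

    def test_bad_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            AnnealingSchedule(scales=(1.0, 3.0, 10.0))
        with pytest.raises(ConfigurationError):
            AnnealingSchedule(scales=(3.0, 1.0), steps=(10, 10))


class TestSelectEnsemble:
    def _scored(self, conf, energies):
        from prelink.annealing import ScoredConformer

        return [
            ScoredConformer(
                conformer=conf, total=e, terms={}, violations={}, provenance=i
            )
            for i, e in enumerate(energies)
        ]

    def test_k1_single_lowest(self, bound_complex):
        conf, _, _ = bound_complex
        pool = self._scored(conf, [3.0, 1.0, 2.0])
        ensemble, (mean, sd) = select_ensemble(pool, k=1)
        assert ensemble[0].total == 1.0
        assert (mean, sd) == (0.0, 0.0)

    def test_identical_conformers_zero_rmsd(self, bound_complex):
        conf, _, _ = bound_complex
        pool = self._scored(conf, [1.0, 2.0, 3.0])
        _, (mean, sd) = select_ensemble(pool, k=3)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_pool_too_small(self, bound_complex):
        conf, _, _ = bound_complex
        with pytest.raises(SizeError):
            select_ensemble(self._scored(conf, [1.0]), k=2)

    def test_tie_break_by_provenance(self, bound_complex):
        conf, _, _ = bound_complex
        pool = self._scored(conf, [1.0, 1.0, 1.0, 0.5])
        ensemble, _ = select_ensemble(pool, k=3)
        assert [sc.provenance for sc in ensemble] == [3, 0, 1]

    def test_centroid_of_identical_is_member(self, bound_complex):
        conf, _, _ = bound_complex
        pool = self._scored(conf, [1.0, 2.0])
        centroid = ensemble_centroid(pool)
        assert backbone_rmsd(centroid, conf) == pytest.approx(0.0, abs=1e-9)
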