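"""Coordinate model, PDB I/O, superposition, steric energy and torsions."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from prelink.exceptions import (
    DomainViolationError,
    EmptyInputError,
    InsufficientPairsError,
    StructureFormatError,
)
from prelink.structure import (
    AtomRecord,
    Conformer,
    DomainPartition,
    Segment,
    StericParams,
    backbone_rmsd,
    coordinate_rmsd,
    get_phi_psi,
    intra_segment_distances,
    read_structure,
    set_linker_torsions,
    superpose,
    vdw_energy,
    write_structure,
)

ONE_ATOM_PDB = (
    "ATOM      1  CA  ALA A   1      11.104  22.200   3.000  1.00  0.00           C\n"
    "END\n"
)


def _toy_conformer():
    """Two chains: a 3-residue protein backbone and a 2-residue RNA stub."""
    atoms = []
    for i in range(3):
        for j, name in enumerate(("N", "CA", "C")):
            atoms.append(
                AtomRecord(name, "ALA", "A", i + 1, [3.8 * i + 1.2 * j, 0.0, 0.0])
            )
    for i in range(2):
        atoms.append(AtomRecord("P", "U", "R", i + 1, [0.0, 6.0 + 6 * i, 0.0]))
        atoms.append(AtomRecord("C4'", "U", "R", i + 1, [1.2, 6.0 + 6 * i, 0.0]))
    return Conformer.from_atoms(atoms)


class TestPdbIO:
    def test_single_atom_roundtrip(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(ONE_ATOM_PDB)
        conf = read_structure(p)
        assert conf.n_atoms == 1
        np.testing.assert_allclose(conf.coords[0], [11.104, 22.2, 3.0])
        out = tmp_path / "out.pdb"
        write_structure(conf, out)
        again = read_structure(out)
        np.testing.assert_allclose(again.coords, conf.coords, atol=5e-4)

    def test_roundtrip_three_decimals_and_chain_order(self, tmp_path):
        conf = _toy_conformer()
        out = tmp_path / "toy.pdb"
        write_structure(conf, out)
        again = read_structure(out)
        np.testing.assert_allclose(again.coords, conf.coords, atol=5e-4)
        assert again.chains == conf.chains
        assert list(again.atom_names) == list(conf.atom_names)

    def test_two_chain_counts(self, tmp_path):
        conf = _toy_conformer()
        out = tmp_path / "toy.pdb"
        write_structure(conf, out)
        again = read_structure(out)
        # chain partition matches what a direct line count of the file gives
        lines = [l for l in out.read_text().splitlines() if l.startswith("ATOM")]
        per_chain = {"A": 0, "R": 0}
        for l in lines:
            per_chain[l[21]] += 1
        assert per_chain["A"] == int(np.sum(again.chain_ids == "A")) == 9
        assert per_chain["R"] == int(np.sum(again.chain_ids == "R")) == 4

    def test_unparsable_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            ONE_ATOM_PDB.replace("11.104", "xx.xxx")
        )
        with pytest.raises(StructureFormatError, match=":1:"):
            read_structure(p)

    def test_empty_model(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(EmptyInputError):
            read_structure(p)


class TestSuperposition:
    def test_identity_and_translation(self):
        conf = _toy_conformer()
        _, _, rmsd = superpose(conf, conf)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        moved = conf.copy()
        moved.coords = conf.coords + np.array([5.0, -3.0, 2.0])
        _, _, rmsd = superpose(moved, conf)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_matches_numerical_minimization_oracle(self, rng):
        """Kabsch result equals direct minimization over rotations."""
        a = _toy_conformer()
        b = a.copy()
        b.coords = a.coords + rng.normal(0, 0.8, a.coords.shape)
        R, t, rmsd = superpose(a, b)
        X = a.coords - a.coords.mean(axis=0)
        Y = b.coords - b.coords.mean(axis=0)

        def cost(rotvec):
            rot = Rotation.from_rotvec(rotvec)
            return np.sqrt(np.mean(np.sum((rot.apply(X) - Y) ** 2, axis=1)))

        best = min(
            (
                minimize(cost, v, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
                for v in rng.normal(0, 1.5, (12, 3))
            ),
            key=lambda r: r.fun,
        )
        assert rmsd == pytest.approx(best.fun, abs=1e-3)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_pairs(self):
        a = _toy_conformer()
        with pytest.raises(InsufficientPairsError):
            superpose(a, a, "A:1-1:CA")

    def test_backbone_rmsd_symmetry(self, rng):
        a = _toy_conformer()
        b = a.copy()
        b.coords = a.coords + rng.normal(0, 1.0, a.coords.shape)
        assert backbone_rmsd(a, b) == pytest.approx(backbone_rmsd(b, a), abs=1e-9)

    def test_displaced_atom_no_fit_rmsd(self):
        """One atom displaced by d among n in a fixed frame -> d/sqrt(n)."""
        a = _toy_conformer()
        b = a.copy()
        d = 2.4
        b.coords = a.coords.copy()
        b.coords[4, 2] += d
        n = a.n_atoms
        assert coordinate_rmsd(a, b) == pytest.approx(d / np.sqrt(n), rel=1e-12)


class TestStericEnergy:
    def test_outside_cutoff_zero(self):
        atoms = [
            AtomRecord("C1", "LIG", "A", 1, [0, 0, 0]),
            AtomRecord("C2", "LIG", "B", 1, [10, 0, 0]),
        ]
        assert vdw_energy(Conformer.from_atoms(atoms)) == 0.0

    def test_boundary_and_monotonicity(self):
        def e(r):
            atoms = [
                AtomRecord("C1", "LIG", "A", 1, [0, 0, 0]),
                AtomRecord("C2", "LIG", "B", 1, [r, 0, 0]),
            ]
            return vdw_energy(Conformer.from_atoms(atoms), StericParams(r_min=3.2))

        assert e(3.2) == 0.0
        energies = [e(r) for r in (3.0, 2.5, 2.0, 1.5)]
        assert energies[0] > 0
        assert all(b > a for a, b in zip(energies, energies[1:]))

    def test_three_atom_cluster_matches_pair_loop(self):
        pos = np.array([[0, 0, 0], [2.5, 0, 0], [1.0, 2.0, 0.5]])
        atoms = [
            AtomRecord(f"C{i}", "LIG", chain, 1, p)
            for i, (chain, p) in enumerate(zip("ABC", pos))
        ]
        conf = Conformer.from_atoms(atoms)
        k, rmin = 1.0, 3.2
        expected = sum(
            k * max(rmin - np.linalg.norm(pos[i] - pos[j]), 0.0) ** 4
            for i in range(3)
            for j in range(i + 1, 3)
        )
        assert vdw_energy(conf) == pytest.approx(expected, rel=1e-12)

    def test_invariance_rotation_translation(self, bound_complex, rng):
        conf, _, _ = bound_complex
        e0 = vdw_energy(conf)
        moved = conf.copy()
        rot = Rotation.from_rotvec(rng.normal(0, 1, 3))
        moved.coords = rot.apply(conf.coords) + np.array([3.0, -7.0, 11.0])
        assert vdw_energy(moved) == pytest.approx(e0, rel=1e-9)


class TestTorsions:
    @pytest.fixture()
    def system(self, bound_complex):
        conf, partition, _ = bound_complex
        return conf, partition

    def test_identity_and_periodicity(self, system):
        conf, partition = system
        ch, res = partition.flexible_residues(partition.sampled_linker)[3]
        phi, psi = get_phi_psi(conf, ch, res)
        same = set_linker_torsions(conf, partition, {(ch, res): (phi, psi)})
        np.testing.assert_allclose(same.coords, conf.coords, atol=1e-6)
        wrapped = set_linker_torsions(conf, partition, {(ch, res): (phi + 360.0, psi - 360.0)})
        np.testing.assert_allclose(wrapped.coords, conf.coords, atol=1e-6)

    def test_mid_linker_rotation_moves_domains_not_internals(self, system):
        conf, partition = system
        linker = partition.segment(partition.sampled_linker)
        res = (linker.start + linker.stop) // 2
        phi, psi = get_phi_psi(conf, linker.chain_id, res)
        rotated = set_linker_torsions(
            conf, partition, {(linker.chain_id, res): (phi, psi + 90.0)}
        )
        last = partition.rigid_segments()[-1]
        first = partition.rigid_segments()[0]

        def center(c, seg):
            mask = partition.atom_mask(c, seg.name)
            return c.coords[mask].mean(axis=0)

        d_before = np.linalg.norm(center(conf, last) - center(conf, first))
        d_after = np.linalg.norm(center(rotated, last) - center(rotated, first))
        assert abs(d_after - d_before) > 1.0
        for seg in partition.rigid_segments():
            np.testing.assert_allclose(
                intra_segment_distances(rotated, partition, seg.name),
                intra_segment_distances(conf, partition, seg.name),
                atol=1e-6,
            )

    def test_rigid_residue_rejected(self, system):
        conf, partition = system
        rigid = partition.rigid_segments()[0]
        with pytest.raises(DomainViolationError):
            set_linker_torsions(conf, partition, {(rigid.chain_id, rigid.start): (10.0, 10.0)})

    def test_rigid_invariance_under_torsion_sequences(self, system, rng):
        """Property: arbitrary torsion sequences never distort rigid bodies."""
        conf, partition = system
        flexible = partition.flexible_residues(partition.sampled_linker)
        current = conf
        for _ in range(5):
            tors = {
                flexible[int(rng.integers(len(flexible)))]: tuple(
                    rng.uniform(-180, 180, 2)
                )
                for _ in range(4)
            }
            current = set_linker_torsions(current, partition, tors)
        for seg in partition.rigid_segments():
            np.testing.assert_allclose(
                intra_segment_distances(current, partition, seg.name),
                intra_segment_distances(conf, partition, seg.name),
                atol=1e-6,
            )

    def test_bond_lengths_preserved(self, system, rng):
        conf, partition = system
        flexible = partition.flexible_residues(partition.sampled_linker)
        tors = {fr: tuple(rng.uniform(-180, 180, 2)) for fr in flexible}
        rotated = set_linker_torsions(conf, partition, tors)
        ch = flexible[0][0]

        def bonds(c):
            out = []
            for res in c.residues(ch):
                for (a1, r1), (a2, r2) in (
                    (("N", res), ("CA", res)),
                    (("CA", res), ("C", res)),
                    (("C", res), ("N", res + 1)),
                ):
                    try:
                        out.append(np.linalg.norm(c.get(ch, r1, a1) - c.get(ch, r2, a2)))
                    except KeyError:
                        pass
            return np.array(out)

        np.testing.assert_allclose(bonds(rotated), bonds(conf), atol=1e-6)


class TestDomainPartition:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DomainPartition(
                segments=[
                    Segment("D1", "A", 1, 10, "rigid"),
                    Segment("L1", "A", 8, 15, "flexible"),
                ],
                sampled_linker="L1",
            )

    def test_needs_flexible(self):
        with pytest.raises(ValueError, match="flexible"):
            DomainPartition(
                segments=[Segment("D1", "A", 1, 10, "rigid")], sampled_linker="D1"
            )
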