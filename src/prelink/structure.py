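"""Coordinate data model and geometry.

A :class:`Conformer` is a flat, numpy-backed collection of atoms grouped by
chain and residue, at whatever resolution the caller chooses -- full-atomic
structures read from PDB files or the pseudo-atomic (N/CA/C + side-chain
centroid) chains used for toy complexes.  All coordinates are in Angstrom and
residue numbering is 1-based, as in the PDB.

The module provides the geometric primitives the modeling stages build on:
PDB input/output (through gemmi), Kabsch least-squares superposition, backbone
RMSD, a purely repulsive quartic steric energy, and phi/psi torsion rotations
that propagate N->C along a chain while leaving rigid-segment internal
geometry untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .exceptions import (
    CapacityError,
    DomainViolationError,
    EmptyInputError,
    InsufficientPairsError,
    StructureFormatError,
)

BACKBONE_ATOMS = ("N", "CA", "C")

# Atom name -> element fallback for pseudo-atoms.
_ELEMENT_GUESS = {"CA": "C", "CB": "C", "C4'": "C", "C1'": "C", "N1": "N", "P": "P"}


@dataclass
class AtomRecord:
    """One atom: identity plus position (Angstrom)."""

    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray
    element: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("position must be a finite 3-vector")
        if not self.element:
            name = self.atom_name.strip()
            self.element = _ELEMENT_GUESS.get(name, name[:1])


class Conformer:
    """Ordered atom collection with per-chain residue indexing.

    Atoms are stored grouped by chain, residues in ascending order within each
    chain; this ordering is what torsion propagation relies on.
    """

    def __init__(
        self,
        atom_names: Sequence[str],
        residue_names: Sequence[str],
        chain_ids: Sequence[str],
        residue_numbers: Sequence[int],
        coords: np.ndarray,
        elements: Sequence[str] | None = None,
    ):
        n = len(atom_names)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.coords = np.array(coords, dtype=float).reshape(n, 3)
        if elements is None:
            elements = [
                _ELEMENT_GUESS.get(str(a).strip(), str(a).strip()[:1])
                for a in atom_names
            ]
        self.elements = np.asarray(elements, dtype=object)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self._validate()
        self._index: dict[tuple[str, int, str], int] | None = None
        self._res_ordinal: np.ndarray | None = None

    # -- construction ------------------------------------------------------
    @classmethod
    def from_atoms(cls, atoms: Iterable[AtomRecord]) -> "Conformer":
        atoms = list(atoms)
        if not atoms:
            raise EmptyInputError("no atoms")
        return cls(
            [a.atom_name for a in atoms],
            [a.residue_name for a in atoms],
            [a.chain_id for a in atoms],
            [a.residue_number for a in atoms],
            np.array([a.position for a in atoms]),
            [a.element for a in atoms],
        )

    def _validate(self) -> None:
        keys = list(zip(self.chain_ids, self.residue_numbers, self.atom_names))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom) keys")
        # residue numbering must be monotone non-decreasing within a chain
        for ch in self.chains:
            nums = self.residue_numbers[self.chain_ids == ch]
            if np.any(np.diff(nums) < 0):
                raise ValueError(f"residue numbering not monotone in chain {ch}")

    # -- basic properties --------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)

    def residues(self, chain_id: str) -> list[int]:
        mask = self.chain_ids == chain_id
        out: dict[int, None] = {}
        for r in self.residue_numbers[mask]:
            out.setdefault(int(r))
        return list(out)

    def copy(self) -> "Conformer":
        c = Conformer.__new__(Conformer)
        c.atom_names = self.atom_names
        c.residue_names = self.residue_names
        c.chain_ids = self.chain_ids
        c.residue_numbers = self.residue_numbers
        c.elements = self.elements
        c.coords = self.coords.copy()
        c._index = self._index
        c._res_ordinal = self._res_ordinal
        return c

    # -- indexing ----------------------------------------------------------
    def _build_index(self) -> None:
        self._index = {
            (str(c), int(r), str(a)): i
            for i, (c, r, a) in enumerate(
                zip(self.chain_ids, self.residue_numbers, self.atom_names)
            )
        }

    def index_of(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        """Flat index of one atom; KeyError if absent."""
        if self._index is None:
            self._build_index()
        assert self._index is not None
        return self._index[(chain_id, int(residue_number), atom_name)]

    def get(self, chain_id: str, residue_number: int, atom_name: str) -> np.ndarray:
        return self.coords[self.index_of(chain_id, residue_number, atom_name)]

    def residue_ordinals(self) -> np.ndarray:
        """Per-atom ordinal of its (chain, residue) in file order (cached)."""
        if self._res_ordinal is None:
            ords = np.empty(self.n_atoms, dtype=int)
            current, k = None, -1
            for i, key in enumerate(zip(self.chain_ids, self.residue_numbers)):
                if key != current:
                    k += 1
                    current = key
                ords[i] = k
            self._res_ordinal = ords
        return self._res_ordinal

    def subset(self, mask: np.ndarray) -> "Conformer":
        return Conformer(
            self.atom_names[mask],
            self.residue_names[mask],
            self.chain_ids[mask],
            self.residue_numbers[mask],
            self.coords[mask],
            self.elements[mask],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Conformer {self.n_atoms} atoms, chains {self.chains}>"


# ---------------------------------------------------------------------------
# Domain partition
# ---------------------------------------------------------------------------

Role = str  # "rigid" | "flexible"


@dataclass(frozen=True)
class Segment:
    name: str
    chain_id: str
    start: int
    stop: int  # inclusive
    role: Role

    def contains(self, chain_id: str, residue_number: int) -> bool:
        return chain_id == self.chain_id and self.start <= residue_number <= self.stop


@dataclass
class DomainPartition:
    """Rigid/flexible split of a multidomain chain.

    ``sampled_linker`` names the flexible segment whose phi/psi angles the
    conformer sampler randomizes; other flexible segments keep their input
    geometry (they still count as flexible for torsion setting).
    """

    segments: list[Segment]
    sampled_linker: str

    def __post_init__(self) -> None:
        by_chain: dict[str, list[Segment]] = {}
        for s in self.segments:
            by_chain.setdefault(s.chain_id, []).append(s)
        for segs in by_chain.values():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.stop:
                    raise ValueError(f"overlapping segments {a.name}/{b.name}")
        if not any(s.role == "flexible" for s in self.segments):
            raise ValueError("partition needs at least one flexible segment")
        if self.sampled_linker not in {s.name for s in self.segments}:
            raise ValueError(f"unknown linker {self.sampled_linker!r}")

    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def segment_of(self, chain_id: str, residue_number: int) -> Segment | None:
        for s in self.segments:
            if s.contains(chain_id, residue_number):
                return s
        return None

    def flexible_residues(self, name: str | None = None) -> list[tuple[str, int]]:
        out = []
        for s in self.segments:
            if s.role != "flexible":
                continue
            if name is not None and s.name != name:
                continue
            out.extend((s.chain_id, r) for r in range(s.start, s.stop + 1))
        return out

    def rigid_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.role == "rigid"]

    def atom_mask(self, conformer: Conformer, name: str) -> np.ndarray:
        s = self.segment(name)
        return (
            (conformer.chain_ids == s.chain_id)
            & (conformer.residue_numbers >= s.start)
            & (conformer.residue_numbers <= s.stop)
        )


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

Predicate = Callable[[str, int, str], bool]  # (chain, resnum, atom_name) -> bool


def parse_selection(spec: str) -> Predicate:
    """Parse ``"chain:resstart-resend[:atomname]"`` into a predicate.

    ``"A:10-30"`` selects all atoms of residues 10..30 of chain A;
    ``"A:10-30:CA"`` restricts to CA atoms; ``"A"`` selects a whole chain.
    """
    parts = spec.split(":")
    chain = parts[0]
    lo, hi = -10**9, 10**9
    atom = None
    if len(parts) >= 2 and parts[1]:
        rng = parts[1].split("-")
        lo = int(rng[0])
        hi = int(rng[1]) if len(rng) > 1 else lo
    if len(parts) >= 3 and parts[2]:
        atom = parts[2]

    def pred(c: str, r: int, a: str) -> bool:
        return c == chain and lo <= r <= hi and (atom is None or a == atom)

    return pred


def _selection_mask(conf: Conformer, selection) -> np.ndarray:
    if selection is None:
        return np.ones(conf.n_atoms, dtype=bool)
    if isinstance(selection, str):
        selection = parse_selection(selection)
    if isinstance(selection, (list, tuple)) and selection and isinstance(selection[0], str):
        preds = [parse_selection(s) for s in selection]
        selection = lambda c, r, a: any(p(c, r, a) for p in preds)  # noqa: E731
    return np.array(
        [
            selection(str(c), int(r), str(a))
            for c, r, a in zip(conf.chain_ids, conf.residue_numbers, conf.atom_names)
        ],
        dtype=bool,
    )


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------


def read_structure(path: str | Path) -> Conformer:
    """Read a PDB file into a Conformer.

    All ATOM/HETATM records of the first model are kept.  Alternate locations
    are resolved to the first occurrence; insertion codes are rejected (this
    package targets renumbered, icode-free models).
    """
    path = Path(path)
    # gemmi is forgiving about malformed records; validate coordinate fields
    # up front so corrupt files fail loudly with a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise StructureFormatError(
                        f"{path}:{lineno}: unparsable coordinates: {line.rstrip()!r}"
                    ) from exc
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyInputError(f"{path}: no models")
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            if residue.seqid.icode not in ("", " "):
                raise StructureFormatError(
                    f"{path}: insertion code {residue.seqid.icode!r} at "
                    f"{chain.name}{residue.seqid.num} not supported"
                )
            seen: set[str] = set()
            for atom in residue:
                if atom.name in seen:  # altloc duplicates: first occurrence wins
                    continue
                seen.add(atom.name)
                atoms.append(
                    AtomRecord(
                        atom_name=atom.name,
                        residue_name=residue.name,
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        element=atom.element.name,
                    )
                )
    if not atoms:
        raise EmptyInputError(f"{path}: empty model")
    return Conformer.from_atoms(atoms)


def write_structure(conformer: Conformer, path: str | Path) -> None:
    """Write a Conformer as fixed-column PDB (re-readable by read_structure)."""
    if conformer.n_atoms == 0:
        raise EmptyInputError("empty conformer")
    if conformer.n_atoms > 99999:
        raise CapacityError("PDB serial field overflows above 99999 atoms")
    _write_models([conformer], path)


def write_models(conformers: Sequence[Conformer], path: str | Path) -> None:
    """Write several conformers as a multi-model PDB (MODEL/ENDMDL)."""
    if not conformers:
        raise EmptyInputError("no conformers")
    _write_models(conformers, path)


def _write_models(conformers: Sequence[Conformer], path: str | Path) -> None:
    st = gemmi.Structure()
    st.name = "prelink"
    for imodel, conf in enumerate(conformers, start=1):
        model = gemmi.Model(imodel)
        for ch_name in conf.chains:
            chain = gemmi.Chain(str(ch_name))
            idx = np.nonzero(conf.chain_ids == ch_name)[0]
            # group atom indices by residue, preserving order (gemmi copies on
            # add_residue, so each residue must be complete before adding)
            groups: list[tuple[tuple[int, str], list[int]]] = []
            for i in idx:
                key = (int(conf.residue_numbers[i]), str(conf.residue_names[i]))
                if not groups or groups[-1][0] != key:
                    groups.append((key, []))
                groups[-1][1].append(i)
            for (resnum, resname), atom_idx in groups:
                residue = gemmi.Residue()
                residue.name = resname
                residue.seqid = gemmi.SeqId(resnum, " ")
                for i in atom_idx:
                    atom = gemmi.Atom()
                    atom.name = str(conf.atom_names[i])
                    x, y, z = conf.coords[i]
                    atom.pos = gemmi.Position(x, y, z)
                    try:
                        atom.element = gemmi.Element(str(conf.elements[i]))
                    except Exception:
                        atom.element = gemmi.Element("X")
                    residue.add_atom(atom)
                chain.add_residue(residue)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc_path = str(Path(path))
    st.write_pdb(doc_path)


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------


def _paired_coords(
    mobile: Conformer, reference: Conformer, selection
) -> tuple[np.ndarray, np.ndarray]:
    mmask = _selection_mask(mobile, selection)
    pairs_m, pairs_r = [], []
    if reference._index is None:
        reference._build_index()
    assert reference._index is not None
    rmask = _selection_mask(reference, selection)
    allowed = {
        (str(c), int(r), str(a))
        for c, r, a in zip(
            reference.chain_ids[rmask],
            reference.residue_numbers[rmask],
            reference.atom_names[rmask],
        )
    }
    for i in np.nonzero(mmask)[0]:
        key = (
            str(mobile.chain_ids[i]),
            int(mobile.residue_numbers[i]),
            str(mobile.atom_names[i]),
        )
        if key in allowed:
            pairs_m.append(i)
            pairs_r.append(reference._index[key])
    if len(pairs_m) < 3:
        raise InsufficientPairsError(
            f"only {len(pairs_m)} paired atoms under selection (need >=3)"
        )
    return mobile.coords[pairs_m], reference.coords[pairs_r]


def superpose(
    mobile: Conformer, reference: Conformer, selection=None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch least-squares fit of mobile onto reference.

    Atoms are paired by (chain, residue_number, atom_name).  Returns the
    proper rotation matrix R (det +1), translation t such that
    ``x' = x @ R.T + t``, and the minimized RMSD in Angstrom.
    """
    X, Y = _paired_coords(mobile, reference, selection)
    R, t = _kabsch(X, Y)
    moved = X @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Y) ** 2, axis=1))))
    return R, t, rmsd


def _kabsch(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - xc @ R.T
    return R, t


def apply_transform(conf: Conformer, R: np.ndarray, t: np.ndarray) -> Conformer:
    out = conf.copy()
    out.coords = conf.coords @ R.T + t
    return out


def coordinate_rmsd(a: Conformer, b: Conformer, selection=None) -> float:
    """RMSD over paired atoms in the current frames (no superposition)."""
    X, Y = _paired_coords(a, b, selection)
    return float(np.sqrt(np.mean(np.sum((X - Y) ** 2, axis=1))))


def backbone_rmsd(a: Conformer, b: Conformer, selection=None) -> float:
    """Backbone RMSD after optimal superposition (symmetric in a, b).

    With ``selection=None`` the backbone atom names N/CA/C (and P/C4' for
    nucleic chains) are used for both the fit and the RMSD.
    """
    if selection is None:
        bb = set(BACKBONE_ATOMS) | {"P", "C4'"}
        selection = lambda c, r, at: at in bb  # noqa: E731
    _, _, rmsd = superpose(a, b, selection)
    return rmsd


# ---------------------------------------------------------------------------
# Steric energy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StericParams:
    """Quartic repulsive steric term: E = sum k (r_min - r)^4 for r < r_min.

    Purely repulsive by design -- the acceptance rule the sampler implements
    only penalizes clashes.  ``r_min`` is a single effective contact distance
    for pseudo-atomic beads; per-element-pair overrides may be supplied.
    """

    r_min: float = 3.2  # Angstrom
    k: float = 1.0  # energy / Angstrom^4
    pair_r_min: dict[frozenset, float] = field(default_factory=dict)


class StericEvaluator:
    """Precomputes the bonded-exclusion table of one topology for fast
    re-scoring.

    Excluded pairs: same residue, and residues adjacent in sequence within
    the same chain (the bonded-neighbor rule).  Because the term is purely
    repulsive with a finite contact radius, each evaluation only needs the
    atom pairs within that radius, found with a KD-tree.
    """

    def __init__(self, conf: Conformer, params: StericParams | None = None):
        self.params = params or StericParams()
        self.n = conf.n_atoms
        ords = conf.residue_ordinals()
        same_chain = conf.chain_ids[:, None] == conf.chain_ids[None, :]
        dres = np.abs(ords[:, None] - ords[None, :])
        ei, ej = np.nonzero(np.triu(same_chain & (dres <= 1), k=1))
        self._excluded_keys = np.sort(ei.astype(np.int64) * self.n + ej)
        self._elements = np.asarray([str(e) for e in conf.elements], dtype=object)
        self._max_rmin = self.params.r_min
        if self.params.pair_r_min:
            self._max_rmin = max(self.params.r_min, *self.params.pair_r_min.values())

    def energy(self, coords: np.ndarray) -> float:
        from scipy.spatial import cKDTree

        pairs = cKDTree(coords).query_pairs(self._max_rmin, output_type="ndarray")
        if len(pairs) == 0:
            return 0.0
        keys = pairs[:, 0].astype(np.int64) * self.n + pairs[:, 1]
        keep = ~np.isin(keys, self._excluded_keys, assume_unique=True)
        pairs = pairs[keep]
        if len(pairs) == 0:
            return 0.0
        d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        if self.params.pair_r_min:
            rmin = np.array(
                [
                    self.params.pair_r_min.get(
                        frozenset((self._elements[i], self._elements[j])),
                        self.params.r_min,
                    )
                    for i, j in pairs
                ]
            )
        else:
            rmin = self.params.r_min
        overlap = np.clip(rmin - r, 0.0, None)
        return float(self.params.k * np.sum(overlap**4))


def vdw_energy(conf: Conformer, params: StericParams | None = None) -> float:
    """Molecule-wide repulsive steric energy (>= 0; 0 when clash-free)."""
    if conf.n_atoms == 0:
        return 0.0
    return StericEvaluator(conf, params).energy(conf.coords)


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Right-handed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang > -180.0 else 180.0)


def get_phi_psi(conf: Conformer, chain_id: str, residue_number: int) -> tuple[float | None, float | None]:
    """Current (phi, psi) of a residue; None where the flanking atom is absent."""
    phi = psi = None
    try:
        n = conf.get(chain_id, residue_number, "N")
        ca = conf.get(chain_id, residue_number, "CA")
        c = conf.get(chain_id, residue_number, "C")
    except KeyError:
        return None, None
    try:
        cprev = conf.get(chain_id, residue_number - 1, "C")
        phi = dihedral(cprev, n, ca, c)
    except KeyError:
        pass
    try:
        nnext = conf.get(chain_id, residue_number + 1, "N")
        psi = dihedral(n, ca, c, nnext)
    except KeyError:
        pass
    return phi, psi


def _rotate_about(coords: np.ndarray, idx: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float) -> None:
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    coords[idx] = rot.apply(coords[idx] - origin) + origin


def set_linker_torsions(
    conf: Conformer,
    partition: DomainPartition,
    torsions: dict[tuple[str, int], tuple[float | None, float | None]],
) -> Conformer:
    """Set absolute (phi, psi) angles, in degrees, on flexible residues.

    Rotations propagate N->C: a phi rotation about the N-CA axis moves the
    residue's own CB/C and every atom later in the chain; a psi rotation about
    the CA-C axis moves every atom after C.  Other chains never move, so a
    partner chain bound to the upstream rigid body rides with it.  ``None``
    for phi or psi leaves that angle unchanged.

    Raises DomainViolationError for residues outside flexible segments.
    """
    for (ch, res) in torsions:
        seg = partition.segment_of(ch, res)
        if seg is None or seg.role != "flexible":
            raise DomainViolationError(
                f"residue {ch}:{res} is not in a flexible segment"
            )
    out = conf.copy()
    coords = out.coords
    ords = conf.residue_ordinals()
    order = sorted(
        torsions.items(),
        key=lambda kv: conf.residue_ordinals()[conf.index_of(kv[0][0], kv[0][1], "CA")],
    )
    for (ch, res), (phi, psi) in order:
        chain_mask = conf.chain_ids == ch
        my_ord = ords[conf.index_of(ch, res, "CA")]
        if phi is not None:
            cur_phi, _ = _phi_psi_from(coords, conf, ch, res)
            if cur_phi is not None:
                i_n = conf.index_of(ch, res, "N")
                i_ca = conf.index_of(ch, res, "CA")
                # atoms moved: this residue past CA (CB, C, ...) + all later residues
                moved = chain_mask & (
                    (ords > my_ord)
                    | ((ords == my_ord) & ~np.isin(conf.atom_names, ("N", "CA")))
                )
                idx = np.nonzero(moved)[0]
                _rotate_about(
                    coords, idx, coords[i_n], coords[i_ca] - coords[i_n], phi - cur_phi
                )
        if psi is not None:
            _, cur_psi = _phi_psi_from(coords, conf, ch, res)
            if cur_psi is not None:
                i_ca = conf.index_of(ch, res, "CA")
                i_c = conf.index_of(ch, res, "C")
                moved = chain_mask & (ords > my_ord)
                idx = np.nonzero(moved)[0]
                _rotate_about(
                    coords, idx, coords[i_ca], coords[i_c] - coords[i_ca], psi - cur_psi
                )
    return out


def _phi_psi_from(coords: np.ndarray, conf: Conformer, ch: str, res: int):
    phi = psi = None
    try:
        n = coords[conf.index_of(ch, res, "N")]
        ca = coords[conf.index_of(ch, res, "CA")]
        c = coords[conf.index_of(ch, res, "C")]
    except KeyError:
        return None, None
    try:
        cprev = coords[conf.index_of(ch, res - 1, "C")]
        phi = dihedral(cprev, n, ca, c)
    except KeyError:
        pass
    try:
        nnext = coords[conf.index_of(ch, res + 1, "N")]
        psi = dihedral(n, ca, c, nnext)
    except KeyError:
        pass
    return phi, psi


def intra_segment_distances(conf: Conformer, partition: DomainPartition, name: str) -> np.ndarray:
    """Condensed pairwise distance vector of one segment (rigidity checks)."""
    mask = partition.atom_mask(conf, name)
    return pdist(conf.coords[mask])


def max_linker_bond(conf: Conformer, partition: DomainPartition) -> float:
    """Longest backbone bond within/adjacent to flexible segments (sanity)."""
    longest = 0.0
    for s in partition.segments:
        if s.role != "flexible":
            continue
        for res in range(s.start, s.stop + 1):
            for (a1, r1), (a2, r2) in (
                (("N", res), ("CA", res)),
                (("CA", res), ("C", res)),
                (("C", res), ("N", res + 1)),
                (("C", res - 1), ("N", res)),
            ):
                try:
                    d = float(
                        np.linalg.norm(
                            conf.get(s.chain_id, r1, a1) - conf.get(s.chain_id, r2, a2)
                        )
                    )
                except KeyError:
                    continue
                longest = max(longest, d)
    return longest
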