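"""Linker randomization: generating a diverse rigid-body/flexible-linker pool.

Starting from a template conformer, each randomization pass walks the sampled
linker N->C, proposing a fresh uniform (phi, psi) pair per residue.  A
proposal is kept only if the molecule-wide repulsive steric energy does not
rise more than a fractional tolerance (default 10%) above the energy at the
start of the pass -- a clash-avoidance rule rather than a Boltzmann
criterion.  A short three-stage downhill torsion minimization then relaxes
residual contacts.  A run whose final geometry fails the linker bond-length
sanity check is recorded as a rejection.  Everything is a pure function of
(template, partition, config), including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import SamplingError
from .structure import (
    Conformer,
    DomainPartition,
    StericEvaluator,
    StericParams,
    max_linker_bond,
    set_linker_torsions,
)


@dataclass
class SamplingConfig:
    n_attempts: int = 2000
    vdw_tolerance: float = 0.10  # fractional rise allowed over the pass-start energy
    seed: int = 0
    minimize_stages: tuple[float, ...] = (30.0, 10.0, 3.0)  # degrees per stage
    minimize_iters: int = 1  # sweeps per stage
    max_linker_bond: float = 3.0  # Angstrom, geometry sanity
    steric: StericParams = field(default_factory=StericParams)

    def __post_init__(self) -> None:
        if self.n_attempts < 1:
            raise ValueError("n_attempts must be >= 1")
        if self.vdw_tolerance < 0:
            raise ValueError("vdw_tolerance must be >= 0")


@dataclass
class Provenance:
    index: int
    accepted_rotations: int
    proposed_rotations: int
    vdw_energy: float


@dataclass
class ConformerPool:
    members: list[Conformer]
    provenance: list[Provenance]
    attempted: int

    @property
    def accepted(self) -> int:
        return len(self.members)


def _apply_pair(
    conf: Conformer,
    partition: DomainPartition,
    chain: str,
    res: int,
    phi: float | None,
    psi: float | None,
) -> Conformer:
    return set_linker_torsions(conf, partition, {(chain, res): (phi, psi)})


def randomize_linker(
    template: Conformer,
    partition: DomainPartition,
    config: SamplingConfig,
    rng: np.random.Generator,
    evaluator: StericEvaluator | None = None,
) -> tuple[Conformer | None, Provenance]:
    """One randomization pass; returns (conformer | None, provenance).

    None signals a rejected run (final geometry failed the bond sanity
    check); the provenance record is returned either way.
    """
    flexible = partition.flexible_residues(partition.sampled_linker)
    if not flexible:
        raise SamplingError("no flexible residues to sample")
    ev = evaluator or StericEvaluator(template, config.steric)
    conf = template.copy()
    e_start = ev.energy(conf.coords)
    threshold = (1.0 + config.vdw_tolerance) * e_start if e_start > 0 else np.inf
    # a clash-free template (E=0) accepts every proposal, matching the rule's
    # intent of only guarding against clashes introduced by the rotation
    if e_start == 0.0 and np.isfinite(config.vdw_tolerance):
        threshold = _absolute_floor(ev, conf)
    accepted = proposed = 0
    for chain, res in flexible:
        phi, psi = rng.uniform(-180.0, 180.0, size=2)
        proposed += 1
        trial = _apply_pair(conf, partition, chain, res, float(phi), float(psi))
        if ev.energy(trial.coords) <= threshold:
            conf = trial
            accepted += 1
    conf = _minimize(conf, partition, flexible, config, ev, rng)
    prov = Provenance(
        index=-1,
        accepted_rotations=accepted,
        proposed_rotations=proposed,
        vdw_energy=ev.energy(conf.coords),
    )
    if max_linker_bond(conf, partition) > config.max_linker_bond:
        return None, prov
    return conf, prov


def _absolute_floor(ev: StericEvaluator, conf: Conformer) -> float:
    # tolerance relative to a zero reference is ill-defined; use the energy of
    # a single mild contact (0.2 A overlap) as the acceptance ceiling
    return ev.params.k * 0.2**4


def _minimize(
    conf: Conformer,
    partition: DomainPartition,
    flexible: Sequence[tuple[str, int]],
    config: SamplingConfig,
    ev: StericEvaluator,
    rng: np.random.Generator,
) -> Conformer:
    """Three-stage greedy torsion relaxation of steric energy."""
    e = ev.energy(conf.coords)
    for amplitude in config.minimize_stages:
        for _ in range(config.minimize_iters):
            if e == 0.0:
                return conf
            for chain, res in flexible:
                dphi, dpsi = rng.normal(0.0, amplitude, size=2)
                from .structure import get_phi_psi

                phi, psi = get_phi_psi(conf, chain, res)
                trial = _apply_pair(
                    conf,
                    partition,
                    chain,
                    res,
                    None if phi is None else phi + float(dphi),
                    None if psi is None else psi + float(dpsi),
                )
                e_trial = ev.energy(trial.coords)
                if e_trial < e:
                    conf, e = trial, e_trial
    return conf


def generate_pool(
    template: Conformer,
    partition: DomainPartition,
    config: SamplingConfig,
) -> ConformerPool:
    """Run ``n_attempts`` independent randomization passes.

    Deterministic under a fixed config seed: each pass gets its own child
    stream spawned from the config seed, so pools are reproducible
    bit-for-bit regardless of acceptance history.
    """
    ev = StericEvaluator(template, config.steric)
    members: list[Conformer] = []
    provenance: list[Provenance] = []
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_attempts)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        conf, prov = randomize_linker(template, partition, config, rng, evaluator=ev)
        prov.index = i
        if conf is not None:
            members.append(conf)
            provenance.append(prov)
    return ConformerPool(members=members, provenance=provenance, attempted=config.n_attempts)
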