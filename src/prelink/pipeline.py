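"""Workflow orchestration: observables -> restraints -> pool -> ensemble -> SAXS.

A single declarative config drives the integrative modeling run: CSP mapping
selects binding-site residues and emits ambiguous protein-RNA restraints, PRE
tables become flat-bottom distance restraints, the linker is randomized into
a conformer pool, the best candidates are annealed against all restraints,
and the resulting ensemble is validated against a SAXS curve.  All
randomness flows from the config seed, so identical configs give identical
reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annealing import (
    AnnealingSchedule,
    EnergyModel,
    RestraintEvaluator,
    anneal,
    select_ensemble,
)
from .csp import (
    build_ambiguous_restraints,
    compute_csp,
    read_peak_table,
    select_above_threshold,
    write_ambiguous_restraints,
    write_csp_profile,
)
from .exceptions import PrelinkError
from .pre import (
    PREParams,
    SpinLabelSite,
    classify_and_build_restraints,
    read_pre_profile,
    write_restraints_table,
)
from .sampling import SamplingConfig, generate_pool
from .saxs import debye_curve, fit_chi2, read_curve
from .structure import DomainPartition, Segment, read_structure, write_models


class PipelineStageError(PrelinkError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    template_pdb: str
    out_dir: str
    segments: list[dict]
    sampled_linker: str
    peaks_free: str
    peaks_bound: str
    pre_tables: dict[int, str]  # label-site residue -> profile path
    saxs_data: str | None = None
    protein_chain: str = "A"
    rna_chain: str = "R"
    rna_positions: list[int] = field(default_factory=lambda: list(range(6, 13)))
    csp_alpha: float = 0.2
    csp_threshold: float = 0.08
    restraint_domain: str | None = None  # default: last rigid segment
    ambiguous_target: float = 4.0
    ambiguous_halfwidth: float = 1.0
    tauc_ns: float = 12.0
    field_1h_mhz: float = 600.0
    t_evol_s: float = 0.010
    r2_dia: float = 15.0
    n_attempts: int = 2000
    vdw_tolerance: float = 0.10
    n_candidates: int = 20  # pool members carried into annealing
    ensemble_k: int = 10
    anneal_steps: tuple[int, int, int] = (2000, 2000, 1000)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["pre_tables"] = {int(k): v for k, v in data.get("pre_tables", {}).items()}
        if "anneal_steps" in data:
            data["anneal_steps"] = tuple(data["anneal_steps"])
        return cls(**data)

    def partition(self) -> DomainPartition:
        segs = [
            Segment(s["name"], s.get("chain", self.protein_chain), int(s["start"]), int(s["stop"]), s["role"])
            for s in self.segments
        ]
        return DomainPartition(segments=segs, sampled_linker=self.sampled_linker)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute csp -> pre -> sample -> anneal -> saxs-fit; returns the report.

    Outputs written to ``config.out_dir``: the CSP profile, both restraint
    tables, the ensemble as a multi-model PDB, a per-model energy table and a
    JSON summary.  A stage failure aborts with the stage name; partial
    outputs remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    partition = config.partition()
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    artifacts: dict = {}

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
            report["stages"][name] = result
            return result

        return deco

    @stage("csp")
    def _csp():
        free = read_peak_table(config.peaks_free)
        bound = read_peak_table(config.peaks_bound)
        profile = compute_csp(free, bound, alpha=config.csp_alpha)
        write_csp_profile(profile, out / "csp_profile.tsv")
        hits = select_above_threshold(profile, config.csp_threshold)
        domain = config.restraint_domain or partition.rigid_segments()[-1].name
        seg = partition.segment(domain)
        in_domain = [r for r in hits if seg.start <= r <= seg.stop]
        restraints = build_ambiguous_restraints(
            in_domain,
            config.rna_positions,
            target=config.ambiguous_target,
            halfwidth=config.ambiguous_halfwidth,
            protein_chain=config.protein_chain,
            rna_chain=config.rna_chain,
        )
        write_ambiguous_restraints(restraints, out / "ambiguous_restraints.tsv")
        artifacts["ambiguous"] = restraints
        return {
            "n_profile": len(profile),
            "n_above_threshold": len(hits),
            "restraint_domain": domain,
            "n_ambiguous_restraints": len(restraints),
        }

    ambiguous = artifacts["ambiguous"]

    @stage("pre")
    def _pre():
        params = PREParams(
            tauc_ns=config.tauc_ns,
            field_1h_mhz=config.field_1h_mhz,
            t_evol_s=config.t_evol_s,
            r2_dia=config.r2_dia,
        )
        restraints = []
        for site_res, path in sorted(config.pre_tables.items()):
            profile = read_pre_profile(path)
            site = SpinLabelSite(residue_number=site_res, chain_id=config.protein_chain)
            restraints.extend(
                classify_and_build_restraints(
                    profile, site, params, chain_id=config.protein_chain
                )
            )
        write_restraints_table(restraints, out / "pre_restraints.tsv")
        counts: dict[str, int] = {}
        for r in restraints:
            counts[r.klass] = counts.get(r.klass, 0) + 1
        artifacts["pre"] = restraints
        return {"n_restraints": len(restraints), "by_class": counts}

    pre_restraints = artifacts["pre"]

    template = read_structure(config.template_pdb)

    @stage("sample")
    def _sample():
        cfg = SamplingConfig(
            n_attempts=config.n_attempts,
            vdw_tolerance=config.vdw_tolerance,
            seed=config.seed,
        )
        pool = generate_pool(template, partition, cfg)
        artifacts["pool"] = pool
        return {"attempted": pool.attempted, "accepted": pool.accepted}

    pool = artifacts["pool"]

    @stage("anneal")
    def _anneal():
        evaluator = RestraintEvaluator(
            template,
            distance_restraints=pre_restraints,
            ambiguous_restraints=ambiguous,
            model=EnergyModel(),
            partition=partition,
        )
        scored = [
            evaluator.score(c, provenance=p.index)
            for c, p in zip(pool.members, pool.provenance)
        ]
        scored.sort(key=lambda s: (s.total, s.provenance))
        n_cand = min(config.n_candidates, len(scored))
        schedule = AnnealingSchedule(steps=tuple(config.anneal_steps))
        rng_root = np.random.SeedSequence(config.seed + 1)
        refined = []
        for child, sc in zip(rng_root.spawn(n_cand), scored[:n_cand]):
            refined.append(
                anneal(
                    sc.conformer,
                    evaluator,
                    schedule,
                    partition,
                    np.random.default_rng(child),
                    provenance=sc.provenance,
                )
            )
        k = min(config.ensemble_k, len(refined))
        ensemble, (rmsd_mean, rmsd_sd) = select_ensemble(refined, k=k)
        write_models([sc.conformer for sc in ensemble], out / "ensemble.pdb")
        with open(out / "energies.tsv", "w") as fh:
            fh.write("model\tprovenance\ttotal\tdistance\tambiguous\tsteric\tbonded\n")
            for i, sc in enumerate(ensemble, start=1):
                t = sc.terms
                fh.write(
                    f"{i}\t{sc.provenance}\t{sc.total:.6g}\t{t['distance']:.6g}"
                    f"\t{t['ambiguous']:.6g}\t{t['steric']:.6g}\t{t['bonded']:.6g}\n"
                )
        artifacts["ensemble"] = ensemble
        return {
            "n_annealed": n_cand,
            "ensemble_k": k,
            "ensemble_rmsd_mean": rmsd_mean,
            "ensemble_rmsd_sd": rmsd_sd,
            "best_energy": ensemble[0].total,
        }

    ensemble = artifacts["ensemble"]

    if config.saxs_data:

        @stage("saxs")
        def _saxs():
            data = read_curve(config.saxs_data)
            chis = []
            for sc in ensemble:
                model = debye_curve(sc.conformer, data.q)
                chi2, c, b = fit_chi2(model, data)
                chis.append(chi2)
            return {
                "chi2_best": chis[0],
                "chi2_min": min(chis),
                "chi2_max": max(chis),
            }

    (out / "summary.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
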