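"""The full workflow through the pipeline driver: fixture -> report.

Writes a synthetic fixture directory (peak tables, PRE profiles, SAXS curve,
template PDB), then runs csp -> pre -> sample -> anneal -> saxs from a
single config.  Scaled down to run in ~20 s; raise n_attempts / n_candidates
/ anneal_steps for production-quality ensembles.
"""

import json
import tempfile
from pathlib import Path

import numpy as np

from prelink.pipeline import PipelineConfig, run_pipeline
from prelink.synthetic import NoiseConfig, make_toy_complex, simulate_observables, write_fixture_dir

workdir = Path(tempfile.mkdtemp(prefix="prelink_demo_"))
conf, partition, truth = make_toy_complex()
bundle = simulate_observables(truth, NoiseConfig(), np.random.default_rng(0))
fixture = workdir / "fixture"
write_fixture_dir(truth, bundle, fixture)
meta = json.loads((fixture / "truth.json").read_text())

config = PipelineConfig(
    template_pdb=str(fixture / "truth.pdb"),
    out_dir=str(workdir / "run"),
    segments=meta["segments"],
    sampled_linker=meta["sampled_linker"],
    peaks_free=str(fixture / "peaks_free.tsv"),
    peaks_bound=str(fixture / "peaks_bound.tsv"),
    pre_tables={s: str(fixture / f"pre_site{s}.tsv") for s in meta["label_sites"]},
    saxs_data=str(fixture / "saxs.dat"),
    tauc_ns=meta["tauc_complex_ns"],
    field_1h_mhz=meta["field_1h_mhz"],
    t_evol_s=meta["t_evol_s"],
    r2_dia=meta["r2_dia"],
    n_attempts=6, n_candidates=3, ensemble_k=3, anneal_steps=(300, 300, 150),
    seed=0,
)
report = run_pipeline(config)
print(json.dumps(report["stages"], indent=1, sort_keys=True))
print(f"outputs in {workdir / 'run'} (ensemble.pdb, restraint tables, summary.json)")
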