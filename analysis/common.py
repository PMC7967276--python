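"""Shared plumbing for the numbered analysis scripts.

The simulated study and the pipeline run live under scratch/ (large,
regenerated on demand); the scripts copy the small summary tables they
discuss into results/.
"""

from __future__ import annotations

import shutil
from pathlib import Path

from divtss.pipeline import PipelineConfig, run_pipeline
from divtss.simulate import default_config, write_fixture

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 17


def ensure_study():
    """Simulate the study and run the pipeline once; reuse thereafter."""
    fixture_dir = SCRATCH / "fixture"
    run_dir = SCRATCH / "run"
    config = default_config(mismatch_read_fraction=0.0)
    if not (run_dir / "manifest.json").exists():
        fx = write_fixture(config, SEED, fixture_dir)
        run_pipeline(
            PipelineConfig(
                genome=fx.paths["genome"],
                annotation=fx.paths["annotation"],
                conditions=fx.paths["sam"],
                outdir=run_dir,
                predicted_tss=fx.paths["predicted_tss"],
            )
        )
    return config, fixture_dir, run_dir


def publish(src: Path, name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    dst = RESULTS / name
    shutil.copyfile(src, dst)
    return dst
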