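"""Shared configuration for the numbered analysis scripts.

The study run writes its raw artifacts (TIFF stacks, per-scene sidecars)
under scratch/, which is disposable; each stage script copies the tables
it produces into results/ so the analysis outputs survive a scratch
cleanup. All scripts share one seed and one parameter set, so rerunning
01..05 in order reproduces results/ byte for byte.
"""

import shutil
from pathlib import Path

from wormnai.pipeline import PipelineConfig

REPO = Path(__file__).resolve().parent.parent
RUN_DIR = REPO / "scratch" / "study"
RESULTS = REPO / "results"


def study_config() -> PipelineConfig:
    cfg = PipelineConfig(output_dir=RUN_DIR, rng_seed=20240601)
    cfg.validate()
    return cfg


def publish(*names: str) -> None:
    """Copy named tables from the run directory into results/."""
    RESULTS.mkdir(exist_ok=True)
    for name in names:
        shutil.copy2(RUN_DIR / name, RESULTS / name)
        print(f"results/{name}")
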