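"""Stage 2: extract dF/F0 traces from the imaging stacks.

Background subtraction, 3x3 smoothing, constrained maximum-intensity
tracking from each seed, motion viability check, and dF/F0 against the
first-second baseline. Per-scene trace tables stay next to the stacks in
scratch/ (they are per-frame and large); stage 3 reduces them.
"""

import logging

import pandas as pd
from common import RUN_DIR, study_config

from wormnai.pipeline import run_extract

if __name__ == "__main__":
    logging.basicConfig(level=logging.INFO)
    scenes = run_extract(study_config())
    total = viable = 0
    for name in scenes.scene:
        per_animal = (
            pd.read_csv(RUN_DIR / "stacks" / f"{name}_traces.csv")
            .groupby("animal_id").viable.first()
        )
        total += len(per_animal)
        viable += int(per_animal.sum())
    print(f"extracted {total} traces across {len(scenes)} scenes, {viable} viable")
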