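"""Stage 1: simulate the study dataset.

Generates the imaging arm (per-subject, per-session calcium stacks with
ground-truth sidecars) and the count-level cohort (36 + 36 subjects with
session activation counts and chemotaxis plate counts). Raw stacks land
in scratch/; the cohort tables are published to results/.
"""

from common import publish, study_config

from wormnai.pipeline import run_simulate

if __name__ == "__main__":
    cfg = study_config()
    out = run_simulate(cfg, force=True)
    print(f"simulated dataset in {out}")
    publish("cohort.csv", "plates.csv", "scenes.csv", "truth.csv")
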