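"""Stage 4: per-subject indices for the full cohort.

Aggregates the count-level cohort (sessions of 25 worms each) into one
record per subject: mean NAI across sessions, session and binomial
standard deviations, and the plate-level chemotaxis index.
"""

from common import publish, study_config

from wormnai.pipeline import run_indices

if __name__ == "__main__":
    subjects = run_indices(study_config(), use_imaging=False)
    g = subjects.groupby("group")["nai_mean"].agg(["mean", "std", "count"])
    print(g.to_string())
    publish("subjects.csv")
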