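"""Stage 5: cohort discrimination.

Zero-threshold sign classifier on the subject NAIs, confusion metrics,
ROC/AUC for CI, NAI and the first principal component, and the
two-variable PCA of (CI, NAI).
"""

from common import publish, study_config

from wormnai.pipeline import run_discriminate

if __name__ == "__main__":
    report = run_discriminate(study_config())
    print(report.to_series().to_string())
    publish("report.csv", "predictions.csv")
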