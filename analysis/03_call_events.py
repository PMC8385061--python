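"""Stage 3: call activation events on the extracted traces.

Applies the 3-sigma rule on the bracketing 10-s windows around odor
removal and reduces each scene to session counts (N_act / N_tot over
viable animals).
"""

from common import publish, study_config

from wormnai.pipeline import run_call

if __name__ == "__main__":
    sessions = run_call(study_config())
    print(sessions.to_string(index=False))
    publish("calls.csv", "sessions.csv")
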