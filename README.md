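# wormnai

Synthetic-data pipeline for odor-evoked calcium imaging of *C. elegans*
AWC^ON neurons and cohort-level discrimination of cancer vs control
urine samples.

## Scientific problem

*C. elegans* is attracted to volatiles in urine from breast-cancer
patients. Two readouts quantify this:

- **Chemotaxis Index (CI)** on quadrant plates:
  `CI = (n_odorant − n_control) / n_total ∈ [−1, 1]`.
- **Neuronal Activation Index (NAI)** from wide-field calcium imaging of
  many immobilized worms in a microfluidic pulse arena:
  `NAI = 2 (N_act / N_tot − 0.5) ∈ [−1, 1]`,
  where `N_act` is the number of viable animals whose AWC^ON neuron
  activated upon odor **removal** (AWC^ON is an odor-OFF neuron) and
  `N_tot` the number of viable animals.

The stimulus protocol is 10 s buffer / 20 s odor / 30 s buffer at
10 frames/s. A trace counts as activated when the mean ΔF/F₀ in the
first 10 s after odor removal exceeds the mean of the last 10 s of odor
by more than 3 on-stimulus standard deviations. Subjects are classified
by the sign of their mean NAI (positive → cancer).

Because no raw recordings are publicly deposited, this package pairs the
full analysis chain with a **synthetic generator** that renders
multi-animal fluorescence stacks (Gaussian neuron blobs, GCaMP-like
off-transients, optional motion and noise) and count-level cohorts with
known ground truth, so every stage can be validated against the truth it
was generated from.

## Modules

| Module | Contents |
| --- | --- |
| `wormnai.synth` | scene/stack generator, cohort and plate-count generators, ground-truth sidecars |
| `wormnai.stackproc` | background subtraction, smoothing, constrained 5×5 max-intensity tracking (≤30 px/step), ΔF/F₀, frame-difference motion check |
| `wormnai.eventcall` | 3σ activation rule on bracketing 10-s windows, activation rate, dose contrast |
| `wormnai.indices` | NAI, CI, binomial dispersion, session-policy aggregation, single-worm sector score |
| `wormnai.cohortstats` | sign classifier, confusion metrics, ROC/AUC, two-variable PCA of (CI, NAI) |
| `wormnai.pipeline` / `wormnai.cli` | stage orchestration and the `wormnai` command (`simulate`, `extract`, `call`, `indices`, `discriminate`, `all`) |

## Worked example

```python
from wormnai import (
    SyntheticSceneSpec, generate_stack, seeds_from_ground_truth,
    extract_traces, call_activation, compute_nai,
)

spec = SyntheticSceneSpec(n_animals=6, rng_seed=7)       # 192x192, 600 frames
stack, truth = generate_stack(spec)
seeds = seeds_from_ground_truth(truth)
tracks = extract_traces(stack, seeds, motion_mask_radius=14)
calls = [call_activation(t, stack.protocol) for t in tracks if t.viable]
n_act = sum(c.responded for c in calls)
print(compute_nai(n_act, len(calls)))
```

Running the numbered scripts in `analysis/` (see below) on the default
study configuration (36 + 36 subjects, 2 sessions × 25 worms, activation
probabilities 0.8 vs 0.2, seed 20240601) gives:

```
group NAI means      cancer +0.592, control −0.582
imaging arm          96 traces / 16 scenes, 88 viable (8 motion-excluded,
                     matching the generator's sidecar exactly)
sign classifier      sensitivity 1.00, specificity 1.00, accuracy 1.00
AUC (CI / NAI / PC1) 1.00 / 1.00 / 1.00
PC1 variance share   0.984
```

## Analysis scripts

`analysis/01_simulate.py` … `05_discriminate.py` are thin, numbered
drivers over `wormnai.pipeline`: simulate → extract traces → call events
→ per-subject indices → discrimination, with an optional
`06_dose_contrast_scan.py`. Raw stacks go to `scratch/` (disposable);
each stage publishes its tables to `results/`. Rerunning 01–05 in order
reproduces `results/` byte for byte. The same chain is available as
`wormnai all --config cfg.yaml`.

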