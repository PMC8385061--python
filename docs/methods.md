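# Methods

## Model

### Imaging scene

A scene is a 16-bit stack of `T` frames covering the full stimulus
protocol (10 s buffer, 20 s odor, 30 s buffer; default 10 frames/s,
T = 600) plus 20 stimulus-free background frames. Each animal's AWC^ON
soma is rendered as an isotropic Gaussian blob (σ = 3 px, truncated at
4σ) on a constant background (default 200 counts). Responders carry a
multiplicative off-transient

```
F(t) = F_rest · (1 + A · g(t − t_off)),   g = difference of exponentials
```

with rise τ = 0.5 s and decay τ = 5 s (GCaMP3-like kinetics), normalized
so the **sampled** peak equals the configured amplitude `A` exactly.
Because the transient scales the whole spatial profile, the recovered
ΔF/F₀ peak equals `A` under any linear spatial smoothing — an exactness
property the tests rely on. Blob centers are integers, so constrained
maximum-intensity tracking is position-exact on noise-free scenes.
Motion is either a single jump (default 12 px, in the middle half of the
recording) or constant drift; a configurable fraction of animals moves.

### Counts

The count-level generator draws per-session activation counts
`N_act ~ Binomial(N_worms, p_act)` with `p_act` = 0.8 (cancer) / 0.2
(control), and quadrant-plate counts from a multinomial with
`E[CI] = attraction` (default ±0.35, 10% neutral worms, 60 worms ×
3 plates). These defaults are the study conditions; they were fixed
before outcomes were inspected and never adjusted afterward.

## Analysis chain

1. **Background subtraction** — mean of the 20 background frames,
   subtracted and clipped at 0 (16-bit dialect).
2. **Smoothing** — k×k uniform filter per frame (default 3), reflect
   boundaries.
3. **Tracking** — from the reference frame (2 s after odor removal),
   bidirectionally: next position is the argmax of the 5×5-patch mean
   over candidates within Chebyshev distance 30 of the previous
   position, clipped to the ROI with a 2-px patch margin; ties break
   row-major (the `argmax` contract).
4. **ΔF/F₀** — `F` is the 5×5-patch mean at the tracked position;
   `F₀` is the mean of the first 10 frames; `F₀ ≤ 0` marks the trace
   non-viable ("zero baseline").
5. **Motion check** — `ID_{i,i+1} = Σ |frame_{i+1} − frame_i|` over the
   ROI; a trace is viable iff every `ID_i < mean + sd` over the window
   `i−20 … i+20`.
6. **Activation** — `(I_off − I_on) > 3 σ_on`, where `I_on` is the mean
   ΔF/F₀ over the last 10 s of odor, `I_off` over the first 10 s after
   removal, and `σ_on` the sample sd of the on-window.
7. **Indices & cohort** — per-session NAI; subjects aggregate sessions
   with an unweighted mean (policy: ≥2 sessions × ≥25 worms → ≥50 worms
   per subject; violations warn, not fail). Discrimination uses the
   zero-threshold sign classifier, ROC/AUC, and a PCA of the 2×2
   covariance of (CI, NAI) with PC1 sign fixed so the cancer group mean
   is positive.

## Motion-criterion analysis

Two properties of the for-all `ID < mean + sd` criterion deserve note.

**Calcium transients register as "motion."** On a noise-free responder
scene the only frame-to-frame change is the transient itself, so its
rise/fall dominates the ID series and rejects a perfectly still animal.
We therefore exclude a fixed disk (default radius 14 px: rendered blob
radius 12 + smoothing halo) around the *seed* position from the ID sum.
The disk is deliberately **not** tracked: the tracker follows
displacements up to 30 px/frame, so a tracked mask would move with — and
hide — the very jump the check must detect, whereas any displacement
beyond the fixed disk's edge still registers.

**I.i.d. noise rejects almost everything.** For i.i.d. Gaussian pixel
noise each ID is approximately normal, ~16% of frame pairs exceed
`mean + sd`, and the probability that all `n` pairs pass is ≈ 0.84ⁿ → 0.
This is a property of the criterion, not a bug; the criterion is
implemented exactly as specified, and the default study condition uses
noise-free rendering rather than a weakened threshold. The oracle tests
exercise the criterion both in this near-degenerate regime (per-series
exact agreement) and on short series where the decision genuinely
splits.

**Numerical floor.** Uniform filtering of constant regions leaves float
dust (~1e-11) that would otherwise create spurious nonzero dispersion;
IDs below `atol = 1e-6` are floored to 0. Windows with zero dispersion
(sd = 0, all IDs equal to the mean) pass: a static scene with all
ID = 0 is viable, and the strict inequality applies whenever the window
has any dispersion.

## Conventions and open-question resolutions

- Sample standard deviations use ddof = 1 (MATLAB convention) for both
  `σ_on` and the motion-window sd.
- Activation windows: `I_on` occupies the 10 s immediately **before**
  odor removal, `I_off` the 10 s immediately after, so the two windows
  bracket the off-transient.
- `dose_contrast` defaults to the rate **difference** (cancer − control);
  a ratio mode is available.
- Both NAI dispersions are reported per subject: the empirical sd across
  sessions and the binomial sd `2 √(p(1−p)/n)` at the subject's pooled
  worm count.
- The single-worm sector score sums **distinct** sectors visited
  (default scores A…E = 2, 1, 0, −1, −2); repeat visits count once.
- Classifier ties (score exactly 0) predict control, the conservative
  direction for a screening readout.
- Problem sizes in the shipped configuration (scene size 192×192,
  6 animals/scene, 4 imaging subjects per group) are the package's own
  choices, sized so the full imaging arm runs in seconds while the
  count-level cohort matches the study's 36 + 36 design.

## Generator realism limits

The generator validates the analysis chain; it does not emulate
microscopy. Omitted: photobleaching, worm body autofluorescence and
non-rigid body motion, flow artifacts at valve switches, shot-noise
scaling with intensity, optical blur beyond the Gaussian soma profile,
and AWC^OFF/AWC^ON asymmetry (only the odor-OFF neuron is modeled;
`hyperpolarization` crudely models on-stimulus dips). Headline cohort
numbers from real recordings are therefore out of scope; the synthetic
cohorts instead support property-based validation (parameter recovery,
oracle equivalence, exactness on noise-free fixtures).
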