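# twinbrain

Connectome-conditioned "digital twin" modeling of task behavior and regional
BOLD dynamics, with the full downstream analysis stack: a hypernetwork (MLP
with Mish activations) maps an individual's resting-state functional
connectome vector (rsFCM) to the complete parameter set of a vanilla
recurrent main network, which rolls out button presses and regional BOLD
time series from sensory + task-condition input at 80-ms resolution.
On top of the trained twin the package provides:

- **GLM indicators** — Glover-HRF + temporal-derivative designs with DCT
  drift, OLS contrast t-statistics (`face>shape`, `incongruent>congruent`),
  group one-sample t-tests;
- **PLS intervention vectors** — closed-form single-component directions over
  main-network parameter space maximizing covariance with a functional
  indicator (right-amygdala contrast t, or mean reaction time), plus
  clinical-measure correlations with Benjamini–Hochberg FDR;
- **SmoothGrad edge targeting** — noise-averaged input gradients through the
  hypernetwork identifying which connectome edges to strengthen/weaken;
- **in-silico intervention simulation** — weight-space perturbations
  (α in SD-of-latent-score units) with pre/post indicator comparison and
  standardized effect sizes;
- **a synthetic cohort generator** — virtual participants with planted
  trait → connectome and trait → behavior/BOLD structure, so the entire
  pipeline is testable end to end without external data.

No GPU autograd framework is required: the hypernetwork, the RNN rollout,
and end-to-end training (BPTT through the RNN into the hypernetwork, Adam)
are implemented in numpy with hand-written backprop, verified against finite
differences in the test suite.

## CLI

The `twinbrain` command chains the pipeline phases; each phase writes its
artifacts plus a provenance manifest (config hash, seeds, input hashes):

```bash
twinbrain simulate-cohort --config configs/toy.yaml
twinbrain preprocess      --config configs/toy.yaml
twinbrain train           --config configs/toy.yaml
twinbrain evaluate        --config configs/toy.yaml
twinbrain glm             --config configs/toy.yaml
twinbrain pls             --config configs/toy.yaml --indicator cognitive
twinbrain intervene       --config configs/toy.yaml --vector cognitive --alpha-sd 2.0
```

Global flags: `--seed`, `--out`, `--log-level` (all override the YAML).
`configs/toy.yaml` runs the whole chain at toy scale in well under 15 min.

## Layout

```
src/twinbrain/
  regions.py           atlas registry and the 20-region modeling set
  synthetic_cohort.py  virtual participants (schedules, behavior, BOLD, rsFCM)
  preprocess.py        rsFCM vectorization, resampling, normalization, splits
  task_codec.py        event <-> channel encoding/decoding, RT/concordance
  twin_model.py        hypernetwork + RNN, packing, backprop, checkpoints
  training.py          segmentation, composite loss, Adam, evaluation metrics
  glm.py               Glover HRF, design matrices, OLS fits, contrasts
  indicators_pls.py    functional indicators, PLS directions, FDR correlations
  intervention.py      SmoothGrad maps, edge reports, weight perturbation
  presets.py           deterministic toy-scale recipes used by tests
  cli.py               phase orchestration
```

### Scale notes

Full-scale defaults (99,235-edge rsFCMs, 400 hidden units, lr 1e-6, equal
action/BOLD loss weights, dropout 0.1) are preserved on the config objects;
the committed toy configuration scales these down (32/32 hidden, lr 3e-3,
action loss weight 10, dropout 0) so training converges within minutes at
40 participants. Headline full-scale results require the external dataset
and are out of scope here; the toy chain instead verifies trait recovery,
oracle equivalence, intervention contracts, and determinism.
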