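# actinf

Discrete-state active inference with two coexisting action-selection
pathways:

* a **representational** route — Bayesian state inference by variational
  free-energy minimization, followed by expected-free-energy (EFE) planning
  with its instrumental/epistemic decomposition and a softmax policy
  posterior;
* a **deontic** route — a cue-conditioned policy likelihood `P(o | π)` whose
  log value can *supplement* the negated EFE inside the policy softmax, or
  *supplant* it entirely, in which case action selection reads only the
  current observation and never touches beliefs about hidden states.

An agent–environment simulator (with the generative process held strictly
separate from the agent's model) demonstrates habit acquisition: a
representational phase accumulates Dirichlet-style cue–policy counts, after
which the agent can act through the learned deontic mapping alone.

## Layout

| Module | Contents |
| --- | --- |
| `actinf.model_core` | model types (`GenerativeModel`, `DeonticModel`), validation, JSON/YAML (de)serialization, random-model fixtures |
| `actinf.perception` | marginal likelihood, exact Bayes posterior, variational free energy with its KL + evidence decomposition, fixed-point and mirror-descent inference |
| `actinf.planning` | belief rollouts, per-policy per-step EFE, policy posterior, action selection |
| `actinf.deontic` | deontic log likelihood, pathway combination (`representational` / `supplement` / `supplant`), count-based learning |
| `actinf.simulator` | `Environment`, episode loop, traffic-light and epistemic-probe scenarios, habitization experiment |
| `actinf.cli` | the `aif` command-line interface |

The model-spec JSON format is documented by
`src/actinf/schema/model_spec.schema.json`.

## CLI

```sh
aif validate model.json                 # invariant report (JSON)
aif infer model.json --obs 0            # Q, F, KL/evidence split
aif efe model.json                      # per-policy/per-step EFE table + posteriors
aif deontic model.json --obs 0          # ln P(o|π) for a cue
aif simulate model.json --mode supplant --steps 20 --seed 3 --out run/
aif habitize --scenario traffic-light --episodes 100 --seed 7 --out run/
```

`simulate` and `habitize` also accept `--config cfg.yaml` mirroring their
flags; explicit CLI flags override the config file.

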