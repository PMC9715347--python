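# fedstar

A desk-scale **federated learning runtime** with a star topology: one
aggregator, N collaborators, a declarative federation plan, and nothing
leaving a site except model weights and scalar metrics.

Federated learning (FL) lets hospitals, labs, and other data holders train
one shared model without pooling their data — the model travels to the
data, not the other way around. `fedstar` implements that workflow end to
end at a scale that fits on a laptop: it is built for methodologists who
want to study aggregation rules, straggler policies, and federated-vs-
centralized behaviour under *controlled, reproducible* conditions, using
synthetic multi-site biomedical tasks instead of protected patient data.

## What it does

* **Federation plan** (`fedstar.plan`) — a YAML contract agreed before
  training: rounds, tasks (train/validate with epochs, batch size,
  learning rate), collaborator roster, aggregation method, straggler
  policy, network address. Canonical serialization is byte-deterministic;
  workspaces (plan + task code) export to reproducible `.tar.gz` archives.
* **Named tensors** (`fedstar.tensors`) — model state in transit as
  float32 tensors keyed by (name, origin, round, tags), with a
  deterministic, CRC-checked binary frame format.
* **Consensus aggregation** (`fedstar.aggregation`) — dataset-size-
  weighted averaging (FedAvg) and coordinate-wise median built in, plus a
  registry for custom aggregation strategies addressed from the plan. For
  collaborator updates x_i with declared local dataset sizes n_i, the
  consensus is

      w = Σ_i n_i · x_i / Σ_i n_i          (element-wise)

  accumulated in float64 with pairwise summation, cast back to float32 —
  making the result invariant to submission order.
* **Aggregator** (`fedstar.aggregator`) — synchronous rounds: assigns the
  plan's tasks once per (collaborator, round), collects submissions,
  closes a round when everyone reported *or* the cutoff has passed with at
  least ⌈min_reporting_fraction × roster⌉ submissions. Late results are
  discarded, duplicates keep the first, and a below-quorum cutoff halts
  the federation loudly. The clock is injected, so every straggler
  scenario is unit-testable.
* **Collaborator** (`fedstar.collaborator`) — pulls tasks, trains locally
  behind a `FrameworkAdapter` contract, submits weights + metrics. Two
  deterministic reference learners ship: full/mini-batch logistic
  regression (tabular risk task) and pixel-wise logistic segmentation
  (lesion-boundary task). Submissions structurally cannot carry data.
* **Transport + identity** (`fedstar.transport`, `fedstar.identity`) —
  seven fixed envelope kinds, nothing else dispatchable; an in-process
  transport for deterministic simulation and a mutually-authenticated TLS
  transport for real sockets; a test-grade PKI workshop (internal CA, CSR
  signing, peer verification) enforcing RSA-3072/SHA-384 or secp384r1
  floors. The internal CA is **for testing and research only**.
* **Synthetic federation** (`fedstar.synthetic`) — multi-site generators
  with a single `site_shift` dial sweeping IID → non-IID, and a parity
  harness that runs the same learner federated and centralized with a
  matched epoch budget.

## Worked example

Four synthetic hospitals with different sample sizes and a per-site
covariate shift train a shared logistic risk model for 15 rounds:

```python
from fedstar import LogisticAdapter
from fedstar.plan import FLPlan, TaskSpec, AggregationSpec
from fedstar.synthetic import SiteConfig, generate_tabular_task, run_simulation

cfg = SiteConfig(n_sites=4, sizes=[200, 400, 600, 800], feature_dim=10,
                 site_shift=1.5, noise_sd=0.5, class_balance=0.5, seed=42)
sites, holdout = generate_tabular_task(cfg, n_holdout=1000)

plan = FLPlan(
    rounds_to_train=15,
    tasks={
        "train": TaskSpec("train", epochs_per_round=2, learning_rate=0.5,
                          batch_size="full"),
        "validate": TaskSpec("validate", metrics=["accuracy", "loss"]),
    },
    collaborators=["site_0", "site_1", "site_2", "site_3"],
    aggregation=AggregationSpec("weighted_mean"),
    seed=42,
)

factory = lambda: LogisticAdapter(10)
report = run_simulation(plan, sites, factory, factory().get_state(),
                        holdout=holdout)
print(f"federated accuracy:    {report.trajectory[-1]:.3f}")
print(f"centralized accuracy:  {report.centralized_metric:.3f}")
print(f"gap:                   {report.gap:+.3f}")
print(f"single-site baselines: {[round(v, 3) for v in report.single_site_metrics]}")
```

Output:

```
federated accuracy:    0.769
centralized accuracy:  0.770
gap:                   -0.001
single-site baselines: [0.764, 0.766, 0.773, 0.77]
```

The federated consensus matches centralized training on the pooled data
to within a tenth of a percentage point — the core empirical claim of the
FL paradigm — while no site's arrays ever crossed the (simulated) wire.

## Command line

```bash
fedstar plan init --out plan.yaml -c site_a -c site_b
fedstar plan validate plan.yaml
fedstar workspace export --plan plan.yaml --code-root code/ --out ws.tar.gz
fedstar cert ca --name fedroot              # test-only internal CA
fedstar cert request --subject site_a
fedstar cert sign --ca-name fedroot --csr site_a.csr --subject site_a --out site_a.crt
fedstar aggregator start --plan plan.yaml --identity-dir ids/ --init init.npz
fedstar collaborator start --plan plan.yaml --id site_a --identity-dir ids/ --data site_a.npz
fedstar simulate run --plan plan.yaml --fixtures fixtures/ --log-json
```

Exit codes: 0 success, 1 usage, 2 validation (violations printed), 3
runtime failure.

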