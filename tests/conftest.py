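import numpy as np
import pytest

from fedstar.plan import (
    AggregationSpec,
    FLPlan,
    NetworkSpec,
    StragglerSpec,
    TaskSpec,
)

PLAN_TEXT = """\
plan_version: '1.0'
rounds_to_train: 10
tasks:
  train:
    kind: train
    epochs_per_round: 1
    learning_rate: 0.5
    batch_size: full
  validate:
    kind: validate
    metrics: [accuracy, loss]
collaborators: [site_a, site_b, site_c]
aggregation:
  method: weighted_mean
straggler:
  min_reporting_fraction: 0.5
  round_cutoff: 100.0
network:
  host: localhost
  port: 50051
seed: 0
"""


@pytest.fixture
def plan_text():
    return PLAN_TEXT


def make_plan(
    rounds=3,
    collaborators=("site_a", "site_b", "site_c"),
    method="weighted_mean",
    min_fraction=1.0,
    cutoff=float("inf"),
    epochs=1,
    lr=0.5,
    batch_size="full",
    seed=0,
):
    return FLPlan(
        rounds_to_train=rounds,
        tasks={
            "train": TaskSpec(
                "train", epochs_per_round=epochs, learning_rate=lr, batch_size=batch_size
            ),
            "validate": TaskSpec("validate", metrics=["accuracy", "loss"]),
        },
        collaborators=list(collaborators),
        aggregation=AggregationSpec(method=method),
        straggler=StragglerSpec(min_reporting_fraction=min_fraction, round_cutoff=cutoff),
        network=NetworkSpec(),
        seed=seed,
    )


def random_plan(rng):
    """A random *valid* plan, for round-trip and fuzz tests."""
    n_collab = int(rng.integers(1, 6))
    tasks = {
        "train": TaskSpec(
            "train",
            epochs_per_round=int(rng.integers(1, 5)),
            learning_rate=float(np.round(10 ** rng.uniform(-3, 0), 6)),
            batch_size="full" if rng.random() < 0.5 else int(rng.integers(1, 64)),
        )
    }
    if rng.random() < 0.7:
        tasks["validate"] = TaskSpec(
            "validate",
            metrics=[str(m) for m in rng.choice(["accuracy", "loss", "dice"], 2, replace=False)],
        )
    return FLPlan(
        rounds_to_train=int(rng.integers(1, 50)),
        tasks=tasks,
        collaborators=[f"site_{i}" for i in range(n_collab)],
        aggregation=AggregationSpec(method="weighted_mean" if rng.random() < 0.5 else "median"),
        straggler=StragglerSpec(
            min_reporting_fraction=float(np.round(rng.uniform(0.01, 1.0), 4)),
            round_cutoff=float(np.round(rng.uniform(1, 1000), 3)),
        ),
        network=NetworkSpec(host="localhost", port=int(rng.integers(1, 65536))),
        seed=int(rng.integers(0, 2**31)),
    )


def random_tensor(rng, name="w", origin="site_a", round_num=0, tags=("trained",), max_rank=4):
    rank = int(rng.integers(0, max_rank + 1))
    shape = tuple(int(rng.integers(1, 5)) for _ in range(rank))
    values = rng.standard_normal(shape).astype(np.float32)
    from fedstar.tensors import NamedTensor, TensorKey

    return NamedTensor(TensorKey(name, origin, round_num, frozenset(tags)), values)


@pytest.fixture
def small_model():
    return {
        "w": np.array([[0.1, -0.2], [0.3, 0.4]], dtype=np.float32),
        "b": np.array(0.5, dtype=np.float32),
    }
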