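"""Collaborator-side task execution: local training behind an adapter contract.

A collaborator never ships data — only model deltas and scalar metrics.
Local learning is abstracted behind :class:`FrameworkAdapter` so any
training framework can plug in; two deterministic reference adapters are
built in, both trained by plain (mini-)batch gradient descent on dense
numpy arrays:

* :class:`LogisticAdapter` — binary logistic regression on tabular
  features (the clinical-risk style task);
* :class:`SegmentationAdapter` — pixel-wise logistic regression on simple
  per-pixel image features (the lesion-segmentation style task).

Both are bit-for-bit reproducible given identical state, data,
hyperparameters, and seed: parameters are held as float32, arithmetic runs
in float64, and mini-batch order is a pure function of the seed. That
determinism is what lets a one-collaborator federation reduce exactly to
centralized training.
"""

from __future__ import annotations

import abc
import csv
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .aggregation import MetricReport
from .aggregator import FINISHED, WAIT, ResultsSubmission, TaskAssignment
from .errors import DivergenceError, TaskError
from .tensors import flatten_model, rebuild_model


@dataclass
class SiteDataset:
    """One site's local data; ``declared_size`` is the aggregation weight."""

    features: np.ndarray  # tabular (n, d) or images (n, H, W)
    labels: np.ndarray  # (n,) or masks (n, H, W)
    declared_size: int = 0

    def __post_init__(self):
        if len(self.features) != len(self.labels):
            raise ValueError(
                f"features ({len(self.features)}) and labels ({len(self.labels)}) "
                "must agree on the first dimension"
            )
        if self.declared_size == 0:
            self.declared_size = len(self.features)
        if self.declared_size != len(self.features):
            raise ValueError("declared_size must equal the number of samples")


def derive_task_seed(plan_seed, origin, round_num):
    """Per-(round, collaborator) seed for mini-batch order: reproducible
    across reruns, distinct across sites and rounds."""
    return (int(plan_seed) ^ zlib.crc32(origin.encode("utf-8")) ^ int(round_num)) & 0x7FFFFFFF


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log_loss(p, y):
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


class FrameworkAdapter(abc.ABC):
    """Contract a training framework must satisfy to join a federation."""

    @abc.abstractmethod
    def get_state(self):
        """Return the model as an ordered name -> float32 array mapping."""

    @abc.abstractmethod
    def set_state(self, state):
        """Load a model state; ``set_state(get_state())`` must be a no-op."""

    @abc.abstractmethod
    def train(self, data, epochs, batch_size, learning_rate, seed):
        """Run local training; returns the final training loss."""

    @abc.abstractmethod
    def evaluate(self, data, metrics):
        """Return a list of MetricReports for the requested metric names."""


class _GDLogisticCore(FrameworkAdapter):
    """Shared gradient-descent core for the two built-in logistic learners."""

    def __init__(self, n_features):
        self.w = np.zeros(n_features, dtype=np.float32)
        self.b = np.zeros((), dtype=np.float32)

    def get_state(self):
        return {"w": self.w.copy(), "b": self.b.copy()}

    def set_state(self, state):
        w = np.asarray(state["w"], dtype=np.float32)
        if w.shape != self.w.shape:
            raise ValueError(f"state 'w' shape {w.shape} != {self.w.shape}")
        self.w = w.copy()
        self.b = np.asarray(state["b"], dtype=np.float32).reshape(()).copy()

    def _design(self, data):
        """Return (X, y) as float64 2-D/1-D arrays."""
        raise NotImplementedError

    def train(self, data, epochs, batch_size, learning_rate, seed):
        X, y = self._design(data)
        n = len(y)
        w = self.w.astype(np.float64)
        b = float(self.b)
        lr = float(learning_rate)
        full = batch_size == "full" or (isinstance(batch_size, int) and batch_size >= n)
        rng = None if full else np.random.default_rng(seed)
        loss = np.nan
        for _ in range(int(epochs)):
            if full:
                batches = [np.arange(n)]
            else:
                order = rng.permutation(n)
                batches = [order[i : i + batch_size] for i in range(0, n, batch_size)]
            with np.errstate(over="ignore", invalid="ignore"):
                for idx in batches:
                    Xb, yb = X[idx], y[idx]
                    p = _sigmoid(Xb @ w + b)
                    err = p - yb
                    w -= lr * (Xb.T @ err) / len(idx)
                    b -= lr * float(err.mean())
                loss = _log_loss(_sigmoid(X @ w + b), y)
            if not np.isfinite(loss) or not np.all(np.isfinite(w)):
                raise DivergenceError(
                    f"training loss diverged (learning_rate={lr}); reduce the step size"
                )
        self.w = w.astype(np.float32)
        self.b = np.float32(b).reshape(())
        return loss

    def predict_proba(self, data):
        X, _ = self._design(data)
        return _sigmoid(X @ self.w.astype(np.float64) + float(self.b))

    def evaluate(self, data, metrics):
        X, y = self._design(data)
        p = _sigmoid(X @ self.w.astype(np.float64) + float(self.b))
        weight = float(data.declared_size)
        out = []
        for m in metrics:
            if m == "accuracy":
                val = float(np.mean((p >= 0.5) == (y >= 0.5)))
            elif m == "loss":
                val = _log_loss(p, y)
            elif m == "dice":
                pred = p >= 0.5
                truth = y >= 0.5
                inter = np.sum(pred & truth)
                denom = pred.sum() + truth.sum()
                val = float(2.0 * inter / denom) if denom else 1.0
            else:
                raise TaskError(f"unknown metric {m!r}")
            out.append(MetricReport(m, val, weight))
        return out


class LogisticAdapter(_GDLogisticCore):
    """Full/mini-batch binary logistic regression on tabular features."""

    def _design(self, data):
        X = np.asarray(data.features, dtype=np.float64)
        y = np.asarray(data.labels, dtype=np.float64).ravel()
        return X, y


class SegmentationAdapter(_GDLogisticCore):
    """Pixel-wise logistic segmentation on fixed local image features.

    Each pixel is classified from three features: its intensity, a 3x3
    local mean, and a 5x5 local mean — enough context for the blob-like
    synthetic lesions while keeping the model a dense weight vector.
    """

    N_FEATURES = 3

    def __init__(self):
        super().__init__(self.N_FEATURES)

    @staticmethod
    def pixel_features(images):
        images = np.asarray(images, dtype=np.float64)
        feats = np.stack(
            [
                images,
                ndimage.uniform_filter(images, size=(1, 3, 3), mode="nearest"),
                ndimage.uniform_filter(images, size=(1, 5, 5), mode="nearest"),
            ],
            axis=-1,
        )
        return feats.reshape(-1, SegmentationAdapter.N_FEATURES)

    def _design(self, data):
        X = self.pixel_features(data.features)
        y = np.asarray(data.labels, dtype=np.float64).reshape(-1)
        return X, y


# ---------------------------------------------------------------------------
# task execution

def run_task(assignment: TaskAssignment, global_tensors, adapter, data, plan, origin):
    """Execute one round's task list from the consensus weights.

    Sets the adapter to the consensus state, runs each task in assignment
    order, and returns a ResultsSubmission carrying trained tensors and
    metric reports — and structurally nothing else: the submission type has
    no data field, so local arrays cannot leak by construction.
    """
    consensus = rebuild_model(global_tensors, template=adapter.get_state())
    adapter.set_state(consensus)
    tensors = []
    metrics = []
    trained = False
    for task_name in assignment.tasks:
        spec = plan.tasks[task_name]
        try:
            if spec.kind == "train":
                seed = derive_task_seed(plan.seed, origin, assignment.round_num)
                loss = adapter.train(
                    data, spec.epochs_per_round, spec.batch_size, spec.learning_rate, seed
                )
                metrics.append(MetricReport("train_loss", loss, float(data.declared_size)))
                trained = True
            else:
                metrics.extend(adapter.evaluate(data, spec.metrics))
        except DivergenceError:
            raise
        except Exception as e:  # adapter failure -> failed-task status upstream
            raise TaskError(f"task {task_name!r} failed: {e}") from e
    if trained:
        tensors = flatten_model(
            adapter.get_state(), origin, assignment.round_num, {"trained"}
        )
    return ResultsSubmission(
        origin=origin,
        round_num=assignment.round_num,
        tensors=tensors,
        metrics=metrics,
        declared_size=data.declared_size,
    )


def run_federation_loop(collab_id, transport, adapter, data, plan, max_polls=100000):
    """Pull tasks, execute, submit — until the finished signal.

    Returns the per-round metric history (one dict per completed round).
    """
    history = []
    polls = 0
    while True:
        reply = transport.request_tasks(collab_id)
        if reply == FINISHED:
            return history
        if reply == WAIT:
            polls += 1
            if polls > max_polls:
                raise TaskError(f"{collab_id}: exceeded {max_polls} polls waiting for a round")
            transport.idle()
            continue
        assignment = reply
        global_tensors = transport.fetch_global_tensors(
            collab_id, assignment.global_tensors_ref
        )
        submission = run_task(assignment, global_tensors, adapter, data, plan, collab_id)
        transport.submit_results(collab_id, submission)
        history.append(
            {
                "round": assignment.round_num,
                **{m.name: m.value for m in submission.metrics},
            }
        )


def write_metric_history_csv(history, path):
    """Per-round local metric log: (round, metric, value) rows."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["round", "metric", "value"])
        for row in history:
            for k, v in row.items():
                if k != "round":
                    w.writerow([row["round"], k, v])
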