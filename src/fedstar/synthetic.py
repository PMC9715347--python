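"""Synthetic multi-site biomedical tasks and federated-vs-centralized parity.

Real federations train on hospital data that cannot ship with a software
package, so the experiments here run on synthetic analogues with
controlled heterogeneity:

* **tabular** — a multi-hospital clinical-risk style task: site *i* draws
  features from N(mu_i, I) with mu_i = site_shift * u_i (u_i a fixed unit
  direction per site), and labels from one shared logistic ground truth
  with optional logit noise. site_shift = 0 gives an IID split; raising it
  sweeps continuously into non-IID territory.
* **segmentation** — a lesion-boundary style task: images are smoothed
  Gaussian noise plus 1-3 bright elliptical lesions; the mask is the lesion
  union; each site adds its own foreground intensity bias.

Every generator is a pure function of (config, seed).

The parity harness runs the same learner through a real federation (one
aggregator + N collaborators over the in-process transport) and through
plain pooled training with an identical total epoch budget, scoring both
on a pooled held-out set drawn with the same per-site shifts. The headline
claim under test is that the federated consensus model performs comparably
to the centralized one.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .aggregator import Aggregator
from .collaborator import (
    FrameworkAdapter,
    SiteDataset,
    derive_task_seed,
    run_task,
)
from .errors import FederationHalt, FedstarError
from .tensors import flatten_model, model_states_equal, rebuild_model
from .transport import AggregatorService, Clock, InProcessTransport


@dataclass
class SiteConfig:
    """Study conditions for one synthetic multi-site draw."""

    n_sites: int
    sizes: list
    feature_dim: int = 10  # tabular only
    image_shape: tuple = (32, 32)  # segmentation only
    site_shift: float = 0.0
    noise_sd: float = 0.5
    class_balance: float = 0.5
    seed: int = 0

    def validate(self, segmentation=False):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if len(self.sizes) != self.n_sites:
            raise ValueError(f"|sizes| ({len(self.sizes)}) must equal n_sites ({self.n_sites})")
        if any(s < 1 for s in self.sizes):
            raise ValueError("every site size must be a positive integer")
        if self.site_shift < 0:
            raise ValueError("site_shift must be non-negative")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if segmentation:
            if min(self.image_shape) < 8:
                raise ValueError("image_shape must be at least 8x8")
        elif self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")


# ---------------------------------------------------------------------------
# tabular generator

def _tabular_truth(cfg, rng):
    """Shared ground truth: coefficients, intercept, per-site directions."""
    beta = rng.normal(0.0, 1.0, size=cfg.feature_dim)
    beta /= np.linalg.norm(beta) / 2.0  # |beta| = 2: clearly learnable signal
    intercept = math.log(cfg.class_balance / (1.0 - cfg.class_balance))
    dirs = rng.normal(size=(cfg.n_sites, cfg.feature_dim))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return beta, intercept, dirs


def _draw_tabular(rng, n, mu, beta, intercept, noise_sd):
    X = mu + rng.standard_normal((n, len(beta)))
    logits = X @ beta + intercept + noise_sd * rng.standard_normal(n)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logits))).astype(np.float64)
    return X, y


def generate_tabular_sites(cfg: SiteConfig):
    """Per-site tabular datasets drawn from a shared logistic ground truth."""
    return generate_tabular_task(cfg, n_holdout=0)[0]


def generate_tabular_task(cfg: SiteConfig, n_holdout=0):
    """Sites plus an optional pooled held-out set under the same truth.

    The holdout is drawn per-site (shift applied) proportionally to the
    training sizes, then pooled, so the federated and centralized arms are
    scored on identical data.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    beta, intercept, dirs = _tabular_truth(cfg, rng)
    sites = []
    for i in range(cfg.n_sites):
        mu = cfg.site_shift * dirs[i]
        X, y = _draw_tabular(rng, cfg.sizes[i], mu, beta, intercept, cfg.noise_sd)
        sites.append(SiteDataset(X, y))
    holdout = None
    if n_holdout:
        total = sum(cfg.sizes)
        parts = [round(n_holdout * s / total) for s in cfg.sizes]
        parts[0] += n_holdout - sum(parts)
        Xs, ys = [], []
        for i, n in enumerate(parts):
            if n <= 0:
                continue
            X, y = _draw_tabular(
                rng, n, cfg.site_shift * dirs[i], beta, intercept, cfg.noise_sd
            )
            Xs.append(X)
            ys.append(y)
        holdout = SiteDataset(np.concatenate(Xs), np.concatenate(ys))
    return sites, holdout


# ---------------------------------------------------------------------------
# segmentation generator

#: lesion geometry: count uniform in {1..3}, semi-axes uniform in
#: [2, min(H,W)/6] pixels, centers placed so every lesion stays in bounds
_MIN_AXIS = 2.0


def generate_segmentation_sites(cfg: SiteConfig):
    """Per-site image/mask stacks: noise background + elliptical lesions."""
    cfg.validate(segmentation=True)
    H, W = cfg.image_shape
    rng = np.random.default_rng(cfg.seed)
    max_axis = min(H, W) / 6.0
    site_bias = rng.standard_normal(cfg.n_sites)
    yy, xx = np.mgrid[0:H, 0:W]
    sites = []
    for i in range(cfg.n_sites):
        n = cfg.sizes[i]
        images = np.empty((n, H, W))
        masks = np.zeros((n, H, W))
        for j in range(n):
            background = ndimage.gaussian_filter(
                rng.standard_normal((H, W)), sigma=1.5, mode="nearest"
            )
            img = cfg.noise_sd * background
            mask = np.zeros((H, W), dtype=bool)
            for _ in range(rng.integers(1, 4)):
                a = rng.uniform(_MIN_AXIS, max_axis)
                b = rng.uniform(_MIN_AXIS, max_axis)
                cy = rng.uniform(a, H - 1 - a)
                cx = rng.uniform(b, W - 1 - b)
                theta = rng.uniform(0, np.pi)
                dy, dx = yy - cy, xx - cx
                ry = dy * np.cos(theta) + dx * np.sin(theta)
                rx = -dy * np.sin(theta) + dx * np.cos(theta)
                mask |= (ry / a) ** 2 + (rx / b) ** 2 <= 1.0
            foreground = 1.0 + cfg.site_shift * site_bias[i]
            img = img + foreground * mask
            images[j] = img
            masks[j] = mask.astype(np.float64)
        sites.append(SiteDataset(images, masks))
    return sites


def expected_foreground_fraction(cfg: SiteConfig):
    """Analytic (lower, upper) bounds on the mean lesion-area fraction,
    ignoring overlap: bounds from 1..3 lesions of mean ellipse area."""
    H, W = cfg.image_shape
    max_axis = min(H, W) / 6.0
    mean_axis = (_MIN_AXIS + max_axis) / 2.0
    one = math.pi * mean_axis * mean_axis / (H * W)
    return one * 0.5, 3.0 * one  # overlap + truncation make the lower end soft


# ---------------------------------------------------------------------------
# centralized reference arm

def pool_sites(sites):
    """Concatenate per-site datasets into one pooled SiteDataset."""
    X = np.concatenate([s.features for s in sites])
    y = np.concatenate([s.labels for s in sites])
    return SiteDataset(X, y)


def train_centralized_reference(
    data: SiteDataset, task, adapter: FrameworkAdapter, rounds, seed, origin="centralized"
):
    """Plain pooled training with the federated arm's total epoch budget.

    Training runs in `rounds` chunks of `epochs_per_round` with the same
    per-(origin, round) batch seeding a collaborator would use, so a
    one-site federation is the same float-op sequence as this reference.
    Returns ``(final_state, final_loss)``.
    """
    loss = math.nan
    for r in range(rounds):
        loss = adapter.train(
            data,
            task.epochs_per_round,
            task.batch_size,
            task.learning_rate,
            derive_task_seed(seed, origin, r),
        )
    return adapter.get_state(), loss


# ---------------------------------------------------------------------------
# simulation + parity

@dataclass
class ParityReport:
    """Federated vs centralized comparison on one synthetic task."""

    metric_name: str
    trajectory: list  # per-round consensus metric on the holdout
    centralized_metric: float
    single_site_metrics: list
    gap: float  # final consensus - centralized
    final_consensus: dict = field(repr=False, default=None)
    rounds_completed: int = 0

    def to_json(self, path=None):
        d = {
            "metric_name": self.metric_name,
            "trajectory": self.trajectory,
            "centralized_metric": self.centralized_metric,
            "single_site_metrics": self.single_site_metrics,
            "gap": self.gap,
            "rounds_completed": self.rounds_completed,
        }
        text = json.dumps(d, indent=2)
        if path:
            Path(path).write_text(text)
        return text

    def write_trajectory_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["round", self.metric_name])
            for r, v in enumerate(self.trajectory):
                w.writerow([r, v])


def _evaluate_state(adapter_factory, state, holdout, metric):
    scorer = adapter_factory()
    scorer.set_state(state)
    return scorer.evaluate(holdout, [metric])[0].value


def run_simulation(
    plan,
    sites,
    adapter_factory,
    initial_model,
    holdout=None,
    metric="accuracy",
    registry=None,
    capture_frames=False,
):
    """Run a full federation in-process and score it against the
    centralized reference with a matched epoch budget.

    *adapter_factory* must return a fresh FrameworkAdapter whose state
    matches *initial_model*'s entry names and shapes.
    """
    if len(sites) != len(plan.collaborators):
        raise ValueError(
            f"{len(sites)} site datasets for {len(plan.collaborators)} collaborators"
        )
    clock = Clock()
    aggregator = Aggregator(plan, initial_model, registry=registry)
    service = AggregatorService(aggregator, clock)
    frames = [] if capture_frames else None
    roster = list(plan.collaborators)
    transports = {
        c: InProcessTransport(service, c, frames=frames if capture_frames else None)
        for c in roster
    }
    adapters = {c: adapter_factory() for c in roster}
    for c in roster:
        adapters[c].set_state(initial_model)
    data = dict(zip(roster, sites))

    trajectory = []
    try:
        while not aggregator.finished:
            round_num = aggregator.round.round_num
            for c in roster:
                t = transports[c]
                assignment = t.request_tasks(c)
                if assignment in ("finished", "wait"):
                    continue
                tensors = t.fetch_global_tensors(c, assignment.global_tensors_ref)
                sub = run_task(assignment, tensors, adapters[c], data[c], plan, c)
                t.submit_results(c, sub)
            if aggregator.round.round_num == round_num and not aggregator.finished:
                # everyone reported but the round did not close: advance past
                # the cutoff so the straggler policy decides
                clock.advance(plan.straggler.round_cutoff + 1.0)
                aggregator.close_round_if_ready(clock.now())
            consensus_tensors = aggregator.get_global_tensors(round_num)
            consensus = rebuild_model(consensus_tensors, template=initial_model)
            if holdout is not None:
                trajectory.append(_evaluate_state(adapter_factory, consensus, holdout, metric))
    except FederationHalt as e:
        raise FedstarError(f"simulation halted in round {e.round_num}: {e}") from e

    final_round = plan.rounds_to_train - 1
    final_consensus = rebuild_model(
        aggregator.get_global_tensors(final_round), template=initial_model
    )

    # centralized arm: pooled data, same initial state, same budget
    train_task = next(iter(plan.train_tasks().values()))
    central = adapter_factory()
    central.set_state(initial_model)
    pooled = pool_sites(sites)
    central_state, _ = train_centralized_reference(
        pooled, train_task, central, plan.rounds_to_train, plan.seed
    )

    single_metrics = []
    centralized_metric = math.nan
    gap = math.nan
    if holdout is not None:
        centralized_metric = _evaluate_state(adapter_factory, central_state, holdout, metric)
        for c, site in data.items():
            solo = adapter_factory()
            solo.set_state(initial_model)
            train_centralized_reference(
                site, train_task, solo, plan.rounds_to_train, plan.seed, origin=c
            )
            single_metrics.append(_evaluate_state(adapter_factory, solo.get_state(), holdout, metric))
        gap = trajectory[-1] - centralized_metric

    report = ParityReport(
        metric_name=metric,
        trajectory=trajectory,
        centralized_metric=centralized_metric,
        single_site_metrics=single_metrics,
        gap=gap,
        final_consensus=final_consensus,
        rounds_completed=aggregator.closed_rounds,
    )
    report.centralized_state = central_state
    report.aggregator = aggregator
    if capture_frames:
        report.frames = frames
    return report


# ---------------------------------------------------------------------------
# fixture I/O (plain NPZ + JSON manifest)

def write_site_fixtures(sites, directory, site_ids=None, kind="tabular"):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    site_ids = site_ids or [f"site_{i}" for i in range(len(sites))]
    manifest = []
    for sid, site in zip(site_ids, sites):
        fname = f"{sid}.npz"
        if kind == "tabular":
            np.savez(directory / fname, X=site.features, y=site.labels)
        else:
            np.savez(directory / fname, images=site.features, masks=site.labels)
        manifest.append({"site": sid, "file": fname, "size": site.declared_size, "kind": kind})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def load_site_fixtures(directory):
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    out = {}
    for entry in manifest:
        npz = np.load(directory / entry["file"])
        if entry.get("kind", "tabular") == "tabular":
            out[entry["site"]] = SiteDataset(npz["X"], npz["y"])
        else:
            out[entry["site"]] = SiteDataset(npz["images"], npz["masks"])
    return out
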