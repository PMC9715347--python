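"""The federation plan: the declarative contract every site agrees to.

A plan fixes, before any training starts, how many federated rounds run,
which tasks collaborators execute, who the collaborators are, how updates
are combined, and when a round may close without everyone. It is exchanged
as a restricted YAML document (scalars, maps, lists only — no anchors,
aliases, or custom tags) so that parsing is deterministic and auditable.

Canonical serialization emits keys in a fixed documented order with
repr-based number formatting, so ``serialize(parse(text))`` is a fixed
point and plan files can be compared or hashed byte-for-byte.

Only three settings may default: ``batch_size`` ("full"), the straggler
policy (wait for all: fraction 1.0, infinite cutoff), and ``seed`` (0).
Rounds, tasks, collaborators, and the aggregation method are the substance
of the contract and must be explicit.
"""

from __future__ import annotations

import gzip
import io
import json
import math
import shutil
import tarfile
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .aggregation import DEFAULT_REGISTRY
from .errors import IntegrityError, PlanParseError, PlanValidationError

PLAN_VERSION = "1.0"

_TOP_KEY_ORDER = (
    "plan_version",
    "rounds_to_train",
    "tasks",
    "collaborators",
    "aggregation",
    "straggler",
    "network",
    "seed",
)


@dataclass
class TaskSpec:
    kind: str  # "train" | "validate"
    epochs_per_round: int | None = None
    batch_size: object = "full"  # positive int or "full"
    learning_rate: float | None = None
    metrics: list = field(default_factory=list)


@dataclass
class AggregationSpec:
    method: str
    params: dict = field(default_factory=dict)


@dataclass
class StragglerSpec:
    min_reporting_fraction: float = 1.0
    round_cutoff: float = math.inf


@dataclass
class NetworkSpec:
    host: str = "localhost"
    port: int = 50051


@dataclass
class FLPlan:
    rounds_to_train: int
    tasks: dict  # ordered task-name -> TaskSpec
    collaborators: list
    aggregation: AggregationSpec
    straggler: StragglerSpec = field(default_factory=StragglerSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    seed: int = 0
    plan_version: str = PLAN_VERSION

    def train_tasks(self):
        return {n: t for n, t in self.tasks.items() if t.kind == "train"}

    def quorum(self):
        return max(1, math.ceil(self.straggler.min_reporting_fraction * len(self.collaborators)))


# ---------------------------------------------------------------------------
# parsing

def _reject_yaml_extensions(text):
    """The plan dialect forbids anchors, aliases, and explicit tags."""
    try:
        for ev in yaml.parse(text):
            if isinstance(ev, yaml.AliasEvent):
                raise PlanParseError("plan dialect forbids YAML aliases/anchors")
            anchor = getattr(ev, "anchor", None)
            if anchor is not None and not isinstance(ev, yaml.AliasEvent):
                raise PlanParseError("plan dialect forbids YAML anchors")
            tag = getattr(ev, "tag", None)
            if tag is not None and tag.startswith("!"):
                raise PlanParseError(f"plan dialect forbids explicit tags ({tag})")
    except yaml.YAMLError as e:
        raise _parse_error(e) from None


def _parse_error(e):
    mark = getattr(e, "problem_mark", None)
    where = f" at line {mark.line + 1}" if mark is not None else ""
    return PlanParseError(f"malformed plan document{where}: {getattr(e, 'problem', e)}")


def _require(mapping, key, path):
    if not isinstance(mapping, dict) or key not in mapping:
        raise PlanValidationError([f"{path}: required field missing"])
    return mapping[key]


def parse_plan(text, registry=None) -> FLPlan:
    """Parse and validate a plan document; raises on any violation."""
    _reject_yaml_extensions(text)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise _parse_error(e) from None
    if not isinstance(doc, dict):
        raise PlanValidationError(["plan: top level must be a mapping"])

    rounds = _require(doc, "rounds_to_train", "rounds_to_train")
    raw_tasks = _require(doc, "tasks", "tasks")
    collaborators = _require(doc, "collaborators", "collaborators")
    raw_agg = _require(doc, "aggregation", "aggregation")
    agg_method = _require(raw_agg, "method", "aggregation.method")

    tasks = {}
    if isinstance(raw_tasks, dict):
        for name, spec in raw_tasks.items():
            spec = spec or {}
            tasks[str(name)] = TaskSpec(
                kind=spec.get("kind", ""),
                epochs_per_round=spec.get("epochs_per_round"),
                batch_size=spec.get("batch_size", "full"),
                learning_rate=spec.get("learning_rate"),
                metrics=list(spec.get("metrics", [])),
            )

    raw_strag = doc.get("straggler") or {}
    cutoff = raw_strag.get("round_cutoff", math.inf)
    if isinstance(cutoff, str) and cutoff in (".inf", "inf"):
        cutoff = math.inf
    straggler = StragglerSpec(
        min_reporting_fraction=float(raw_strag.get("min_reporting_fraction", 1.0)),
        round_cutoff=float(cutoff),
    )
    raw_net = doc.get("network") or {}
    network = NetworkSpec(
        host=str(raw_net.get("host", "localhost")),
        port=raw_net.get("port", 50051),
    )

    plan = FLPlan(
        rounds_to_train=rounds,
        tasks=tasks,
        collaborators=list(collaborators) if isinstance(collaborators, list) else collaborators,
        aggregation=AggregationSpec(
            method=str(agg_method), params=dict(raw_agg.get("params") or {})
        ),
        straggler=straggler,
        network=network,
        seed=doc.get("seed", 0),
        plan_version=str(doc.get("plan_version", PLAN_VERSION)),
    )
    violations = validate_plan(plan, registry=registry)
    if violations:
        raise PlanValidationError(violations)
    return plan


def validate_plan(plan: FLPlan, registry=None) -> list:
    """Return a list of human-readable violations; empty iff the plan is valid."""
    registry = registry or DEFAULT_REGISTRY
    v = []
    if not isinstance(plan.rounds_to_train, int) or isinstance(plan.rounds_to_train, bool):
        v.append("rounds_to_train: must be an integer")
    elif plan.rounds_to_train < 1:
        v.append("rounds_to_train: must be >= 1")

    if not plan.tasks:
        v.append("tasks: at least one task required")
    else:
        kinds = [t.kind for t in plan.tasks.values()]
        if "train" not in kinds:
            v.append("tasks: at least one task of kind 'train' required")
        for name, t in plan.tasks.items():
            path = f"tasks.{name}"
            if t.kind not in ("train", "validate"):
                v.append(f"{path}.kind: must be 'train' or 'validate', got {t.kind!r}")
                continue
            if t.kind == "train":
                if not isinstance(t.epochs_per_round, int) or t.epochs_per_round < 1:
                    v.append(f"{path}.epochs_per_round: train tasks need a positive integer")
                if t.learning_rate is None or not (
                    isinstance(t.learning_rate, (int, float)) and t.learning_rate > 0
                ):
                    v.append(f"{path}.learning_rate: train tasks need a positive real")
            else:
                if not t.metrics:
                    v.append(f"{path}.metrics: validate tasks need >= 1 metric name")
            if t.batch_size != "full" and not (
                isinstance(t.batch_size, int)
                and not isinstance(t.batch_size, bool)
                and t.batch_size >= 1
            ):
                v.append(f"{path}.batch_size: must be a positive integer or 'full'")

    if not isinstance(plan.collaborators, list) or not plan.collaborators:
        v.append("collaborators: non-empty list required")
    else:
        if any(not isinstance(c, str) or not c for c in plan.collaborators):
            v.append("collaborators: identifiers must be non-empty strings")
        if len(set(plan.collaborators)) != len(plan.collaborators):
            v.append("collaborators: identifiers must be unique")

    if plan.aggregation.method not in registry:
        v.append(
            f"aggregation.method: {plan.aggregation.method!r} not in registry "
            f"(known: {', '.join(registry.names())})"
        )

    f = plan.straggler.min_reporting_fraction
    if not (isinstance(f, (int, float)) and 0 < f <= 1):
        v.append("straggler.min_reporting_fraction: must be in (0, 1]")
    if not (isinstance(plan.straggler.round_cutoff, (int, float)) and plan.straggler.round_cutoff > 0):
        v.append("straggler.round_cutoff: must be a positive real")

    if not isinstance(plan.network.port, int) or not (1 <= plan.network.port <= 65535):
        v.append("network.port: must be an integer in 1..65535")
    if not plan.network.host:
        v.append("network.host: must be non-empty")

    if not isinstance(plan.seed, int) or isinstance(plan.seed, bool) or plan.seed < 0:
        v.append("seed: must be a non-negative integer")
    return v


# ---------------------------------------------------------------------------
# canonical serialization

def serialize_plan(plan: FLPlan, registry=None) -> str:
    """Emit the canonical plan document (fixed key order, explicit defaults)."""
    violations = validate_plan(plan, registry=registry)
    if violations:
        raise PlanValidationError(violations)
    tasks = {}
    for name, t in plan.tasks.items():
        entry = {"kind": t.kind}
        if t.kind == "train":
            entry["epochs_per_round"] = t.epochs_per_round
            entry["learning_rate"] = t.learning_rate
        entry["batch_size"] = t.batch_size
        entry["metrics"] = list(t.metrics)
        tasks[name] = entry
    doc = {
        "plan_version": plan.plan_version,
        "rounds_to_train": plan.rounds_to_train,
        "tasks": tasks,
        "collaborators": list(plan.collaborators),
        "aggregation": {
            "method": plan.aggregation.method,
            "params": dict(sorted(plan.aggregation.params.items())),
        },
        "straggler": {
            "min_reporting_fraction": plan.straggler.min_reporting_fraction,
            "round_cutoff": plan.straggler.round_cutoff,
        },
        "network": {"host": plan.network.host, "port": plan.network.port},
        "seed": plan.seed,
    }
    assert tuple(doc) == _TOP_KEY_ORDER
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False, width=120)


# ---------------------------------------------------------------------------
# workspace packaging

@dataclass
class Workspace:
    """A distributable federation bundle: plan + task code + requirements."""

    plan: FLPlan
    task_code_manifest: list
    requirements_manifest: list = field(default_factory=list)


_PLAN_ENTRY = "plan.yaml"
_REQ_ENTRY = "requirements.txt"


def export_workspace(plan, code_root, manifest=None, requirements=()) -> bytes:
    """Package the plan plus manifested files into a deterministic tar.gz.

    Entries are sorted, timestamps zeroed, and ownership cleared so identical
    inputs always give byte-identical archives. ``manifest=None`` includes
    every regular file under *code_root*.
    """
    code_root = Path(code_root)
    if not code_root.is_dir():
        raise FileNotFoundError(f"code root {code_root} does not exist")
    if manifest is None:
        manifest = sorted(
            str(p.relative_to(code_root))
            for p in code_root.rglob("*")
            if p.is_file()
        )
    else:
        manifest = sorted(str(m) for m in manifest)
    for rel in manifest:
        if rel in (_PLAN_ENTRY, _REQ_ENTRY):
            raise ValueError(f"manifest entry {rel!r} collides with a reserved name")
        p = (code_root / rel).resolve()
        if not p.is_file():
            raise FileNotFoundError(f"manifest file missing: {rel}")
        if code_root.resolve() not in p.parents and p != code_root.resolve():
            raise ValueError(f"manifest entry {rel!r} escapes the code root")

    buf = io.BytesIO()
    with tarfile.open(fileobj=buf, mode="w", format=tarfile.USTAR_FORMAT) as tar:
        def add_bytes(name, data):
            info = tarfile.TarInfo(name)
            info.size = len(data)
            info.mtime = 0
            info.uid = info.gid = 0
            info.uname = info.gname = ""
            info.mode = 0o644
            tar.addfile(info, io.BytesIO(data))

        add_bytes(_PLAN_ENTRY, serialize_plan(plan).encode("utf-8"))
        add_bytes(_REQ_ENTRY, ("\n".join(requirements) + "\n").encode("utf-8"))
        for rel in manifest:
            add_bytes(rel, (code_root / rel).read_bytes())
    return gzip.compress(buf.getvalue(), compresslevel=9, mtime=0)


def import_workspace(archive: bytes, dest) -> Workspace:
    """Unpack an exported workspace; nothing is materialized unless the
    archive is intact and its plan validates."""
    dest = Path(dest)
    try:
        raw = gzip.decompress(archive)
    except (OSError, EOFError) as e:
        raise IntegrityError(f"corrupt workspace archive: {e}") from None

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        try:
            with tarfile.open(fileobj=io.BytesIO(raw), mode="r") as tar:
                names = tar.getnames()
                for m in tar.getmembers():
                    if m.name.startswith("/") or ".." in Path(m.name).parts:
                        raise IntegrityError(f"unsafe archive entry {m.name!r}")
                tar.extractall(tmp, filter="data")
        except tarfile.TarError as e:
            raise IntegrityError(f"corrupt workspace archive: {e}") from None
        if _PLAN_ENTRY not in names:
            raise IntegrityError("archive has no plan.yaml at its root")
        plan = parse_plan((tmp / _PLAN_ENTRY).read_text())  # raises if invalid
        requirements = [
            line
            for line in (tmp / _REQ_ENTRY).read_text().splitlines()
            if line.strip()
        ] if _REQ_ENTRY in names else []
        code_files = sorted(n for n in names if n not in (_PLAN_ENTRY, _REQ_ENTRY))
        dest.mkdir(parents=True, exist_ok=True)
        for name in names:
            target = dest / name
            target.parent.mkdir(parents=True, exist_ok=True)
            shutil.copy2(tmp / name, target)
    return Workspace(plan=plan, task_code_manifest=code_files, requirements_manifest=requirements)
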