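"""Consensus aggregation of per-collaborator tensors and metrics.

The default combination rule is dataset-size-weighted averaging (FedAvg):
each collaborator's update is weighted by its declared local dataset size,
the only weighting signal exchanged over the protocol. A coordinate-wise
median is provided as a robust alternative, and a registry lets custom
aggregation strategies plug in under a name the plan can reference.

Numerical policy: tensors travel as float32, but all aggregation arithmetic
runs in float64 with numpy's pairwise summation before casting back, which
bounds order-dependence to below float32 resolution — weighted means are
invariant to submission order at the bit level after the final cast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AggregationError
from .tensors import NamedTensor, TensorKey


@dataclass
class WeightedUpdate:
    """One collaborator's tensor plus its aggregation weight (dataset size)."""

    tensor: NamedTensor
    weight: float

    def __post_init__(self):
        if not self.weight > 0:
            raise AggregationError(f"weight must be positive, got {self.weight}")


@dataclass
class MetricReport:
    """A scalar metric from one site, weighted by local dataset size."""

    name: str
    value: float
    weight: float

    def __post_init__(self):
        if not self.weight > 0:
            raise AggregationError(f"metric weight must be positive, got {self.weight}")


def _check_group(group):
    if not group:
        raise AggregationError("cannot aggregate an empty group")
    ref = group[0].tensor
    for u in group[1:]:
        if u.tensor.key.name != ref.key.name:
            raise AggregationError(
                f"mixed tensor names in group: {ref.key.name!r} vs {u.tensor.key.name!r}"
            )
        if u.tensor.declared_shape != ref.declared_shape:
            raise AggregationError(
                f"shape mismatch for {ref.key.name!r}: "
                f"{u.tensor.key.origin} has {u.tensor.declared_shape}, "
                f"{ref.key.origin} has {ref.declared_shape}"
            )
    return ref


def _consensus_key(ref: NamedTensor) -> TensorKey:
    return TensorKey(ref.key.name, "aggregator", ref.key.round_num, frozenset({"aggregated"}))


def weighted_mean_aggregate(group, round_num=None) -> NamedTensor:
    """Element-wise sum(w_i * x_i) / sum(w_i) over the group.

    Accumulates in float64 (numpy pairwise summation) and casts the result
    back to float32.
    """
    ref = _check_group(group)
    stack = np.stack([u.tensor.values.astype(np.float64) for u in group])
    w = np.array([u.weight for u in group], dtype=np.float64)
    num = np.einsum("i,i...->...", w, stack)
    out = (num / w.sum()).astype(np.float32)
    return NamedTensor(_consensus_key(ref), out)


def median_aggregate(group, round_num=None) -> NamedTensor:
    """Element-wise sample median; weights are ignored.

    An even group size yields the midpoint of the two middle order
    statistics.
    """
    ref = _check_group(group)
    stack = np.stack([u.tensor.values.astype(np.float64) for u in group])
    out = np.median(stack, axis=0).astype(np.float32)
    return NamedTensor(_consensus_key(ref), out)


def aggregate_metric(reports) -> float:
    """Dataset-size-weighted mean of one named metric across sites."""
    if not reports:
        raise AggregationError("cannot aggregate an empty metric list")
    names = {r.name for r in reports}
    if len(names) > 1:
        raise AggregationError(f"mixed metric names: {sorted(names)}")
    w = np.array([r.weight for r in reports], dtype=np.float64)
    v = np.array([r.value for r in reports], dtype=np.float64)
    return float((w * v).sum() / w.sum())


class AggregatorRegistry:
    """Name -> aggregation function map addressed by the plan.

    Functions follow the contract ``fn(group, round_num) -> NamedTensor``.
    The built-ins ``weighted_mean`` and ``median`` are always present;
    re-registering an existing name is an error. Custom strategies see the
    full weighted group and the round index (enabling stateful schemes) but
    never any site's raw data.
    """

    BUILTINS = {
        "weighted_mean": weighted_mean_aggregate,
        "median": median_aggregate,
    }

    def __init__(self):
        self._methods = dict(self.BUILTINS)

    def register(self, name, fn):
        if name in self._methods:
            raise AggregationError(f"aggregation method {name!r} already registered")
        if not callable(fn):
            raise AggregationError("aggregation method must be callable")
        self._methods[name] = fn
        return self

    def resolve(self, name):
        try:
            return self._methods[name]
        except KeyError:
            raise AggregationError(f"unknown aggregation method {name!r}") from None

    def __contains__(self, name):
        return name in self._methods

    def names(self):
        return sorted(self._methods)


#: process-wide default registry used when a plan or aggregator is built
#: without an explicit one
DEFAULT_REGISTRY = AggregatorRegistry()


def register_aggregator(name, fn, registry=None):
    """Register a custom aggregation method (module-level convenience)."""
    return (registry or DEFAULT_REGISTRY).register(name, fn)
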