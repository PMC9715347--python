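"""Named-tensor model state and its deterministic binary codec.

Model state travels between nodes as a list of named dense float32 tensors.
Each tensor is addressed by a :class:`TensorKey` — entry name, originating
site, federated round, and a small tag set — so the aggregator can tell which
update came from whom in which round.

Wire frame layout (all integers little-endian):

    magic   4 bytes   b"FST1"
    name    u16 length + UTF-8 bytes
    origin  u16 length + UTF-8 bytes
    round   i32 (signed; -1 is reserved for the initial model)
    tags    u8 bitmask (trained=1, aggregated=2, metric=4)
    rank    u8
    shape   rank x u32
    count   u64 (must equal the product of the shape)
    payload count x f32, row-major
    crc     u32 CRC-32 of everything above

Frames are byte-deterministic: encoding the same tensor twice yields
identical bytes on any platform.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrityError

MAGIC = b"FST1"

#: tags a tensor may carry; encoded as a bitmask on the wire
TAGS = ("trained", "aggregated", "metric")
_TAG_BIT = {t: 1 << i for i, t in enumerate(TAGS)}

#: round index reserved for the initial (pre-round-0) model
INITIAL_ROUND = -1


@dataclass(frozen=True)
class TensorKey:
    """Identity of one model fragment in transit or in the store."""

    name: str
    origin: str
    round_num: int
    tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.name:
            raise ValueError("tensor name must be non-empty")
        if self.round_num < INITIAL_ROUND:
            raise ValueError(f"round must be >= {INITIAL_ROUND}, got {self.round_num}")
        unknown = set(self.tags) - set(TAGS)
        if unknown:
            raise ValueError(f"unknown tags: {sorted(unknown)}")
        object.__setattr__(self, "tags", frozenset(self.tags))


@dataclass
class NamedTensor:
    """A dense float32 array plus the key identifying it."""

    key: TensorKey
    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=np.float32)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"tensor {self.key.name!r} contains non-finite values")
        self.values = arr

    @property
    def declared_shape(self):
        return tuple(self.values.shape)

    def __eq__(self, other):
        if not isinstance(other, NamedTensor):
            return NotImplemented
        return (
            self.key == other.key
            and self.declared_shape == other.declared_shape
            and np.array_equal(self.values, other.values)
        )


# ---------------------------------------------------------------------------
# ModelState <-> tensor list

def flatten_model(state, origin, round_num, tags):
    """Turn an ordered name->array mapping into a list of NamedTensors.

    Names and order are preserved; ``rebuild_model(flatten_model(s)) == s``.
    Non-finite entries are rejected by name.
    """
    if not state:
        raise ValueError("model state must have at least one entry")
    out = []
    for name, arr in state.items():
        arr = np.asarray(arr, dtype=np.float32)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"model entry {name!r} contains non-finite values")
        out.append(NamedTensor(TensorKey(name, origin, round_num, frozenset(tags)), arr))
    return out


def rebuild_model(tensors, template=None):
    """Reassemble an ordered ModelState from a list of NamedTensors.

    If *template* (a name->array mapping) is given, every template entry must
    be present and the result follows the template's order.
    """
    if not tensors:
        raise ValueError("cannot rebuild a model from zero tensors")
    state = {}
    for t in tensors:
        if t.key.name in state:
            raise ValueError(f"duplicate tensor name {t.key.name!r}")
        state[t.key.name] = t.values.copy()
    if template is not None:
        missing = [n for n in template if n not in state]
        if missing:
            raise ValueError(f"missing model entries: {missing}")
        state = {n: state[n] for n in template}
    return state


def model_states_equal(a, b):
    """Exact (bit-level) equality of two model states."""
    if list(a) != list(b):
        return False
    return all(np.array_equal(a[k], b[k]) for k in a)


# ---------------------------------------------------------------------------
# binary codec

def _pack_str(s):
    b = s.encode("utf-8")
    if len(b) > 0xFFFF:
        raise ValueError("string field too long")
    return struct.pack("<H", len(b)) + b


def encode_tensor(t: NamedTensor) -> bytes:
    """Serialize a NamedTensor into a deterministic binary frame."""
    tag_mask = 0
    for tag in t.key.tags:
        tag_mask |= _TAG_BIT[tag]
    # note: ascontiguousarray would promote rank-0 to rank-1
    arr = np.asarray(t.values, dtype="<f4", order="C")
    shape = arr.shape
    head = bytearray()
    head += MAGIC
    head += _pack_str(t.key.name)
    head += _pack_str(t.key.origin)
    head += struct.pack("<iBB", t.key.round_num, tag_mask, len(shape))
    head += struct.pack(f"<{len(shape)}I", *shape)
    head += struct.pack("<Q", arr.size)
    body = arr.tobytes(order="C")
    frame = bytes(head) + body
    return frame + struct.pack("<I", zlib.crc32(frame))


class _Reader:
    def __init__(self, b):
        self.b = b
        self.i = 0

    def take(self, n, what):
        if self.i + n > len(self.b):
            raise IntegrityError(f"truncated frame while reading {what}")
        out = self.b[self.i : self.i + n]
        self.i += n
        return out

    def unpack(self, fmt, what):
        return struct.unpack(fmt, self.take(struct.calcsize(fmt), what))


def decode_tensor(b: bytes) -> NamedTensor:
    """Exact inverse of :func:`encode_tensor`; validates CRC, shape, count."""
    if len(b) < 4 + 4:
        raise IntegrityError("frame too short")
    crc_stored = struct.unpack("<I", b[-4:])[0]
    if zlib.crc32(b[:-4]) != crc_stored:
        raise IntegrityError("CRC mismatch: frame corrupted")
    r = _Reader(b[:-4])
    if r.take(4, "magic") != MAGIC:
        raise IntegrityError("bad magic: not a tensor frame")
    (nlen,) = r.unpack("<H", "name length")
    name = r.take(nlen, "name").decode("utf-8")
    (olen,) = r.unpack("<H", "origin length")
    origin = r.take(olen, "origin").decode("utf-8")
    round_num, tag_mask, rank = r.unpack("<iBB", "header")
    shape = r.unpack(f"<{rank}I", "shape") if rank else ()
    (count,) = r.unpack("<Q", "element count")
    expected = 1
    for d in shape:
        expected *= d
    if count != expected:
        raise IntegrityError(
            f"element count {count} does not match shape {tuple(shape)}"
        )
    payload = r.take(4 * count, "payload")
    if r.i != len(r.b):
        raise IntegrityError("trailing bytes after payload")
    tags = frozenset(t for t, bit in _TAG_BIT.items() if tag_mask & bit)
    values = np.frombuffer(payload, dtype="<f4").reshape(shape).copy()
    return NamedTensor(TensorKey(name, origin, round_num, tags), values)


def encode_tensor_list(tensors) -> bytes:
    """Concatenate tensor frames behind a u32 count, for transport payloads."""
    parts = [struct.pack("<I", len(tensors))]
    for t in tensors:
        frame = encode_tensor(t)
        parts.append(struct.pack("<I", len(frame)))
        parts.append(frame)
    return b"".join(parts)


def decode_tensor_list(b: bytes):
    r = _Reader(b)
    (n,) = r.unpack("<I", "tensor count")
    out = []
    for _ in range(n):
        (flen,) = r.unpack("<I", "frame length")
        out.append(decode_tensor(r.take(flen, "frame")))
    if r.i != len(r.b):
        raise IntegrityError("trailing bytes after tensor list")
    return out
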