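"""Node-to-node message schema and the two interchangeable transports.

Only seven envelope kinds exist and only these are dispatchable — the
protocol surface is closed by construction, so a peer cannot request
anything beyond task assignment, tensor exchange, and result submission.

Two transports satisfy the same contract:

* :class:`InProcessTransport` — deterministic, single-process; every frame
  that would cross the wire is recorded, which is how the test suite
  asserts that no site's raw data ever leaves a collaborator.
* :class:`TlsTransport` / :func:`serve_tls` — a socket transport with
  mutual certificate verification on both ends (TLS >= 1.2); each side
  authenticates the other against the federation root, and the aggregator
  additionally refuses authenticated subjects that are not on the plan
  roster.
"""

from __future__ import annotations

import json
import socket
import ssl
import struct
import tempfile
import threading
import zlib
from dataclasses import dataclass
from pathlib import Path

from .aggregation import MetricReport
from .aggregator import FINISHED, WAIT, Aggregator, ResultsSubmission, TaskAssignment
from .errors import AuthorizationError, ProtocolError
from .tensors import decode_tensor_list, encode_tensor_list

MAGIC = b"FE01"

KINDS = (
    "tasks_request",
    "tasks_response",
    "tensor_request",
    "tensor_response",
    "results_submission",
    "ack",
    "finished",
)
_KIND_CODE = {k: i + 1 for i, k in enumerate(KINDS)}
_CODE_KIND = {v: k for k, v in _KIND_CODE.items()}


@dataclass
class Envelope:
    kind: str
    sender: str
    round_num: int
    payload: bytes = b""

    def __post_init__(self):
        if self.kind not in _KIND_CODE:
            raise ProtocolError(f"unknown envelope kind {self.kind!r}")


def serialize_envelope(env: Envelope) -> bytes:
    sender = env.sender.encode("utf-8")
    head = MAGIC + struct.pack(
        "<BH", _KIND_CODE[env.kind], len(sender)
    ) + sender + struct.pack("<iI", env.round_num, len(env.payload))
    frame = head + env.payload
    return frame + struct.pack("<I", zlib.crc32(frame))


def deserialize_envelope(b: bytes) -> Envelope:
    if len(b) < 4 + 4:
        raise ProtocolError("envelope frame too short")
    if zlib.crc32(b[:-4]) != struct.unpack("<I", b[-4:])[0]:
        raise ProtocolError("envelope CRC mismatch")
    body = b[:-4]
    if body[:4] != MAGIC:
        raise ProtocolError("bad envelope magic")
    code, slen = struct.unpack("<BH", body[4:7])
    if code not in _CODE_KIND:
        raise ProtocolError(f"unknown envelope kind byte {code}")
    sender = body[7 : 7 + slen].decode("utf-8")
    round_num, plen = struct.unpack("<iI", body[7 + slen : 15 + slen])
    payload = body[15 + slen :]
    if len(payload) != plen:
        raise ProtocolError("envelope payload length mismatch")
    return Envelope(_CODE_KIND[code], sender, round_num, payload)


# ---------------------------------------------------------------------------
# payload codecs

def encode_submission_payload(sub: ResultsSubmission) -> bytes:
    meta = json.dumps(
        {
            "origin": sub.origin,
            "round": sub.round_num,
            "declared_size": sub.declared_size,
            "metrics": [[m.name, m.value, m.weight] for m in sub.metrics],
        },
        sort_keys=True,
    ).encode("utf-8")
    return struct.pack("<I", len(meta)) + meta + encode_tensor_list(sub.tensors)


def decode_submission_payload(b: bytes) -> ResultsSubmission:
    (mlen,) = struct.unpack("<I", b[:4])
    meta = json.loads(b[4 : 4 + mlen].decode("utf-8"))
    tensors = decode_tensor_list(b[4 + mlen :])
    return ResultsSubmission(
        origin=meta["origin"],
        round_num=meta["round"],
        tensors=tensors,
        metrics=[MetricReport(n, v, w) for n, v, w in meta["metrics"]],
        declared_size=meta["declared_size"],
    )


def encode_assignment_payload(a: TaskAssignment) -> bytes:
    return json.dumps(
        {"round": a.round_num, "tasks": a.tasks, "global_tensors_ref": a.global_tensors_ref},
        sort_keys=True,
    ).encode("utf-8")


def decode_assignment_payload(b: bytes) -> TaskAssignment:
    d = json.loads(b.decode("utf-8"))
    return TaskAssignment(d["round"], d["tasks"], d["global_tensors_ref"])


# ---------------------------------------------------------------------------
# aggregator-side dispatch (shared by both transports)

class Clock:
    """Injectable abstract clock."""

    def __init__(self, t0=0.0):
        self.t = float(t0)

    def now(self):
        return self.t

    def advance(self, dt=1.0):
        self.t += dt
        return self.t


class AggregatorService:
    """Maps envelopes onto the aggregator state machine, enforcing the
    roster on the *authenticated* peer subject (not the claimed sender)."""

    def __init__(self, aggregator: Aggregator, clock: Clock | None = None):
        self.aggregator = aggregator
        self.clock = clock or Clock()
        self._lock = threading.Lock()

    def handle(self, env: Envelope, authenticated_subject: str) -> Envelope:
        with self._lock:
            return self._dispatch(env, authenticated_subject)

    def _dispatch(self, env, subject):
        agg = self.aggregator
        roster = agg.plan.collaborators
        if subject not in roster:
            raise AuthorizationError(f"peer {subject!r} is not in the plan roster")
        if env.sender != subject:
            raise AuthorizationError(
                f"claimed sender {env.sender!r} != authenticated subject {subject!r}"
            )
        now = self.clock.now()
        if env.kind == "tasks_request":
            result = agg.next_tasks(subject, clock=now)
            agg.close_round_if_ready(now)
            if result == FINISHED:
                return Envelope("finished", "aggregator", -1)
            if result == WAIT:
                return Envelope("ack", "aggregator", -1, json.dumps({"status": "wait"}).encode())
            return Envelope(
                "tasks_response", "aggregator", result.round_num,
                encode_assignment_payload(result),
            )
        if env.kind == "tensor_request":
            req = json.loads(env.payload.decode("utf-8"))
            tensors = agg.get_global_tensors(req["round"])
            if tensors is None:
                return Envelope(
                    "ack", "aggregator", req["round"],
                    json.dumps({"status": "not_ready"}).encode(),
                )
            return Envelope(
                "tensor_response", "aggregator", req["round"], encode_tensor_list(tensors)
            )
        if env.kind == "results_submission":
            sub = decode_submission_payload(env.payload)
            if sub.origin != subject:
                raise AuthorizationError(
                    f"submission origin {sub.origin!r} != authenticated subject {subject!r}"
                )
            status = agg.accept_results(sub, clock=now)
            agg.close_round_if_ready(now)
            return Envelope(
                "ack", "aggregator", sub.round_num,
                json.dumps({"status": status}).encode(),
            )
        raise ProtocolError(f"envelope kind {env.kind!r} is not dispatchable to the aggregator")


# ---------------------------------------------------------------------------
# client-side convenience shared by both transports

class _ClientBase:
    """Implements the collaborator-facing request surface over raw frames."""

    def _exchange_frame(self, frame: bytes) -> bytes:
        raise NotImplementedError

    def _exchange(self, env: Envelope) -> Envelope:
        return deserialize_envelope(self._exchange_frame(serialize_envelope(env)))

    def request_tasks(self, collab_id):
        reply = self._exchange(Envelope("tasks_request", collab_id, -1))
        if reply.kind == "finished":
            return FINISHED
        if reply.kind == "ack":
            body = json.loads(reply.payload.decode())
            if body["status"] == "wait":
                return WAIT
            if body["status"] == "refused":
                raise AuthorizationError(body.get("reason", "refused by aggregator"))
            raise ProtocolError(f"unexpected ack status {body['status']!r} to a tasks request")
        if reply.kind != "tasks_response":
            raise ProtocolError(f"unexpected reply kind {reply.kind!r} to a tasks request")
        return decode_assignment_payload(reply.payload)

    def fetch_global_tensors(self, collab_id, round_num):
        reply = self._exchange(
            Envelope(
                "tensor_request", collab_id, round_num,
                json.dumps({"round": round_num}).encode(),
            )
        )
        if reply.kind == "ack":
            return None  # not ready
        if reply.kind != "tensor_response":
            raise ProtocolError(f"unexpected reply kind {reply.kind!r} to a tensor request")
        return decode_tensor_list(reply.payload)

    def submit_results(self, collab_id, sub: ResultsSubmission):
        reply = self._exchange(
            Envelope(
                "results_submission", collab_id, sub.round_num,
                encode_submission_payload(sub),
            )
        )
        if reply.kind != "ack":
            raise ProtocolError(f"unexpected reply kind {reply.kind!r} to a submission")
        return json.loads(reply.payload.decode())["status"]

    def idle(self):
        """Called by the federation loop when told to wait."""


class InProcessTransport(_ClientBase):
    """Deterministic in-process channel to an AggregatorService.

    Every frame in both directions is appended to ``frames`` so tests can
    byte-scan exactly what would have crossed the network.
    """

    def __init__(self, service: AggregatorService, subject: str, frames=None):
        self.service = service
        self.subject = subject
        self.frames = frames if frames is not None else []

    def _exchange_frame(self, frame: bytes) -> bytes:
        self.frames.append(frame)
        env = deserialize_envelope(frame)
        reply = self.service.handle(env, authenticated_subject=self.subject)
        out = serialize_envelope(reply)
        self.frames.append(out)
        return out

    def idle(self):
        self.service.clock.advance(0.0)


# ---------------------------------------------------------------------------
# mutually-authenticated TLS transport (stdlib ssl)

def _mtls_context(purpose, root_pem, own_cert_pem, own_key_pem):
    ctx = ssl.SSLContext(
        ssl.PROTOCOL_TLS_SERVER if purpose == "server" else ssl.PROTOCOL_TLS_CLIENT
    )
    ctx.minimum_version = ssl.TLSVersion.TLSv1_2
    ctx.verify_mode = ssl.CERT_REQUIRED
    ctx.check_hostname = False  # subject binding is checked against the roster instead
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        (tmp / "root.pem").write_bytes(root_pem)
        (tmp / "cert.pem").write_bytes(own_cert_pem)
        (tmp / "key.pem").write_bytes(own_key_pem)
        ctx.load_verify_locations(tmp / "root.pem")
        ctx.load_cert_chain(tmp / "cert.pem", tmp / "key.pem")
    return ctx


def _peer_common_name(sslsock) -> str:
    cert = sslsock.getpeercert()
    for rdn in cert.get("subject", ()):
        for key, value in rdn:
            if key == "commonName":
                return value
    raise AuthorizationError("peer certificate has no common name")


def _recv_frame(sock):
    head = _recv_exact(sock, 4)
    if head is None:
        return None
    (n,) = struct.unpack("<I", head)
    return _recv_exact(sock, n)


def _recv_exact(sock, n):
    buf = b""
    while len(buf) < n:
        chunk = sock.recv(n - len(buf))
        if not chunk:
            return None
        buf += chunk
    return buf


def _send_frame(sock, frame):
    sock.sendall(struct.pack("<I", len(frame)) + frame)


class TlsServer:
    """Serves an AggregatorService over mutually-authenticated TLS."""

    def __init__(self, service, host, port, root_pem, cert_pem, key_pem):
        self.service = service
        self.ctx = _mtls_context("server", root_pem, cert_pem, key_pem)
        self._sock = socket.create_server((host, port))
        self.port = self._sock.getsockname()[1]
        self._stop = threading.Event()
        self._thread = None

    def serve_in_background(self):
        self._thread = threading.Thread(target=self.serve_forever, daemon=True)
        self._thread.start()
        return self

    def serve_forever(self):
        self._sock.settimeout(0.2)
        while not self._stop.is_set():
            try:
                conn, _ = self._sock.accept()
            except TimeoutError:
                continue
            except OSError:
                break
            threading.Thread(target=self._serve_conn, args=(conn,), daemon=True).start()

    def _serve_conn(self, conn):
        try:
            with self.ctx.wrap_socket(conn, server_side=True) as tls:
                subject = _peer_common_name(tls)
                while True:
                    frame = _recv_frame(tls)
                    if frame is None:
                        return
                    try:
                        env = deserialize_envelope(frame)
                        reply = self.service.handle(env, authenticated_subject=subject)
                    except AuthorizationError as e:
                        reply = Envelope(
                            "ack", "aggregator", -1,
                            json.dumps({"status": "refused", "reason": str(e)}).encode(),
                        )
                    _send_frame(tls, serialize_envelope(reply))
        except (ssl.SSLError, OSError):
            return

    def close(self):
        self._stop.set()
        try:
            self._sock.close()
        except OSError:
            pass
        if self._thread is not None:
            self._thread.join(timeout=2)


class TlsTransport(_ClientBase):
    """Collaborator-side client over mutually-authenticated TLS."""

    def __init__(self, host, port, root_pem, cert_pem, key_pem, retries=3, retry_wait=0.2):
        self.host, self.port = host, port
        self.ctx = _mtls_context("client", root_pem, cert_pem, key_pem)
        self.retries = retries
        self.retry_wait = retry_wait
        self._tls = None

    def _connect(self):
        raw = socket.create_connection((self.host, self.port), timeout=10)
        self._tls = self.ctx.wrap_socket(raw)

    def _exchange_frame(self, frame):
        import time

        last = None
        for _ in range(self.retries):
            try:
                if self._tls is None:
                    self._connect()
                _send_frame(self._tls, frame)
                reply = _recv_frame(self._tls)
                if reply is None:
                    raise ConnectionError("server closed the connection")
                return reply
            except (OSError, ssl.SSLError) as e:
                last = e
                self._tls = None
                time.sleep(self.retry_wait)
        raise ConnectionError(f"transport failed after {self.retries} retries: {last}")

    def idle(self):
        import time

        time.sleep(self.retry_wait)

    def close(self):
        if self._tls is not None:
            self._tls.close()
            self._tls = None
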