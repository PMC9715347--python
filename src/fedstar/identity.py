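"""Test-grade PKI workshop: internal CA, CSR signing, mutual verification.

A federation run under mutual TLS needs every node to hold an X.509
certificate signed by a CA all parties trust. This module creates such a
CA *inside* the federation — explicitly a test-only convenience for
research federations; production deployments should use an external CA.

Key-strength floors are enforced at creation and at signing time:
RSA >= 3072 bits with SHA-384, or ECDSA on secp384r1 (or stronger).
(Reference material sometimes abbreviates the curve "secp384r"; the
registered curve name secp384r1 is meant.)

All key material handling is delegated to the ``openssl`` command-line
tool; this module never implements cryptographic primitives itself.
Validity windows and verification time are injectable so expiry behaviour
is testable without waiting for wall-clock time.
"""

from __future__ import annotations

import datetime as _dt
import secrets
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FedstarError

#: enforced floors per the mutual-TLS hardening guidance
MIN_RSA_BITS = 3072
ALLOWED_CURVES = ("secp384r1", "secp521r1")
ALLOWED_DIGESTS = ("sha384", "sha512")
DEFAULT_VALIDITY_DAYS = 365


class PKIError(FedstarError):
    """Certificate creation or signing was refused or failed."""


@dataclass
class Identity:
    """A subject plus its key material and certificate chain."""

    subject: str
    key_pem: bytes
    cert_pem: bytes
    chain: list = field(default_factory=list)  # intermediates up to (not incl.) root


def _run(args, input_bytes=None):
    proc = subprocess.run(
        ["openssl", *args],
        input=input_bytes,
        capture_output=True,
    )
    if proc.returncode != 0:
        raise PKIError(
            f"openssl {' '.join(args[:2])} failed: {proc.stderr.decode(errors='replace').strip()}"
        )
    return proc.stdout


def _check_floor(key_type, rsa_bits, curve, digest):
    if digest not in ALLOWED_DIGESTS:
        raise PKIError(
            f"digest {digest!r} below the SHA-384 floor (allowed: {ALLOWED_DIGESTS})"
        )
    if key_type == "rsa":
        if rsa_bits < MIN_RSA_BITS:
            raise PKIError(
                f"RSA-{rsa_bits} below the RSA-{MIN_RSA_BITS} floor for federation identities"
            )
    elif key_type == "ecdsa":
        if curve not in ALLOWED_CURVES:
            raise PKIError(
                f"curve {curve!r} below the secp384r1 floor (allowed: {ALLOWED_CURVES})"
            )
    else:
        raise PKIError(f"unsupported key type {key_type!r} (rsa or ecdsa)")


def _newkey_arg(key_type, rsa_bits, curve):
    if key_type == "rsa":
        return ["-newkey", f"rsa:{rsa_bits}"]
    return ["-newkey", "ec", "-pkeyopt", f"ec_paramgen_curve:{curve}"]


def _ts(dt: _dt.datetime) -> str:
    return dt.astimezone(_dt.timezone.utc).strftime("%Y%m%d%H%M%SZ")


def create_ca(
    federation_name,
    key_type="ecdsa",
    rsa_bits=MIN_RSA_BITS,
    curve="secp384r1",
    digest="sha384",
    days=DEFAULT_VALIDITY_DAYS,
) -> Identity:
    """Create a self-signed root CA for a federation (test-only PKI)."""
    _check_floor(key_type, rsa_bits, curve, digest)
    with tempfile.TemporaryDirectory() as tmp:
        key = Path(tmp) / "ca.key"
        cert = Path(tmp) / "ca.crt"
        _run(
            [
                "req", "-x509", "-nodes",
                *_newkey_arg(key_type, rsa_bits, curve),
                f"-{digest}",
                "-days", str(days),
                "-subj", f"/CN={federation_name}",
                "-addext", "basicConstraints=critical,CA:TRUE",
                "-addext", "keyUsage=critical,keyCertSign,cRLSign",
                "-keyout", str(key),
                "-out", str(cert),
            ]
        )
        return Identity(federation_name, key.read_bytes(), cert.read_bytes())


def create_csr(
    subject,
    key_type="ecdsa",
    rsa_bits=MIN_RSA_BITS,
    curve="secp384r1",
    digest="sha384",
):
    """Generate a key pair and certificate signing request for a site.

    Returns ``(key_pem, csr_pem)``.
    """
    _check_floor(key_type, rsa_bits, curve, digest)
    with tempfile.TemporaryDirectory() as tmp:
        key = Path(tmp) / "id.key"
        csr = Path(tmp) / "id.csr"
        _run(
            [
                "req", "-new", "-nodes",
                *_newkey_arg(key_type, rsa_bits, curve),
                f"-{digest}",
                "-subj", f"/CN={subject}",
                "-keyout", str(key),
                "-out", str(csr),
            ]
        )
        return key.read_bytes(), csr.read_bytes()


def csr_subject(csr_pem: bytes) -> str:
    out = _run(
        ["req", "-noout", "-subject", "-nameopt", "RFC2253", "-in", "/dev/stdin"],
        input_bytes=csr_pem,
    )
    return _parse_cn(out.decode())


def _parse_cn(subject_line: str) -> str:
    # "subject=CN=site_a" (RFC2253)
    line = subject_line.strip()
    if "=" in line:
        line = line.split("=", 1)[1]
    for part in line.split(","):
        part = part.strip()
        if part.startswith("CN="):
            return part[3:]
    raise PKIError(f"no CN in subject {subject_line!r}")


def _csr_key_meets_floor(csr_pem: bytes):
    text = _run(["req", "-noout", "-text", "-in", "/dev/stdin"], input_bytes=csr_pem).decode()
    if "Public-Key:" in text:
        bits_line = next(l for l in text.splitlines() if "Public-Key:" in l)
        bits = int("".join(c for c in bits_line if c.isdigit()))
        if "RSA" in text or "rsaEncryption" in text:
            if bits < MIN_RSA_BITS:
                raise PKIError(f"CSR key RSA-{bits} below the RSA-{MIN_RSA_BITS} floor")
        else:
            if bits < 384:
                raise PKIError(f"CSR EC key {bits}-bit below the secp384r1 floor")


def issue_certificate(
    ca: Identity,
    csr_pem: bytes,
    subject: str,
    days=DEFAULT_VALIDITY_DAYS,
    not_before: _dt.datetime | None = None,
    not_after: _dt.datetime | None = None,
    digest="sha384",
) -> bytes:
    """Sign a CSR with the federation CA after checking the subject binding.

    The CSR's common name must equal the claimed *subject* (which in turn
    must be a roster identifier for collaborator certificates). Explicit
    ``not_before``/``not_after`` override ``days`` for expiry testing.
    """
    if digest not in ALLOWED_DIGESTS:
        raise PKIError(f"digest {digest!r} below the SHA-384 floor")
    actual = csr_subject(csr_pem)
    if actual != subject:
        raise PKIError(f"CSR subject {actual!r} does not match requested {subject!r}")
    _csr_key_meets_floor(csr_pem)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        (tmp / "req.csr").write_bytes(csr_pem)
        (tmp / "ca.crt").write_bytes(ca.cert_pem)
        (tmp / "ca.key").write_bytes(ca.key_pem)
        out = tmp / "issued.crt"
        args = [
            "x509", "-req",
            "-in", str(tmp / "req.csr"),
            "-CA", str(tmp / "ca.crt"),
            "-CAkey", str(tmp / "ca.key"),
            "-set_serial", str(secrets.randbits(63)),
            f"-{digest}",
            "-out", str(out),
        ]
        if not_before is not None or not_after is not None:
            if not_before is None or not_after is None:
                raise PKIError("not_before and not_after must be given together")
            args += ["-not_before", _ts(not_before), "-not_after", _ts(not_after)]
        else:
            args += ["-days", str(days)]
        _run(args)
        return out.read_bytes()


def verify_peer(cert_pem, trusted_root_pem, expected_subject, at_time=None, chain=()):
    """Accept iff the chain verifies to the trusted root, the certificate is
    within its validity window, and the subject CN matches.

    Returns ``(accepted: bool, reason: str)``; rejection is a return value,
    never an exception. *at_time* (a unix timestamp or datetime) injects the
    verification clock.
    """
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        (tmp / "peer.crt").write_bytes(cert_pem)
        (tmp / "root.crt").write_bytes(trusted_root_pem)
        args = ["verify", "-CAfile", str(tmp / "root.crt")]
        if chain:
            (tmp / "chain.crt").write_bytes(b"".join(chain))
            args += ["-untrusted", str(tmp / "chain.crt")]
        if at_time is not None:
            if isinstance(at_time, _dt.datetime):
                at_time = int(at_time.timestamp())
            args += ["-attime", str(int(at_time))]
        args.append(str(tmp / "peer.crt"))
        proc = subprocess.run(["openssl", *args], capture_output=True)
        if proc.returncode != 0:
            msg = (proc.stderr + proc.stdout).decode(errors="replace")
            if "expired" in msg:
                return False, "expired"
            if "not yet valid" in msg:
                return False, "not yet valid"
            return False, "untrusted chain"
        try:
            out = _run(
                ["x509", "-noout", "-subject", "-nameopt", "RFC2253", "-in", str(tmp / "peer.crt")]
            )
            cn = _parse_cn(out.decode())
        except PKIError as e:
            return False, str(e)
    if cn != expected_subject:
        return False, "subject mismatch"
    return True, "ok"


def cert_subject(cert_pem: bytes) -> str:
    out = _run(
        ["x509", "-noout", "-subject", "-nameopt", "RFC2253", "-in", "/dev/stdin"],
        input_bytes=cert_pem,
    )
    return _parse_cn(out.decode())


# ---------------------------------------------------------------------------
# on-disk layout used by the CLI cert workshop

def cert_dir_layout(root):
    root = Path(root)
    return {
        "ca": root / "cert" / "ca",
        "server": root / "cert" / "server",
        "client": root / "cert" / "client",
    }


def save_identity(identity: Identity, directory):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / f"{identity.subject}.key").write_bytes(identity.key_pem)
    (directory / f"{identity.subject}.crt").write_bytes(identity.cert_pem)
    return directory


def load_identity(subject, directory) -> Identity:
    directory = Path(directory)
    return Identity(
        subject,
        (directory / f"{subject}.key").read_bytes(),
        (directory / f"{subject}.crt").read_bytes(),
    )
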