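"""Anonymous key-code generation from identity-field patterns.

A key code is the anonymous join key that replaces personal information in
the claims database.  It is produced in two stages:

1. **Stream cipher.**  The identity fields selected by a pattern are
   serialized unambiguously, padded to a fixed block length L, and XOR-ed
   with a keystream derived from a secret key.  This yields a fixed-length
   *preliminary code* regardless of how long the underlying names or numbers
   are, so code lengths leak nothing about the original data.
2. **Hash.**  A 256-bit cryptographic hash of the preliminary code gives the
   final key code: a one-way, fixed-length digest from which the original
   fields cannot be regenerated.

Two records carry equal key codes for a pattern iff they carry identical
values in that pattern's fields, so equality of digests performs name
identification without any identity field ever entering the database.  A
pattern whose fields are incomplete on a record yields ``MISSING`` (no code
can be generated from absent data); multiple patterns are therefore generated
per record and combined downstream.

The secret is held by the code-generation authority, never stored alongside
the codes; a :class:`KeyCodeSession` loads it, emits codes, and destroys its
in-memory key material, after which the session refuses further cryptographic
work.  Both the keystream generator and the hash are injectable so the
pipeline is algorithm-agnostic; the default keystream is a SHA-256
pseudorandom generator run in counter mode, domain-separated per pattern via
a nonce so identical field values under different patterns cannot collide.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .model import IdentityBlock

__all__ = [
    "DEFAULT_BLOCK_LENGTH",
    "PATTERN_1",
    "PATTERN_2",
    "DEFAULT_PATTERNS",
    "MISSING",
    "KeyCodePattern",
    "KeyCode",
    "KeyCodeSession",
    "SessionDestroyedError",
    "PayloadTooLongError",
    "hash_counter_keystream",
    "identity_keystream",
    "serialize_pattern_fields",
    "pad_to_block",
    "stream_encrypt",
    "derive_keycode",
    "generate_keycodes",
    "read_patterns",
    "write_patterns",
]

DEFAULT_BLOCK_LENGTH = 64

IDENTITY_FIELDS = (
    "certificate_number",
    "name",
    "sex",
    "date_of_birth",
    "relationship",
)

MISSING = None  # sentinel for "no code can be generated: required field absent"


@dataclass(frozen=True)
class KeyCodePattern:
    """An ordered subset of identity fields used to generate one key code."""

    pattern_id: int
    field_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.field_names:
            raise ValueError("pattern field list must be non-empty")
        if len(set(self.field_names)) != len(self.field_names):
            raise ValueError("pattern field list must not repeat fields")
        unknown = set(self.field_names) - set(IDENTITY_FIELDS)
        if unknown:
            raise ValueError(f"unknown identity fields {sorted(unknown)}")
        if not 0 <= self.pattern_id <= 255:
            raise ValueError("pattern_id must fit in one byte")


# The two canonical evaluation patterns: certificate number + name + sex, and
# certificate number + date of birth + relationship status.
PATTERN_1 = KeyCodePattern(1, ("certificate_number", "name", "sex"))
PATTERN_2 = KeyCodePattern(2, ("certificate_number", "date_of_birth", "relationship"))
DEFAULT_PATTERNS = (PATTERN_1, PATTERN_2)


@dataclass(frozen=True)
class KeyCode:
    """Final anonymous code: a fixed-length hex digest tied to one pattern."""

    pattern_id: int
    digest: str


class SessionDestroyedError(RuntimeError):
    """Cryptographic operation attempted after the session key was destroyed."""


class PayloadTooLongError(ValueError):
    """Serialized identity payload exceeds the cipher block length."""


KeystreamFn = Callable[[bytes, int, int], bytes]


def hash_counter_keystream(secret: bytes, nonce: int, length: int) -> bytes:
    """Default keystream: SHA-256 pseudorandom generator in counter mode.

    Successive 32-byte blocks are SHA-256(secret || nonce || counter); the
    nonce provides domain separation between key-code patterns.
    """
    out = bytearray()
    counter = 0
    nonce_bytes = nonce.to_bytes(8, "big")
    while len(out) < length:
        out += hashlib.sha256(
            secret + nonce_bytes + counter.to_bytes(8, "big")
        ).digest()
        counter += 1
    return bytes(out[:length])


def identity_keystream(secret: bytes, nonce: int, length: int) -> bytes:
    """All-zero keystream (XOR identity). Test hook only — provides a known
    plaintext path so the hash stage can be checked against an independent
    implementation; never use in production configurations."""
    return bytes(length)


@dataclass
class KeyCodeSession:
    """Holds the stream-cipher secret for one code-generation run.

    ``destroy()`` overwrites the in-memory key material and flips the state;
    afterwards every cryptographic call raises :class:`SessionDestroyedError`.
    Codes generated before destruction remain valid plain values.  Nothing on
    the public surface exposes the secret or any decryption capability.
    """

    _secret: bytearray = field(repr=False)
    state: str = "open"
    block_length: int = DEFAULT_BLOCK_LENGTH
    keystream_fn: KeystreamFn = hash_counter_keystream
    hash_name: str = "sha256"

    @classmethod
    def from_secret(cls, secret: bytes, **kwargs) -> "KeyCodeSession":
        if not secret:
            raise ValueError("secret must be non-empty")
        return cls(_secret=bytearray(secret), **kwargs)

    @classmethod
    def from_secret_file(cls, path: str | Path, **kwargs) -> "KeyCodeSession":
        """Load a secret from a file holding its hex encoding."""
        text = Path(path).read_text(encoding="utf-8").strip()
        return cls.from_secret(bytes.fromhex(text), **kwargs)

    def _require_open(self) -> bytes:
        if self.state != "open":
            raise SessionDestroyedError("session secret has been destroyed")
        return bytes(self._secret)

    def destroy(self) -> None:
        """Release (delete) the decode key. Idempotent."""
        if self.state == "destroyed":
            return
        for i in range(len(self._secret)):
            self._secret[i] = 0
        self._secret = bytearray()
        self.state = "destroyed"


# ---------------------------------------------------------------------------
# Stage 0: serialization
# ---------------------------------------------------------------------------


def serialize_pattern_fields(
    identity: IdentityBlock, pattern: KeyCodePattern
) -> bytes | None:
    """Serialize the pattern's fields into an unambiguous byte payload.

    Returns ``MISSING`` (None) if any required field is empty: a key code
    cannot be generated when the data needed to generate it are absent.
    Encoding: one pattern_id byte, then per field a 2-byte big-endian length
    prefix followed by the field's UTF-8 bytes, in pattern order.  The length
    prefixes make the encoding injective — ("12345","X") and ("1234","5X")
    serialize differently.
    """
    values = [identity.get(name) for name in pattern.field_names]
    if any(v == "" for v in values):
        return MISSING
    payload = bytearray([pattern.pattern_id])
    for value in values:
        raw = value.encode("utf-8")
        if len(raw) > 0xFFFF:
            raise PayloadTooLongError(f"field value of {len(raw)} bytes exceeds encoding")
        payload += len(raw).to_bytes(2, "big")
        payload += raw
    return bytes(payload)


# ---------------------------------------------------------------------------
# Stage 1: pad + stream cipher -> preliminary code
# ---------------------------------------------------------------------------


def pad_to_block(payload: bytes, block_length: int = DEFAULT_BLOCK_LENGTH) -> bytes:
    """Injective padding: payload, one 0x80 byte, zeros up to the block length."""
    if len(payload) > block_length - 1:
        raise PayloadTooLongError(
            f"payload of {len(payload)} bytes exceeds block capacity {block_length - 1}"
        )
    return payload + b"\x80" + bytes(block_length - len(payload) - 1)


def stream_encrypt(block: bytes, session: KeyCodeSession, nonce: int = 0) -> bytes:
    """XOR the padded block with the session keystream: the preliminary code.

    Deterministic for a fixed (secret, nonce, block); output length equals the
    block length exactly.
    """
    secret = session._require_open()
    if len(block) != session.block_length:
        raise ValueError(
            f"block must be exactly {session.block_length} bytes, got {len(block)}"
        )
    keystream = session.keystream_fn(secret, nonce, len(block))
    return bytes(b ^ k for b, k in zip(block, keystream))


# ---------------------------------------------------------------------------
# Stage 2: hash -> key code
# ---------------------------------------------------------------------------


def derive_keycode(
    prelim: bytes, pattern_id: int, hash_name: str = "sha256"
) -> KeyCode:
    """Hash the preliminary code into the final fixed-length key code digest."""
    digest = hashlib.new(hash_name, prelim).hexdigest()
    return KeyCode(pattern_id=pattern_id, digest=digest)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def generate_keycodes(
    identity: IdentityBlock,
    patterns: Sequence[KeyCodePattern],
    session: KeyCodeSession,
) -> dict[int, KeyCode | None]:
    """Generate one key code (or MISSING) per configured pattern.

    Composes serialization, padding, the stream cipher (nonce = pattern_id),
    and the hash.  Identical identity values — whether they come from a
    receipt or from the insurer's registry — yield identical codes, which is
    what lets registry records join the linkage graph.
    """
    session._require_open()
    out: dict[int, KeyCode | None] = {}
    for pattern in patterns:
        payload = serialize_pattern_fields(identity, pattern)
        if payload is MISSING:
            out[pattern.pattern_id] = MISSING
            continue
        block = pad_to_block(payload, session.block_length)
        prelim = stream_encrypt(block, session, nonce=pattern.pattern_id)
        out[pattern.pattern_id] = derive_keycode(
            prelim, pattern.pattern_id, session.hash_name
        )
    return out


# ---------------------------------------------------------------------------
# Pattern configuration files
# ---------------------------------------------------------------------------


def read_patterns(path: str | Path) -> tuple[KeyCodePattern, ...]:
    """Read a pattern configuration: JSON list of {pattern_id, field_names}."""
    import json

    with Path(path).open("r", encoding="utf-8") as fh:
        raw = json.load(fh)
    patterns = tuple(
        KeyCodePattern(int(d["pattern_id"]), tuple(d["field_names"])) for d in raw
    )
    ids = [p.pattern_id for p in patterns]
    if len(set(ids)) != len(ids):
        raise ValueError("pattern_id values must be unique within a configuration")
    return patterns


def write_patterns(patterns: Iterable[KeyCodePattern], path: str | Path) -> None:
    import json

    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(
            [
                {"pattern_id": p.pattern_id, "field_names": list(p.field_names)}
                for p in patterns
            ],
            fh,
            indent=2,
        )
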