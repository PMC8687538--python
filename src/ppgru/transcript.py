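"""Ordered log of inter-party messages with byte counts.

Every interactive step of the protocol (ciphertext transfers for share
conversion and masked refresh, garbled tables, oblivious transfers, wire
labels, blinded bits) appends an entry here, which is what makes the
communication profile of a run auditable without asserting any particular
hardware-dependent number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = ["Transcript", "TranscriptEntry"]

_KINDS = {"ciphertext", "garbled tables", "OT", "labels", "bits"}


@dataclass(frozen=True)
class TranscriptEntry:
    round_label: str
    direction: str  # "server->client" | "client->server"
    n_bytes: int
    payload_kind: str


@dataclass
class Transcript:
    """Append-only message log; totals are always the sum of the entries."""

    entries: list = field(default_factory=list)

    def log(self, round_label: str, direction: str, n_bytes: int, payload_kind: str) -> None:
        if n_bytes < 0:
            raise ValueError("byte count must be non-negative")
        if payload_kind not in _KINDS:
            raise ValueError(f"unknown payload kind {payload_kind!r}")
        if direction not in ("server->client", "client->server"):
            raise ValueError(f"unknown direction {direction!r}")
        self.entries.append(TranscriptEntry(round_label, direction, int(n_bytes), payload_kind))

    @property
    def total_bytes(self) -> int:
        return sum(e.n_bytes for e in self.entries)

    def bytes_by_direction(self, direction: str) -> int:
        return sum(e.n_bytes for e in self.entries if e.direction == direction)

    def bytes_for_round(self, prefix: str) -> int:
        return sum(e.n_bytes for e in self.entries if e.round_label.startswith(prefix))

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "round": e.round_label,
                    "direction": e.direction,
                    "bytes": e.n_bytes,
                    "kind": e.payload_kind,
                }
                for e in self.entries
            ],
            indent=2,
        )
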