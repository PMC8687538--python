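"""Yao garbled-circuit engine and the adder+comparator circuit.

The input-adjustment protocol needs one specific two-party function: the
parties hold additive shares ``m_s`` (server) and ``m_c`` (client) of a
rounded pre-activation ``m``, the server additionally holds two blind bits
``b_g`` and ``b_l``, and the client must learn exactly the two blinded
comparison bits

    h_g = (m > R) xor b_g        h_l = (m < -R) xor b_l

and nothing else.  The circuit is a two's-complement ripple-carry adder
(internally widened by two bits so the share sum can never overflow) followed
by two constant-threshold comparisons and the XOR blinding.

Garbling is classic Yao with point-and-permute and free-XOR: wire labels are
128-bit strings whose least significant bit is the select bit, the two labels
of a wire differ by a global offset with select bit 1, XOR and NOT gates are
label arithmetic only, and each AND gate carries a four-row table encrypted
under a blake2s-based PRF.  Rows authenticate themselves (128 zero check
bits), so a corrupted label produces a decode failure rather than a silently
wrong output.  Oblivious transfer is an in-process "ideal OT": the sender
object never sees the choice bits, the receiver only ever sees its chosen
labels.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from functools import lru_cache

__all__ = [
    "BooleanCircuit",
    "GarbledCircuit",
    "CompareInputs",
    "GCError",
    "GCParameterError",
    "GCShapeError",
    "GCProtocolError",
    "GCDecodeError",
    "build_compare_circuit",
    "eval_plain",
    "garble",
    "evaluate_garbled",
    "decode_outputs",
    "ot_choose",
    "run_2pc_compare",
    "compare_oracle",
    "to_bits",
]

XOR, AND, NOT = 0, 1, 2

_MASK128 = (1 << 128) - 1


class GCError(Exception):
    """Base class for garbled-circuit errors."""


class GCParameterError(GCError, ValueError):
    pass


class GCShapeError(GCError, ValueError):
    pass


class GCProtocolError(GCError, RuntimeError):
    """Share out of range / overflow risk; caller must widen k or shrink masks."""


class GCDecodeError(GCError, RuntimeError):
    """An output label failed authentication (corrupted or invalid label)."""


@dataclass(frozen=True)
class BooleanCircuit:
    """Acyclic gate list over wires written exactly once.

    Wires 0 and 1 are the constant-0 and constant-1 wires; the garbler owns
    them and supplies their labels like any other garbler input.  ``gates``
    entries are ``(kind, a, b, out)`` with ``b = -1`` for NOT.  Integer inputs
    are two's-complement, LSB-first, ``width`` bits per integer.
    """

    n_wires: int
    gates: tuple
    input_map: dict
    output_map: dict
    width: int
    n_and: int

    def wires_of(self, name: str) -> list:
        return list(self.input_map[name])


@dataclass
class CompareInputs:
    """One comparator instance: shares, blinds, and the circuit constant R."""

    m_s: int
    m_c: int
    b_g: int
    b_l: int
    R: int


class _Builder:
    def __init__(self) -> None:
        self.n = 2  # wires 0/1 reserved for constants
        self.gates = []
        self.input_map = {}
        self.output_map = {}

    def inputs(self, name: str, count: int) -> list:
        ws = list(range(self.n, self.n + count))
        self.n += count
        self.input_map.setdefault(name, []).extend(ws)
        return ws

    def _new(self) -> int:
        w = self.n
        self.n += 1
        return w

    def xor(self, a: int, b: int) -> int:
        w = self._new()
        self.gates.append((XOR, a, b, w))
        return w

    def and_(self, a: int, b: int) -> int:
        w = self._new()
        self.gates.append((AND, a, b, w))
        return w

    def not_(self, a: int) -> int:
        w = self._new()
        self.gates.append((NOT, a, -1, w))
        return w

    def full_adder(self, a: int, b: int, cin: int):
        axb = self.xor(a, b)
        s = self.xor(axb, cin)
        cout = self.xor(self.and_(a, b), self.and_(axb, cin))
        return s, cout

    def add(self, a_bits: list, b_bits: list) -> list:
        # two's-complement addition mod 2^len; final carry dropped
        out, cin = [], 0  # wire 0 is constant 0
        for a, b in zip(a_bits, b_bits):
            s, cin = self.full_adder(a, b, cin)
            out.append(s)
        return out

    def add_const(self, a_bits: list, const: int) -> list:
        out, cin = [], 0
        for i, a in enumerate(a_bits):
            if (const >> i) & 1:
                axc = self.xor(a, cin)
                out.append(self.not_(axc))
                cin = self.xor(axc, self.and_(a, cin))  # a OR cin
            else:
                out.append(self.xor(a, cin))
                cin = self.and_(a, cin)
        return out


@lru_cache(maxsize=32)
def build_compare_circuit(k: int, R: int, n_slots: int = 1) -> BooleanCircuit:
    """Adder+comparator circuit for ``n_slots`` independent share pairs.

    Each slot contributes ``k``-bit inputs ``m_s`` and ``m_c`` plus one blind
    bit to each of ``b_g``/``b_l``; the outputs ``h_g``/``h_l`` hold one
    blinded comparison bit per slot.  Internally the sum is computed over
    ``k+2`` bits (sign-extended), so any pair of representable shares adds
    without overflow; strictness is exact: ``c_g = (m > R)``, ``c_l = (m < -R)``.
    """
    if k < 4:
        raise GCParameterError("comparator width k must be >= 4")
    if not (1 <= R < (1 << (k - 2))):
        raise GCParameterError(f"R={R} does not fit width k={k} (need R < 2^(k-2))")
    if n_slots < 1:
        raise GCParameterError("n_slots must be >= 1")
    b = _Builder()
    kk = k + 2
    hg_ws, hl_ws = [], []
    for _ in range(n_slots):
        ms = b.inputs("m_s", k)
        mc = b.inputs("m_c", k)
        bg = b.inputs("b_g", 1)[0]
        bl = b.inputs("b_l", 1)[0]
        ms_x = ms + [ms[-1]] * (kk - k)
        mc_x = mc + [mc[-1]] * (kk - k)
        m = b.add(ms_x, mc_x)
        # m > R  <=>  m - (R+1) >= 0  <=>  sign(m - (R+1)) = 0
        t_g = b.add_const(m, ((1 << kk) - (R + 1)) & ((1 << kk) - 1))
        c_g = b.not_(t_g[-1])
        # m < -R  <=>  m + R < 0  <=>  sign(m + R) = 1
        t_l = b.add_const(m, R)
        c_l = t_l[-1]
        hg_ws.append(b.xor(c_g, bg))
        hl_ws.append(b.xor(c_l, bl))
    b.output_map["h_g"] = hg_ws
    b.output_map["h_l"] = hl_ws
    return BooleanCircuit(
        n_wires=b.n,
        gates=tuple(b.gates),
        input_map={k_: tuple(v) for k_, v in b.input_map.items()},
        output_map={k_: tuple(v) for k_, v in b.output_map.items()},
        width=k,
        n_and=sum(1 for g in b.gates if g[0] == AND),
    )


def compare_oracle(m_s: int, m_c: int, b_g: int, b_l: int, R: int):
    """Arithmetic reference for the circuit: ((m>R)^b_g, (m<-R)^b_l)."""
    m = m_s + m_c
    return (int(m > R) ^ b_g, int(m < -R) ^ b_l)


def to_bits(value: int, k: int) -> list:
    """Two's-complement encoding, LSB first."""
    if not (-(1 << (k - 1)) <= value < (1 << (k - 1))):
        raise GCProtocolError(f"value {value} not representable in {k} signed bits")
    u = value & ((1 << k) - 1)
    return [(u >> i) & 1 for i in range(k)]


def eval_plain(circuit: BooleanCircuit, inputs: dict) -> dict:
    """Evaluate the Boolean circuit on plain bits (the garbling oracle)."""
    vals = [0] * circuit.n_wires
    vals[1] = 1
    for name, wires in circuit.input_map.items():
        bits = inputs[name]
        if len(bits) != len(wires):
            raise GCShapeError(f"input {name!r}: expected {len(wires)} bits, got {len(bits)}")
        for w, bit in zip(wires, bits):
            vals[w] = int(bit) & 1
    for kind, a, b, out in circuit.gates:
        if kind == XOR:
            vals[out] = vals[a] ^ vals[b]
        elif kind == AND:
            vals[out] = vals[a] & vals[b]
        else:
            vals[out] = vals[a] ^ 1
    return {name: [vals[w] for w in ws] for name, ws in circuit.output_map.items()}


# ---------------------------------------------------------------------------
# garbling
# ---------------------------------------------------------------------------


def _prf(data: bytes) -> int:
    return int.from_bytes(hashlib.blake2s(data).digest(), "little")


@dataclass
class GarbledCircuit:
    """Garbled form of a circuit plus the garbler's secrets.

    ``tables`` (one 4-row table per AND gate), ``decode`` (per-output-wire
    authentication hashes for both labels) and the circuit topology are what
    the evaluator receives; ``label0``/``delta`` stay with the garbler, who
    uses them to hand out input labels.
    """

    circuit: BooleanCircuit
    seed: int
    delta: int = field(repr=False)
    label0: list = field(repr=False)  # label of bit 0 for every wire (garbler side)
    tables: list = field(repr=False)  # per-AND-gate [4 x 256-bit int]
    decode: dict = field(repr=False)  # output name -> [(hash0, hash1) per wire]

    def input_labels(self, name: str, bits: list) -> list:
        """Garbler-side label selection for its own input bits."""
        wires = self.circuit.input_map[name]
        if len(bits) != len(wires):
            raise GCShapeError(f"input {name!r}: expected {len(wires)} bits")
        return [self.label0[w] ^ (self.delta if (bit & 1) else 0) for w, bit in zip(wires, bits)]

    def label_pairs(self, name: str) -> list:
        """(label0, label1) pairs for the named input — the OT sender's input."""
        return [(self.label0[w], self.label0[w] ^ self.delta) for w in self.circuit.input_map[name]]

    def const_labels(self) -> dict:
        return {0: self.label0[0], 1: self.label0[1] ^ self.delta}

    def tables_byte_size(self) -> int:
        return self.circuit.n_and * 4 * 32


def _out_tag(wire: int, label: int) -> int:
    return _prf(label.to_bytes(16, "little") + b"out" + struct.pack("<i", wire))


def garble(circuit: BooleanCircuit, seed: int) -> GarbledCircuit:
    """Garble with a seed-keyed PRF; same (circuit, seed) -> identical garbling."""
    sb = struct.pack("<q", int(seed))
    delta = _prf(sb + b"delta") & _MASK128 | 1  # select bit of the offset is 1
    label0 = [0] * circuit.n_wires
    for w in range(2):
        label0[w] = _prf(sb + b"const" + struct.pack("<i", w)) & _MASK128
    for wires in circuit.input_map.values():
        for w in wires:
            label0[w] = _prf(sb + b"in" + struct.pack("<i", w)) & _MASK128
    tables = []
    gid = 0
    for kind, a, b, out in circuit.gates:
        if kind == XOR:
            label0[out] = label0[a] ^ label0[b]
        elif kind == NOT:
            # the evaluator keeps its held label; semantics flip garbler-side
            label0[out] = label0[a] ^ delta
        else:
            c0 = _prf(sb + b"and" + struct.pack("<i", gid)) & _MASK128
            label0[out] = c0
            gh = struct.pack("<i", gid)
            rows = [0, 0, 0, 0]
            for va in (0, 1):
                la = label0[a] ^ (delta if va else 0)
                for vb in (0, 1):
                    lb = label0[b] ^ (delta if vb else 0)
                    lo = c0 ^ (delta if (va & vb) else 0)
                    idx = ((la & 1) << 1) | (lb & 1)
                    pad = _prf(la.to_bytes(16, "little") + lb.to_bytes(16, "little") + gh)
                    rows[idx] = pad ^ (lo << 128)
            tables.append(rows)
            gid += 1
    decode = {
        name: [(_out_tag(w, label0[w]), _out_tag(w, label0[w] ^ delta)) for w in ws]
        for name, ws in circuit.output_map.items()
    }
    return GarbledCircuit(circuit, int(seed), delta, label0, tables, decode)


def evaluate_garbled(gc_or_view, input_labels: dict) -> dict:
    """Evaluate a garbled circuit given one label per input wire.

    ``input_labels`` maps input name -> list of held labels (const labels under
    the reserved name ``"__const__"`` as ``[label_for_0, label_for_1]``).
    Returns held labels per output name; decode with :func:`decode_outputs`.
    """
    circuit = gc_or_view.circuit
    tables = gc_or_view.tables
    held = [0] * circuit.n_wires
    held[0], held[1] = input_labels["__const__"]
    for name, wires in circuit.input_map.items():
        labels = input_labels[name]
        if len(labels) != len(wires):
            raise GCShapeError(f"labels for {name!r}: expected {len(wires)}, got {len(labels)}")
        for w, lab in zip(wires, labels):
            held[w] = lab
    gid = 0
    prf = hashlib.blake2s
    for kind, a, b, out in circuit.gates:
        if kind == XOR:
            held[out] = held[a] ^ held[b]
        elif kind == NOT:
            held[out] = held[a]
        else:
            la, lb = held[a], held[b]
            row = tables[gid][((la & 1) << 1) | (lb & 1)]
            gid += 1
            pad = int.from_bytes(
                prf(
                    la.to_bytes(16, "little") + lb.to_bytes(16, "little") + struct.pack("<i", gid - 1)
                ).digest(),
                "little",
            )
            val = row ^ pad
            if val & _MASK128:
                raise GCDecodeError(f"AND gate {gid - 1}: row authentication failed")
            held[out] = val >> 128
    return {name: [held[w] for w in ws] for name, ws in circuit.output_map.items()}


def decode_outputs(gc_or_view, held: dict) -> dict:
    """Map held output labels to bits; unrecognized labels raise GCDecodeError."""
    circuit = gc_or_view.circuit
    out = {}
    for name, ws in circuit.output_map.items():
        pairs = gc_or_view.decode[name]
        bits = []
        for (w, lab), (h0, h1) in zip(zip(ws, held[name]), pairs):
            tag = _out_tag(w, lab)
            if tag == h0:
                bits.append(0)
            elif tag == h1:
                bits.append(1)
            else:
                raise GCDecodeError(f"output wire {w}: label failed decode check")
        out[name] = bits
    return out


# ---------------------------------------------------------------------------
# oblivious transfer (ideal, in-process) and the two-party comparison
# ---------------------------------------------------------------------------


def ot_choose(sender_labels: list, choice_bits: list) -> list:
    """Ideal 1-of-2 OT batch: the receiver gets exactly its chosen labels.

    Structural isolation stands in for the cryptographic guarantee: the
    function receives the sender's pairs and the receiver's bits and returns
    only the chosen labels; neither party object ever holds the other's input.
    """
    if len(sender_labels) != len(choice_bits):
        raise GCShapeError(
            f"OT count mismatch: {len(sender_labels)} pairs vs {len(choice_bits)} choices"
        )
    out = []
    for pair, bit in zip(sender_labels, choice_bits):
        if len(pair) != 2:
            raise GCShapeError("each OT sender input must be a (label0, label1) pair")
        out.append(pair[int(bit) & 1])
    return out


def run_2pc_compare(server: dict, client: dict, k: int, R: int, *, seed: int, transcript=None):
    """Full garbled comparison: client learns the blinded bits, nothing more.

    ``server`` holds ``m_s`` (int or list), ``b_g``, ``b_l``; ``client`` holds
    ``m_c``.  Vector inputs are batched into a single garbled execution over a
    concatenated-wire circuit.  Returns ``(h_g, h_l)`` matching the input
    shape (scalars for scalar inputs, lists otherwise).
    """
    scalar = not isinstance(server["m_s"], (list, tuple))
    m_s = [server["m_s"]] if scalar else list(server["m_s"])
    b_g = [server["b_g"]] if scalar else list(server["b_g"])
    b_l = [server["b_l"]] if scalar else list(server["b_l"])
    m_c = [client["m_c"]] if scalar else list(client["m_c"])
    if not (len(m_s) == len(b_g) == len(b_l) == len(m_c)):
        raise GCShapeError("mismatched slot counts across comparison inputs")
    n = len(m_s)
    circuit = build_compare_circuit(k, R, n)
    gc = garble(circuit, seed)

    # server side: garble, select own labels
    ms_bits = [bit for v in m_s for bit in to_bits(int(v), k)]
    server_labels = {
        "m_s": gc.input_labels("m_s", ms_bits),
        "b_g": gc.input_labels("b_g", [int(x) & 1 for x in b_g]),
        "b_l": gc.input_labels("b_l", [int(x) & 1 for x in b_l]),
        "__const__": [gc.const_labels()[0], gc.const_labels()[1]],
    }
    # client side: OT for its share bits
    mc_bits = [bit for v in m_c for bit in to_bits(int(v), k)]
    chosen = ot_choose(gc.label_pairs("m_c"), mc_bits)

    if transcript is not None:
        transcript.log("2pc/garbled-tables", "server->client", gc.tables_byte_size(), "garbled tables")
        n_direct = len(ms_bits) + 2 * n + 2
        transcript.log("2pc/garbler-labels", "server->client", 16 * n_direct, "labels")
        transcript.log("2pc/ot", "client->server", len(mc_bits), "OT")
        transcript.log("2pc/ot", "server->client", 32 * len(mc_bits), "OT")

    held = evaluate_garbled(gc, {**server_labels, "m_c": chosen})
    bits = decode_outputs(gc, held)
    h_g, h_l = bits["h_g"], bits["h_l"]
    if scalar:
        return h_g[0], h_l[0]
    return h_g, h_l
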