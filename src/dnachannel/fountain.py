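"""Minimal LT fountain codec and droplet -> DNA mapping.

This module supplies everything the channel studies need on the encoding
side, with no external data: a deterministic pseudo-random file generator, an
LT (Luby transform) encoder with a robust-soliton degree distribution, a
peeling (belief-propagation) decoder that measures how many droplets a decode
actually consumes — the (1+beta)M samples the redundancy planner fits — and
the 2-bits-per-base mapping that turns droplets into fixed-length DNA
sequences (seed + payload + RS placeholder bytes).

Reed–Solomon codes are modelled at the capacity level only: ``L_RS`` parity
bytes correct up to ``floor(L_RS / 2)`` byte errors (:func:`rs_recoverable`);
no finite-field arithmetic is performed, which is exactly the granularity the
redundancy-planning equations require.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Droplet",
    "generate_file",
    "robust_soliton",
    "lt_encode",
    "lt_droplet_stream",
    "lt_decode",
    "lt_min_droplets",
    "droplet_members",
    "droplets_to_dna",
    "dna_to_bytes",
    "bytes_to_dna",
    "rs_recoverable",
    "byte_errors",
    "DecodeFailure",
]

BASES = "ACGT"
_SEED_BYTES = 4  # droplet seed width in the DNA layout


class DecodeFailure(RuntimeError):
    """Raised when the droplet stream is exhausted before decoding finishes."""

    def __init__(self, resolved: int, total: int):
        super().__init__(f"stream exhausted with {resolved}/{total} chunks resolved")
        self.resolved = resolved
        self.total = total


def generate_file(size_bytes: int, seed: int) -> bytes:
    """Deterministic pseudo-random payload of ``size_bytes`` bytes."""
    if size_bytes < 1:
        raise ValueError("file size must be >= 1 byte")
    rng = np.random.Generator(np.random.PCG64(seed))
    return rng.integers(0, 256, size_bytes, dtype=np.uint8).tobytes()


def robust_soliton(M: int, c: float = 0.05, delta: float = 0.05) -> np.ndarray:
    """Robust-soliton degree pmf over degrees 1..M.

    The ideal soliton rho is patched by the spike-and-tail term tau with
    ripple-size parameter R = c * ln(M/delta) * sqrt(M), then normalized.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if M == 1:
        return np.array([1.0])
    d = np.arange(1, M + 1)
    rho = np.zeros(M)
    rho[0] = 1.0 / M
    rho[1:] = 1.0 / (d[1:] * (d[1:] - 1.0))
    tau = np.zeros(M)
    R = c * np.log(M / delta) * np.sqrt(M)
    if R > 1:
        spike = int(min(M, max(1, round(M / R))))
        tau[: spike - 1] = R / (d[: spike - 1] * M)
        tau[spike - 1] = R * np.log(R / delta) / M
    pmf = rho + tau
    return pmf / pmf.sum()


def _chunk(data: bytes, M: int) -> np.ndarray:
    """Split (and zero-pad) data into M equal chunks, as a (M, L) byte array."""
    if M < 1:
        raise ValueError("M must be >= 1")
    chunk_len = -(-len(data) // M)
    padded = data + b"\x00" * (M * chunk_len - len(data))
    return np.frombuffer(padded, dtype=np.uint8).reshape(M, chunk_len).copy()


@dataclass(frozen=True)
class Droplet:
    """One fountain-code output unit.

    The member set (which chunks were XOR-ed) is not stored: it is re-derived
    from ``seed`` via the documented PRNG (numpy PCG64) and the degree
    distribution, exactly as a decoder would.
    """

    seed: int
    payload: bytes

    def members(self, M: int, pmf: np.ndarray) -> frozenset[int]:
        return droplet_members(self.seed, M, pmf)


def droplet_members(seed: int, M: int, pmf: np.ndarray) -> frozenset[int]:
    """Degree and member set implied by a droplet seed."""
    rng = np.random.Generator(np.random.PCG64(seed))
    degree = int(rng.choice(len(pmf), p=pmf)) + 1
    return frozenset(int(x) for x in rng.choice(M, size=degree, replace=False))


def lt_droplet_stream(
    data: bytes, M: int, seed: int, c: float = 0.05, delta: float = 0.05
) -> Iterator[Droplet]:
    """Endless reproducible droplet stream for ``data`` split into M chunks."""
    chunks = _chunk(data, M)
    pmf = robust_soliton(M, c, delta)
    master = np.random.Generator(np.random.PCG64(seed))
    while True:
        dseed = int(master.integers(0, 2**32))
        members = droplet_members(dseed, M, pmf)
        payload = np.bitwise_xor.reduce(chunks[sorted(members)], axis=0)
        yield Droplet(dseed, payload.tobytes())


def lt_encode(
    data: bytes, M: int, n_droplets: int, seed: int, c: float = 0.05, delta: float = 0.05
) -> list[Droplet]:
    """Encode ``data`` into ``n_droplets`` droplets ((1+alpha)M of them when
    encoding at fountain overhead alpha)."""
    stream = lt_droplet_stream(data, M, seed, c, delta)
    return [next(stream) for _ in range(n_droplets)]


class _Peeler:
    """Incremental peeling decoder: feed droplets, read out chunks."""

    def __init__(self, M: int, chunk_len: int, pmf: np.ndarray):
        self.M = M
        self.pmf = pmf
        self.chunks: list[bytes | None] = [None] * M
        self.resolved = 0
        self.pending: dict[int, tuple[set[int], np.ndarray]] = {}
        self.by_member: dict[int, set[int]] = {}
        self._next_id = 0
        self.chunk_len = chunk_len

    def feed(self, droplet: Droplet) -> None:
        members = set(droplet_members(droplet.seed, self.M, self.pmf))
        payload = np.frombuffer(droplet.payload, dtype=np.uint8).copy()
        for m in [m for m in members if self.chunks[m] is not None]:
            payload ^= np.frombuffer(self.chunks[m], dtype=np.uint8)
            members.discard(m)
        if not members:
            return
        did = self._next_id
        self._next_id += 1
        self.pending[did] = (members, payload)
        for m in members:
            self.by_member.setdefault(m, set()).add(did)
        if len(members) == 1:
            self._peel((next(iter(members)), payload))

    def _peel(self, first: tuple[int, np.ndarray]) -> None:
        queue = [first]
        while queue:
            chunk_id, payload = queue.pop()
            if self.chunks[chunk_id] is not None:
                continue
            self.chunks[chunk_id] = payload.tobytes()
            self.resolved += 1
            # XOR from the frozen stored bytes: `payload` may alias a pending
            # droplet's array and be zeroed by its own update below
            src = np.frombuffer(self.chunks[chunk_id], dtype=np.uint8)
            for did in list(self.by_member.get(chunk_id, ())):
                members, dpay = self.pending[did]
                dpay ^= src
                members.discard(chunk_id)
                self.by_member[chunk_id].discard(did)
                if len(members) == 1:
                    last = next(iter(members))
                    del self.pending[did]
                    self.by_member[last].discard(did)
                    queue.append((last, dpay.copy()))
                elif not members:
                    del self.pending[did]

    @property
    def done(self) -> bool:
        return self.resolved == self.M


class _GF2Solver:
    """Inactivation decoder: incremental GF(2) elimination over droplets.

    Each droplet is a row ``(member vector | payload bits)`` packed into one
    Python integer, so eliminating a pivot XORs the payload along with the
    membership vector.  Rank reaches M exactly when the received droplets
    determine every chunk — the minimum-droplets count of a decoder that
    wastes nothing (peeling plus elimination of the stalled residual).
    """

    def __init__(self, M: int, chunk_len: int):
        self.M = M
        self.payload_bits = 8 * chunk_len
        self.chunk_len = chunk_len
        self.basis: dict[int, int] = {}  # pivot chunk -> reduced row

    def feed_row(self, members: Iterable[int], payload: bytes) -> None:
        vec = 0
        for m in members:
            vec |= 1 << m
        row = (vec << self.payload_bits) | int.from_bytes(payload, "big")
        shift = self.payload_bits
        while row >> shift:
            piv = (row >> shift).bit_length() - 1
            pivot_row = self.basis.get(piv)
            if pivot_row is None:
                self.basis[piv] = row
                return
            row ^= pivot_row

    @property
    def done(self) -> bool:
        return len(self.basis) == self.M

    def solve(self) -> list[bytes]:
        if not self.done:
            raise DecodeFailure(len(self.basis), self.M)
        shift = self.payload_bits
        mask = (1 << shift) - 1
        chunks: list[bytes] = [b""] * self.M
        for piv in sorted(self.basis):  # back-substitute from low pivots up
            row = self.basis[piv]
            vec = (row >> shift) ^ (1 << piv)
            while vec:
                sub = vec.bit_length() - 1
                row ^= self.basis[sub]
                vec = (row >> shift) ^ (1 << piv)
            self.basis[piv] = row
            chunks[piv] = (row & mask).to_bytes(self.chunk_len, "big")
        return chunks


def lt_decode(
    droplets: Iterable[Droplet],
    M: int,
    data_len: int | None = None,
    c: float = 0.05,
    delta: float = 0.05,
    method: str = "inactivation",
) -> bytes:
    """Decode a droplet collection back into the original data.

    ``method="peeling"`` uses pure belief propagation; the default
    ``"inactivation"`` additionally solves the stalled residual system by
    GF(2) elimination, the strategy of production fountain decoders.
    """
    droplets = list(droplets)
    if not droplets:
        raise DecodeFailure(0, M)
    chunk_len = len(droplets[0].payload)
    pmf = robust_soliton(M, c, delta)
    if method == "peeling":
        peeler = _Peeler(M, chunk_len, pmf)
        for drop in droplets:
            peeler.feed(drop)
            if peeler.done:
                break
        if not peeler.done:
            raise DecodeFailure(peeler.resolved, M)
        data = b"".join(peeler.chunks)  # type: ignore[arg-type]
    elif method == "inactivation":
        solver = _GF2Solver(M, chunk_len)
        for drop in droplets:
            solver.feed_row(droplet_members(drop.seed, M, pmf), drop.payload)
            if solver.done:
                break
        data = b"".join(solver.solve())
    else:
        raise ValueError("method must be 'peeling' or 'inactivation'")
    return data[:data_len] if data_len is not None else data


def lt_min_droplets(
    droplets: Iterable[Droplet],
    M: int,
    c: float = 0.05,
    delta: float = 0.05,
    method: str = "inactivation",
) -> int:
    """Feed droplets one at a time; return how many were consumed when every
    chunk resolved — one sample of the decoding overhead (1+beta)M.

    The default inactivation decoder needs close to M droplets (a few percent
    of duplicates/rank deficiency); pure peeling stalls earlier and its
    overhead at M ~ 2000 is several times larger.
    """
    if method not in ("peeling", "inactivation"):
        raise ValueError("method must be 'peeling' or 'inactivation'")
    peeler: _Peeler | None = None
    solver: _GF2Solver | None = None
    pmf = None
    n = 0
    for drop in droplets:
        if pmf is None:
            pmf = robust_soliton(M, c, delta)
        n += 1
        if method == "peeling":
            if peeler is None:
                peeler = _Peeler(M, len(drop.payload), pmf)
            peeler.feed(drop)
            if peeler.done:
                return n
        else:
            if solver is None:
                solver = _GF2Solver(M, len(drop.payload))
            solver.feed_row(droplet_members(drop.seed, M, pmf), drop.payload)
            if solver.done:
                return n
    resolved = peeler.resolved if peeler else (len(solver.basis) if solver else 0)
    raise DecodeFailure(resolved, M)


# ---------------------------------------------------------------------------
# droplet <-> DNA mapping
# ---------------------------------------------------------------------------

_BYTE_TO_DNA = ["".join(BASES[(b >> s) & 3] for s in (6, 4, 2, 0)) for b in range(256)]
_DNA_TO_VAL = {b: i for i, b in enumerate(BASES)}


def bytes_to_dna(data: bytes) -> str:
    """2 bits/base, MSB first: A=00, C=01, G=10, T=11 (0x1B -> "ACGT")."""
    return "".join(_BYTE_TO_DNA[b] for b in data)


def dna_to_bytes(seq: str) -> bytes:
    if len(seq) % 4:
        raise ValueError("DNA length must be a multiple of 4 to decode bytes")
    out = bytearray()
    for i in range(0, len(seq), 4):
        val = 0
        for ch in seq[i : i + 4]:
            val = (val << 2) | _DNA_TO_VAL[ch]
        out.append(val)
    return bytes(out)


def _placeholder_parity(body: bytes, l_rs: int) -> bytes:
    """Deterministic stand-in parity bytes (not true Reed–Solomon codewords:
    error handling is modelled by capacity counting, see rs_recoverable)."""
    out = bytearray()
    acc_xor, acc_sum = 0, 0
    for b in body:
        acc_xor ^= b
        acc_sum = (acc_sum + b) & 0xFF
    for k in range(l_rs):
        out.append((acc_xor + k * acc_sum) & 0xFF)
    return bytes(out)


def droplets_to_dna(droplets: Sequence[Droplet], l_rs: int = 2) -> list[str]:
    """Map droplets to DNA strands: 4-byte seed + payload + L_RS parity bytes.

    A 4-byte seed, 20-byte payload and 2 parity bytes give the 104-nt strand
    layout used throughout the default study.
    """
    if l_rs < 0:
        raise ValueError("l_rs must be >= 0")
    out = []
    for d in droplets:
        body = d.seed.to_bytes(_SEED_BYTES, "big") + d.payload
        out.append(bytes_to_dna(body + _placeholder_parity(body, l_rs)))
    return out


def byte_errors(read: str, reference: str) -> int:
    """Number of differing bytes (4-nt blocks) between equal-length strands."""
    if len(read) != len(reference):
        raise ValueError("byte_errors requires equal lengths")
    mism = {i // 4 for i, (a, b) in enumerate(zip(read, reference)) if a != b}
    return len(mism)


def rs_recoverable(read: str, reference: str, l_rs: int) -> bool:
    """Capacity rule: recoverable iff byte errors <= floor(L_RS / 2).

    Length mismatches are treated as unrecoverable (the RS abstraction has no
    notion of synchronization loss).
    """
    if len(read) != len(reference):
        return False
    return byte_errors(read, reference) <= l_rs // 2
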