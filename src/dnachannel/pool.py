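"""Variant-table representation of an oligo pool and the two channel primitives.

A designed (reference) sequence does not exist as a single molecule in an oligo
pool: it is present as many copies, each possibly carrying errors.  The pool is
therefore represented per reference as a table of *variants* — distinct edited
versions of the reference, each identified by a canonical edit list and carrying
a copy number.  Every stage of the storage channel is a composition of exactly
two primitives acting on this table:

* :func:`generate_errors` (the E primitive) — molecules independently acquire
  new substitutions/deletions/insertions and move between variants; the total
  copy number of each reference is conserved exactly.
* :func:`change_distribution` (the D primitive) — every variant's copy number
  is replaced by an independent stochastic draw (thinning, amplification, ...);
  a reference whose total drops to zero is lost.

Edit coordinates are 0-based offsets into the *original* reference, and edits
are applied substitutions first, then deletions, then insertions, so an edit
list has a unique canonical form and variant identity is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "BASES",
    "Edit",
    "VariantRecord",
    "ErrorRates",
    "SequencePool",
    "CoordinateError",
    "ValidationError",
    "materialize",
    "diff",
    "generate_errors",
    "change_distribution",
    "binomial_thinning",
    "edits_to_string",
    "string_to_edits",
    "canonicalize",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# ops, in canonical order: substitution < deletion < insertion
OP_SUB, OP_DEL, OP_INS = 0, 1, 2
_OP_CHARS = "SDI"
_OP_INDEX = {c: i for i, c in enumerate(_OP_CHARS)}

# integer packing of one edit: position * 16 + op * 4 + base
_POS_STRIDE = 16

_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _ch in enumerate(BASES):
    _CODE_LUT[ord(_ch)] = _b


class CoordinateError(ValueError):
    """An edit position falls outside the reference."""


class ValidationError(ValueError):
    """A value violates a documented contract."""


class Edit(NamedTuple):
    """One elementary edit against a reference sequence.

    ``position`` is a 0-based offset into the original reference; insertions
    insert *before* that offset (``position == len(reference)`` appends).
    ``base`` is the new base for substitutions/insertions and ``None`` for
    deletions.
    """

    position: int
    op: str  # 'S' | 'D' | 'I'
    base: str | None = None

    def __str__(self) -> str:
        return f"{self.position}{self.op}{self.base or ''}"


def _edit_to_code(e: Edit) -> int:
    b = 0 if e.base is None else _BASE_INDEX[e.base]
    return e.position * _POS_STRIDE + _OP_INDEX[e.op] * 4 + b


def _code_to_edit(code: int) -> Edit:
    pos, rest = divmod(code, _POS_STRIDE)
    op, b = divmod(rest, 4)
    return Edit(pos, _OP_CHARS[op], None if op == OP_DEL else BASES[b])


def edits_to_string(edits: Iterable[Edit]) -> str:
    """Serialize an edit list to the documented grammar, e.g. ``"1SG;2D"``."""
    return ";".join(str(e) for e in edits)


def string_to_edits(s: str) -> tuple[Edit, ...]:
    """Parse the ``"1SG;2D"`` edit-string grammar back to an edit tuple."""
    if not s:
        return ()
    out = []
    for token in s.split(";"):
        i = 0
        while i < len(token) and token[i].isdigit():
            i += 1
        if i == 0 or i == len(token):
            raise ValidationError(f"malformed edit token {token!r}")
        pos, op, rest = int(token[:i]), token[i], token[i + 1 :]
        if op not in _OP_INDEX or (op == "D") != (rest == ""):
            raise ValidationError(f"malformed edit token {token!r}")
        if rest and rest not in _BASE_INDEX:
            raise ValidationError(f"bad base in edit token {token!r}")
        out.append(Edit(pos, op, rest or None))
    return tuple(out)


def canonicalize(edits: Iterable[Edit]) -> tuple[Edit, ...]:
    """Stable-sort edits by (position, op-order S<D<I) into canonical form.

    The sort is stable so several insertions at one position keep their
    left-to-right order (they insert a multi-base run, and order matters).
    """
    return tuple(sorted(edits, key=lambda e: (e.position, _OP_INDEX[e.op])))


def _validate_edits(reference: str, edits: Sequence[Edit]) -> None:
    L = len(reference)
    seen: set[tuple[int, int]] = set()
    for e in edits:
        opi = _OP_INDEX.get(e.op)
        if opi is None:
            raise ValidationError(f"unknown edit op {e.op!r}")
        hi = L if opi == OP_INS else L - 1
        if not 0 <= e.position <= hi:
            raise CoordinateError(f"edit {e} out of range for length-{L} reference")
        if opi == OP_DEL:
            if e.base is not None:
                raise ValidationError(f"deletion {e} must not carry a base")
        else:
            if e.base not in _BASE_INDEX:
                raise ValidationError(f"edit {e} needs a base in {BASES}")
            if opi == OP_SUB and reference[e.position] == e.base:
                raise ValidationError(f"substitution {e} equals the reference base")
        key = (e.position, opi)
        if opi != OP_INS:  # several insertions may stack at one position
            if key in seen:
                raise ValidationError(f"duplicate edit at position {e.position} op {e.op}")
            if (e.position, OP_SUB if opi == OP_DEL else OP_DEL) in seen:
                raise ValidationError(
                    f"contradictory substitution and deletion at position {e.position}"
                )
            seen.add(key)


@dataclass(frozen=True)
class VariantRecord:
    """One error type of a reference: a canonical edit list plus a copy number."""

    edits: tuple[Edit, ...]
    count: int

    def __post_init__(self):
        if self.count < 0:
            raise ValidationError("variant copy number must be >= 0")
        object.__setattr__(self, "edits", canonicalize(self.edits))


def materialize(reference: str, edits: Sequence[Edit]) -> str:
    """Apply an edit list to a reference and return the molecule sequence.

    Substitutions are applied first, then deletions, then insertions, all in
    original-reference coordinates, so the result does not depend on the order
    in which the edits are listed.
    """
    _validate_edits(reference, edits)
    return _materialize_codes(reference, [_edit_to_code(e) for e in edits])


def _materialize_codes(reference: str, codes: Iterable[int]) -> str:
    subs: dict[int, str] = {}
    dels: set[int] = set()
    ins: dict[int, list[str]] = {}
    for code in codes:
        pos, rest = divmod(code, _POS_STRIDE)
        op, b = divmod(rest, 4)
        if op == OP_SUB:
            subs[pos] = BASES[b]
        elif op == OP_DEL:
            dels.add(pos)
        else:
            ins.setdefault(pos, []).append(BASES[b])
    out: list[str] = []
    for i, base in enumerate(reference):
        if i in ins:
            out += ins[i]
        if i in dels:
            continue
        out.append(subs.get(i, base))
    if len(reference) in ins:
        out += ins[len(reference)]
    return "".join(out)


def diff(reference: str, read: str) -> tuple[Edit, ...]:
    """Minimum unit-cost edit script turning ``reference`` into ``read``.

    Ties between equally cheap scripts are broken deterministically: prefer
    matches, then substitution over deletion over insertion, scanning from the
    left, which yields the leftmost canonical script.  The round trip
    ``materialize(reference, diff(reference, read)) == read`` always holds.
    """
    if not reference or not read:
        raise ValidationError("diff requires non-empty sequences")
    n, m = len(reference), len(read)
    ref_a = np.frombuffer(reference.encode(), dtype=np.uint8)
    read_a = np.frombuffer(read.encode(), dtype=np.uint8)
    # dp[i, j] = cost of aligning reference[i:] with read[j:]
    dp = np.zeros((n + 1, m + 1), dtype=np.int32)
    dp[n] = m - np.arange(m + 1)
    dp[:, m] = n - np.arange(n + 1)
    for i in range(n - 1, -1, -1):
        cand = np.minimum(dp[i + 1, 1:] + (ref_a[i] != read_a), dp[i + 1, :m] + 1)
        row = dp[i]
        for j in range(m - 1, -1, -1):  # right-to-left so insertion sees row[j+1]
            c = row[j + 1] + 1
            row[j] = c if c < cand[j] else cand[j]
    edits: list[Edit] = []
    i = j = 0
    while i < n or j < m:
        if i < n and j < m and reference[i] == read[j] and dp[i, j] == dp[i + 1, j + 1]:
            i += 1
            j += 1
        elif i < n and j < m and reference[i] != read[j] and dp[i, j] == dp[i + 1, j + 1] + 1:
            edits.append(Edit(i, "S", read[j]))
            i += 1
            j += 1
        elif i < n and dp[i, j] == dp[i + 1, j] + 1:
            edits.append(Edit(i, "D"))
            i += 1
        else:
            edits.append(Edit(i, "I", read[j]))
            j += 1
    return canonicalize(edits)


@dataclass(frozen=True, eq=False)
class ErrorRates:
    """Flat per-base error rates for one channel stage.

    ``t_sub`` is a 4x4 matrix of substitution probabilities (row = original
    base in A,C,G,T order, column = new base); the diagonal is ignored and
    treated as no-change mass.  ``p_del`` and ``p_ins`` are per-base deletion
    and per-position insertion probabilities.
    """

    t_sub: np.ndarray
    p_del: float = 0.0
    p_ins: float = 0.0

    def __post_init__(self):
        t = np.array(self.t_sub, dtype=float)
        if t.shape != (4, 4):
            raise ValidationError("t_sub must be 4x4")
        object.__setattr__(self, "t_sub", t)
        off = t - np.diag(np.diag(t))
        if (t < 0).any() or (t > 1).any() or (off.sum(axis=1) > 1).any():
            raise ValidationError(
                "t_sub entries must be probabilities with off-diagonal row sums <= 1"
            )
        if not (0 <= self.p_del <= 1 and 0 <= self.p_ins <= 1):
            raise ValidationError("p_del and p_ins must lie in [0, 1]")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ErrorRates)
            and np.array_equal(self.t_sub, other.t_sub)
            and self.p_del == other.p_del
            and self.p_ins == other.p_ins
        )

    def __hash__(self):
        return hash((self.t_sub.tobytes(), self.p_del, self.p_ins))

    @classmethod
    def uniform(cls, sub: float = 0.0, dele: float = 0.0, ins: float = 0.0) -> "ErrorRates":
        """Uniform rates: total substitution probability ``sub`` split evenly
        over the three alternative bases, plus flat deletion/insertion rates."""
        t = np.full((4, 4), sub / 3.0)
        np.fill_diagonal(t, 0.0)
        return cls(t, dele, ins)

    @property
    def sub_totals(self) -> np.ndarray:
        """Per-base total substitution probability (off-diagonal row sums)."""
        off = self.t_sub - np.diag(np.diag(self.t_sub))
        return off.sum(axis=1)

    @property
    def is_zero(self) -> bool:
        return self.p_del == 0 and self.p_ins == 0 and float(self.sub_totals.sum()) == 0

    def to_dict(self) -> dict:
        return {"t_sub": self.t_sub.tolist(), "p_del": self.p_del, "p_ins": self.p_ins}

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorRates":
        if "t_sub" in d:
            return cls(np.array(d["t_sub"]), d.get("p_del", 0.0), d.get("p_ins", 0.0))
        return cls.uniform(d.get("sub", 0.0), d.get("del", 0.0), d.get("ins", 0.0))


def seq_to_codes(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3 as an int64 vector (rejects other characters)."""
    codes = _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValidationError("sequence contains non-ACGT characters")
    return codes.astype(np.int64)


class SequencePool:
    """M reference sequences with their variant tables.

    The pool is stored column-wise for speed: ``ref_index[v]`` gives the
    reference of variant ``v``, ``edit_sets[v]`` its canonical edit tuple
    (packed integers) and ``counts[v]`` its copy number.  The public API deals
    in :class:`VariantRecord` objects.
    """

    def __init__(
        self,
        references: Sequence[str],
        ref_index: np.ndarray,
        edit_sets: list[tuple[int, ...]],
        counts: np.ndarray,
        stage_label: str = "",
    ):
        if len(references) < 1:
            raise ValidationError("a pool needs at least one reference")
        if any(not r for r in references):
            raise ValidationError("reference strings must be non-empty")
        self.references = list(references)
        self.ref_index = np.asarray(ref_index, dtype=np.int64)
        self.edit_sets = edit_sets
        self.counts = np.asarray(counts, dtype=np.int64)
        self.stage_label = stage_label
        if not (len(self.edit_sets) == len(self.counts) == len(self.ref_index)):
            raise ValidationError("variant columns must have equal length")
        if (self.counts < 0).any():
            raise ValidationError("copy numbers must be >= 0")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_references(
        cls,
        references: Sequence[str],
        counts: Sequence[int] | np.ndarray,
        stage_label: str = "initial",
    ) -> "SequencePool":
        """Pool holding only the error-free variant of each reference."""
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (len(references),):
            raise ValidationError("need one copy number per reference")
        keep = np.arange(len(references))
        return cls(references, keep, [()] * len(references), counts, stage_label)

    @classmethod
    def from_records(
        cls,
        references: Sequence[str],
        variants: Sequence[Sequence[VariantRecord]],
        stage_label: str = "",
    ) -> "SequencePool":
        ref_index: list[int] = []
        edit_sets: list[tuple[int, ...]] = []
        counts: list[int] = []
        for i, recs in enumerate(variants):
            seen = set()
            for rec in recs:
                _validate_edits(references[i], rec.edits)
                key = tuple(_edit_to_code(e) for e in rec.edits)
                if key in seen:
                    raise ValidationError(
                        f"reference {i} has two variants with the same canonical edits"
                    )
                seen.add(key)
                ref_index.append(i)
                edit_sets.append(key)
                counts.append(rec.count)
        return cls(
            references,
            np.array(ref_index, dtype=np.int64),
            edit_sets,
            np.array(counts, dtype=np.int64),
            stage_label,
        )

    # -- inspection --------------------------------------------------------
    @property
    def n_references(self) -> int:
        return len(self.references)

    @property
    def n_variants(self) -> int:
        return len(self.counts)

    def totals(self) -> np.ndarray:
        """Per-reference total copy numbers N_i."""
        return np.bincount(
            self.ref_index, weights=self.counts, minlength=self.n_references
        ).astype(np.int64)

    @property
    def lost(self) -> np.ndarray:
        """Boolean mask of references with zero surviving copies."""
        return self.totals() == 0

    def variants_of(self, i: int) -> Iterator[VariantRecord]:
        for v in np.flatnonzero(self.ref_index == i):
            yield VariantRecord(
                tuple(_code_to_edit(c) for c in self.edit_sets[v]), int(self.counts[v])
            )

    def molecule(self, v: int) -> str:
        """Materialized sequence of variant ``v``."""
        return _materialize_codes(self.references[self.ref_index[v]], self.edit_sets[v])

    def validate(self) -> None:
        """Check all type invariants (meant for small pools and tests)."""
        for i in range(self.n_references):
            seen = set()
            for v in np.flatnonzero(self.ref_index == i):
                edits = tuple(_code_to_edit(c) for c in self.edit_sets[v])
                _validate_edits(self.references[i], edits)
                if self.edit_sets[v] != tuple(sorted(self.edit_sets[v])):
                    raise ValidationError("edit set not canonical")
                if self.edit_sets[v] in seen:
                    raise ValidationError("duplicate canonical edit set")
                seen.add(self.edit_sets[v])

    def copy(self, stage_label: str | None = None) -> "SequencePool":
        return SequencePool(
            self.references,
            self.ref_index.copy(),
            list(self.edit_sets),
            self.counts.copy(),
            self.stage_label if stage_label is None else stage_label,
        )


# ---------------------------------------------------------------------------
# E primitive: error generation
# ---------------------------------------------------------------------------

def _merge_new_edits(parent: tuple[int, ...], new_codes: Sequence[int]) -> tuple[int, ...]:
    """Fold newly drawn edits into a parent edit set.

    Rules (deterministic): an event on a deleted position is discarded (the
    base no longer exists; insertions before it are kept); a new deletion
    supersedes a substitution at the same position; a repeated substitution
    replaces the earlier one; a repeated insertion at an occupied slot is
    discarded.
    """
    table: dict[tuple[int, int], int] = {}
    for code in parent:
        pos, rest = divmod(code, _POS_STRIDE)
        table[(pos, rest // 4)] = code
    for code in new_codes:
        pos, rest = divmod(code, _POS_STRIDE)
        op = rest // 4
        if op == OP_INS:
            table.setdefault((pos, OP_INS), code)
            continue
        if (pos, OP_DEL) in table:
            continue
        if op == OP_DEL:
            table.pop((pos, OP_SUB), None)
        table[(pos, op)] = code
    return tuple(sorted(table.values()))


class _RateTables:
    """Per-reference quantities derived from (references, rates)."""

    def __init__(self, references: Sequence[str], rates: ErrorRates):
        sub_tot = rates.sub_totals
        q_base = sub_tot + rates.p_del + rates.p_ins
        self.uniform_q = bool(np.allclose(q_base, q_base[0]))
        # cumulative event-type thresholds per original base: [del, ins, sub->A..T]
        cum = np.zeros((4, 6))
        for b in range(4):
            masses = [rates.p_del, rates.p_ins] + [
                rates.t_sub[b, x] if x != b else 0.0 for x in range(4)
            ]
            cum[b] = np.cumsum(masses) / max(q_base[b], 1e-300)
            if cum[b, -1] > 0:  # land exactly on 1 so u < 1 always hits a slot
                cum[b] /= cum[b, -1]
        self.cum = cum
        self.lengths = np.array([len(r) for r in references], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        self.seq_codes = np.concatenate([seq_to_codes(r) for r in references])
        q = q_base[self.seq_codes]
        self.q = q
        # per-reference no-event probability and mean per-base event rate
        self.p0 = np.empty(len(references))
        self.qbar = np.empty(len(references))
        self.cdf: list[np.ndarray] = []
        for i in range(len(references)):
            qi = q[self.offsets[i] : self.offsets[i + 1]]
            if (qi >= 1).any():
                self.p0[i] = 0.0
            else:
                self.p0[i] = float(np.exp(np.log1p(-qi).sum()))
            s = float(qi.sum())
            self.qbar[i] = s / len(qi)
            self.cdf.append(np.cumsum(qi) / s if (s > 0 and not self.uniform_q) else None)


def _draw_positions(
    tables: _RateTables, ev_ref: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Event positions: uniform over the reference for flat rates, else
    proportional to the per-base event probability."""
    if tables.uniform_q:
        return np.floor(rng.random(ev_ref.size) * tables.lengths[ev_ref]).astype(np.int64)
    pos = np.empty(ev_ref.size, dtype=np.int64)
    order = np.argsort(ev_ref, kind="stable")
    sorted_ref = ev_ref[order]
    bounds = np.searchsorted(sorted_ref, np.arange(tables.lengths.size + 1))
    u = rng.random(ev_ref.size)
    for i in range(tables.lengths.size):
        lo, hi = bounds[i], bounds[i + 1]
        if lo == hi:
            continue
        pos[order[lo:hi]] = np.minimum(
            np.searchsorted(tables.cdf[i], u[lo:hi], side="right"),
            tables.lengths[i] - 1,
        )
    return pos


def generate_errors(
    pool: SequencePool, rates: ErrorRates, rng: np.random.Generator
) -> SequencePool:
    """E primitive: molecules independently acquire new edits.

    The per-reference total copy number is conserved exactly.  For each variant
    the error-free fraction is drawn in one binomial, and only the molecules
    that actually mutate are materialized as new variants, so the cost scales
    with the number of mutated molecules rather than with pool size times
    sequence length.  For the uniform-rate presets shipped with the package the
    procedure is distributionally identical to a per-base, per-molecule
    simulation; with base-dependent substitution rows the per-molecule event
    count uses the mean per-base rate while positions follow the per-base
    rates.
    """
    if rates.is_zero or pool.n_variants == 0:
        return pool.copy()
    refs = pool.references
    tables = _RateTables(refs, rates)

    v_ref = pool.ref_index
    movers = pool.counts - rng.binomial(pool.counts, tables.p0[v_ref])
    keep_counts = pool.counts - movers

    total_movers = int(movers.sum())
    new_by_ref: dict[int, dict[tuple[int, ...], int]] = {}
    fast_keys = fast_counts = None
    if total_movers:
        mol_variant = np.repeat(np.arange(pool.n_variants), movers)
        mol_ref = v_ref[mol_variant]
        # new-edit count per mutated molecule: Binomial(L, qbar) given >= 1
        m = rng.binomial(tables.lengths[mol_ref], tables.qbar[mol_ref])
        redo = np.flatnonzero(m == 0)
        while redo.size:
            m[redo] = rng.binomial(
                tables.lengths[mol_ref[redo]], tables.qbar[mol_ref[redo]]
            )
            redo = redo[m[redo] == 0]
        ev_mol = np.repeat(np.arange(total_movers), m)
        ev_ref = mol_ref[ev_mol]
        pos = _draw_positions(tables, ev_ref, rng)
        # positions must be distinct within a molecule (sampling without
        # replacement); redraw the rare molecules with a clash
        multi = np.flatnonzero(m > 1)
        if multi.size:
            bounds_all = np.concatenate([[0], np.cumsum(m)])
            key = ev_mol * np.int64(2 * tables.lengths.max() + 2) + pos
            key.sort(kind="stable")
            clash_mol = np.unique(
                (key[1:] // np.int64(2 * tables.lengths.max() + 2))[np.diff(key) == 0]
            )
            for k in clash_mol.tolist():
                i = int(mol_ref[k])
                L = int(tables.lengths[i])
                p = None if tables.uniform_q else (
                    tables.q[tables.offsets[i] : tables.offsets[i + 1]]
                    / tables.q[tables.offsets[i] : tables.offsets[i + 1]].sum()
                )
                pos[bounds_all[k] : bounds_all[k + 1]] = rng.choice(
                    L, int(m[k]), replace=False, p=p
                )
        base_at = tables.seq_codes[tables.offsets[ev_ref] + pos]
        u = rng.random(ev_mol.size)
        outcome = (u[:, None] >= tables.cum[base_at]).sum(axis=1)
        outcome = np.minimum(outcome, 5)  # guard against u == 1.0 edge
        op = np.where(outcome == 0, OP_DEL, np.where(outcome == 1, OP_INS, OP_SUB))
        new_base = np.where(outcome >= 2, outcome - 2, 0)
        # inserted bases are uniform over ACGT (flat insertion model)
        ins_mask = op == OP_INS
        if ins_mask.any():
            new_base[ins_mask] = rng.integers(0, 4, int(ins_mask.sum()))
        codes = pos * _POS_STRIDE + op * 4 + new_base

        # vectorized fast path: single-edit children of the error-free variant
        parent_sets = pool.edit_sets
        is_root = np.fromiter((not s for s in parent_sets), dtype=bool, count=len(parent_sets))
        bounds = np.concatenate([[0], np.cumsum(m)])
        fast_mask = (m == 1) & is_root[mol_variant]
        if fast_mask.any():
            fmol = np.flatnonzero(fast_mask)
            fcodes = codes[bounds[fmol]]
            span = np.int64((tables.lengths.max() + 1) * _POS_STRIDE)
            fast_keys, fast_counts = np.unique(
                mol_ref[fmol] * span + fcodes, return_counts=True
            )
            fast_refs = (fast_keys // span).astype(np.int64)
            fast_codes = (fast_keys % span).astype(np.int64)
        slow = np.flatnonzero(~fast_mask)
        codes_list = codes.tolist()
        slow_lo = bounds[slow].tolist()
        slow_hi = bounds[slow + 1].tolist()
        slow_variant = mol_variant[slow].tolist()
        slow_ref = mol_ref[slow].tolist()
        for lo, hi, var, r in zip(slow_lo, slow_hi, slow_variant, slow_ref):
            parent = parent_sets[var]
            if not parent:
                # root parent: event positions are distinct by construction,
                # so the sorted codes already form a canonical valid set
                new_set = tuple(sorted(codes_list[lo:hi]))
            else:
                new_set = _merge_new_edits(parent, codes_list[lo:hi])
                if new_set == parent:  # every event discarded by the merge rules
                    keep_counts[var] += 1
                    continue
            d = new_by_ref.setdefault(r, {})
            d[new_set] = d.get(new_set, 0) + 1

    # rebuild the variant table, merging new sets with surviving parents
    merged: dict[int, dict[tuple[int, ...], int]] = {}
    keep_idx = np.flatnonzero(keep_counts > 0)
    keep_refs = v_ref[keep_idx].tolist()
    keep_vals = keep_counts[keep_idx].tolist()
    for r, v, c in zip(keep_refs, keep_idx.tolist(), keep_vals):
        merged.setdefault(r, {})[pool.edit_sets[v]] = c
    if fast_keys is not None:
        for r, code, c in zip(fast_refs.tolist(), fast_codes.tolist(), fast_counts.tolist()):
            d = merged.setdefault(r, {})
            key = (code,)
            d[key] = d.get(key, 0) + c
    for r, d in new_by_ref.items():
        tgt = merged.setdefault(r, {})
        for s, c in d.items():
            tgt[s] = tgt.get(s, 0) + c

    ref_idx: list[int] = []
    out_sets: list[tuple[int, ...]] = []
    chunks: list[np.ndarray] = []
    for r, d in merged.items():
        ref_idx.extend([r] * len(d))
        out_sets.extend(d.keys())
        chunks.append(np.fromiter(d.values(), dtype=np.int64, count=len(d)))
    new_counts = np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.int64)
    new_pool = SequencePool(
        refs, np.array(ref_idx, dtype=np.int64), out_sets, new_counts, pool.stage_label
    )
    if not np.array_equal(new_pool.totals(), pool.totals()):
        raise AssertionError("E primitive failed to conserve per-reference copy numbers")
    return new_pool


# ---------------------------------------------------------------------------
# D primitive: distribution change
# ---------------------------------------------------------------------------

def change_distribution(
    pool: SequencePool,
    sampler: Callable[[np.ndarray, np.random.Generator], np.ndarray],
    rng: np.random.Generator,
    stage_label: str | None = None,
) -> SequencePool:
    """D primitive: replace every variant count by an independent draw.

    ``sampler(counts, rng)`` maps the vector of current copy numbers to a
    vector of new non-negative integer copy numbers.  Variants whose count
    drops to zero are removed; references whose total drops to zero are lost.
    """
    new_counts = np.asarray(sampler(pool.counts, rng))
    if new_counts.shape != pool.counts.shape:
        raise ValidationError("sampler must return one count per variant")
    if not np.issubdtype(new_counts.dtype, np.integer):
        if not np.allclose(new_counts, np.round(new_counts)):
            raise ValidationError("sampler must return integer counts")
        new_counts = np.round(new_counts).astype(np.int64)
    if (new_counts < 0).any():
        raise ValidationError("sampler returned negative counts")
    keep = new_counts > 0
    return SequencePool(
        pool.references,
        pool.ref_index[keep],
        [pool.edit_sets[v] for v in np.flatnonzero(keep)],
        new_counts[keep].astype(np.int64),
        pool.stage_label if stage_label is None else stage_label,
    )


def binomial_thinning(p: float) -> Callable[[np.ndarray, np.random.Generator], np.ndarray]:
    """Sampler factory: keep each molecule independently with probability ``p``."""
    if not 0 <= p <= 1:
        raise ValidationError("thinning probability must lie in [0, 1]")

    def sampler(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return rng.binomial(counts, p)

    return sampler
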