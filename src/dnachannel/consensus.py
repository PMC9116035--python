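"""Position-wise voting consensus and the two final error classes.

After the channel, each designed sequence is recovered by voting its reads
base-by-base.  Two kinds of error remain: a sequence is *lost* when no reads
qualify for the vote, and a *voting error* occurs at a position where a wrong
base outvotes the true one.  Together with the per-stage snapshots these are
the channel's final noise summary.

By default only reads whose length equals the reference length enter the vote:
positional voting is ill-defined across lengths, and indel-carrying reads
would otherwise smear frame-shifted bases over the tally.  An optional
alignment mode tallies all reads after pairwise alignment to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pool import BASES, OP_SUB, _POS_STRIDE, _edit_to_code, diff, seq_to_codes
from .stages import ReadSet, SimulationResult

__all__ = ["LOST", "ConsensusResult", "ChannelSummary", "vote", "call_consensus", "count_voting_errors", "summarize"]

LOST = None  # marker for a reference with no qualifying reads


@dataclass
class ConsensusResult:
    """Voting outcome for one reference."""

    consensus: str | None  # LOST (None) when no reads qualify
    voting_error_count: int
    contributing_reads: int

    @property
    def lost(self) -> bool:
        return self.consensus is LOST


def vote(
    reads: list[tuple[str, int]],
    reference_length: int,
    tie_rule: str = BASES,
    mode: str = "length-filter",
) -> str | None:
    """Plurality-vote a read multiset into a consensus sequence.

    ``reads`` are (sequence, multiplicity) pairs.  In the default
    ``length-filter`` mode only reads of exactly ``reference_length`` are
    tallied; position ties are broken by ``tie_rule`` order (default A<C<G<T,
    deterministic and documented as arbitrary).  In ``align`` mode reads of
    other lengths are first projected onto reference coordinates via pairwise
    alignment to the plurality-length read.  Returns ``LOST`` when no reads
    qualify.  The result is invariant to read order and to how the multiset is
    split into (read, multiplicity) pairs.
    """
    if reference_length < 1:
        raise ValueError("reference_length must be >= 1")
    if sorted(tie_rule) != sorted(BASES):
        raise ValueError("tie_rule must be a permutation of ACGT")
    if mode not in ("length-filter", "align"):
        raise ValueError("mode must be 'length-filter' or 'align'")
    qualifying = [(s, m) for s, m in reads if len(s) == reference_length]
    if mode == "align" and not qualifying and reads:
        # project every read onto the coordinates of the plurality-length read
        lengths: dict[int, int] = {}
        for s, m in reads:
            lengths[len(s)] = lengths.get(len(s), 0) + m
        anchor_len = max(sorted(lengths), key=lambda L: lengths[L])
        anchor = next(s for s, _ in sorted(reads) if len(s) == anchor_len)
        projected: list[tuple[str, int]] = []
        for s, m in reads:
            if len(s) == anchor_len:
                projected.append((s, m))
                continue
            aligned = _project(anchor, s)
            projected.append((aligned, m))
        qualifying = projected
        reference_length = anchor_len
    if not qualifying:
        return LOST
    tally = np.zeros((4, reference_length), dtype=np.int64)
    cols = np.arange(reference_length)
    for s, m in qualifying:
        tally[seq_to_codes(s), cols] += m
    order = np.array([BASES.index(b) for b in tie_rule])
    winners = order[np.argmax(tally[order], axis=0)]  # argmax keeps first => tie_rule order
    return "".join(BASES[b] for b in winners)


def call_consensus(
    reads: list[tuple[str, int]],
    reference: str,
    tie_rule: str = BASES,
    mode: str = "length-filter",
) -> ConsensusResult:
    """Vote one reference's reads and package the outcome."""
    cons = vote(reads, len(reference), tie_rule=tie_rule, mode=mode)
    if cons is LOST:
        return ConsensusResult(LOST, 0, 0)
    contributing = sum(m for s, m in reads if len(s) == len(reference)) or sum(
        m for _, m in reads
    )
    return ConsensusResult(cons, count_voting_errors(cons, reference), contributing)


def _project(anchor: str, read: str) -> str:
    """Rewrite ``read`` in the coordinates of ``anchor`` (anchor base kept at
    deleted positions, insertions dropped)."""
    out = list(anchor)
    for e in diff(anchor, read):
        code = _edit_to_code(e)
        op = (code % _POS_STRIDE) // 4
        if op == OP_SUB:
            out[e.position] = e.base
    return "".join(out)


def count_voting_errors(consensus: str, reference: str) -> int:
    """Voting errors of a consensus: Hamming distance at equal length,
    unit-cost edit distance otherwise (only reachable in align mode)."""
    if consensus is LOST:
        raise ValueError("cannot count voting errors for a lost sequence")
    if len(consensus) == len(reference):
        return int(sum(a != b for a, b in zip(consensus, reference)))
    return len(diff(reference, consensus))


@dataclass
class ChannelSummary:
    """Final error summary of a simulated channel run.

    ``n_lost`` counts references with no qualifying reads after voting (the
    paper-level lost class N_l); ``n_lost_reads`` counts references with zero
    reads at all.  ``base_error_hist[i]`` is the number of sequences with
    exactly ``i`` base voting errors; ``byte_error_hist`` groups 4 consecutive
    nucleotides (2 bits/base) into one byte, the unit Reed–Solomon capacity is
    counted in.  ``sum(base_error_hist) + n_lost == M`` always.
    """

    n_references: int
    n_lost: int
    n_lost_reads: int
    base_error_hist: dict[int, int]
    byte_error_hist: dict[int, int]
    mean_depth: float
    stage_totals: dict[str, np.ndarray] = field(default_factory=dict)
    consensus: list[str | None] = field(default_factory=list)

    @property
    def partition_ok(self) -> bool:
        return sum(self.base_error_hist.values()) + self.n_lost == self.n_references


def summarize(
    result: SimulationResult | ReadSet,
    references: list[str] | None = None,
    mode: str = "length-filter",
    tie_rule: str = BASES,
) -> ChannelSummary:
    """Vote every reference and tabulate lost counts and error histograms."""
    if isinstance(result, SimulationResult):
        reads, refs = result.reads, result.references
        stage_totals = dict(result.snapshots)
    else:
        reads, refs = result, list(result.references)
        stage_totals = {}
    if references is not None:
        refs = references
    base_hist: dict[int, int] = {}
    byte_hist: dict[int, int] = {}
    consensus_list: list[str | None] = []
    n_lost = 0
    total_reads = 0
    for i, ref in enumerate(refs):
        rec = reads.reads[i]
        total_reads += sum(m for _, m in rec)
        cons = vote(rec, len(ref), tie_rule=tie_rule, mode=mode)
        consensus_list.append(cons)
        if cons is LOST:
            n_lost += 1
            continue
        if len(cons) == len(ref):
            mism = np.flatnonzero(
                np.frombuffer(cons.encode(), np.uint8) != np.frombuffer(ref.encode(), np.uint8)
            )
            n_base = int(mism.size)
            n_byte = int(np.unique(mism // 4).size)
        else:
            n_base = count_voting_errors(cons, ref)
            n_byte = (len(ref) + 3) // 4  # length mismatch: whole payload suspect
        base_hist[n_base] = base_hist.get(n_base, 0) + 1
        byte_hist[n_byte] = byte_hist.get(n_byte, 0) + 1
    return ChannelSummary(
        n_references=len(refs),
        n_lost=n_lost,
        n_lost_reads=int(reads.lost.sum()),
        base_error_hist=dict(sorted(base_hist.items())),
        byte_error_hist=dict(sorted(byte_hist.items())),
        mean_depth=total_reads / max(len(refs), 1),
        stage_totals=stage_totals,
        consensus=consensus_list,
    )
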