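"""Stage models for the DNA data storage channel.

Each stage — synthesis, decay, PCR, sampling, sequencing — is built from the
two pool primitives (error generation and distribution change) and the stages
compose in series into the full channel:

    synthesis -> decay -> PCR -> sampling -> sequencing

Every stage takes its own sub-configuration and a seeded generator, so stages
can be run separately to study what each contributes to the final noise
structure, or composed with :func:`run_channel`.  Any stage can be configured
as the identity (survival 1, ratio 1, cycles 0, zero rates) and skipped
explicitly via ``run_channel(..., skip={"pcr"})``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .pool import (
    ErrorRates,
    SequencePool,
    ValidationError,
    binomial_thinning,
    change_distribution,
    generate_errors,
)

__all__ = [
    "SynthesisConfig",
    "DecayConfig",
    "PcrConfig",
    "SamplingConfig",
    "SequencingConfig",
    "ChannelConfig",
    "ReadSet",
    "SimulationResult",
    "synthesis",
    "decay",
    "pcr",
    "sample",
    "sequencing",
    "run_channel",
    "NGS_RATES",
    "NANOPORE_RATES",
    "SYNTHESIS_RATES",
    "DECAY_RATES",
]

STAGE_ORDER = ("synthesis", "decay", "pcr", "sampling", "sequencing")

# Platform presets.  The paper's sources for per-stage rates are not printed in
# its main text, so these are this package's own editable defaults: array
# synthesis with deletion-dominated errors, mild hydrolytic decay, a low-error
# short-read platform and a high-error long-read platform.
SYNTHESIS_RATES = ErrorRates.uniform(sub=0.004, dele=0.0035, ins=0.0005)
DECAY_RATES = ErrorRates.uniform(sub=0.002)
NGS_RATES = ErrorRates.uniform(sub=0.002, dele=0.0002, ins=0.0002)
NANOPORE_RATES = ErrorRates.uniform(sub=0.05, dele=0.03, ins=0.02)

_PLATFORMS = {"NGS": NGS_RATES, "Nanopore": NANOPORE_RATES}


@dataclass(frozen=True)
class SynthesisConfig:
    """Initial copy numbers plus synthesis errors.

    ``mean_depth`` is the expected number of synthesized copies per designed
    sequence.  ``count_distribution`` is "binomial" (each of ``mean_depth * M``
    molecules picks a sequence uniformly, the classic even-pool model),
    "negative-binomial" with ``dispersion`` (shape) for overdispersed pools,
    or "constant" for deterministic identity-style configurations.
    """

    mean_depth: float = 5000.0
    rates: ErrorRates = field(default_factory=lambda: SYNTHESIS_RATES)
    count_distribution: str = "binomial"
    dispersion: float = 10.0

    def __post_init__(self):
        if self.mean_depth < 0:
            raise ValidationError("synthesis mean_depth must be >= 0")
        if self.count_distribution not in ("binomial", "negative-binomial", "constant"):
            raise ValidationError(
                "count_distribution must be binomial, negative-binomial or constant"
            )


@dataclass(frozen=True)
class DecayConfig:
    """Storage decay: molecule survival plus damage substitutions."""

    survival_prob: float = 0.99
    rates: ErrorRates = field(default_factory=lambda: DECAY_RATES)

    def __post_init__(self):
        if not 0 <= self.survival_prob <= 1:
            raise ValidationError("survival_prob must lie in [0, 1]")


@dataclass(frozen=True)
class PcrConfig:
    """Per-cycle Galton–Watson amplification with per-sequence bias.

    Each reference draws one efficiency from a clipped normal
    (mean ``efficiency``, s.d. ``bias_sigma``); every variant count then grows
    per cycle as ``n <- n + Binomial(n, efficiency_i)``.  With ``normalize``
    on (the default) the amplified pool is binomially diluted back to the
    pre-PCR total, modelling the aliquot of PCR product actually carried
    forward; relative skew between sequences is preserved.  ``max_molecules``
    caps counts against overflow.
    """

    cycles: int = 12
    efficiency: float = 0.8
    bias_sigma: float = 0.015
    normalize: bool = True
    max_molecules: float = 1e15

    def __post_init__(self):
        if self.cycles < 0:
            raise ValidationError("PCR cycles must be >= 0")
        if not 0 <= self.efficiency <= 1:
            raise ValidationError("PCR efficiency must lie in [0, 1]")
        if self.bias_sigma < 0:
            raise ValidationError("bias_sigma must be >= 0")


@dataclass(frozen=True)
class SamplingConfig:
    """Fraction of the physical pool taken forward into sequencing prep."""

    ratio: float = 0.001

    def __post_init__(self):
        if not 0 <= self.ratio <= 1:
            raise ValidationError("sampling ratio must lie in [0, 1]")


@dataclass(frozen=True)
class SequencingConfig:
    """Mean reads per surviving reference plus platform error rates."""

    depth: float = 10.0
    rates: ErrorRates = field(default_factory=lambda: NGS_RATES)
    platform: str = "NGS"

    def __post_init__(self):
        if self.depth < 0:
            raise ValidationError("sequencing depth must be >= 0")

    @classmethod
    def preset(cls, platform: str, depth: float = 10.0) -> "SequencingConfig":
        try:
            return cls(depth=depth, rates=_PLATFORMS[platform], platform=platform)
        except KeyError:
            raise ValidationError(f"unknown platform {platform!r}") from None


@dataclass(frozen=True)
class ChannelConfig:
    """All stage parameters of the full channel."""

    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    decay: DecayConfig = field(default_factory=DecayConfig)
    pcr: PcrConfig = field(default_factory=PcrConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    sequencing: SequencingConfig = field(default_factory=SequencingConfig)

    def replace(self, **kw) -> "ChannelConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "synthesis": {
                "mean_depth": self.synthesis.mean_depth,
                "rates": self.synthesis.rates.to_dict(),
                "count_distribution": self.synthesis.count_distribution,
                "dispersion": self.synthesis.dispersion,
            },
            "decay": {
                "survival_prob": self.decay.survival_prob,
                "rates": self.decay.rates.to_dict(),
            },
            "pcr": {
                "cycles": self.pcr.cycles,
                "efficiency": self.pcr.efficiency,
                "bias_sigma": self.pcr.bias_sigma,
                "normalize": self.pcr.normalize,
                "max_molecules": self.pcr.max_molecules,
            },
            "sampling": {"ratio": self.sampling.ratio},
            "sequencing": {
                "depth": self.sequencing.depth,
                "rates": self.sequencing.rates.to_dict(),
                "platform": self.sequencing.platform,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChannelConfig":
        def rates(sub: Mapping, default: ErrorRates) -> ErrorRates:
            return ErrorRates.from_dict(sub["rates"]) if "rates" in sub else default

        syn = d.get("synthesis", {})
        dec = d.get("decay", {})
        p = d.get("pcr", {})
        sam = d.get("sampling", {})
        seq = d.get("sequencing", {})
        seq_rates = (
            ErrorRates.from_dict(seq["rates"])
            if "rates" in seq
            else _PLATFORMS.get(seq.get("platform", "NGS"), NGS_RATES)
        )
        return cls(
            synthesis=SynthesisConfig(
                mean_depth=syn.get("mean_depth", 5000.0),
                rates=rates(syn, SYNTHESIS_RATES),
                count_distribution=syn.get("count_distribution", "binomial"),
                dispersion=syn.get("dispersion", 10.0),
            ),
            decay=DecayConfig(
                survival_prob=dec.get("survival_prob", 0.99), rates=rates(dec, DECAY_RATES)
            ),
            pcr=PcrConfig(
                cycles=p.get("cycles", 12),
                efficiency=p.get("efficiency", 0.8),
                bias_sigma=p.get("bias_sigma", 0.015),
                normalize=p.get("normalize", True),
                max_molecules=p.get("max_molecules", 1e15),
            ),
            sampling=SamplingConfig(ratio=sam.get("ratio", 0.001)),
            sequencing=SequencingConfig(
                depth=seq.get("depth", 10.0),
                rates=seq_rates,
                platform=seq.get("platform", "NGS"),
            ),
        )


class ReadSet:
    """Sequencing readouts grouped by their originating reference.

    ``reads[i]`` is a list of ``(read sequence, multiplicity)`` pairs; the
    ground-truth linkage read -> reference is retained (no clustering step, as
    in the channel abstraction).  A reference with zero reads is lost.
    """

    def __init__(self, references: Sequence[str], reads: list[list[tuple[str, int]]]):
        if len(reads) != len(references):
            raise ValidationError("need one read list per reference")
        if any(mult < 1 for recs in reads for _, mult in recs):
            raise ValidationError("read multiplicities must be >= 1")
        self.references = list(references)
        self.reads = reads

    @property
    def lost(self) -> np.ndarray:
        return np.array([len(r) == 0 for r in self.reads])

    @property
    def n_lost(self) -> int:
        return int(self.lost.sum())

    def n_reads(self) -> np.ndarray:
        return np.array([sum(m for _, m in r) for r in self.reads], dtype=np.int64)


@dataclass
class SimulationResult:
    """Output of a full channel run: reads plus per-stage snapshots.

    ``snapshots`` maps a stage name to the per-reference total copy numbers
    after that stage (count histograms derive from these), which is what the
    distribution-evolution figures of a channel study need without retaining
    full variant tables.
    """

    references: list[str]
    reads: ReadSet
    snapshots: dict[str, np.ndarray]
    config: ChannelConfig
    seed: int | None = None

    def snapshot_histogram(self, stage: str, bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
        counts = self.snapshots[stage]
        return np.histogram(counts, bins=bins)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def synthesis(
    references: Sequence[str], cfg: SynthesisConfig, rng: np.random.Generator
) -> SequencePool:
    """Synthesize the pool: draw initial copy numbers, then synthesis errors."""
    M = len(references)
    if M == 0:
        raise ValidationError("cannot synthesize an empty reference set")
    if cfg.mean_depth == 0:
        counts = np.zeros(M, dtype=np.int64)
    elif cfg.count_distribution == "constant":
        counts = np.full(M, int(round(cfg.mean_depth)), dtype=np.int64)
    elif cfg.count_distribution == "binomial":
        total = int(round(cfg.mean_depth * M))
        counts = rng.binomial(total, 1.0 / M, size=M)
    else:
        r = cfg.dispersion
        p = r / (r + cfg.mean_depth)
        counts = rng.negative_binomial(r, p, size=M)
    pool = SequencePool.from_references(references, counts, stage_label="synthesis")
    return generate_errors(pool, cfg.rates, rng)


def decay(pool: SequencePool, cfg: DecayConfig, rng: np.random.Generator) -> SequencePool:
    """Storage decay: binomial survival thinning, then damage errors."""
    out = change_distribution(pool, binomial_thinning(cfg.survival_prob), rng, "decay")
    return generate_errors(out, cfg.rates, rng)


def pcr(pool: SequencePool, cfg: PcrConfig, rng: np.random.Generator) -> SequencePool:
    """PCR amplification as a per-cycle branching process with sequence bias."""
    if cfg.cycles == 0:
        return pool.copy("pcr")
    eff = np.clip(
        rng.normal(cfg.efficiency, cfg.bias_sigma, size=pool.n_references), 0.0, 1.0
    )
    total_before = int(pool.counts.sum())

    def amplify(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = counts.astype(np.int64).copy()
        p = eff[pool.ref_index]
        capped = False
        for _ in range(cfg.cycles):
            out = out + rng.binomial(out, p)
            if (out > cfg.max_molecules).any():
                out = np.minimum(out, int(cfg.max_molecules))
                capped = True
        if capped:
            warnings.warn("PCR counts hit the configured molecule ceiling", stacklevel=2)
        return out

    out = change_distribution(pool, amplify, rng, "pcr")
    if cfg.normalize and out.counts.sum() > 0:
        dilution = min(1.0, total_before / float(out.counts.sum()))
        out = change_distribution(out, binomial_thinning(dilution), rng, "pcr")
    return out


def sample(pool: SequencePool, cfg: SamplingConfig, rng: np.random.Generator) -> SequencePool:
    """Take a sub-pool: independent binomial thinning with the sampling ratio.

    At realistic pool sizes this is indistinguishable from an exact
    hypergeometric draw of the aliquot and is linear in the number of
    variants.
    """
    return change_distribution(pool, binomial_thinning(cfg.ratio), rng, "sampling")


def sequencing(
    pool: SequencePool, cfg: SequencingConfig, rng: np.random.Generator
) -> ReadSet:
    """Sequence the pool: allocate a global read budget, then read errors.

    The total budget is ``depth x (number of surviving references)``,
    multinomially allocated across molecules proportionally to their copy
    numbers, so per-reference coverage inherits the pool's copy-number skew.
    """
    totals = pool.totals()
    n_surviving = int((totals > 0).sum())
    budget = int(round(cfg.depth * n_surviving))
    M = pool.n_references
    if budget == 0 or pool.counts.sum() == 0:
        return ReadSet(pool.references, [[] for _ in range(M)])
    probs = pool.counts / pool.counts.sum()
    draw = rng.multinomial(budget, probs)
    keep = draw > 0
    read_pool = SequencePool(
        pool.references,
        pool.ref_index[keep],
        [pool.edit_sets[v] for v in np.flatnonzero(keep)],
        draw[keep].astype(np.int64),
        "sequencing",
    )
    read_pool = generate_errors(read_pool, cfg.rates, rng)
    reads: list[list[tuple[str, int]]] = [[] for _ in range(M)]
    for v in range(read_pool.n_variants):
        reads[int(read_pool.ref_index[v])].append(
            (read_pool.molecule(v), int(read_pool.counts[v]))
        )
    return ReadSet(pool.references, reads)


def run_channel(
    references: Sequence[str],
    config: ChannelConfig,
    seed: int | np.random.SeedSequence | None = None,
    skip: Sequence[str] = (),
) -> SimulationResult:
    """Run the full channel and capture per-stage copy-number snapshots.

    Each stage consumes an independent child generator spawned from ``seed``,
    so runs replay exactly and skipping a stage does not perturb the random
    streams of the others.
    """
    unknown = set(skip) - set(STAGE_ORDER)
    if unknown:
        raise ValidationError(f"unknown stage(s) to skip: {sorted(unknown)}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rngs = {name: np.random.Generator(np.random.PCG64(child))
            for name, child in zip(STAGE_ORDER, ss.spawn(len(STAGE_ORDER)))}
    snapshots: dict[str, np.ndarray] = {}

    def _stage(name: str, fn, pool):
        if name in skip:
            out = pool.copy(name)
        else:
            try:
                out = fn(pool, rngs[name])
            except Exception as err:
                raise RuntimeError(f"channel stage {name!r} failed: {err}") from err
        if isinstance(out, SequencePool):
            snapshots[name] = out.totals()
        return out

    if "synthesis" in skip:
        pool = SequencePool.from_references(
            references, np.ones(len(references), dtype=np.int64), "synthesis"
        )
        snapshots["synthesis"] = pool.totals()
    else:
        try:
            pool = synthesis(references, config.synthesis, rngs["synthesis"])
        except Exception as err:
            raise RuntimeError(f"channel stage 'synthesis' failed: {err}") from err
        snapshots["synthesis"] = pool.totals()
    pool = _stage("decay", lambda p, rng: decay(p, config.decay, rng), pool)
    pool = _stage("pcr", lambda p, rng: pcr(p, config.pcr, rng), pool)
    pool = _stage("sampling", lambda p, rng: sample(p, config.sampling, rng), pool)
    if "sequencing" in skip:
        reads = ReadSet(list(references),
                        [[(r, 1)] for r in references])  # identity: one perfect read each
    else:
        try:
            reads = sequencing(pool, config.sequencing, rngs["sequencing"])
        except Exception as err:
            raise RuntimeError(f"channel stage 'sequencing' failed: {err}") from err
    snapshots["sequencing"] = reads.n_reads()
    seed_val = seed if isinstance(seed, int) else None
    return SimulationResult(list(references), reads, snapshots, config, seed_val)
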