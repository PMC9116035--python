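"""The default end-to-end storage study: encode, channel, profile, plan.

This module wires the pieces into the reference experiment used throughout
the documentation and tests: a pseudo-random 40 KB file is fountain-encoded
into M = 2048 droplets laid out as 104-nt strands (4-byte seed, 20-byte
payload, 2 parity bytes at 2 bits/base), the strands pass through the default
channel (mean 5000 synthesized copies, mild decay, 12 normalized PCR cycles,
0.1 % sampling, short-read sequencing at mean depth 10), consensus voting
yields the error profile, and the redundancy planner turns repeated runs into
a (L_RS, alpha) recommendation.

Everything is deterministic in the seeds passed in; independent sub-studies
derive child seeds through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ChannelSummary, summarize
from .fountain import (
    Droplet,
    droplets_to_dna,
    generate_file,
    lt_encode,
    lt_droplet_stream,
    lt_min_droplets,
)
from .pool import SequencePool
from .redundancy import RedundancyPlan, plan_redundancy
from .stages import (
    STAGE_ORDER,
    ChannelConfig,
    ReadSet,
    SequencingConfig,
    decay,
    pcr,
    sample,
    sequencing,
    synthesis,
)

__all__ = [
    "StudyDesign",
    "default_config",
    "study_references",
    "upstream_pool",
    "sequence_at_depths",
    "noise_convergence",
    "sample_droplets_needed",
    "redundancy_study",
    "StudyResult",
]

CHUNK_BYTES = 20  # payload bytes per strand
SEED_BYTES = 4
DEFAULT_L_RS = 2  # parity bytes in the strand layout (104 nt total)
DEFAULT_M = 2048


@dataclass
class StudyDesign:
    """Geometry of the encoded pool."""

    m: int = DEFAULT_M
    chunk_bytes: int = CHUNK_BYTES
    l_rs: int = DEFAULT_L_RS

    @property
    def file_bytes(self) -> int:
        return self.m * self.chunk_bytes

    @property
    def strand_length(self) -> int:
        return 4 * (SEED_BYTES + self.chunk_bytes + self.l_rs)


def default_config() -> ChannelConfig:
    """The package's default channel parameters (see docs/methods.md)."""
    return ChannelConfig()


def study_references(
    seed: int, design: StudyDesign | None = None
) -> tuple[bytes, list[Droplet], list[str]]:
    """Generate the study file, its droplets and their DNA strands."""
    design = design or StudyDesign()
    ss = np.random.SeedSequence([seed, 0xD1A])
    file_seed, enc_seed = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2)]
    data = generate_file(design.file_bytes, file_seed)
    droplets = lt_encode(data, design.m, design.m, enc_seed)
    refs = droplets_to_dna(droplets, design.l_rs)
    return data, droplets, refs


def _stage_rngs(seed_entropy) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed_entropy)
    return {
        name: np.random.Generator(np.random.PCG64(child))
        for name, child in zip(STAGE_ORDER, ss.spawn(len(STAGE_ORDER)))
    }


def upstream_pool(
    references: list[str], config: ChannelConfig, seed_entropy
) -> tuple[SequencePool, dict[str, np.ndarray]]:
    """Run synthesis -> decay -> PCR -> sampling once; sequencing is run
    separately so several depths can share one (expensive) upstream pool."""
    rngs = _stage_rngs(seed_entropy)
    snapshots: dict[str, np.ndarray] = {}
    pool = synthesis(references, config.synthesis, rngs["synthesis"])
    snapshots["synthesis"] = pool.totals()
    pool = decay(pool, config.decay, rngs["decay"])
    snapshots["decay"] = pool.totals()
    pool = pcr(pool, config.pcr, rngs["pcr"])
    snapshots["pcr"] = pool.totals()
    pool = sample(pool, config.sampling, rngs["sampling"])
    snapshots["sampling"] = pool.totals()
    return pool, snapshots


def sequence_at_depths(
    pool: SequencePool,
    config: ChannelConfig,
    depths,
    seed_entropy,
) -> dict[float, ReadSet]:
    """Sequence one sampled pool at several depths with independent child
    generators (coverage comparisons across depths, as in depth-sweep plots)."""
    ss = np.random.SeedSequence(seed_entropy)
    out: dict[float, ReadSet] = {}
    for depth, child in zip(depths, ss.spawn(len(depths))):
        cfg = SequencingConfig(
            depth=depth, rates=config.sequencing.rates, platform=config.sequencing.platform
        )
        out[depth] = sequencing(pool, cfg, np.random.Generator(np.random.PCG64(child)))
    return out


def noise_convergence(
    references: list[str],
    config: ChannelConfig,
    base_seed: int,
    depths=(5, 10, 20, 40, 50, 60),
    n_seeds: int = 10,
) -> pd.DataFrame:
    """Lost-sequence counts versus sequencing depth, averaged over seeds.

    Returns a tidy frame with one row per (seed, depth): the number of
    references with zero reads, plus the post-sampling lost count the curve
    converges to as depth grows.
    """
    rows = []
    for r in range(n_seeds):
        pool, _ = upstream_pool(references, config, [base_seed, r, 0x5A11])
        post_sampling_lost = int((pool.totals() == 0).sum())
        readsets = sequence_at_depths(pool, config, depths, [base_seed, r, 0x5E0])
        for depth, rs in readsets.items():
            rows.append(
                {
                    "seed": r,
                    "depth": depth,
                    "lost_reads": rs.n_lost,
                    "post_sampling_lost": post_sampling_lost,
                }
            )
    return pd.DataFrame(rows)


def sample_droplets_needed(
    data: bytes, m: int, n_samples: int, base_seed: int
) -> list[int]:
    """Droplets consumed by peeling decodes of fresh droplet streams."""
    ss = np.random.SeedSequence([base_seed, 0xF0])
    out = []
    for child in ss.spawn(n_samples):
        stream_seed = int(child.generate_state(1)[0] % 2**31)
        out.append(lt_min_droplets(lt_droplet_stream(data, m, stream_seed), m))
    return out


@dataclass
class StudyResult:
    """Everything the redundancy study produced."""

    design: StudyDesign
    summaries: list[ChannelSummary]
    droplets_needed: list[int]
    plan: RedundancyPlan
    convergence: pd.DataFrame | None = None


def redundancy_study(
    base_seed: int,
    n_replicates: int = 10,
    design: StudyDesign | None = None,
    config: ChannelConfig | None = None,
    target_success: float = 0.99,
    n_droplet_samples: int | None = None,
) -> StudyResult:
    """Repeat the default channel, fit the loss models, plan the redundancy.

    ``n_replicates`` channel runs provide total-lost samples (the paper-style
    workflow fits distributions from ~10 repeats); droplets-needed samples
    default to the same count.
    """
    design = design or StudyDesign()
    config = config or default_config()
    data, _, refs = study_references(base_seed, design)
    summaries: list[ChannelSummary] = []
    for r in range(n_replicates):
        pool, snapshots = upstream_pool(refs, config, [base_seed, r, 0x5A11])
        reads = sequence_at_depths(pool, config, [config.sequencing.depth], [base_seed, r, 0x5E0])
        summary = summarize(reads[config.sequencing.depth], references=refs)
        summary.stage_totals = snapshots
        summaries.append(summary)
    droplets_needed = sample_droplets_needed(
        data, design.m, n_droplet_samples or n_replicates, base_seed
    )
    plan = plan_redundancy(
        summaries,
        droplets_needed,
        payload_bytes=design.chunk_bytes,
        m=design.m,
        target_success=target_success,
    )
    return StudyResult(design, summaries, droplets_needed, plan)
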