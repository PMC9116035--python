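"""Replicate orchestration: repeated channel runs with derived child seeds.

The distribution-fitting workflow needs repeated experiments (10 repeats for
the Poisson/Gumbel fits, more for empirical distribution checks).  Replicates
derive independent child seeds from ``(base_seed, replicate index)`` through
``numpy.random.SeedSequence``, so the aggregate is reproducible from the base
seed while any single replicate can be replayed on its own.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .consensus import ChannelSummary, summarize
from .redundancy import total_lost
from .stages import ChannelConfig, run_channel

__all__ = ["run_replicates", "replicate_seed"]


def replicate_seed(base_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic child seed for one replicate."""
    return np.random.SeedSequence([base_seed, index])


def run_replicates(
    references: list[str],
    config: ChannelConfig,
    n_replicates: int,
    base_seed: int,
    l_rs: int = 2,
) -> tuple[list[ChannelSummary], pd.DataFrame]:
    """Run the full channel + voting ``n_replicates`` times.

    Returns the per-replicate summaries plus an aggregate table with one row
    per replicate (lost counts, total lost at capacity floor(l_rs/2), mean
    depth) ready for the redundancy fits.  Any replicate failure aborts with
    the replicate index and seed attached.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    summaries: list[ChannelSummary] = []
    rows = []
    for r in range(n_replicates):
        ss = replicate_seed(base_seed, r)
        try:
            result = run_channel(references, config, seed=ss)
            summary = summarize(result)
        except Exception as err:
            raise RuntimeError(
                f"replicate {r} (base_seed={base_seed}) failed: {err}"
            ) from err
        summaries.append(summary)
        rows.append(
            {
                "replicate": r,
                "n_lost": summary.n_lost,
                "n_lost_reads": summary.n_lost_reads,
                "n_tl": total_lost(summary, l_rs),
                "mean_depth": summary.mean_depth,
            }
        )
    return summaries, pd.DataFrame(rows)
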