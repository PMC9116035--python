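"""Stage models and the composed channel."""

import numpy as np
import pytest

from dnachannel.pool import ErrorRates, SequencePool, ValidationError
from dnachannel.stages import (
    ChannelConfig,
    DecayConfig,
    PcrConfig,
    SamplingConfig,
    SequencingConfig,
    SynthesisConfig,
    decay,
    pcr,
    run_channel,
    sample,
    sequencing,
    synthesis,
)

ZERO = ErrorRates.uniform()


def identity_config(depth: float = 30.0) -> ChannelConfig:
    return ChannelConfig(
        synthesis=SynthesisConfig(mean_depth=depth, rates=ZERO,
                                  count_distribution="constant"),
        decay=DecayConfig(survival_prob=1.0, rates=ZERO),
        pcr=PcrConfig(cycles=0),
        sampling=SamplingConfig(ratio=1.0),
        sequencing=SequencingConfig(depth=depth, rates=ZERO),
    )


class TestSynthesis:
    def test_zero_depth_loses_everything(self, small_refs, rng):
        pool = synthesis(small_refs, SynthesisConfig(mean_depth=0, rates=ZERO), rng)
        assert pool.lost.all()

    def test_empty_reference_set_rejected(self, rng):
        with pytest.raises(ValidationError):
            synthesis([], SynthesisConfig(), rng)

    def test_mean_count_and_error_free(self, rng):
        refs = ["ACGTACGTACGT"] * 1000
        pool = synthesis(refs, SynthesisConfig(mean_depth=200, rates=ZERO), rng)
        totals = pool.totals()
        assert abs(totals.mean() - 200) < 3 * np.sqrt(200 / 1000)
        assert all(s == () for s in pool.edit_sets)

    def test_error_generation_conserves_the_count_draw(self, small_refs):
        noisy = SynthesisConfig(mean_depth=50, rates=ErrorRates.uniform(sub=0.02))
        clean = SynthesisConfig(mean_depth=50, rates=ZERO)
        a = synthesis(small_refs, noisy, np.random.default_rng(3))
        b = synthesis(small_refs, clean, np.random.default_rng(3))
        assert np.array_equal(a.totals(), b.totals())

    def test_negative_binomial_overdispersion(self, rng):
        refs = ["ACGT" * 10] * 2000
        nb = synthesis(
            refs,
            SynthesisConfig(mean_depth=100, rates=ZERO,
                            count_distribution="negative-binomial", dispersion=5),
            rng,
        )
        bi = synthesis(refs, SynthesisConfig(mean_depth=100, rates=ZERO), rng)
        assert nb.totals().var() > 5 * bi.totals().var()


class TestDecay:
    def test_identity(self, small_refs, rng):
        pool = SequencePool.from_references(small_refs, np.full(len(small_refs), 9))
        out = decay(pool, DecayConfig(survival_prob=1.0, rates=ZERO), rng)
        assert np.array_equal(out.counts, pool.counts)

    def test_full_decay(self, small_refs, rng):
        pool = SequencePool.from_references(small_refs, np.full(len(small_refs), 9))
        out = decay(pool, DecayConfig(survival_prob=0.0, rates=ZERO), rng)
        assert out.lost.all()

    def test_half_survival_rarely_loses_deep_sequences(self, rng):
        # P[Binomial(400, 0.5) = 0] ~ 0: no sequence of 500 should be lost
        pool = SequencePool.from_references(["ACGT"] * 500, np.full(500, 400))
        out = decay(pool, DecayConfig(survival_prob=0.5, rates=ZERO), rng)
        assert out.lost.sum() == 0
        assert abs(out.totals().mean() - 200) < 5


class TestPcr:
    def test_zero_cycles_identity(self, small_refs, rng):
        pool = SequencePool.from_references(small_refs, np.arange(1, len(small_refs) + 1))
        out = pcr(pool, PcrConfig(cycles=0), rng)
        assert np.array_equal(out.counts, pool.counts)

    def test_perfect_efficiency_doubles_exactly(self, small_refs, rng):
        pool = SequencePool.from_references(small_refs, np.full(len(small_refs), 7))
        out = pcr(
            pool,
            PcrConfig(cycles=5, efficiency=1.0, bias_sigma=0.0, normalize=False),
            rng,
        )
        assert np.array_equal(out.totals(), pool.totals() * 2**5)

    def test_bias_increases_dispersion(self):
        refs = ["ACGT" * 5] * 200
        pool = SequencePool.from_references(refs, np.full(200, 1000))
        biased = pcr(pool, PcrConfig(cycles=10, efficiency=0.9, bias_sigma=0.05,
                                     normalize=False), np.random.default_rng(11))
        flat = pcr(pool, PcrConfig(cycles=10, efficiency=0.9, bias_sigma=0.0,
                                   normalize=False), np.random.default_rng(11))
        cv = lambda x: x.std() / x.mean()
        assert cv(biased.totals()) > cv(flat.totals())

    def test_normalize_keeps_pool_scale(self, rng):
        pool = SequencePool.from_references(["ACGT" * 6] * 300, np.full(300, 500))
        out = pcr(pool, PcrConfig(cycles=8, efficiency=0.8, bias_sigma=0.01), rng)
        before, after = pool.counts.sum(), out.counts.sum()
        assert abs(after - before) < 5 * np.sqrt(before)


class TestSampling:
    def test_identity_and_extinction(self, small_refs, rng):
        pool = SequencePool.from_references(small_refs, np.full(len(small_refs), 6))
        assert np.array_equal(sample(pool, SamplingConfig(ratio=1.0), rng).counts, pool.counts)
        assert sample(pool, SamplingConfig(ratio=0.0), rng).lost.all()

    def test_poisson_limit_loss_fraction(self, rng):
        # Binomial(5000, 0.001) ~ Poisson(5): loss fraction ~ e^-5
        M = 2000
        pool = SequencePool.from_references(["ACGT"] * M, np.full(M, 5000))
        out = sample(pool, SamplingConfig(ratio=0.001), rng)
        frac = out.lost.sum() / M
        expected = np.exp(-5)
        assert abs(frac - expected) < 4 * np.sqrt(expected / M)
        assert abs(out.totals().mean() - 5) < 0.2


class TestSequencing:
    def test_zero_depth_all_lost(self, small_refs, rng):
        pool = SequencePool.from_references(small_refs, np.full(len(small_refs), 5))
        reads = sequencing(pool, SequencingConfig(depth=0, rates=ZERO), rng)
        assert reads.n_lost == len(small_refs)

    def test_single_reference_reads_match_molecules(self, rng):
        ref = "ACGTACGTACGTACGTACGT"
        pool = SequencePool.from_references([ref], [50])
        reads = sequencing(pool, SequencingConfig(depth=30, rates=ZERO), rng)
        assert sum(m for _, m in reads.reads[0]) == 30
        assert all(s == ref for s, _ in reads.reads[0])

    def test_read_budget_is_depth_times_survivors(self, small_refs, rng):
        pool = SequencePool.from_references(small_refs, np.full(len(small_refs), 100))
        reads = sequencing(pool, SequencingConfig(depth=20, rates=ZERO), rng)
        assert reads.n_reads().sum() == 20 * len(small_refs)

    def test_coverage_inherits_count_skew(self, rng):
        refs = ["ACGT" * 8] * 400
        counts = np.concatenate([np.full(200, 20), np.full(200, 200)])
        pool = SequencePool.from_references(refs, counts)
        reads = sequencing(pool, SequencingConfig(depth=10, rates=ZERO), rng)
        n = reads.n_reads()
        assert n[200:].mean() > 5 * n[:200].mean()


class TestRunChannel:
    def test_identity_channel_reproduces_references(self, small_refs):
        res = run_channel(small_refs, identity_config(), seed=4)
        for i, ref in enumerate(small_refs):
            assert res.reads.reads[i], f"reference {i} lost in identity channel"
            assert all(s == ref for s, _ in res.reads.reads[i])

    def test_fixed_seed_is_byte_identical(self, small_refs):
        cfg = ChannelConfig(
            synthesis=SynthesisConfig(mean_depth=30),
            sampling=SamplingConfig(ratio=0.5),
            sequencing=SequencingConfig(depth=5),
        )
        a = run_channel(small_refs, cfg, seed=9)
        b = run_channel(small_refs, cfg, seed=9)
        assert a.reads.reads == b.reads.reads
        assert all(np.array_equal(a.snapshots[k], b.snapshots[k]) for k in a.snapshots)

    def test_skip_stage_is_identity(self, small_refs):
        cfg = identity_config().replace(
            decay=DecayConfig(survival_prob=0.0, rates=ZERO)  # would lose everything
        )
        res = run_channel(small_refs, cfg, seed=2, skip=("decay",))
        assert not res.reads.lost.any()
        with pytest.raises(ValidationError):
            run_channel(small_refs, cfg, seed=2, skip=("nonsense",))

    def test_stage_errors_carry_stage_name(self):
        with pytest.raises(RuntimeError, match="synthesis"):
            run_channel([], identity_config(), seed=0)

    def test_pcr_bias_skews_snapshot_beyond_synthesis(self, small_refs):
        cfg = ChannelConfig(
            synthesis=SynthesisConfig(mean_depth=500, rates=ZERO),
            decay=DecayConfig(survival_prob=1.0, rates=ZERO),
            pcr=PcrConfig(cycles=10, efficiency=0.8, bias_sigma=0.05),
            sampling=SamplingConfig(ratio=1.0),
            sequencing=SequencingConfig(depth=1, rates=ZERO),
        )
        res = run_channel(small_refs * 10, cfg, seed=21)  # 200 references
        cv = lambda x: x.std() / x.mean()
        assert cv(res.snapshots["pcr"]) > cv(res.snapshots["synthesis"])


def test_lost_counts_decrease_with_sampling_ratio_and_depth():
    """Mean lost counts are non-increasing in sampling ratio and in depth."""
    refs = ["ACGTACGTACGTACGTACGTACGTACGTACGT"] * 300
    base = ChannelConfig(
        synthesis=SynthesisConfig(mean_depth=500, rates=ZERO),
        decay=DecayConfig(survival_prob=0.99, rates=ZERO),
        pcr=PcrConfig(cycles=4, efficiency=0.8, bias_sigma=0.01),
        sequencing=SequencingConfig(depth=4, rates=ZERO),
    )
    seeds = range(10)

    def mean_lost(cfg):
        return np.mean([
            run_channel(refs, cfg, seed=int(s)).reads.n_lost for s in seeds
        ])

    by_ratio = [mean_lost(base.replace(sampling=SamplingConfig(ratio=r)))
                for r in (0.002, 0.01, 0.05)]
    assert by_ratio[0] >= by_ratio[1] >= by_ratio[2]

    sampled = base.replace(sampling=SamplingConfig(ratio=0.004))
    by_depth = [
        np.mean([
            run_channel(refs, sampled.replace(
                sequencing=SequencingConfig(depth=d, rates=ZERO)), seed=int(s)
            ).reads.n_lost
            for s in seeds
        ])
        for d in (1, 4, 16)
    ]
    assert by_depth[0] >= by_depth[1] >= by_depth[2]
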