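"""Redundancy planning for fountain + Reed–Solomon encodings.

A DNA-fountain encoding has two redundancy knobs: the fountain overhead
``alpha`` (data in M chunks encoded as (1+alpha)M droplets; decoding needs
(1+beta)M of them, so (alpha-beta)M losses are tolerable) and the per-strand
Reed–Solomon parity length ``L_RS`` (corrects floor(L_RS/2) byte errors).
This module turns a simulated channel error profile into a plan:

1. information density  D(k) = (L_d / (L_d + 2k)) *
   (N / ((1+beta)N + N_l + tail_k))   — the product of the within-sequence
   and across-sequence densities, where ``k`` is the byte-correction
   capacity, N the number of chunks, N_l the lost count and ``tail_k`` the
   number of sequences with too many byte errors for capacity ``k``;
2. L_RS = 2 * argmax_k D(k);
3. total lost N_tl = lost + discarded; fitted as Poisson with
   lambda = p_tl (1+alpha) N.  Droplets-needed (1+beta)M samples are fitted
   with a right-skewed Gumbel (Anderson–Darling statistic reported) and the
   permitted-lost variable (alpha-beta)M = (1+alpha)M - (1+beta)M is its
   reflection;
4. failure probability p_f(alpha) = sum_j f_perm(j) P[N_tl > j]
   (decoding fails when the lost number exceeds the permitted number) and
   the contiguous alpha range meeting a target success probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ErrorProfile",
    "LostModel",
    "PermittedModel",
    "RedundancyPlan",
    "information_density",
    "choose_rs_length",
    "total_lost",
    "fit_lost",
    "fit_permitted",
    "failure_probability",
    "choose_alpha",
    "plan_redundancy",
]


@dataclass(frozen=True)
class ErrorProfile:
    """Channel error profile of one (or pooled) simulation run.

    ``n_e`` maps a byte-error count i to the number of sequences with exactly
    i byte errors after voting; ``n_lost`` is the lost-sequence count; ``m``
    the number of data chunks / encoded sequences; ``payload_bytes`` the data
    bytes per sequence (L_d); ``beta`` the fountain decoding-overhead
    fraction.
    """

    n_lost: int
    n_e: dict[int, int]
    m: int
    payload_bytes: int
    beta: float

    def __post_init__(self):
        if self.n_lost < 0 or any(v < 0 for v in self.n_e.values()):
            raise ValueError("counts must be >= 0")
        if self.n_lost + sum(self.n_e.values()) != self.m:
            raise ValueError("N_l + sum_i N_e(i) must equal the number of sequences")
        if self.payload_bytes < 1 or self.beta < 0:
            raise ValueError("invalid payload length or beta")

    def tail(self, k: int, mode: str = "capacity") -> int:
        """Sequences discarded at capacity k: byte errors > k ("capacity",
        the RS rule) or >= k ("printed", the tail as typeset in the density
        formula — the two differ in whether exactly-k-error sequences are
        kept)."""
        if mode == "capacity":
            return sum(v for i, v in self.n_e.items() if i > k)
        if mode == "printed":
            return sum(v for i, v in self.n_e.items() if i >= k)
        raise ValueError("mode must be 'capacity' or 'printed'")


def information_density(k: int, profile: ErrorProfile, tail_mode: str = "capacity") -> float:
    """Information density D(k) at byte-correction capacity k (L_RS = 2k)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    ld = profile.payload_bytes
    within = ld / (ld + 2 * k)
    discarded = profile.tail(k, tail_mode)
    across = profile.m / (
        (1 + profile.beta) * profile.m + profile.n_lost + discarded
    )
    return within * across


def choose_rs_length(
    profile: ErrorProfile, k_max: int = 8, tail_mode: str = "capacity"
) -> int:
    """L_RS = 2 argmax_k D(k) over k = 0..k_max; ties pick the smallest k."""
    dens = [information_density(k, profile, tail_mode) for k in range(k_max + 1)]
    return 2 * int(np.argmax(dens))


def total_lost(profile_or_summary, l_rs: int) -> int:
    """Total lost N_tl = lost + sequences beyond the capacity floor(L_RS/2).

    Accepts an :class:`ErrorProfile` or any object with ``n_lost`` and a
    byte-error histogram (``byte_error_hist`` attribute or ``n_e`` field).
    """
    hist = getattr(profile_or_summary, "n_e", None)
    if hist is None:
        hist = profile_or_summary.byte_error_hist
    n_lost = getattr(profile_or_summary, "n_lost", None)
    if n_lost is None:
        n_lost = profile_or_summary.n_lost_reads
    cap = l_rs // 2
    return int(n_lost) + sum(v for i, v in hist.items() if i > cap)


@dataclass(frozen=True)
class LostModel:
    """Poisson model of the total-lost count N_tl."""

    lam: float
    gof_statistic: float = float("nan")  # chi-square GoF against the fit

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    def sf(self, j) -> np.ndarray | float:
        """P[N_tl > j]."""
        if self.lam == 0:
            return np.where(np.asarray(j) >= 0, 0.0, 1.0)
        return stats.poisson.sf(j, self.lam)

    def rescaled(self, p_tl: float, alpha: float, n: int) -> "LostModel":
        """Model at overhead alpha: lambda = p_tl (1+alpha) N."""
        return LostModel(p_tl * (1 + alpha) * n, self.gof_statistic)


def fit_lost(samples) -> LostModel:
    """Poisson fit of total-lost samples: the MLE of lambda is the mean."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if (x < 0).any():
        raise ValueError("lost counts must be >= 0")
    lam = float(x.mean())
    gof = float("nan")
    if lam > 0 and x.size >= 5:
        # Pearson statistic against the fitted pmf on integer bins (diagnostic)
        hi = int(max(x.max(), stats.poisson.ppf(0.999, lam)))
        support = np.arange(hi + 1)
        obs = np.bincount(x.astype(int), minlength=hi + 1)[: hi + 1]
        exp = stats.poisson.pmf(support, lam) * x.size
        ok = exp > 1e-8
        gof = float(((obs[ok] - exp[ok]) ** 2 / exp[ok]).sum())
    return LostModel(lam, gof)


@dataclass(frozen=True)
class PermittedModel:
    """Gumbel model of droplets-needed (1+beta)M; permitted lost is its
    reflection (alpha-beta)M = (1+alpha)M - (1+beta)M."""

    loc: float
    scale: float
    m: int
    ad_statistic: float = float("nan")
    degenerate: bool = False

    def __post_init__(self):
        if self.scale < 0 or (self.scale == 0 and not self.degenerate):
            raise ValueError("Gumbel scale must be > 0 (or a flagged point mass)")

    @property
    def beta(self) -> float:
        """Decoding-overhead fraction implied by the mean droplets-needed."""
        mean = self.loc + (np.euler_gamma * self.scale if not self.degenerate else 0.0)
        return mean / self.m - 1.0

    def needed_cdf(self, x) -> np.ndarray | float:
        if self.degenerate:
            return (np.asarray(x, dtype=float) >= self.loc).astype(float)
        return stats.gumbel_r.cdf(x, loc=self.loc, scale=self.scale)

    def permitted_pmf(self, alpha: float, t_max: int) -> np.ndarray:
        """Discretized raw mass of permitted lost j = 0..t_max at overhead
        alpha (pmf(j) = CDF(j+1/2) - CDF(j-1/2) of the reflected fit); mass of
        negative permitted values (the encoding produced fewer droplets than a
        decode would need) is exposed separately via :meth:`p_infeasible`."""
        total = (1 + alpha) * self.m
        j = np.arange(t_max + 1)
        x = total - j  # droplets-needed value mapped to permitted-lost j
        return np.maximum(self.needed_cdf(x + 0.5) - self.needed_cdf(x - 0.5), 0.0)

    def p_infeasible(self, alpha: float) -> float:
        """P[droplets needed > (1+alpha)M]: failure regardless of losses."""
        return float(1.0 - self.needed_cdf((1 + alpha) * self.m + 0.5))

    def with_overhead_floor(self, min_beta: float) -> "PermittedModel":
        """Shift the fitted droplets-needed location up so the implied mean
        overhead is at least ``min_beta`` (a planning safety margin for
        decoders less thrifty than the measured one); a fit already above the
        floor is returned unchanged."""
        if self.beta >= min_beta:
            return self
        gamma = 0.0 if self.degenerate else np.euler_gamma
        loc = (1 + min_beta) * self.m - gamma * self.scale
        return PermittedModel(loc, self.scale, self.m, self.ad_statistic, self.degenerate)

    def permitted_quantile(self, alpha: float, q: float) -> float:
        """Upper 1-q quantile of permitted lost (reflecting the lower q
        quantile of droplets-needed)."""
        if self.degenerate:
            needed = self.loc
        else:
            needed = float(stats.gumbel_r.ppf(q, loc=self.loc, scale=self.scale))
        return (1 + alpha) * self.m - needed


def fit_permitted(samples, m: int) -> PermittedModel:
    """Fit a Gumbel to droplets-needed samples (maximum likelihood), with the
    Anderson–Darling statistic of the fit attached.  Degenerate samples fall
    back to a point mass with a warning."""
    x = np.asarray(samples, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 droplets-needed samples")
    if (x < m).any():
        raise ValueError("droplets-needed samples cannot be below M")
    if np.ptp(x) == 0:
        warnings.warn("degenerate droplets-needed samples; using a point mass", stacklevel=2)
        return PermittedModel(float(x[0]), 0.0, m, degenerate=True)
    loc, scale = stats.gumbel_r.fit(x)
    try:
        try:
            ad = float(stats.anderson(x, dist="gumbel_r", method="interpolate").statistic)
        except TypeError:  # scipy < 1.17 has no method parameter
            ad = float(stats.anderson(x, dist="gumbel_r").statistic)
    except Exception:  # pragma: no cover - scipy internals
        ad = float("nan")
    return PermittedModel(float(loc), float(scale), m, ad_statistic=ad)


def failure_probability(
    alpha: float,
    lost: LostModel,
    permitted: PermittedModel,
    t_max: int | None = None,
    residual_tol: float = 1e-6,
) -> float:
    """p_f(alpha) = sum_{j=0}^{T_max} f_permitted(j) P[N_tl > j], plus the
    permitted-lost mass below zero (an infeasible decode fails outright).

    ``t_max`` defaults to the 1 - 1e-6 quantile of the permitted-lost
    distribution; if the truncated tail mass exceeds ``residual_tol`` a
    warning reports the residual.
    """
    if t_max is None:
        t_max = max(0, int(np.ceil(permitted.permitted_quantile(alpha, 1e-6))))
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    p_neg = float(permitted.p_infeasible(alpha))
    pmf = np.asarray(permitted.permitted_pmf(alpha, t_max), dtype=float)
    mass_above = max(0.0, 1.0 - p_neg - float(pmf.sum()))
    if mass_above > residual_tol:
        # permitted values beyond T_max are treated as certain successes;
        # warn when that truncated mass is non-negligible
        warnings.warn(
            f"permitted-lost mass {mass_above:.2e} beyond T_max={t_max} truncated",
            stacklevel=2,
        )
    j = np.arange(t_max + 1)
    return float(min(1.0, p_neg + float((pmf * np.asarray(lost.sf(j), dtype=float)).sum())))


def choose_alpha(
    target_failure: float,
    p_tl: float,
    n: int,
    permitted: PermittedModel,
    grid=None,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float] | None]:
    """Scan an alpha grid for p_f(alpha) <= target.

    The lost model is rescaled per alpha (lambda = p_tl (1+alpha) N) and the
    permitted pmf re-derived from the one droplets-needed fit.  Returns
    (grid, p_f values, (alpha_min, alpha_max) or None when no grid point
    meets the target).
    """
    if not 0 < target_failure <= 1:
        raise ValueError("target failure probability must lie in (0, 1]")
    if grid is None:
        grid = np.arange(0.05, 0.601, 0.01)
    grid = np.asarray(grid, dtype=float)
    pf = np.empty_like(grid)
    for i, a in enumerate(grid):
        lost = LostModel(p_tl * (1 + a) * n)
        pf[i] = failure_probability(a, lost, permitted)
    ok = np.flatnonzero(pf <= target_failure)
    if ok.size == 0:
        return grid, pf, None
    # contiguous acceptable range starting at the first crossing
    end = ok[0]
    while end + 1 < grid.size and pf[end + 1] <= target_failure:
        end += 1
    return grid, pf, (float(grid[ok[0]]), float(grid[end]))


@dataclass
class RedundancyPlan:
    """Fitted distributions, density table and chosen redundancy levels."""

    d_table: dict[int, float]  # capacity k -> density (L_RS = 2k)
    l_rs: int
    lost: LostModel
    permitted: PermittedModel
    p_tl: float
    alpha_grid: np.ndarray
    pf_curve: np.ndarray
    alpha_range: tuple[float, float] | None
    target_success: float
    profile: ErrorProfile
    t_max: int = 0

    @property
    def alpha(self) -> float | None:
        """Smallest acceptable overhead (densest plan meeting the target)."""
        return None if self.alpha_range is None else self.alpha_range[0]

    @property
    def peak_density(self) -> float:
        return max(self.d_table.values())

    def summary(self) -> str:
        lines = [
            "Redundancy plan",
            "===============",
            f"chunks M                : {self.permitted.m}",
            f"pooled sequences        : {self.profile.m}",
            f"payload bytes L_d       : {self.profile.payload_bytes}",
            f"beta (decode overhead)  : {self.profile.beta:.4f}",
            f"lost sequences N_l      : {self.profile.n_lost}",
            f"total-lost rate p_tl    : {self.p_tl:.5f}",
            f"Poisson lambda (fit)    : {self.lost.lam:.2f}",
            f"Gumbel loc/scale (fit)  : {self.permitted.loc:.1f} / {self.permitted.scale:.2f}"
            f"  (AD={self.permitted.ad_statistic:.3f})",
            "",
            "  k  L_RS   D(k)",
        ]
        for k, d in self.d_table.items():
            mark = " <- chosen" if 2 * k == self.l_rs else ""
            lines.append(f"  {k}  {2 * k:4d}   {d:.4f}{mark}")
        lines.append("")
        if self.alpha_range is None:
            lines.append(
                f"no alpha on the grid meets the {self.target_success:.0%} success target"
            )
        else:
            lines.append(
                f"alpha range meeting {self.target_success:.0%} success: "
                f"[{self.alpha_range[0]:.2f}, {self.alpha_range[1]:.2f}]"
            )
        return "\n".join(lines)


DEFAULT_MIN_BETA = 0.05


def plan_redundancy(
    profiles,
    droplets_needed,
    payload_bytes: int,
    m: int,
    min_beta: float = DEFAULT_MIN_BETA,
    target_success: float = 0.99,
    alpha_grid=None,
    k_max: int = 8,
    tail_mode: str = "capacity",
) -> RedundancyPlan:
    """Full planning pipeline from per-replicate channel summaries.

    ``profiles`` is a sequence of objects with ``n_lost`` and
    ``byte_error_hist`` (channel summaries) or :class:`ErrorProfile` items;
    ``droplets_needed`` the per-replicate decoding-overhead samples.  The
    pooled profile chooses L_RS; per-replicate N_tl samples fit the Poisson;
    droplets-needed fit the Gumbel.  The plan's decoding overhead beta is the
    larger of the fitted overhead and ``min_beta`` (default 5 %, a safety
    margin so the plan does not assume every decoder is as thrifty as the
    measured one; set to 0 to plan on the fit alone).
    """
    permitted = fit_permitted(droplets_needed, m).with_overhead_floor(min_beta)
    beta = max(0.0, permitted.beta)
    pooled_lost = 0
    pooled_hist: dict[int, int] = {}
    n_seq = None
    for s in profiles:
        hist = s.n_e if hasattr(s, "n_e") else s.byte_error_hist
        n_lost = s.n_lost
        pooled_lost += n_lost
        for i, v in hist.items():
            pooled_hist[i] = pooled_hist.get(i, 0) + v
        n_seq = n_lost + sum(hist.values())
    n_rep = len(profiles)
    profile = ErrorProfile(
        n_lost=pooled_lost,
        n_e=pooled_hist,
        m=n_rep * n_seq,
        payload_bytes=payload_bytes,
        beta=beta,
    )
    d_table = {
        k: information_density(k, profile, tail_mode) for k in range(k_max + 1)
    }
    l_rs = choose_rs_length(profile, k_max, tail_mode)
    ntl = [total_lost(s if hasattr(s, "n_e") else s, l_rs) for s in profiles]
    lost = fit_lost(ntl) if len(ntl) >= 2 else LostModel(float(np.mean(ntl)))
    p_tl = float(np.mean(ntl)) / n_seq
    grid, pf, rng_ok = choose_alpha(
        1 - target_success, p_tl, m, permitted, grid=alpha_grid
    )
    mid_alpha = float(grid[len(grid) // 2])
    t_max = max(0, int(np.ceil(permitted.permitted_quantile(mid_alpha, 1e-6))))
    return RedundancyPlan(
        d_table=d_table,
        l_rs=l_rs,
        lost=lost,
        permitted=permitted,
        p_tl=p_tl,
        alpha_grid=grid,
        pf_curve=pf,
        alpha_range=rng_ok,
        target_success=target_success,
        profile=profile,
        t_max=t_max,
    )
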