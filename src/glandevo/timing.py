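"""Chronological timing of clonal expansions and CN-LOH events.

Under a constant somatic mutation rate from birth to sampling, the age at
which the most recent clonal expansion of a gland cluster occurred is the
sampling age scaled by the share of mutations that predate the expansion
(the public mutations):

    T_CE = Age * MB_pub / (MB_pub + MB_ps + MB_priv)

with a binomial normal-approximation CI on the public proportion p:
p +/- 1.96 * sqrt(p(1-p)/m), m the total mutation count.

For a CN-LOH, public SNVs inside the affected region are probabilistically
assigned to before/after the event from their read counts: a pre-event
mutation sits on both copies of the duplicated chromosome (per-read success
probability rho_i in gland i), a post-event mutation on one copy (rho_i/2).
Because pre-event mutations on the lost allele disappeared, the surviving
pre-event count is doubled. The event time is

    T_CNLOH = T_CE * MB_pre / (MB_pre + MB_post)

and assignment uncertainty is propagated by Monte Carlo: each iteration
draws an assignment from the per-SNV weights, computes the estimate and its
CI via the independence variance identity
V(XY) = V(X)V(Y) + E(X)^2 V(Y) + E(Y)^2 V(X); the reported estimate and CI
are means over the iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

Z95 = 1.959963984540054


@dataclass
class TimingEstimate:
    """Estimated chronological age of a genomic event with 95% CI."""

    event: str  # "expansion" | "cnloh"
    age_estimate: float
    ci_low: float
    ci_high: float
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.age_estimate <= self.ci_high:
            raise ValueError("CI must bracket the estimate")


@dataclass
class SnvTimingWeight:
    """Pre/post CN-LOH assignment weights for one public SNV site."""

    site: object
    w_pre: float
    w_post: float

    def __post_init__(self) -> None:
        if not math.isclose(self.w_pre + self.w_post, 1.0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")
        if self.w_pre < 0 or self.w_post < 0:
            raise ValueError("weights must be non-negative")


def time_expansion(
    age: float, mb_pub: int, mb_ps: int, mb_priv: int
) -> TimingEstimate:
    """Time the most recent clonal expansion of a cluster.

    Uses mutation counts outside copy-number-altered regions. The CI is
    the normal approximation on the public proportion, scaled by age and
    clipped to [0, age].
    """
    if age <= 0:
        raise ValueError("age must be positive")
    m = mb_pub + mb_ps + mb_priv
    if m < 1:
        raise ValueError("cluster has no mutations")
    if min(mb_pub, mb_ps, mb_priv) < 0:
        raise ValueError("negative mutation count")
    p = mb_pub / m
    half = Z95 * math.sqrt(p * (1.0 - p) / m)
    return TimingEstimate(
        event="expansion",
        age_estimate=age * p,
        ci_low=max(0.0, age * (p - half)),
        ci_high=min(age, age * (p + half)),
        inputs={
            "age": age, "mb_pub": mb_pub, "mb_ps": mb_ps, "mb_priv": mb_priv,
            "m": m, "p": p,
        },
    )


def snv_cnloh_weights(
    site: object,
    depths: Sequence[int],
    alt_reads: Sequence[int],
    rho: Sequence[float],
) -> SnvTimingWeight:
    """Pre/post CN-LOH weights for one public SNV across glands.

    Computes the joint probabilities of the observed mutant-read counts
    under the pre-event model (success probability rho_i per read) and the
    post-event model (rho_i / 2), working in log space; the binomial
    coefficient is common to both and cancels in the normalized weights.
    """
    d = np.asarray(depths, dtype=float)
    dm = np.asarray(alt_reads, dtype=float)
    r = np.asarray(rho, dtype=float)
    if not (d.shape == dm.shape == r.shape):
        raise ValueError("depths, alt_reads and rho must be equal-length")
    if np.any((dm < 0) | (dm > d)):
        raise ValueError("alt_reads outside [0, depth]")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("cellular fractions must be in (0, 1]")
    dref = d - dm

    def log_joint(p_success: np.ndarray) -> float:
        # 0 * log(0) -> 0 by convention; a ref read under rho = 1 gives -inf
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = dm * np.log(p_success)
            lq = dref * np.log1p(-p_success)
        lp = np.where(dm > 0, lp, 0.0)
        lq = np.where(dref > 0, lq, 0.0)
        return float(np.sum(lp + lq))

    lpre = log_joint(r)
    lpost = log_joint(r / 2.0)
    if lpre == -math.inf and lpost == -math.inf:
        raise ValueError("both assignment likelihoods are zero")
    mx = max(lpre, lpost)
    ppre = math.exp(lpre - mx)
    ppost = math.exp(lpost - mx)
    w_pre = ppre / (ppre + ppost)
    return SnvTimingWeight(site=site, w_pre=w_pre, w_post=1.0 - w_pre)


def variance_product(ex: float, vx: float, ey: float, vy: float) -> float:
    """Variance of the product of two independent variables.

    V(XY) = V(X)V(Y) + E(X)^2 V(Y) + E(Y)^2 V(X).
    """
    if vx < 0 or vy < 0:
        raise ValueError("variances must be >= 0")
    return vx * vy + ex * ex * vy + ey * ey * vx


def time_cnloh(
    t_ce: TimingEstimate,
    weights: Sequence[SnvTimingWeight],
    n_iter: int = 10_000,
    seed: int | None = None,
) -> TimingEstimate:
    """Time a CN-LOH event from public SNVs in the affected region.

    Each iteration assigns every SNV to pre/post by Bernoulli(w_pre),
    doubles the pre-event count (the allele lost in the event carried a
    like number of mutations), and computes
    T = T_CE * MB_pre / (MB_pre + MB_post) together with 95% limits from
    the product-variance identity applied to the public proportion X
    (from the expansion estimate) and the pre-event proportion Y. The
    estimate and CI are means over ``n_iter`` iterations; deterministic
    given the seed.
    """
    if t_ce.event != "expansion":
        raise ValueError("t_ce must be an expansion timing estimate")
    if not weights:
        raise ValueError("no public SNVs in the CN-LOH region")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    w_pre = np.array([w.w_pre for w in weights], dtype=float)
    if np.all(w_pre == 0) and len(w_pre) == 0:
        raise ValueError("all-zero weights")
    age = float(t_ce.inputs["age"])
    x = float(t_ce.inputs["p"])
    m_exp = float(t_ce.inputs["m"])
    vx = x * (1.0 - x) / m_exp

    rng = np.random.default_rng(seed)
    draws = rng.random((n_iter, w_pre.size)) < w_pre[None, :]
    n_pre = draws.sum(axis=1).astype(float)
    mb_pre = 2.0 * n_pre
    mb_post = w_pre.size - n_pre
    m = mb_pre + mb_post
    y = mb_pre / m
    vy = y * (1.0 - y) / m
    t_iter = age * x * y
    half = Z95 * age * np.sqrt(
        vx * vy + x * x * vy + y * y * vx
    )
    estimate = float(t_iter.mean())
    ci_low = max(0.0, float((t_iter - half).mean()))
    ci_high = min(age, float((t_iter + half).mean()))
    ci_low = min(ci_low, estimate)
    ci_high = max(ci_high, estimate)
    return TimingEstimate(
        event="cnloh",
        age_estimate=estimate,
        ci_low=ci_low,
        ci_high=ci_high,
        inputs={
            "age": age, "t_ce": t_ce.age_estimate, "n_snvs": int(w_pre.size),
            "n_iter": n_iter, "mean_mb_pre": float(mb_pre.mean()),
            "mean_mb_post": float(mb_post.mean()),
        },
    )
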