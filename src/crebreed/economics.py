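"""Production calculus: stochastic overproduction vs deterministic stopping.

Producing descendants with a suitable genotype is a Bernoulli process with
the Mendelian success probability ``p`` (1/4 for the single-homozygote
sibling cross, 1/16 for the double).  Two workflows are compared:

* **stochastic** — genotypes only become known after a delay, so enough
  descendants must be produced up front that, with confidence ``c``, at
  least ``k`` of them are suitable.  The planner inverts the complementary
  cumulative binomial: the smallest ``n`` with ``P(X >= k) >= c`` for
  ``X ~ Binomial(n, p)``.
* **deterministic** — genotypes are scored directly upon nascence, so
  production stops at the ``k``-th success.  The number of trials is
  negative-binomial with mean ``k/p``.

The headline comparison (p=1/16, k=1, c=0.95) gives n=47 vs E=16 — about a
two-thirds reduction in produced-but-unneeded animals; the absolute saving
grows with each additional independently segregating transgene.

All quantities are exact rationals; ``float()`` them for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Union

Probability = Union[Fraction, int, float, str]


def _as_probability(value: Probability, name: str = "p") -> Fraction:
    p = Fraction(value)
    if not 0 <= p <= 1:
        raise ValueError(f"{name} must lie in [0, 1], got {p}")
    return p


@dataclass(frozen=True)
class WorkflowParams:
    """Planner inputs: per-descendant success probability ``p``, required
    number of suitable individuals ``k``, and the confidence level."""

    p: Fraction
    k: int = 1
    confidence: Fraction = Fraction(95, 100)

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", _as_probability(self.p))
        object.__setattr__(self, "confidence", Fraction(self.confidence))
        if self.p == 0:
            raise ValueError("p must be positive")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not 0 < self.confidence < 1:
            raise ValueError(
                f"confidence must lie in (0, 1), got {self.confidence}"
            )


@dataclass(frozen=True)
class WorkflowComparison:
    """Stochastic plan vs deterministic expectation for one parameter set."""

    n_stochastic: int
    expected_deterministic: Fraction
    reduction_fraction: Fraction
    params: WorkflowParams


def binomial_tail(n: int, p: Probability, k: int) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, p), by exact summation."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    prob = _as_probability(p)
    if k > n:
        return Fraction(0)
    q = 1 - prob
    # sum the smaller side of the pmf: P(X >= k) = 1 - P(X <= k-1)
    if k <= n - k + 1:
        head = sum(
            (math.comb(n, i) * prob**i * q ** (n - i) for i in range(k)),
            Fraction(0),
        )
        return 1 - head
    return sum(
        (math.comb(n, i) * prob**i * q ** (n - i) for i in range(k, n + 1)),
        Fraction(0),
    )


def min_required(params: WorkflowParams) -> int:
    """Smallest ``n`` whose binomial tail reaches the confidence level.

    This is the stochastic workflow's up-front production size: e.g. 11
    descendants at p=1/4 and 47 at p=1/16 for one suitable individual at
    95% confidence.
    """
    n = params.k
    while binomial_tail(n, params.p, params.k) < params.confidence:
        n += 1
    return n


def expected_deterministic(p: Probability, k: int = 1) -> Fraction:
    """Mean number of trials until the k-th success: ``k/p``.

    The deterministic workflow stops production at the k-th suitable
    descendant, so on average k/p descendants are produced (4 at p=1/4,
    16 at p=1/16 for k=1).
    """
    prob = _as_probability(p)
    if prob == 0:
        raise ValueError("p must be positive")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return Fraction(k) / prob


def stopping_time_pmf(p: Probability, k: int, n: int) -> Fraction:
    """P(k-th success occurs exactly at trial n) — negative-binomial pmf.

    ``C(n-1, k-1) p^k (1-p)^(n-k)``; zero for n < k by contract.
    """
    prob = _as_probability(p)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n < k:
        return Fraction(0)
    return math.comb(n - 1, k - 1) * prob**k * (1 - prob) ** (n - k)


def compare_workflows(params: WorkflowParams) -> WorkflowComparison:
    """Assemble the stochastic plan, the deterministic expectation, and the
    fractional reduction 1 − (k/p)/n of produced descendants."""
    n = min_required(params)
    expected = expected_deterministic(params.p, params.k)
    return WorkflowComparison(
        n_stochastic=n,
        expected_deterministic=expected,
        reduction_fraction=1 - expected / n,
        params=params,
    )


def scaling_with_transgenes(
    m: int,
    per_locus_p: Probability = Fraction(1, 4),
    k: int = 1,
    confidence: Probability = Fraction(95, 100),
) -> list[WorkflowComparison]:
    """Workflow comparison for 1..m independently segregating transgenes.

    With each additional transgene the suitable-genotype probability
    multiplies by ``per_locus_p``, so the stochastic safety margin — and
    with it the absolute number of wasted animals — grows geometrically.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    base = _as_probability(per_locus_p, "per_locus_p")
    return [
        compare_workflows(
            WorkflowParams(p=base**i, k=k, confidence=Fraction(confidence))
        )
        for i in range(1, m + 1)
    ]
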