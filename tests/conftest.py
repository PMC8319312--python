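"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's gamete/cross code path: they
enumerate every ordered transmission (4^L for L loci) or every Bernoulli
outcome sequence (2^n) and sum exact rational probabilities directly.
"""

import itertools
import random
from fractions import Fraction

import pytest

from crebreed.genetics import (
    DUAL,
    MC,
    MCE,
    MO,
    MVE,
    Genotype,
    TransgeneLocus,
    WILDTYPE_ALLELE,
    genotype,
    single,
)

AGOC = TransgeneLocus("AGOC", (MO, MC))
ACOS = TransgeneLocus("ACOS", (MCE, MVE))
HELPER = TransgeneLocus("helper", (MC,))
# third locus for multi-locus oracle tests; marker overlap with AGOC is
# irrelevant at the transmission level
XTRA = TransgeneLocus("XTRA", (MO, MVE))


@pytest.fixture
def agoc():
    return AGOC


@pytest.fixture
def acos():
    return ACOS


@pytest.fixture
def helper_locus():
    return HELPER


def brute_force_cross(parent_a: Genotype, parent_b: Genotype) -> dict:
    """Oracle: enumerate all 4^L ordered transmissions of a cross."""
    loci = [locus for locus, _ in parent_a.entries]
    n_loci = len(loci)
    weight = Fraction(1, 4**n_loci)
    acc: dict = {}
    for choice_a in itertools.product((0, 1), repeat=n_loci):
        for choice_b in itertools.product((0, 1), repeat=n_loci):
            entries = tuple(
                (
                    locus,
                    (
                        parent_a.entries[i][1][choice_a[i]],
                        parent_b.entries[i][1][choice_b[i]],
                    ),
                )
                for i, locus in enumerate(loci)
            )
            cls = Genotype(entries).to_class()
            acc[cls] = acc.get(cls, Fraction(0)) + weight
    return acc


def brute_force_binomial_tail(n: int, p, k: int) -> Fraction:
    """Oracle: P(X >= k) by enumerating all 2^n outcome sequences."""
    prob = Fraction(p)
    total = Fraction(0)
    for bits in itertools.product((0, 1), repeat=n):
        if sum(bits) < k:
            continue
        seq_prob = Fraction(1)
        for bit in bits:
            seq_prob *= prob if bit else 1 - prob
        total += seq_prob
    return total


def random_genotype(rng: random.Random, loci) -> Genotype:
    def rand_allele(locus):
        options = [WILDTYPE_ALLELE] + [single(m) for m in locus.marker_pair]
        if len(locus.marker_pair) == 2:
            options.append(DUAL)
        return rng.choice(options)

    return genotype({locus: (rand_allele(locus), rand_allele(locus)) for locus in loci})


@pytest.fixture
def oracle_cross():
    return brute_force_cross


@pytest.fixture
def oracle_binomial_tail():
    return brute_force_binomial_tail
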