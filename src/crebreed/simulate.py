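"""Seeded synthetic progeny samples and vial-level scoring tables.

Emulates the statistical structure of published vial-scoring tables: per
cross, several vials of progeny are scored non-invasively for marker
phenotypes, each vial being one multinomial draw from the exact Mendelian
phenotype distribution of that cross.  Defaults follow the published
husbandry setup — up to six female-male pairs mated per cross, so six
vials — with 100 scored progeny per vial as a realistic vial yield.

A single top-level seed is expanded into independent per-vial substreams
via :class:`numpy.random.SeedSequence` spawning, so adding vials never
perturbs the draws of earlier vials.

Also provides the Monte-Carlo twin of the production calculus in
:mod:`crebreed.economics`: simulated stochastic (fixed ``n``) and
deterministic (stop at the ``k``-th success) workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .economics import WorkflowParams, min_required
from .genetics import PhenotypeClass

_COLUMNS = ["vial_id", "cross_id", "generation", "phenotype", "count"]


class TableFormatError(ValueError):
    """A scoring table violates the layout or content contract."""


@dataclass
class ScoringTable:
    """Per-vial phenotype-class counts tagged with cross and generation.

    Wraps a :class:`pandas.DataFrame` with columns ``vial_id, cross_id,
    generation, phenotype, count``.  Per vial the phenotype rows are
    complete: every scored class appears (possibly with count 0), and
    every vial carries the same class set.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.frame.columns) != _COLUMNS:
            raise TableFormatError(
                f"scoring table needs columns {_COLUMNS}, got "
                f"{list(self.frame.columns)}"
            )
        frame = self.frame.copy()
        frame["count"] = pd.to_numeric(frame["count"], errors="raise")
        if (frame["count"] < 0).any():
            bad = frame.loc[frame["count"] < 0, "vial_id"].iloc[0]
            raise TableFormatError(f"negative count in vial {bad!r}")
        if (frame["count"] % 1 != 0).any():
            raise TableFormatError("counts must be integers")
        frame["count"] = frame["count"].astype(int)
        try:
            frame["phenotype"] = [
                str(PhenotypeClass.parse(p)) for p in frame["phenotype"]
            ]
        except ValueError as exc:  # unknown marker token
            raise TableFormatError(str(exc)) from exc
        if frame.duplicated(["vial_id", "phenotype"]).any():
            dup = frame.loc[
                frame.duplicated(["vial_id", "phenotype"]), ["vial_id", "phenotype"]
            ].iloc[0]
            raise TableFormatError(
                f"duplicate row for vial {dup['vial_id']!r}, "
                f"phenotype {dup['phenotype']!r}"
            )
        class_sets = frame.groupby("vial_id")["phenotype"].agg(frozenset)
        if len(set(class_sets)) > 1:
            raise TableFormatError(
                "all vials must score the same set of phenotype classes"
            )
        self.frame = frame.reset_index(drop=True)

    def vial_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["vial_id"]))

    def phenotypes(self) -> list[str]:
        return sorted(
            set(self.frame["phenotype"]),
            key=lambda s: PhenotypeClass.parse(s).sort_key,
        )

    def vial_totals(self) -> pd.Series:
        return self.frame.groupby("vial_id", sort=False)["count"].sum()

    def pivot(self) -> pd.DataFrame:
        """Wide layout for human inspection: one column per phenotype class."""
        wide = self.frame.pivot_table(
            index=["vial_id", "cross_id", "generation"],
            columns="phenotype",
            values="count",
            aggfunc="sum",
        ).reset_index()
        wide.columns.name = None
        ordered = ["vial_id", "cross_id", "generation"] + self.phenotypes()
        return wide[ordered]


@dataclass(frozen=True)
class VialSpec:
    """How many vials to simulate for one cross, and how many progeny each."""

    cross_id: str
    n_vials: int = 6
    progeny_per_vial: Union[int, Sequence[int]] = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vials < 1:
            raise ValueError(f"n_vials must be >= 1, got {self.n_vials}")
        counts = self.counts()
        if len(counts) != self.n_vials:
            raise ValueError(
                f"got {len(counts)} per-vial counts for {self.n_vials} vials"
            )
        if any(c < 0 for c in counts):
            raise ValueError("progeny counts must be >= 0")

    def counts(self) -> list[int]:
        if isinstance(self.progeny_per_vial, int):
            return [self.progeny_per_vial] * self.n_vials
        return [int(c) for c in self.progeny_per_vial]


def _normalize_dist(
    dist: Mapping[Union[PhenotypeClass, str], Fraction],
) -> list[tuple[PhenotypeClass, Fraction]]:
    items = [
        (p if isinstance(p, PhenotypeClass) else PhenotypeClass.parse(p), Fraction(v))
        for p, v in dist.items()
    ]
    total = sum((v for _, v in items), Fraction(0))
    if total != 1:
        raise ValueError(f"distribution must sum exactly to 1, got {total}")
    if any(v < 0 for _, v in items):
        raise ValueError("distribution has negative entries")
    return sorted(items, key=lambda item: item[0].sort_key)


def sample_progeny(
    dist: Mapping[Union[PhenotypeClass, str], Fraction],
    n: int,
    seed: Union[int, np.random.Generator, np.random.SeedSequence],
) -> dict[PhenotypeClass, int]:
    """One multinomial draw of ``n`` progeny from an exact phenotype
    distribution; reproducible under a fixed seed."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    items = _normalize_dist(dist)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    probs = np.array([float(v) for _, v in items])
    probs /= probs.sum()  # guard float round-off; exactness checked above
    counts = rng.multinomial(n, probs)
    return {pheno: int(c) for (pheno, _), c in zip(items, counts)}


def simulate_vials(
    dist: Mapping[Union[PhenotypeClass, str], Fraction],
    spec: VialSpec,
    generation_label: str = "",
) -> ScoringTable:
    """Simulate a vial-scoring table for one cross.

    Each vial is an independent multinomial draw from ``dist`` on its own
    seed substream; every supported phenotype class appears in every vial
    (count possibly 0), mirroring the published table layout.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_vials)
    rows = []
    for i, (stream, n) in enumerate(zip(streams, spec.counts()), start=1):
        counts = sample_progeny(dist, n, np.random.default_rng(stream))
        for pheno, count in counts.items():
            rows.append(
                {
                    "vial_id": f"v{i}",
                    "cross_id": spec.cross_id,
                    "generation": generation_label,
                    "phenotype": str(pheno),
                    "count": count,
                }
            )
    return ScoringTable(pd.DataFrame(rows, columns=_COLUMNS))


@dataclass(frozen=True)
class WorkflowSimResult:
    """Per-replicate produced counts and success indicators."""

    strategy: str
    params: WorkflowParams
    produced: np.ndarray
    success: np.ndarray
    n_planned: int | None = None

    @property
    def mean_produced(self) -> float:
        return float(np.mean(self.produced))

    @property
    def success_rate(self) -> float:
        return float(np.mean(self.success))


def simulate_workflow(
    strategy: str,
    params: WorkflowParams,
    reps: int,
    seed: int,
) -> WorkflowSimResult:
    """Monte-Carlo twin of the production calculus.

    ``stochastic``: every replicate produces the planner-recommended
    ``min_required(params)`` descendants and succeeds when at least ``k``
    are suitable.  ``deterministic``: every replicate draws descendants
    until the ``k``-th success and records the number of trials
    (negative-binomial stopping time); it always succeeds.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    p = float(params.p)
    if strategy == "stochastic":
        n = min_required(params)
        successes = rng.binomial(n, p, size=reps)
        return WorkflowSimResult(
            strategy=strategy,
            params=params,
            produced=np.full(reps, n, dtype=np.int64),
            success=successes >= params.k,
            n_planned=n,
        )
    if strategy == "deterministic":
        # negative_binomial returns failures before the k-th success
        failures = rng.negative_binomial(params.k, p, size=reps)
        return WorkflowSimResult(
            strategy=strategy,
            params=params,
            produced=failures + params.k,
            success=np.ones(reps, dtype=bool),
        )
    raise ValueError(
        f"strategy must be 'stochastic' or 'deterministic', got {strategy!r}"
    )
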