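"""Declarative multi-generation mating schemes.

A :class:`MatingScheme` is an ordered list of crossing steps.  Each step
names its two parents either explicitly (a genotype string) or as a
phenotype-based selection from an earlier generation — exactly what a
non-invasive marker screen can do: selection rules see visible markers
only, never the underlying genotype.  Propagation is exact: every
generation is a :class:`~crebreed.genetics.GenotypeDistribution` and
selection is exact Bayesian conditioning on the phenotype.

Three built-in schemes mirror the published breeding procedures:

* ``agoc_single`` — creation of single homozygous lines from a
  dual-cassette founder via a Cre helper cross (reconstructed procedure),
* ``agoc_acos_double`` — the F7→F10 procedure creating double homozygotes
  for two transgenes marked with the color-complementary pairs mO/mC and
  mCe/mVe,
* ``resegregation`` — the F12→F15 outcross/re-build cycle demonstrating
  reversibility with alternative marker combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .genetics import (
    ONE,
    ZERO,
    ConfigurationError,
    Genotype,
    GenotypeClass,
    GenotypeDistribution,
    Marker,
    PhenotypeClass,
    TransgeneLocus,
    cross,
    get_marker,
    parse_genotype,
    phenotype_of,
    wildtype_genotype,
)


class EmptySelectionError(ValueError):
    """A selection rule matches no positive-probability phenotype."""


class InconsistentScoringError(ValueError):
    """An observed testcross phenotype set matches no candidate genotype."""


@dataclass(frozen=True)
class SelectionRule:
    """Phenotype-based selection: markers that must / must not be visible."""

    required: frozenset[Marker] = frozenset()
    forbidden: frozenset[Marker] = frozenset()
    sex_label: str | None = None

    def __post_init__(self) -> None:
        if self.required & self.forbidden:
            raise ConfigurationError(
                "required and forbidden marker sets must be disjoint"
            )

    def matches(self, pheno: PhenotypeClass) -> bool:
        return self.required <= pheno.markers and not (
            self.forbidden & pheno.markers
        )

    def describe(self) -> str:
        req = "+".join(str(m) for m in sorted(self.required, key=lambda m: m.order))
        parts = [f"require {req or 'nothing'}"]
        if self.forbidden:
            forb = "+".join(
                str(m) for m in sorted(self.forbidden, key=lambda m: m.order)
            )
            parts.append(f"forbid {forb}")
        if self.sex_label:
            parts.append(f"sex {self.sex_label}")
        return ", ".join(parts)


@dataclass(frozen=True)
class ExplicitParent:
    genotype: Genotype


@dataclass(frozen=True)
class SelectedParent:
    source: str
    rule: SelectionRule


ParentSpec = Union[ExplicitParent, SelectedParent]


@dataclass(frozen=True)
class SchemeStep:
    """One cross: two parents, a progeny generation label, optional Cre.

    ``cre_active`` marks crosses performed in the presence of the Cre
    helper: dual cassettes in transmitted gametes are resolved with
    ``cre_efficiency`` (germline action).
    """

    generation_label: str
    parent_a: ParentSpec
    parent_b: ParentSpec
    cre_active: bool = False
    cre_efficiency: Fraction = ONE


@dataclass(frozen=True)
class MatingScheme:
    name: str
    loci: tuple[TransgeneLocus, ...]
    steps: tuple[SchemeStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ConfigurationError("scheme needs at least one step")
        ids = [locus.id for locus in self.loci]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate locus ids in scheme {self.name!r}")
        seen: set[str] = set()
        for step in self.steps:
            for parent in (step.parent_a, step.parent_b):
                if isinstance(parent, SelectedParent) and parent.source not in seen:
                    raise ConfigurationError(
                        f"step {step.generation_label!r} references generation "
                        f"{parent.source!r} which does not precede it"
                    )
            seen.add(step.generation_label)


@dataclass(frozen=True)
class GenerationReport:
    """Exact per-generation theoretical ratios of one scheme step."""

    generation_label: str
    genotype_distribution: GenotypeDistribution
    phenotype_distribution: dict[PhenotypeClass, Fraction]
    #: selected parent distributions, keyed "parent_a"/"parent_b" where a
    #: selection rule was applied
    parent_selections: dict[str, GenotypeDistribution] = field(default_factory=dict)

    def scoring(self) -> dict[PhenotypeClass, frozenset[GenotypeClass]]:
        return scoring_map(self.genotype_distribution)


# ---------------------------------------------------------------------------
# Operations


def phenotype_distribution(
    dist: GenotypeDistribution,
) -> dict[PhenotypeClass, Fraction]:
    """Pushforward of a genotype distribution through the marker phenotype."""
    out: dict[PhenotypeClass, Fraction] = {}
    for cls, prob in dist.items():
        pheno = phenotype_of(cls)
        out[pheno] = out.get(pheno, ZERO) + prob
    return dict(sorted(out.items(), key=lambda item: item[0].sort_key))


def scoring_map(
    dist: GenotypeDistribution,
) -> dict[PhenotypeClass, frozenset[GenotypeClass]]:
    """Which genotype classes each visible phenotype could hide.

    A phenotype is *deterministic* — scoring it identifies the genotype —
    exactly when its set is a singleton.
    """
    acc: dict[PhenotypeClass, set[GenotypeClass]] = {}
    for cls in dist:
        acc.setdefault(phenotype_of(cls), set()).add(cls)
    return {
        pheno: frozenset(classes)
        for pheno, classes in sorted(acc.items(), key=lambda item: item[0].sort_key)
    }


def apply_selection(
    dist: GenotypeDistribution,
    rule: SelectionRule,
    context: str = "",
) -> GenotypeDistribution:
    """Condition a genotype distribution on passing a phenotype screen."""
    kept = {
        cls: prob for cls, prob in dist.items() if rule.matches(phenotype_of(cls))
    }
    total = sum(kept.values(), ZERO)
    if total == 0:
        where = f" at {context}" if context else ""
        raise EmptySelectionError(
            f"empty selection{where}: rule ({rule.describe()}) matches no progeny"
        )
    return GenotypeDistribution({cls: prob / total for cls, prob in kept.items()})


def cross_distributions(
    dist_a: GenotypeDistribution,
    dist_b: GenotypeDistribution,
    *,
    cre_efficiency: Fraction | None = None,
) -> GenotypeDistribution:
    """Progeny distribution when each parent is drawn independently from a
    genotype distribution (mixture of pairwise crosses)."""
    acc: dict[GenotypeClass, Fraction] = {}
    cache: dict[tuple[GenotypeClass, GenotypeClass], GenotypeDistribution] = {}
    for cls_a, pa in dist_a.items():
        for cls_b, pb in dist_b.items():
            key = (cls_a, cls_b)
            if key not in cache:
                cache[key] = cross(
                    cls_a.representative(),
                    cls_b.representative(),
                    cre_efficiency=cre_efficiency,
                )
            for child, pc in cache[key].items():
                acc[child] = acc.get(child, ZERO) + pa * pb * pc
    return GenotypeDistribution(acc)


def _parent_distribution(
    spec: ParentSpec,
    generations: Mapping[str, GenotypeDistribution],
    scheme: MatingScheme,
    step_label: str,
) -> tuple[GenotypeDistribution, GenotypeDistribution | None]:
    if isinstance(spec, ExplicitParent):
        if set(spec.genotype.loci()) != set(scheme.loci):
            raise ConfigurationError(
                f"step {step_label!r}: explicit parent does not cover the "
                f"scheme locus set"
            )
        return GenotypeDistribution.degenerate(spec.genotype.to_class()), None
    if spec.source not in generations:
        raise ConfigurationError(
            f"step {step_label!r}: dangling reference to generation "
            f"{spec.source!r}"
        )
    selected = apply_selection(
        generations[spec.source],
        spec.rule,
        context=f"step {step_label!r} (parent from {spec.source!r})",
    )
    return selected, selected


def run_scheme(scheme: MatingScheme) -> list[GenerationReport]:
    """Propagate exact genotype distributions through every scheme step."""
    generations: dict[str, GenotypeDistribution] = {}
    reports: list[GenerationReport] = []
    for step in scheme.steps:
        selections: dict[str, GenotypeDistribution] = {}
        dist_a, sel_a = _parent_distribution(
            step.parent_a, generations, scheme, step.generation_label
        )
        dist_b, sel_b = _parent_distribution(
            step.parent_b, generations, scheme, step.generation_label
        )
        if sel_a is not None:
            selections["parent_a"] = sel_a
        if sel_b is not None:
            selections["parent_b"] = sel_b
        eff = step.cre_efficiency if step.cre_active else None
        progeny = cross_distributions(dist_a, dist_b, cre_efficiency=eff)
        generations[step.generation_label] = progeny
        reports.append(
            GenerationReport(
                generation_label=step.generation_label,
                genotype_distribution=progeny,
                phenotype_distribution=phenotype_distribution(progeny),
                parent_selections=selections,
            )
        )
    return reports


def testcross_expectation(g: Genotype) -> dict[PhenotypeClass, Fraction]:
    """Phenotype distribution of the progeny of ``g`` × all-wildtype.

    The classic way to read a candidate's genotype without touching it: a
    homozygote throws uniformly marked progeny, a heterozygote segregates.
    """
    wt = wildtype_genotype(g.loci())
    return phenotype_distribution(cross(g, wt))


def infer_parent_from_testcross(
    observed: Iterable[PhenotypeClass],
    candidates: Iterable[GenotypeClass],
) -> frozenset[GenotypeClass]:
    """Candidates whose testcross phenotype support equals the observed set."""
    observed_set = frozenset(observed)
    if not observed_set:
        raise ValueError("observed phenotype set must be nonempty")
    matches = {
        cls
        for cls in candidates
        if frozenset(testcross_expectation(cls.representative())) == observed_set
    }
    if not matches:
        raise InconsistentScoringError(
            "inconsistent scoring: observed phenotypes "
            f"{{{', '.join(sorted(str(p) for p in observed_set))}}} match no "
            "candidate genotype"
        )
    return frozenset(matches)


@dataclass(frozen=True)
class MarkerCollision:
    locus_a: TransgeneLocus
    locus_b: TransgeneLocus
    shared: frozenset[Marker]


def check_marker_collisions(scheme: MatingScheme) -> list[MarkerCollision]:
    """Locus pairs whose marker sets intersect — phenotype scoring of such a
    scheme would be ambiguous (the reason the helper line is recolored when
    its marker clashes with a cassette marker)."""
    conflicts = []
    loci = scheme.loci
    for i, locus_a in enumerate(loci):
        for locus_b in loci[i + 1 :]:
            shared = frozenset(locus_a.marker_pair) & frozenset(locus_b.marker_pair)
            if shared:
                conflicts.append(MarkerCollision(locus_a, locus_b, shared))
    return conflicts


def report_frame(reports: Sequence[GenerationReport]) -> pd.DataFrame:
    """Tabular view of scheme reports: one row per generation × phenotype."""
    rows = []
    for report in reports:
        scoring = report.scoring()
        for pheno, ratio in report.phenotype_distribution.items():
            classes = scoring[pheno]
            rows.append(
                {
                    "generation": report.generation_label,
                    "phenotype": str(pheno),
                    "theoretical_ratio": str(ratio),
                    "theoretical_ratio_decimal": round(float(ratio), 6),
                    "genotype_classes": "|".join(sorted(str(c) for c in classes)),
                    "deterministic": len(classes) == 1,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "generation",
            "phenotype",
            "theoretical_ratio",
            "theoretical_ratio_decimal",
            "genotype_classes",
            "deterministic",
        ],
    )


# ---------------------------------------------------------------------------
# Scheme configuration


def _parse_parent(raw: Mapping, loci: Sequence[TransgeneLocus]) -> ParentSpec:
    if "genotype" in raw:
        return ExplicitParent(parse_genotype(raw["genotype"], loci))
    if "from" in raw:
        rule = SelectionRule(
            required=frozenset(get_marker(n) for n in raw.get("require", [])),
            forbidden=frozenset(get_marker(n) for n in raw.get("forbid", [])),
            sex_label=raw.get("sex"),
        )
        return SelectedParent(source=raw["from"], rule=rule)
    raise ConfigurationError(
        f"parent spec needs either 'genotype' or 'from', got {dict(raw)!r}"
    )


def scheme_from_dict(config: Mapping) -> MatingScheme:
    """Build a scheme from its declarative config (the YAML file layout)."""
    loci = tuple(
        TransgeneLocus(
            id=item["id"],
            marker_pair=tuple(get_marker(n) for n in item["markers"]),
            chromosome_label=item.get("chromosome", ""),
        )
        for item in config["loci"]
    )
    steps = tuple(
        SchemeStep(
            generation_label=raw["generation"],
            parent_a=_parse_parent(raw["parent_a"], loci),
            parent_b=_parse_parent(raw["parent_b"], loci),
            cre_active=bool(raw.get("cre", False)),
            cre_efficiency=Fraction(str(raw.get("cre_efficiency", 1))),
        )
        for raw in config["steps"]
    )
    return MatingScheme(name=config["name"], loci=loci, steps=steps)


#: Built-in scheme configs; `agoc_single` is a reconstruction of the
#: single-transgene procedure (founder dual-cassette line × Cre helper,
#: Cre-active outcross, marker-heterozygote selection, sibling cross).
BUILTIN_SCHEMES: dict[str, dict] = {
    "agoc_single": {
        "name": "agoc_single",
        "loci": [
            {"id": "ACOS", "markers": ["mCe", "mVe"]},
            {"id": "helper", "markers": ["mC"]},
        ],
        "steps": [
            {
                "generation": "F4",
                "parent_a": {"genotype": "ACOS:D/+"},
                "parent_b": {"genotype": "helper:mC/+"},
            },
            {
                "generation": "F5",
                "parent_a": {"from": "F4", "require": ["mCe", "mVe", "mC"]},
                "parent_b": {"genotype": "wt"},
                "cre": True,
            },
            {
                "generation": "F6",
                "parent_a": {"from": "F5", "require": ["mCe"], "forbid": ["mVe", "mC"]},
                "parent_b": {"from": "F5", "require": ["mVe"], "forbid": ["mCe", "mC"]},
            },
            {
                "generation": "F7",
                "parent_a": {"from": "F6", "require": ["mCe", "mVe"]},
                "parent_b": {"from": "F6", "require": ["mCe", "mVe"]},
            },
        ],
    },
    "agoc_acos_double": {
        "name": "agoc_acos_double",
        "loci": [
            {"id": "AGOC", "markers": ["mO", "mC"]},
            {"id": "ACOS", "markers": ["mCe", "mVe"]},
        ],
        "steps": [
            {
                "generation": "F8-OCe",
                "parent_a": {"genotype": "AGOC:mO/mO"},
                "parent_b": {"genotype": "ACOS:mCe/mCe"},
            },
            {
                "generation": "F8-CVe",
                "parent_a": {"genotype": "AGOC:mC/mC"},
                "parent_b": {"genotype": "ACOS:mVe/mVe"},
            },
            {
                "generation": "F9",
                "parent_a": {"from": "F8-OCe", "require": ["mO", "mCe"]},
                "parent_b": {"from": "F8-CVe", "require": ["mC", "mVe"]},
            },
            {
                "generation": "F10",
                "parent_a": {"from": "F9", "require": ["mO", "mC", "mCe", "mVe"]},
                "parent_b": {"from": "F9", "require": ["mO", "mC", "mCe", "mVe"]},
            },
        ],
    },
    "resegregation": {
        "name": "resegregation",
        "loci": [
            {"id": "AGOC", "markers": ["mO", "mC"]},
            {"id": "ACOS", "markers": ["mCe", "mVe"]},
        ],
        "steps": [
            {
                "generation": "F12-OCe",
                "parent_a": {"genotype": "AGOC:mO/+;ACOS:mCe/+"},
                "parent_b": {"genotype": "wt"},
            },
            {
                "generation": "F12-CVe",
                "parent_a": {"genotype": "AGOC:mC/+;ACOS:mVe/+"},
                "parent_b": {"genotype": "wt"},
            },
            {
                "generation": "F13-OVe",
                "parent_a": {"from": "F12-OCe", "require": ["mO"], "forbid": ["mCe"]},
                "parent_b": {"from": "F12-CVe", "require": ["mVe"], "forbid": ["mC"]},
            },
            {
                "generation": "F13-CCe",
                "parent_a": {"from": "F12-CVe", "require": ["mC"], "forbid": ["mVe"]},
                "parent_b": {"from": "F12-OCe", "require": ["mCe"], "forbid": ["mO"]},
            },
            {
                "generation": "F14",
                "parent_a": {"from": "F13-OVe", "require": ["mO", "mVe"]},
                "parent_b": {"from": "F13-CCe", "require": ["mC", "mCe"]},
            },
            {
                "generation": "F15",
                "parent_a": {"from": "F14", "require": ["mO", "mC", "mCe", "mVe"]},
                "parent_b": {"from": "F14", "require": ["mO", "mC", "mCe", "mVe"]},
            },
        ],
    },
}


def list_schemes() -> list[str]:
    return sorted(BUILTIN_SCHEMES)


def get_scheme(name: str) -> MatingScheme:
    """Instantiate a built-in scheme by name."""
    try:
        config = BUILTIN_SCHEMES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scheme {name!r}; built-ins: {', '.join(list_schemes())}"
        ) from None
    return scheme_from_dict(config)
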