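"""Exact transmission genetics for dual-marker Cre-Lox transgene cassettes.

The model tracks, for every transgene locus, one of three allele states on
each homologous chromosome:

* ``wildtype`` — no transgene present,
* ``dual`` — the unresolved cassette carrying *both* transformation markers
  of its locus, embedded in interweaved but mutually incompatible Lox site
  pairs,
* ``single`` — a Cre-resolved cassette carrying exactly one of the two
  markers.

Any transgene-bearing allele (dual or single) advertises its presence
through the visible marker(s) it carries, which is what makes zygosity
readable by phenotype alone: a cross of two marker-heterozygotes (e.g.
mO/mC) yields homozygotes that are *revealed by the lack of one marker*.

All probability propagation — Cre resolution, gamete formation, crossing —
is performed with exact rational arithmetic (:class:`fractions.Fraction`).
Floating point appears only at presentation time and inside statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Iterable, Iterator, Mapping, Sequence, Union

HALF = Fraction(1, 2)
ONE = Fraction(1)
ZERO = Fraction(0)


class ConfigurationError(ValueError):
    """A genotype, cross or scheme is structurally invalid."""


class UnknownMarkerError(ConfigurationError):
    """A marker token is not one of the four canonical transformation markers."""


#: Canonical marker order; fixed once for all serialization and sorting.
CANONICAL_MARKER_ORDER = ("mO", "mC", "mCe", "mVe")


@dataclass(frozen=True)
class Marker:
    """A visible, eye-specific transformation marker.

    Parameters
    ----------
    name:
        One of the four canonical marker names ``mO``, ``mC``, ``mCe``,
        ``mVe`` (mOrange, mCherry, mCerulean, mVenus based markers).
    filter_label:
        Free-text description of the detection filter set.
    """

    name: str
    filter_label: str = ""

    def __post_init__(self) -> None:
        if self.name not in CANONICAL_MARKER_ORDER:
            raise UnknownMarkerError(
                f"unknown marker {self.name!r}; expected one of "
                f"{CANONICAL_MARKER_ORDER}"
            )

    @property
    def order(self) -> int:
        """Index in the canonical marker order (mO < mC < mCe < mVe)."""
        return CANONICAL_MARKER_ORDER.index(self.name)

    def __str__(self) -> str:
        return self.name


MO = Marker("mO", "mOrange filter set")
MC = Marker("mC", "mCherry filter set")
MCE = Marker("mCe", "mCerulean filter set")
MVE = Marker("mVe", "mVenus filter set")

#: The four canonical markers, keyed by name.
MARKERS: dict[str, Marker] = {m.name: m for m in (MO, MC, MCE, MVE)}


def get_marker(name: str) -> Marker:
    """Look up a canonical marker by name; raise :class:`UnknownMarkerError`."""
    try:
        return MARKERS[name]
    except KeyError:
        raise UnknownMarkerError(
            f"unknown marker {name!r}; expected one of {CANONICAL_MARKER_ORDER}"
        ) from None


def sort_markers(markers: Iterable[Marker]) -> list[Marker]:
    return sorted(markers, key=lambda m: m.order)


@dataclass(frozen=True)
class TransgeneLocus:
    """One autosomal transgene insertion site.

    ``marker_pair`` holds the one or two markers of the cassette carried at
    this locus.  Regular dual-marker cassettes (AGOC, ACOS style) have two
    distinct markers; a Cre helper transgene carries a single marker and can
    never be in the ``dual`` state.
    """

    id: str
    marker_pair: tuple[Marker, ...]
    chromosome_label: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ConfigurationError("locus id must be non-empty")
        if len(self.marker_pair) not in (1, 2):
            raise ConfigurationError(
                f"locus {self.id!r}: marker_pair must hold 1 or 2 markers"
            )
        if len(set(m.name for m in self.marker_pair)) != len(self.marker_pair):
            raise ConfigurationError(
                f"locus {self.id!r}: marker_pair members must be distinct"
            )

    def __str__(self) -> str:
        return self.id


class Zygosity(str, Enum):
    """Per-locus zygosity as readable from marker phenotypes.

    Heterozygous means two transgene-bearing alleles whose visible marker
    sets differ (the key selectable intermediate); homozygous means two
    transgene-bearing alleles with identical visible marker sets.
    """

    WILDTYPE = "wildtype"
    HEMIZYGOUS = "hemizygous"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"


_ALLELE_STATES = ("wildtype", "dual", "single")


@dataclass(frozen=True)
class Allele:
    """State of one chromosome at one transgene locus."""

    state: str
    marker: Marker | None = None

    def __post_init__(self) -> None:
        if self.state not in _ALLELE_STATES:
            raise ConfigurationError(
                f"allele state must be one of {_ALLELE_STATES}, got {self.state!r}"
            )
        if self.state == "single" and self.marker is None:
            raise ConfigurationError("single-state allele requires a marker")
        if self.state != "single" and self.marker is not None:
            raise ConfigurationError(
                f"{self.state}-state allele must not carry a marker"
            )

    @property
    def bears_transgene(self) -> bool:
        return self.state != "wildtype"

    def __str__(self) -> str:
        return allele_token(self)


WILDTYPE_ALLELE = Allele("wildtype")
DUAL = Allele("dual")


def single(marker: Marker) -> Allele:
    """A Cre-resolved allele carrying exactly one marker."""
    return Allele("single", marker)


def allele_token(allele: Allele) -> str:
    """Serialization token: ``+`` wildtype, ``D`` dual, marker name otherwise."""
    if allele.state == "wildtype":
        return "+"
    if allele.state == "dual":
        return "D"
    return allele.marker.name  # type: ignore[union-attr]


def parse_allele(token: str, locus: TransgeneLocus) -> Allele:
    if token == "+":
        return WILDTYPE_ALLELE
    if token == "D":
        if len(locus.marker_pair) != 2:
            raise ConfigurationError(
                f"locus {locus.id!r} has a single marker; no dual state exists"
            )
        return DUAL
    marker = get_marker(token)
    if marker not in locus.marker_pair:
        raise ConfigurationError(
            f"marker {token!r} does not belong to locus {locus.id!r}"
        )
    return single(marker)


def visible_markers(allele: Allele, locus: TransgeneLocus) -> frozenset[Marker]:
    """Markers an allele shows under the filter sets.

    A dual cassette shows both markers of the locus pair, a resolved
    cassette shows its single marker, wildtype shows nothing.
    """
    if allele.state == "wildtype":
        return frozenset()
    if allele.state == "dual":
        if len(locus.marker_pair) != 2:
            raise ConfigurationError(
                f"dual allele at single-marker locus {locus.id!r}"
            )
        return frozenset(locus.marker_pair)
    if allele.marker not in locus.marker_pair:
        raise ConfigurationError(
            f"allele marker {allele.marker} not in pair of locus {locus.id!r}"
        )
    return frozenset({allele.marker})  # type: ignore[arg-type]


def _allele_key(allele: Allele) -> tuple[int, int]:
    # single (by canonical marker order) < dual < wildtype
    if allele.state == "single":
        return (0, allele.marker.order)  # type: ignore[union-attr]
    if allele.state == "dual":
        return (1, 0)
    return (2, 0)


@dataclass(frozen=True)
class PhenotypeClass:
    """The set of visible markers an individual shows."""

    markers: frozenset[Marker]

    def __str__(self) -> str:
        if not self.markers:
            return "wt"
        return "+".join(m.name for m in sort_markers(self.markers))

    @classmethod
    def parse(cls, text: str) -> "PhenotypeClass":
        """Parse a phenotype string like ``mO+mCe`` (``wt`` = no markers).

        Marker order in the input is irrelevant; the result is canonical.
        """
        text = text.strip()
        if text in ("wt", ""):
            return cls(frozenset())
        return cls(frozenset(get_marker(tok.strip()) for tok in text.split("+")))

    @property
    def sort_key(self) -> tuple[int, ...]:
        return tuple(m.order for m in sort_markers(self.markers))


WT_PHENOTYPE = PhenotypeClass(frozenset())


def phenotype(*names: str) -> PhenotypeClass:
    """Convenience constructor: ``phenotype("mO", "mCe")``."""
    return PhenotypeClass(frozenset(get_marker(n) for n in names))


_Entries = tuple[tuple[TransgeneLocus, tuple[Allele, Allele]], ...]


@dataclass(frozen=True)
class Genotype:
    """Ordered (maternal, paternal) allele pairs over a set of unlinked loci.

    Entries are kept sorted by locus id so equal genotypes hash equally.
    ``sex_label`` is a pure annotation with no genetic effect (all loci are
    treated as autosomal).
    """

    entries: _Entries
    sex_label: str | None = None

    def loci(self) -> tuple[TransgeneLocus, ...]:
        return tuple(locus for locus, _ in self.entries)

    def pair(self, locus: TransgeneLocus) -> tuple[Allele, Allele]:
        for loc, pair in self.entries:
            if loc == locus:
                return pair
        raise ConfigurationError(f"locus {locus.id!r} not in genotype")

    def to_class(self) -> "GenotypeClass":
        return GenotypeClass.from_genotype(self)

    def __str__(self) -> str:
        return ";".join(
            f"{locus.id}:{allele_token(a)}/{allele_token(b)}"
            for locus, (a, b) in self.entries
        )


def _validate_pair(locus: TransgeneLocus, pair: tuple[Allele, Allele]) -> None:
    for allele in pair:
        if allele.state == "single" and allele.marker not in locus.marker_pair:
            raise ConfigurationError(
                f"allele marker {allele.marker} foreign to locus {locus.id!r}"
            )
        if allele.state == "dual" and len(locus.marker_pair) != 2:
            raise ConfigurationError(
                f"dual allele at single-marker locus {locus.id!r}"
            )


def genotype(
    alleles: Mapping[TransgeneLocus, tuple[Allele, Allele]],
    sex_label: str | None = None,
) -> Genotype:
    """Build a validated :class:`Genotype` from a locus → (mat, pat) mapping."""
    entries = []
    for locus in sorted(alleles, key=lambda l: l.id):
        pair = tuple(alleles[locus])
        if len(pair) != 2:
            raise ConfigurationError(f"locus {locus.id!r}: need two alleles")
        _validate_pair(locus, pair)  # type: ignore[arg-type]
        entries.append((locus, pair))
    return Genotype(tuple(entries), sex_label=sex_label)


def wildtype_genotype(loci: Iterable[TransgeneLocus]) -> Genotype:
    return genotype({locus: (WILDTYPE_ALLELE, WILDTYPE_ALLELE) for locus in loci})


def parse_genotype(
    text: str,
    loci: Sequence[TransgeneLocus],
    sex_label: str | None = None,
) -> Genotype:
    """Parse ``"AGOC:mO/mC;ACOS:+/+"`` against a scheme's locus set.

    Loci omitted from the string default to wildtype/wildtype; ``"wt"`` or
    the empty string denote the all-wildtype genotype.
    """
    by_id = {locus.id: locus for locus in loci}
    alleles: dict[TransgeneLocus, tuple[Allele, Allele]] = {
        locus: (WILDTYPE_ALLELE, WILDTYPE_ALLELE) for locus in loci
    }
    text = text.strip()
    if text not in ("", "wt"):
        for part in text.split(";"):
            locus_id, _, pair_text = part.strip().partition(":")
            if locus_id not in by_id:
                raise ConfigurationError(f"unknown locus {locus_id!r} in genotype")
            tokens = pair_text.split("/")
            if len(tokens) != 2:
                raise ConfigurationError(
                    f"genotype entry {part!r}: expected two '/'-separated alleles"
                )
            locus = by_id[locus_id]
            alleles[locus] = (
                parse_allele(tokens[0].strip(), locus),
                parse_allele(tokens[1].strip(), locus),
            )
    return genotype(alleles, sex_label=sex_label)


@dataclass(frozen=True)
class GenotypeClass:
    """Unordered genotype class: per locus, the multiset of the two alleles.

    Maternal/paternal origin is deliberately erased — mO/mC and mC/mO are
    the same class for every reporting purpose.
    """

    entries: _Entries

    @classmethod
    def from_genotype(cls, g: Genotype) -> "GenotypeClass":
        entries = tuple(
            (locus, tuple(sorted(pair, key=_allele_key)))
            for locus, pair in g.entries
        )
        return cls(entries)  # type: ignore[arg-type]

    def representative(self) -> Genotype:
        """An arbitrary ordered genotype of this class (loci are autosomal)."""
        return Genotype(self.entries)

    def loci(self) -> tuple[TransgeneLocus, ...]:
        return tuple(locus for locus, _ in self.entries)

    def __str__(self) -> str:
        return ";".join(
            f"{locus.id}:{allele_token(a)}/{allele_token(b)}"
            for locus, (a, b) in self.entries
        )


@dataclass(frozen=True)
class Haplotype:
    """One allele per locus — the content of a single gamete."""

    entries: tuple[tuple[TransgeneLocus, Allele], ...]

    def allele(self, locus: TransgeneLocus) -> Allele:
        for loc, allele in self.entries:
            if loc == locus:
                return allele
        raise ConfigurationError(f"locus {locus.id!r} not in haplotype")


GenotypeLike = Union[Genotype, GenotypeClass]


class GenotypeDistribution(Mapping[GenotypeClass, Fraction]):
    """Exact-rational probability map over unordered genotype classes.

    The universal currency of crossing and scheme propagation: entries are
    strictly positive :class:`~fractions.Fraction` probabilities that sum
    to exactly 1.  Iteration order is deterministic (lexicographic in the
    class serialization).
    """

    __slots__ = ("_entries",)

    def __init__(self, entries: Mapping[GenotypeClass, Fraction]):
        cleaned: dict[GenotypeClass, Fraction] = {}
        for cls, prob in entries.items():
            prob = Fraction(prob)
            if prob < 0:
                raise ValueError(f"negative probability for class {cls}")
            if prob > 0:
                cleaned[cls] = prob
        total = sum(cleaned.values(), ZERO)
        if total != 1:
            raise ValueError(f"probabilities must sum exactly to 1, got {total}")
        self._entries = dict(
            sorted(cleaned.items(), key=lambda item: str(item[0]))
        )

    @classmethod
    def degenerate(cls, genotype_class: GenotypeClass) -> "GenotypeDistribution":
        return cls({genotype_class: ONE})

    def __getitem__(self, key: GenotypeClass) -> Fraction:
        return self._entries[key]

    def __iter__(self) -> Iterator[GenotypeClass]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def p(self, genotype_class: GenotypeClass) -> Fraction:
        """Probability of a class (0 if outside the support)."""
        return self._entries.get(genotype_class, ZERO)

    def support(self) -> frozenset[GenotypeClass]:
        return frozenset(self._entries)

    def __repr__(self) -> str:
        inner = ", ".join(f"{cls}: {p}" for cls, p in self._entries.items())
        return f"GenotypeDistribution({{{inner}}})"


# ---------------------------------------------------------------------------
# Operations


def phenotype_of(g: GenotypeLike) -> PhenotypeClass:
    """Visible marker set of a genotype: union over all alleles at all loci.

    Invariant under maternal/paternal swap at every locus, hence well
    defined on unordered classes too.
    """
    markers: set[Marker] = set()
    for locus, pair in g.entries:
        for allele in pair:
            markers |= visible_markers(allele, locus)
    return PhenotypeClass(frozenset(markers))


def classify_zygosity(g: GenotypeLike, locus: TransgeneLocus) -> Zygosity:
    """Zygosity at one locus, as defined by visible marker content."""
    pair = None
    for loc, p in g.entries:
        if loc == locus:
            pair = p
            break
    if pair is None:
        raise ConfigurationError(f"locus {locus.id!r} not in genotype")
    bearing = [a for a in pair if a.bears_transgene]
    if not bearing:
        return Zygosity.WILDTYPE
    if len(bearing) == 1:
        return Zygosity.HEMIZYGOUS
    sets = {visible_markers(a, locus) for a in bearing}
    return Zygosity.HOMOZYGOUS if len(sets) == 1 else Zygosity.HETEROZYGOUS


def cre_resolve(
    allele: Allele,
    locus: TransgeneLocus,
    efficiency: Fraction | int | str = ONE,
) -> dict[Allele, Fraction]:
    """Outcome distribution of Cre acting on one transmitted allele.

    A dual cassette is resolved with probability ``efficiency``, the two
    single-marker outcomes being equally likely (both Lox pairs assumed
    equally reactive); single and wildtype alleles pass through unchanged.
    """
    eff = Fraction(efficiency)
    if not 0 <= eff <= 1:
        raise ValueError(f"efficiency must lie in [0, 1], got {eff}")
    if allele.state != "dual":
        return {allele: ONE}
    if len(locus.marker_pair) != 2:
        raise ConfigurationError(
            f"dual allele at single-marker locus {locus.id!r}"
        )
    m1, m2 = locus.marker_pair
    out: dict[Allele, Fraction] = {}
    if eff < 1:
        out[DUAL] = 1 - eff
    if eff > 0:
        out[single(m1)] = eff / 2
        out[single(m2)] = eff / 2
    return out


def gametes(g: Genotype) -> dict[Haplotype, Fraction]:
    """Exact gamete distribution: Mendel's first law per locus, free
    recombination across loci (all loci unlinked)."""
    per_locus: list[list[tuple[TransgeneLocus, Allele, Fraction]]] = []
    for locus, (mat, pat) in g.entries:
        if mat == pat:
            per_locus.append([(locus, mat, ONE)])
        else:
            per_locus.append([(locus, mat, HALF), (locus, pat, HALF)])
    out: dict[Haplotype, Fraction] = {}
    for combo in itertools.product(*per_locus):
        hap = Haplotype(tuple((locus, allele) for locus, allele, _ in combo))
        prob = ONE
        for _, _, p in combo:
            prob *= p
        out[hap] = out.get(hap, ZERO) + prob
    return out


def resolve_gametes(
    haplotype_dist: Mapping[Haplotype, Fraction],
    efficiency: Fraction | int | str = ONE,
) -> dict[Haplotype, Fraction]:
    """Apply germline Cre resolution to every dual allele in a gamete pool."""
    out: dict[Haplotype, Fraction] = {}
    for hap, prob in haplotype_dist.items():
        options = [
            [(locus, a, p) for a, p in cre_resolve(allele, locus, efficiency).items()]
            for locus, allele in hap.entries
        ]
        for combo in itertools.product(*options):
            new_hap = Haplotype(tuple((locus, a) for locus, a, _ in combo))
            p = prob
            for _, _, q in combo:
                p *= q
            out[new_hap] = out.get(new_hap, ZERO) + p
    return out


def cross(
    parent_a: Genotype,
    parent_b: Genotype,
    *,
    cre_efficiency: Fraction | int | str | None = None,
) -> GenotypeDistribution:
    """Exact progeny distribution of a cross, collapsed to unordered classes.

    The product of the two parental gamete distributions; when
    ``cre_efficiency`` is given, germline Cre resolution is applied to the
    gametes of both parents before they combine (a parent carrying no dual
    cassette is unaffected).  Symmetric in parent order after collapse.
    """
    if set(parent_a.loci()) != set(parent_b.loci()):
        raise ConfigurationError(
            "parents must share the same locus set: "
            f"{[l.id for l in parent_a.loci()]} vs {[l.id for l in parent_b.loci()]}"
        )
    ga = gametes(parent_a)
    gb = gametes(parent_b)
    if cre_efficiency is not None:
        ga = resolve_gametes(ga, cre_efficiency)
        gb = resolve_gametes(gb, cre_efficiency)
    acc: dict[GenotypeClass, Fraction] = {}
    for (ha, pa), (hb, pb) in itertools.product(ga.items(), gb.items()):
        child = Genotype(
            tuple(
                (locus, (ha.allele(locus), hb.allele(locus)))
                for locus, _ in parent_a.entries
            )
        )
        cls = child.to_class()
        acc[cls] = acc.get(cls, ZERO) + pa * pb
    return GenotypeDistribution(acc)


def count_genotype_classes(dist: GenotypeDistribution) -> int:
    """Number of genotype classes with positive probability."""
    return len(dist)


def enumerate_genotype_classes(
    loci: Sequence[TransgeneLocus],
    include_dual: bool = False,
) -> list[GenotypeClass]:
    """All unordered genotype classes over a locus set.

    Per locus the allele universe is wildtype plus each single-marker
    resolved state (plus the dual cassette if requested); classes are the
    unordered pairs with repetition, combined across loci.
    """
    per_locus: list[list[tuple[TransgeneLocus, tuple[Allele, Allele]]]] = []
    for locus in sorted(loci, key=lambda l: l.id):
        alleles = [WILDTYPE_ALLELE] + [single(m) for m in locus.marker_pair]
        if include_dual and len(locus.marker_pair) == 2:
            alleles.append(DUAL)
        pairs = [
            tuple(sorted(p, key=_allele_key))
            for p in itertools.combinations_with_replacement(alleles, 2)
        ]
        per_locus.append([(locus, pair) for pair in pairs])
    return [GenotypeClass(tuple(combo)) for combo in itertools.product(*per_locus)]
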