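"""Table and config I/O: scoring-table TSV, scheme YAML, ratio specs."""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path
from typing import Mapping, Union

import pandas as pd
import yaml

from .genetics import PhenotypeClass
from .schemes import MatingScheme, scheme_from_dict
from .simulate import _COLUMNS, ScoringTable


def read_scoring_table(path: Union[str, Path]) -> ScoringTable:
    """Read and validate a scoring-table TSV.

    Canonicalizes phenotype strings (``mCe+mO`` becomes ``mO+mCe``);
    rejects unknown marker tokens, negative counts and duplicate
    (vial, phenotype) rows.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"vial_id": str, "cross_id": str,
                                               "generation": str, "phenotype": str})
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"scoring table {path}: missing columns {missing}")
    return ScoringTable(frame[_COLUMNS])


def write_scoring_table(table: ScoringTable, path: Union[str, Path]) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def load_scheme(path: Union[str, Path]) -> MatingScheme:
    """Load a mating scheme from a YAML config file."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    return scheme_from_dict(config)


def parse_ratio_spec(spec: str) -> dict[PhenotypeClass, Fraction]:
    """Parse ``"mO+mCe=9/16,mO=3/16"`` into phenotype → ratio."""
    out: dict[PhenotypeClass, Fraction] = {}
    for part in spec.split(","):
        pheno_text, _, ratio_text = part.strip().partition("=")
        if not ratio_text:
            raise ValueError(f"ratio spec {part!r}: expected PHENOTYPE=RATIO")
        out[PhenotypeClass.parse(pheno_text)] = Fraction(ratio_text)
    return out


def parse_probability(text: str) -> Fraction:
    """Accept a decimal ("0.0625") or a fraction string ("1/16")."""
    return Fraction(text)
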