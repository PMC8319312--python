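"""Statistical verification of scored progeny ratios.

Replicates the verification used for the published vial tables: per
phenotype class, the per-vial proportions are compared with the
theoretical Mendelian ratio by a one-sample two-tailed Student's t-test
on their arithmetic mean.  Ratios are plain proportions (no variance
stabilizing transform) and no multiple-testing correction is applied by
default; an optional Bonferroni flag is provided as an extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence, Union

import pandas as pd
from scipy import stats as sps

from .genetics import PhenotypeClass
from .simulate import ScoringTable


@dataclass(frozen=True)
class RatioTestResult:
    phenotype: PhenotypeClass | None
    theoretical_ratio: Fraction
    vial_ratios: tuple[Fraction, ...]
    mean_ratio: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    significant: bool
    alpha: float
    degenerate_variance: bool = False


def vial_ratios(
    table: ScoringTable,
    phenotype: Union[PhenotypeClass, str],
) -> list[Fraction]:
    """Per-vial count/total proportions for one phenotype, in vial order."""
    pheno_str = str(
        phenotype
        if isinstance(phenotype, PhenotypeClass)
        else PhenotypeClass.parse(phenotype)
    )
    totals = table.vial_totals()
    ratios = []
    for vial in table.vial_ids():
        total = int(totals[vial])
        if total == 0:
            raise ValueError(f"vial {vial!r} has zero scored progeny")
        sub = table.frame
        mask = (sub["vial_id"] == vial) & (sub["phenotype"] == pheno_str)
        count = int(sub.loc[mask, "count"].sum())
        ratios.append(Fraction(count, total))
    return ratios


def mendelian_ttest(
    ratios: Sequence[Union[Fraction, float]],
    theoretical: Union[Fraction, str, float],
    alpha: float = 0.05,
    phenotype: PhenotypeClass | None = None,
) -> RatioTestResult:
    """One-sample two-tailed t-test of per-vial ratios against a Mendelian
    ratio.

    t = (mean − theoretical) / (s / √n) with n−1 degrees of freedom.
    Degenerate zero-variance samples follow a fixed contract: t = 0 and
    p = 1 when the mean equals the theoretical ratio exactly, otherwise
    the difference is reported as significant with p = 0 and flagged.
    """
    if len(ratios) < 2:
        raise ValueError("need at least two vial ratios for a t-test")
    exact = tuple(Fraction(r) for r in ratios)
    theo = Fraction(theoretical)
    values = [float(r) for r in exact]
    n = len(values)
    mean = sum(exact, Fraction(0)) / n
    var = sum(((r - mean) ** 2 for r in exact), Fraction(0)) / (n - 1)
    degenerate = var == 0
    if degenerate:
        if mean == theo:
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat = math.inf if mean > theo else -math.inf
            p_value = 0.0
    else:
        se = math.sqrt(float(var)) / math.sqrt(n)
        t_stat = (float(mean) - float(theo)) / se
        p_value = 2.0 * float(sps.t.sf(abs(t_stat), n - 1))
    return RatioTestResult(
        phenotype=phenotype,
        theoretical_ratio=theo,
        vial_ratios=exact,
        mean_ratio=float(mean),
        t_statistic=t_stat,
        degrees_of_freedom=n - 1,
        p_value=p_value,
        significant=p_value < alpha,
        alpha=alpha,
        degenerate_variance=degenerate,
    )


def verify_table(
    table: ScoringTable,
    expectations: Mapping[Union[PhenotypeClass, str], Union[Fraction, str]],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[RatioTestResult]:
    """Run the per-phenotype ratio t-test for every expected class.

    ``bonferroni`` divides alpha by the number of tested classes (off by
    default, matching the published analysis)."""
    level = alpha / len(expectations) if bonferroni else alpha
    results = []
    for pheno, theo in expectations.items():
        pheno_cls = (
            pheno if isinstance(pheno, PhenotypeClass) else PhenotypeClass.parse(pheno)
        )
        ratios = vial_ratios(table, pheno_cls)
        results.append(
            mendelian_ttest(
                ratios, Fraction(theo), alpha=level, phenotype=pheno_cls
            )
        )
    return results


def results_frame(results: Sequence[RatioTestResult]) -> pd.DataFrame:
    rows = [
        {
            "phenotype": str(r.phenotype) if r.phenotype is not None else "",
            "theoretical_ratio": str(r.theoretical_ratio),
            "mean_ratio": round(r.mean_ratio, 6),
            "t_statistic": round(r.t_statistic, 6) if math.isfinite(r.t_statistic) else r.t_statistic,
            "df": r.degrees_of_freedom,
            "p_value": round(r.p_value, 6),
            "significant": r.significant,
            "degenerate_variance": r.degenerate_variance,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
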