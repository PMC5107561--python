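"""Segregation, penetrance, prediction and bolting-rate statistics.

Covers the single-locus genetics of an F2 mapped with a codominant marker:
the 1:2:1 segregation test, phenotype prediction from genotype under a
dominant/recessive model, exact-binomial penetrance estimation, per-family
bolting-rate summaries for F3 progeny grouped by parental genotype, and
pairwise Pearson chi-square comparisons of bolting rates between treatment
groups with multiple-testing adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

HOM_RECESSIVE = "hom_recessive"
HET = "het"
HOM_DOMINANT = "hom_dominant"
GENOTYPE_CLASSES = (HOM_RECESSIVE, HET, HOM_DOMINANT)


@dataclass(frozen=True)
class GenotypeCounts:
    n_hom_dominant: int
    n_het: int
    n_hom_recessive: int

    def __post_init__(self) -> None:
        if min(self.n_hom_dominant, self.n_het, self.n_hom_recessive) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.total < 1:
            raise ValueError("at least one plant required")

    @property
    def total(self) -> int:
        return self.n_hom_dominant + self.n_het + self.n_hom_recessive


@dataclass(frozen=True)
class PhenotypeByGenotype:
    """(n_resistant, n_bolting) per genotype class."""

    hom_recessive: tuple[int, int]
    het: tuple[int, int]
    hom_dominant: tuple[int, int]


@dataclass(frozen=True)
class SegTestResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class FamilyRecord:
    family_id: str
    parent_genotype: str  # one of GENOTYPE_CLASSES
    n_bolting: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_bolting <= self.n_total:
            raise ValueError("need 0 <= n_bolting <= n_total")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")

    @property
    def bolting_rate(self) -> float:
        return self.n_bolting / self.n_total


@dataclass(frozen=True)
class GroupRate:
    mean: float
    sd: float | None  # None when n == 1
    n: int


@dataclass(frozen=True)
class PenetranceEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    ci_level: float


def chi_square_upper_tail(statistic: float, df: int) -> float:
    """P(X >= statistic) for a chi-square variable via the regularized
    upper incomplete gamma function Q(df/2, x/2)."""
    if statistic < 0:
        raise ValueError("statistic must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(special.gammaincc(df / 2, statistic / 2))


def chi_square_ratio(
    observed: Sequence[int], ratio_weights: Sequence[float]
) -> SegTestResult:
    """Goodness-of-fit of observed class counts to a Mendelian ratio.

    Expected counts are total x w_i / sum(w); invariant under rescaling the
    weights. E.g. genotype counts (95, 201, 114) against 1:2:1 give
    X^2 = 1.917 on 2 df.
    """
    obs = np.asarray(observed, dtype=float)
    w = np.asarray(ratio_weights, dtype=float)
    if obs.shape != w.shape:
        raise ValueError("observed and ratio_weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("ratio weights must be positive")
    total = obs.sum()
    if total < 1:
        raise ValueError("total observed must be >= 1")
    expected = total * w / w.sum()
    if np.any(expected == 0):
        raise ValueError("an expected count is zero")
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    return SegTestResult(statistic, df, chi_square_upper_tail(statistic, df))


def prediction_accuracy(counts: GenotypeCounts, pheno: PhenotypeByGenotype) -> float:
    """Fraction of plants whose phenotype the recessive model predicts.

    Rule: recessive homozygote -> resistant, any dominant-allele carrier ->
    bolting. Accuracy = (resistant among hom-recessive + bolting among the
    other two classes) / total.
    """
    table = {
        HOM_RECESSIVE: pheno.hom_recessive,
        HET: pheno.het,
        HOM_DOMINANT: pheno.hom_dominant,
    }
    totals = {
        HOM_RECESSIVE: counts.n_hom_recessive,
        HET: counts.n_het,
        HOM_DOMINANT: counts.n_hom_dominant,
    }
    for cls, (res, bolt) in table.items():
        if res + bolt != totals[cls]:
            raise ValueError(f"phenotype totals for {cls} do not match genotype counts")
    correct = (
        table[HOM_RECESSIVE][0] + table[HET][1] + table[HOM_DOMINANT][1]
    )
    return correct / counts.total


def penetrance_estimate(
    n_resistant: int, n_hom_recessive: int, ci_level: float = 0.95
) -> PenetranceEstimate:
    """Penetrance of resistance among recessive homozygotes, with an exact
    Clopper-Pearson binomial confidence interval."""
    if n_hom_recessive < 1:
        raise ValueError("n_hom_recessive must be >= 1")
    if not 0 <= n_resistant <= n_hom_recessive:
        raise ValueError("need 0 <= n_resistant <= n_hom_recessive")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0,1)")
    k, n = n_resistant, n_hom_recessive
    alpha = 1 - ci_level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return PenetranceEstimate(k / n, low, high, ci_level)


def family_rates(families: Sequence[FamilyRecord]) -> dict[str, GroupRate]:
    """Per parental-genotype group: unweighted mean, sample SD and count of
    family bolting rates. Groups without families are omitted with a
    warning; SD is None for singleton groups."""
    out: dict[str, GroupRate] = {}
    for cls in GENOTYPE_CLASSES:
        rates = [f.bolting_rate for f in families if f.parent_genotype == cls]
        if not rates:
            warnings.warn(f"no families with parent genotype {cls}; group omitted")
            continue
        arr = np.asarray(rates)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
        out[cls] = GroupRate(float(arr.mean()), sd, len(arr))
    return out


@dataclass(frozen=True)
class PairwiseComparison:
    i: int
    j: int
    statistic: float
    p_raw: float
    p_adjusted: float


_ADJUST = {"holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh"}


def compare_rates(
    groups: Sequence[tuple[int, int]],
    adjust: Literal["holm", "bonferroni", "bh"] = "holm",
    continuity: bool = False,
) -> list[PairwiseComparison]:
    """All pairwise 2x2 Pearson chi-square tests of bolting counts.

    Each group is (n_bolting, n_total). Continuity correction is off by
    default. p-values are adjusted across the pairs with the chosen method.
    """
    if adjust not in _ADJUST:
        raise ValueError(f"unknown adjustment {adjust!r}")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for b, n in groups:
        if n < 1:
            raise ValueError("every group needs n_total >= 1")
        if not 0 <= b <= n:
            raise ValueError("need 0 <= n_bolting <= n_total")
    pairs: list[tuple[int, int]] = [
        (i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))
    ]
    stats_p: list[tuple[float, float]] = []
    for i, j in pairs:
        b1, n1 = groups[i]
        b2, n2 = groups[j]
        table = np.array([[b1, n1 - b1], [b2, n2 - b2]])
        if table.sum(axis=0).min() == 0:
            # a phenotype class absent from both groups: proportions equal
            stats_p.append((0.0, 1.0))
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
        stats_p.append((float(chi2), float(p)))
    _, p_adj, _, _ = multipletests([p for _, p in stats_p], method=_ADJUST[adjust])
    return [
        PairwiseComparison(i, j, s, p, float(pa))
        for (i, j), (s, p), pa in zip(pairs, stats_p, p_adj)
    ]
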