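"""Per-pool genotype classification from allele depths, and the candidate filter.

Pooled DNA of many F2 plants is not a diploid sample, so genotype states are
assigned from the pooled alternate-allele frequency with a transparent
frequency-band rule: below the band the pool is homozygous-reference, above
it homozygous-alternate, inside it polymorphic (called HET by analogy with a
diploid caller run on pooled reads). A pool below the per-pool depth floor
is NO_CALL and vetoes candidacy.

A site is a *candidate* when the bolting pool is polymorphic (so the site is
a true cross-specific polymorphism, not shared divergence from the reference
assembly) while the resistant pool is monomorphic, and joint coverage over
both pools reaches the floor (default 50x).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence


class PoolState(str, Enum):
    HOM_REF = "HOM_REF"
    HOM_ALT = "HOM_ALT"
    HET = "HET"
    NO_CALL = "NO_CALL"


HOMOZYGOUS = (PoolState.HOM_REF, PoolState.HOM_ALT)


class MultiallelicSiteError(ValueError):
    """A site with more than one alternate allele reached the classifier."""


class UnsortedSitesError(ValueError):
    """Site list is not sorted by (scaffold, pos)."""


@dataclass(frozen=True)
class CallConfig:
    """Classifier thresholds.

    ``min_joint_coverage`` is the summed-depth floor over both pools for a
    site to be considered at all (default 50). ``min_pool_depth`` is the
    per-pool floor below which the pool is NO_CALL. ``het_band`` is the open
    alt-frequency interval called polymorphic.
    """

    min_joint_coverage: int = 50
    min_pool_depth: int = 10
    het_band: tuple[float, float] = (0.15, 0.85)

    def __post_init__(self) -> None:
        low, high = self.het_band
        if not 0 < low < high < 1:
            raise ValueError("het_band must satisfy 0 < low < high < 1")
        if self.min_joint_coverage < 0 or self.min_pool_depth < 0:
            raise ValueError("coverage thresholds must be non-negative")


@dataclass(frozen=True)
class PoolCall:
    state: PoolState
    alt_frequency: float | None
    depth: int


@dataclass(frozen=True)
class PooledSite:
    """One variant position with allele depths in both pools."""

    scaffold: str
    pos: int
    ref_allele: str
    alt_allele: str
    br_ref: int
    br_alt: int
    b_ref: int
    b_alt: int

    def __post_init__(self) -> None:
        if min(self.br_ref, self.br_alt, self.b_ref, self.b_alt) < 0:
            raise ValueError(f"negative allele depth at {self.scaffold}:{self.pos}")


@dataclass(frozen=True)
class SiteCalls:
    """A site with both pool calls and its candidate flag."""

    site: PooledSite
    br: PoolCall
    b: PoolCall
    candidate: bool


def classify_pool(ref_count: int, alt_count: int, config: CallConfig | None = None) -> PoolCall:
    """Classify one pool at one site from its ref/alt depths."""
    config = config or CallConfig()
    if ref_count < 0 or alt_count < 0:
        raise ValueError("allele counts must be non-negative")
    depth = ref_count + alt_count
    if depth == 0:
        return PoolCall(PoolState.NO_CALL, None, 0)
    q = alt_count / depth
    if depth < config.min_pool_depth:
        return PoolCall(PoolState.NO_CALL, q, depth)
    low, high = config.het_band
    if q < low:
        state = PoolState.HOM_REF
    elif q > high:
        state = PoolState.HOM_ALT
    else:
        state = PoolState.HET
    return PoolCall(state, q, depth)


def _check_sorted(sites: Sequence[PooledSite]) -> None:
    for a, b in zip(sites, sites[1:]):
        if (a.scaffold, a.pos) >= (b.scaffold, b.pos):
            raise UnsortedSitesError(
                f"sites not sorted by (scaffold, pos) near {b.scaffold}:{b.pos}"
            )


def filter_candidates(
    sites: Sequence[PooledSite], config: CallConfig | None = None
) -> list[SiteCalls]:
    """Call both pools at every site and flag candidates.

    Candidate: joint depth over both pools >= min_joint_coverage, the
    bolting pool called HET, and the resistant pool called homozygous
    (either direction). Every site is returned with its calls — the flag is
    not a projection — so downstream scans can use b-HET sites as the
    denominator.
    """
    config = config or CallConfig()
    _check_sorted(sites)
    out: list[SiteCalls] = []
    for s in sites:
        br = classify_pool(s.br_ref, s.br_alt, config)
        b = classify_pool(s.b_ref, s.b_alt, config)
        joint = br.depth + b.depth
        cand = (
            joint >= config.min_joint_coverage
            and b.state is PoolState.HET
            and br.state in HOMOZYGOUS
        )
        out.append(SiteCalls(s, br, b, cand))
    return out
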