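"""Sliding-window scan and contiguous monomorphic-region detection.

The localisation statistic is, per window, the number of sites monomorphic
in the resistant pool out of the sites polymorphic in the bolting pool
(default 200 kb windows, 100 kb step). Around a recessive causal locus the
resistant pool — all recessive homozygotes — is monomorphic across the
linked block, so the statistic peaks there; elsewhere both pools are
polymorphic and the count stays low.

Region detection then finds, per scaffold, maximal runs of consecutive
bolting-pool-polymorphic sites that are all monomorphic in the resistant
pool. The run's outermost supporting sites delimit the mapped interval
(1-based inclusive; length = end - start + 1); the nearest non-monomorphic
site on each side bounds the recombination uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .poolcalls import HOMOZYGOUS, PoolState, SiteCalls


@dataclass(frozen=True)
class ScanConfig:
    window_bp: int = 200_000
    step_bp: int = 100_000
    min_region_sites: int = 20
    region_frequency_mode: str = "by_call"  # or "exact"

    def __post_init__(self) -> None:
        if self.window_bp < 1 or self.step_bp < 1:
            raise ValueError("window_bp and step_bp must be positive")
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must not exceed window_bp")
        if self.min_region_sites < 1:
            raise ValueError("min_region_sites must be >= 1")
        if self.region_frequency_mode not in ("by_call", "exact"):
            raise ValueError("region_frequency_mode must be 'by_call' or 'exact'")


@dataclass(frozen=True)
class WindowScore:
    scaffold: str
    start: int
    end: int
    n_monomorphic_br: int
    n_polymorphic_b: int


@dataclass(frozen=True)
class MonomorphicRegion:
    """Maximal run of resistant-pool-monomorphic sites; 1-based inclusive."""

    scaffold: str
    start: int
    end: int
    n_sites: int
    flank_left: int | None  # nearest non-monomorphic b-polymorphic site, or None at scaffold edge
    flank_right: int | None

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PeakResult:
    best: WindowScore
    tied: tuple[WindowScore, ...]


def make_windows(scaffold_length: int, config: ScanConfig | None = None) -> list[tuple[int, int]]:
    """Window starts at 1, 1+step, ...; ends truncated at the scaffold end."""
    config = config or ScanConfig()
    if scaffold_length < 1:
        raise ValueError("scaffold_length must be >= 1")
    windows = []
    start = 1
    while start <= scaffold_length:
        windows.append((start, min(start + config.window_bp - 1, scaffold_length)))
        start += config.step_bp
    return windows


def _is_monomorphic(sc: SiteCalls, mode: str) -> bool:
    if mode == "exact":
        return sc.br.alt_frequency in (0.0, 1.0)
    return sc.candidate


def score_windows(
    calls: Sequence[SiteCalls],
    scaffold_lengths: Mapping[str, int],
    config: ScanConfig | None = None,
) -> list[WindowScore]:
    """Count, per window, candidate sites out of bolting-pool-HET sites."""
    config = config or ScanConfig()
    by_scaffold: dict[str, list[SiteCalls]] = {}
    for c in calls:
        by_scaffold.setdefault(c.site.scaffold, []).append(c)
    scores: list[WindowScore] = []
    for scaffold in sorted(scaffold_lengths):
        here = [c for c in by_scaffold.get(scaffold, []) if c.b.state is PoolState.HET]
        for start, end in make_windows(scaffold_lengths[scaffold], config):
            inside = [c for c in here if start <= c.site.pos <= end]
            n_mono = sum(1 for c in inside if c.candidate)
            scores.append(WindowScore(scaffold, start, end, n_mono, len(inside)))
    return scores


def find_peak(scores: Sequence[WindowScore]) -> PeakResult:
    """Window with the maximal monomorphic count; ties broken by (scaffold, start)."""
    if not scores:
        raise ValueError("no window scores given")
    best_count = max(s.n_monomorphic_br for s in scores)
    tied = sorted(
        (s for s in scores if s.n_monomorphic_br == best_count),
        key=lambda s: (s.scaffold, s.start),
    )
    return PeakResult(best=tied[0], tied=tuple(tied))


def allele_frequency_track(calls: Sequence[SiteCalls]) -> list[tuple[str, int, float]]:
    """Resistant-pool alt frequency at every bolting-pool-HET site.

    This is the per-site track whose runs of exactly 0 and 1 delimit the
    mapped interval when plotted.
    """
    return [
        (c.site.scaffold, c.site.pos, float(c.br.alt_frequency))
        for c in calls
        if c.b.state is PoolState.HET and c.br.alt_frequency is not None
    ]


def find_monomorphic_regions(
    calls: Sequence[SiteCalls], config: ScanConfig | None = None
) -> list[MonomorphicRegion]:
    """Maximal runs of resistant-pool-monomorphic sites, longest first.

    Only bolting-pool-HET sites with a resistant-pool call participate. In
    ``by_call`` mode a site supports a region iff it is a candidate; in
    ``exact`` mode iff its resistant-pool alt frequency is exactly 0 or 1.
    Runs shorter than ``min_region_sites`` are dropped.
    """
    config = config or ScanConfig()
    by_scaffold: dict[str, list[SiteCalls]] = {}
    for c in calls:
        if c.b.state is PoolState.HET and c.br.state is not PoolState.NO_CALL:
            by_scaffold.setdefault(c.site.scaffold, []).append(c)
    regions: list[MonomorphicRegion] = []
    for scaffold, here in by_scaffold.items():
        here.sort(key=lambda c: c.site.pos)
        mono = [_is_monomorphic(c, config.region_frequency_mode) for c in here]
        i = 0
        while i < len(here):
            if not mono[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(here) and mono[j + 1]:
                j += 1
            if j - i + 1 >= config.min_region_sites:
                regions.append(
                    MonomorphicRegion(
                        scaffold=scaffold,
                        start=here[i].site.pos,
                        end=here[j].site.pos,
                        n_sites=j - i + 1,
                        flank_left=here[i - 1].site.pos if i > 0 else None,
                        flank_right=here[j + 1].site.pos if j + 1 < len(here) else None,
                    )
                )
            i = j + 1
    regions.sort(key=lambda r: (-r.length_bp, r.scaffold, r.start))
    return regions
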