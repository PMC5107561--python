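"""Codominant marker analysis around a focal locus.

Given an ordered panel of codominant markers genotyped A/H/B (A = homozygous
for the resistant-parent allele, B = homozygous for the bolting-parent
allele, H = heterozygous), this module verifies the genotype of each plant
at a focal marker, detects crossover breakpoints as transitions between
adjacent non-missing marker genotypes, and reports the breakpoints nearest
the focal marker on each side — the resolution bound the recombinants
impose on the mapped interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

GENOTYPES = ("A", "H", "B")


@dataclass(frozen=True)
class Marker:
    name: str
    scaffold: str
    pos: int


@dataclass
class MarkerMatrix:
    markers: list[Marker]
    plants: list[tuple[str, list[str | None]]]  # (plant_id, genotypes); None = missing

    def __post_init__(self) -> None:
        order = [(m.scaffold, m.pos) for m in self.markers]
        if order != sorted(order):
            raise ValueError("markers must be sorted by (scaffold, pos)")
        for pid, genos in self.plants:
            if len(genos) != len(self.markers):
                raise ValueError(f"plant {pid}: genotype list length != marker count")
            for g in genos:
                if g is not None and g not in GENOTYPES:
                    raise ValueError(f"plant {pid}: invalid genotype {g!r}")

    def marker_index(self, name: str) -> int:
        for i, m in enumerate(self.markers):
            if m.name == name:
                return i
        raise KeyError(f"unknown marker {name!r}")


@dataclass(frozen=True)
class Breakpoint:
    plant_id: str
    left_marker: str
    right_marker: str
    interval: tuple[int, int]
    transition: tuple[str, str]


@dataclass(frozen=True)
class LocusVerification:
    per_plant: dict[str, bool]
    missing: tuple[str, ...]
    n_match: int
    n_total: int


def verify_locus_genotype(
    matrix: MarkerMatrix, focal_marker: str, expected: str
) -> LocusVerification:
    """Per-plant check that the focal-marker genotype equals ``expected``.

    Plants with a missing call at the focal marker count as non-matching and
    are listed separately.
    """
    if expected not in GENOTYPES:
        raise ValueError(f"expected genotype must be one of {GENOTYPES}")
    idx = matrix.marker_index(focal_marker)
    per_plant: dict[str, bool] = {}
    missing: list[str] = []
    for pid, genos in matrix.plants:
        g = genos[idx]
        if g is None:
            per_plant[pid] = False
            missing.append(pid)
        else:
            per_plant[pid] = g == expected
    return LocusVerification(
        per_plant=per_plant,
        missing=tuple(missing),
        n_match=sum(per_plant.values()),
        n_total=len(matrix.plants),
    )


def detect_breakpoints(matrix: MarkerMatrix) -> list[Breakpoint]:
    """One breakpoint per plant per adjacent-marker pair with differing
    genotypes; missing calls are skipped over, widening the interval to the
    nearest non-missing flanking markers. Adjacency never spans scaffolds.
    """
    if len(matrix.markers) < 2:
        raise ValueError("need at least two markers")
    out: list[Breakpoint] = []
    for pid, genos in matrix.plants:
        prev_idx: int | None = None
        for i, g in enumerate(genos):
            if g is None:
                continue
            if prev_idx is not None:
                left, right = matrix.markers[prev_idx], matrix.markers[i]
                if left.scaffold == right.scaffold and genos[prev_idx] != g:
                    out.append(
                        Breakpoint(
                            plant_id=pid,
                            left_marker=left.name,
                            right_marker=right.name,
                            interval=(left.pos, right.pos),
                            transition=(genos[prev_idx], g),
                        )
                    )
            prev_idx = i
    return out


@dataclass(frozen=True)
class FlankResult:
    nearest_left: Breakpoint | None  # None = open-ended on that side
    nearest_right: Breakpoint | None


def flank_refinement(
    breakpoints: Sequence[Breakpoint], matrix: MarkerMatrix, focal_marker: str
) -> FlankResult:
    """The breakpoint interval closest to the focal marker on each side.

    A breakpoint lies left of the focal marker when its interval ends at or
    before the focal position, right when it starts at or after it. Sides
    with no breakpoint are open-ended.
    """
    focal = matrix.markers[matrix.marker_index(focal_marker)]
    same = [
        bp
        for bp in breakpoints
        if matrix.markers[matrix.marker_index(bp.left_marker)].scaffold == focal.scaffold
    ]
    left = [bp for bp in same if bp.interval[1] <= focal.pos]
    right = [bp for bp in same if bp.interval[0] >= focal.pos]
    nearest_left = max(left, key=lambda bp: bp.interval[1], default=None)
    nearest_right = min(right, key=lambda bp: bp.interval[0], default=None)
    return FlankResult(nearest_left, nearest_right)
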