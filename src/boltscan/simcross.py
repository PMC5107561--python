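"""Synthetic F2 pooled-sequencing data with a recessive, incompletely penetrant locus.

This module generates the kind of dataset a bulked-segregant (BSA-seq)
experiment produces from a biparental cross: a catalog of biallelic sites
segregating between the two parents (plus sites where both parents diverge
identically from the reference assembly), recombinant F2 plants built from
Poisson-crossover gametes, binary phenotypes under incomplete penetrance of
the recessive allele, phenotype-defined DNA pools, and per-pool read depths
at every site.

The default configuration emulates an F2 of 410 plants segregating 1:2:1 at
a single causal locus, where the recessive homozygote expresses resistance
with probability 26/95 and every carrier of the dominant allele bolts. The
resistant pool holds every resistant plant; the bolting pool is a random
sample of 297 bolting plants.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

P_BR = "P_br"  # resistant parent
P_B = "P_b"  # bolting parent
BOTH = "both"  # both parents carry the non-reference allele

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Invalid simulator configuration or state."""


class EmptyResistantPoolError(SimulationError):
    """No resistant plants were produced; pooling cannot proceed."""


@dataclass(frozen=True)
class CrossSimConfig:
    """All parameters of the cross/pooling/sequencing simulator.

    Defaults are the desk-scale study conditions: two 5-Mb scaffolds at one
    polymorphic site per kb, a causal locus in the middle of the first
    scaffold, penetrance 26/95 for resistance among recessive homozygotes,
    410 F2 plants pooled 26-ish/297, pool depths 60x/30x, and a per-base
    miscall rate of 0.005.
    """

    scaffolds: tuple[tuple[str, int], ...] = (("sca01", 5_000_000), ("sca02", 5_000_000))
    snp_density: float = 1e-3
    ref_divergent_fraction: float = 0.3
    causal: tuple[str, int] = ("sca01", 2_500_000)
    penetrance_resistant: float = 26 / 95
    n_f2: int = 410
    n_b_pool: int = 297
    mean_depth_br: float = 60.0
    mean_depth_b: float = 30.0
    error_rate: float = 0.005
    crossover_lambda_per_bp: float = 2e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scaffolds:
            raise SimulationError("at least one scaffold is required")
        lengths = dict(self.scaffolds)
        if len(lengths) != len(self.scaffolds):
            raise SimulationError("scaffold names must be unique")
        for name, length in self.scaffolds:
            if length < 1:
                raise SimulationError(f"scaffold {name} has non-positive length")
        if self.causal[0] not in lengths:
            raise SimulationError(f"causal scaffold {self.causal[0]!r} not in scaffolds")
        if not 1 <= self.causal[1] <= lengths[self.causal[0]]:
            raise SimulationError("causal position outside its scaffold")
        if self.snp_density <= 0:
            raise SimulationError("snp_density must be > 0")
        total = sum(length for _, length in self.scaffolds)
        if self.snp_density * total < 1:
            raise SimulationError("expected site count below 1; raise snp_density")
        if not 0 <= self.ref_divergent_fraction <= 1:
            raise SimulationError("ref_divergent_fraction must be in [0,1]")
        if not 0 <= self.penetrance_resistant <= 1:
            raise SimulationError("penetrance_resistant must be in [0,1]")
        if self.n_f2 < 1 or self.n_b_pool < 1:
            raise SimulationError("n_f2 and n_b_pool must be positive")
        if self.mean_depth_br <= 0 or self.mean_depth_b <= 0:
            raise SimulationError("mean depths must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise SimulationError("error_rate must be in [0, 0.5)")
        if self.crossover_lambda_per_bp < 0:
            raise SimulationError("crossover_lambda_per_bp must be >= 0")

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return dict(self.scaffolds)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scaffolds"] = [list(s) for s in self.scaffolds]
        d["causal"] = list(self.causal)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CrossSimConfig":
        d = dict(d)
        d["scaffolds"] = tuple((str(n), int(l)) for n, l in d["scaffolds"])
        d["causal"] = (str(d["causal"][0]), int(d["causal"][1]))
        # YAML 1.1 reads exponent notation without a decimal point as text
        for key in (
            "snp_density", "ref_divergent_fraction", "penetrance_resistant",
            "mean_depth_br", "mean_depth_b", "error_rate", "crossover_lambda_per_bp",
        ):
            if key in d:
                d[key] = float(d[key])
        for key in ("n_f2", "n_b_pool", "seed"):
            if key in d:
                d[key] = int(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class CatalogSite:
    """One biallelic site.

    ``kind`` is ``cross_specific`` (the parents carry different alleles) or
    ``ref_divergent`` (both parents carry the same non-reference allele).
    ``alt_parent`` names the parent carrying the alternate allele, or
    ``both`` for ref-divergent sites.
    """

    scaffold: str
    pos: int
    kind: str
    ref_allele: str
    alt_allele: str
    alt_parent: str


@dataclass
class SiteCatalog:
    sites: list[CatalogSite]

    def __post_init__(self) -> None:
        prev: tuple[str, int] | None = None
        seen_scaffolds: set[str] = set()
        current: str | None = None
        for s in self.sites:
            if s.ref_allele == s.alt_allele:
                raise SimulationError(f"ref == alt at {s.scaffold}:{s.pos}")
            if current != s.scaffold:
                if s.scaffold in seen_scaffolds:
                    raise SimulationError("catalog not grouped by scaffold")
                seen_scaffolds.add(s.scaffold)
                current = s.scaffold
                prev = None
            if prev is not None and s.pos <= prev[1]:
                raise SimulationError(
                    f"positions not strictly increasing at {s.scaffold}:{s.pos}"
                )
            prev = (s.scaffold, s.pos)

    def __len__(self) -> int:
        return len(self.sites)

    def scaffolds(self) -> list[str]:
        out: list[str] = []
        for s in self.sites:
            if not out or out[-1] != s.scaffold:
                out.append(s.scaffold)
        return out

    def positions(self, scaffold: str) -> np.ndarray:
        return np.array([s.pos for s in self.sites if s.scaffold == scaffold], dtype=np.int64)


@dataclass
class Haplotype:
    """A gamete: per-scaffold parental-origin mosaic.

    ``start_parent[sc]`` is the origin at position 1; origin flips at each
    breakpoint in ``breakpoints[sc]`` (a crossover between position b and
    b+1 is stored as b, so positions > b have the flipped origin).
    """

    start_parent: dict[str, str]
    breakpoints: dict[str, np.ndarray]

    def origin_at(self, scaffold: str, positions: np.ndarray) -> np.ndarray:
        """Boolean array: True where the origin is the resistant parent."""
        flips = np.searchsorted(self.breakpoints[scaffold], positions, side="left")
        start_is_br = self.start_parent[scaffold] == P_BR
        return (flips % 2 == 0) == start_is_br

    def origin_segments(self, scaffold: str, length: int) -> list[tuple[int, int, str]]:
        """1-based inclusive segments tiling [1, length], parents alternating."""
        parents = (P_BR, P_B) if self.start_parent[scaffold] == P_BR else (P_B, P_BR)
        bps = [int(b) for b in self.breakpoints[scaffold] if b < length]
        bounds = [0] + bps + [length]
        return [
            (bounds[i] + 1, bounds[i + 1], parents[i % 2])
            for i in range(len(bounds) - 1)
            if bounds[i] + 1 <= bounds[i + 1]
        ]


@dataclass
class F2Plant:
    id: str
    hap1: Haplotype
    hap2: Haplotype
    causal_genotype: str  # BRBR / BRbr / brbr
    phenotype: str  # resistant / bolting


def simulate_catalog(config: CrossSimConfig, rng: np.random.Generator) -> SiteCatalog:
    """Draw the polymorphic-site catalog.

    Site counts are Poisson(snp_density x length) per scaffold; a fraction
    ``ref_divergent_fraction`` of sites carries the alternate allele on both
    parental haplotypes (divergence from the reference assembly shared by
    the parents). The causal position is always included as a
    cross-specific site.
    """
    causal_sc, causal_pos = config.causal
    sites: list[CatalogSite] = []
    for name, length in config.scaffolds:
        n = int(rng.poisson(config.snp_density * length))
        n = min(n, length)
        # collisions are negligible at desk densities; draw with margin then dedupe
        draw = rng.integers(1, length + 1, size=n + max(16, n // 10))
        pos = np.unique(draw)[:n]
        if name == causal_sc and causal_pos not in pos:
            pos = np.unique(np.append(pos, causal_pos))
        for p in pos.tolist():
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            if name == causal_sc and p == causal_pos:
                kind, alt_parent = "cross_specific", P_BR
            elif rng.random() < config.ref_divergent_fraction:
                kind, alt_parent = "ref_divergent", BOTH
            else:
                kind = "cross_specific"
                alt_parent = P_BR if rng.random() < 0.5 else P_B
            sites.append(CatalogSite(name, int(p), kind, str(ref), str(alt), alt_parent))
    return SiteCatalog(sites)


def _random_gamete(config: CrossSimConfig, rng: np.random.Generator) -> Haplotype:
    start: dict[str, str] = {}
    bps: dict[str, np.ndarray] = {}
    for name, length in config.scaffolds:
        k = int(rng.poisson(config.crossover_lambda_per_bp * length))
        bps[name] = np.sort(rng.integers(1, length, size=k)) if k else np.empty(0, dtype=np.int64)
        start[name] = P_BR if rng.random() < 0.5 else P_B
    return Haplotype(start, bps)


def simulate_f2(
    config: CrossSimConfig, catalog: SiteCatalog, rng: np.random.Generator
) -> list[F2Plant]:
    """Build the F2: two independent recombinant gametes per plant.

    Phenotype rule: a plant is resistant with probability
    ``penetrance_resistant`` iff it is homozygous for the resistant-parent
    allele at the causal position; every other plant bolts.
    """
    if len(catalog) == 0:
        raise SimulationError("catalog is empty")
    causal_sc, causal_pos = config.causal
    cp = np.array([causal_pos])
    plants: list[F2Plant] = []
    for i in range(config.n_f2):
        hap1 = _random_gamete(config, rng)
        hap2 = _random_gamete(config, rng)
        br1 = bool(hap1.origin_at(causal_sc, cp)[0])
        br2 = bool(hap2.origin_at(causal_sc, cp)[0])
        if br1 and br2:
            genotype = "brbr"
        elif br1 or br2:
            genotype = "BRbr"
        else:
            genotype = "BRBR"
        resistant = genotype == "brbr" and rng.random() < config.penetrance_resistant
        plants.append(
            F2Plant(
                id=f"F2_{i + 1:04d}",
                hap1=hap1,
                hap2=hap2,
                causal_genotype=genotype,
                phenotype="resistant" if resistant else "bolting",
            )
        )
    return plants


def make_pools(
    plants: Sequence[F2Plant], n_b_pool: int, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Pool by phenotype: every resistant plant vs a random bolting sample."""
    br_ids = [p.id for p in plants if p.phenotype == "resistant"]
    bolting = [p.id for p in plants if p.phenotype == "bolting"]
    if not br_ids:
        raise EmptyResistantPoolError(
            "no resistant plants in the F2; the resistant pool is empty"
        )
    if n_b_pool > len(bolting):
        raise SimulationError(
            f"n_b_pool={n_b_pool} exceeds the {len(bolting)} bolting plants"
        )
    idx = rng.choice(len(bolting), size=n_b_pool, replace=False)
    b_ids = [bolting[i] for i in sorted(idx.tolist())]
    return br_ids, b_ids


def alt_dosage_matrix(plants: Sequence[F2Plant], catalog: SiteCatalog) -> np.ndarray:
    """Per-plant alternate-allele dosage (0/1/2) at every catalog site."""
    n_sites = len(catalog)
    dosage = np.zeros((len(plants), n_sites), dtype=np.int8)
    offset = 0
    for sc in catalog.scaffolds():
        pos = catalog.positions(sc)
        seg = [s for s in catalog.sites if s.scaffold == sc]
        alt_is_br = np.array([s.alt_parent == P_BR for s in seg])
        alt_is_both = np.array([s.alt_parent == BOTH for s in seg])
        for i, plant in enumerate(plants):
            d = np.zeros(len(pos), dtype=np.int8)
            for hap in (plant.hap1, plant.hap2):
                is_br = hap.origin_at(sc, pos)
                d += np.where(alt_is_both, 1, np.where(alt_is_br == is_br, 1, 0)).astype(np.int8)
            dosage[i, offset : offset + len(pos)] = d
        offset += len(pos)
    return dosage


def true_pool_alt_frequency(dosage: np.ndarray) -> np.ndarray:
    """Pool alternate-allele frequency from the member dosage rows."""
    return dosage.sum(axis=0) / (2 * dosage.shape[0])


def sample_pool_reads(
    true_alt_freq: np.ndarray,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequence a pool: Poisson depths, binomial alt counts with miscalls.

    The observed alt probability at a site with true frequency f is
    f(1-e) + (1-f)e for per-base miscall rate e (miscalls flip ref<->alt).
    """
    f = np.asarray(true_alt_freq, dtype=float)
    depth = rng.poisson(mean_depth, size=f.shape)
    p = f * (1 - error_rate) + (1 - f) * error_rate
    alt = rng.binomial(depth, p)
    return (depth - alt).astype(np.int64), alt.astype(np.int64)


def marker_genotypes(
    plants: Sequence[F2Plant], positions: Sequence[tuple[str, int]]
) -> dict[str, list[str]]:
    """Codominant marker calls (A/H/B) at arbitrary positions.

    A = homozygous resistant-parent allele, B = homozygous bolting-parent
    allele, H = heterozygous.
    """
    out: dict[str, list[str]] = {}
    for plant in plants:
        calls = []
        for sc, pos in positions:
            p = np.array([pos])
            br = int(plant.hap1.origin_at(sc, p)[0]) + int(plant.hap2.origin_at(sc, p)[0])
            calls.append({2: "A", 1: "H", 0: "B"}[br])
        out[plant.id] = calls
    return out


@dataclass
class SimulatedDataset:
    """One full simulator run, ready for export or direct analysis."""

    config: CrossSimConfig
    catalog: SiteCatalog
    plants: list[F2Plant]
    br_ids: list[str]
    b_ids: list[str]
    br_ref: np.ndarray
    br_alt: np.ndarray
    b_ref: np.ndarray
    b_alt: np.ndarray


def simulate_dataset(config: CrossSimConfig) -> SimulatedDataset:
    """Run the whole generator from the config's seed: catalog, plants,
    pools, and pooled read counts for both pools."""
    rng = np.random.default_rng(config.seed)
    catalog = simulate_catalog(config, rng)
    plants = simulate_f2(config, catalog, rng)
    br_ids, b_ids = make_pools(plants, config.n_b_pool, rng)
    by_id = {p.id: p for p in plants}
    br_dosage = alt_dosage_matrix([by_id[i] for i in br_ids], catalog)
    b_dosage = alt_dosage_matrix([by_id[i] for i in b_ids], catalog)
    br_f = true_pool_alt_frequency(br_dosage)
    b_f = true_pool_alt_frequency(b_dosage)
    br_ref, br_alt = sample_pool_reads(br_f, config.mean_depth_br, config.error_rate, rng)
    b_ref, b_alt = sample_pool_reads(b_f, config.mean_depth_b, config.error_rate, rng)
    return SimulatedDataset(config, catalog, plants, br_ids, b_ids, br_ref, br_alt, b_ref, b_alt)


def export_dataset(
    dataset: SimulatedDataset,
    outdir: str | Path,
    marker_positions: Sequence[tuple[str, int]] = (),
) -> dict[str, Path]:
    """Write the dataset as plain-text files.

    Produces ``variants.vcf`` (per-pool AD depths), ``phenotypes.tsv``,
    ``markers.tsv`` (one column per marker, A/H/B) and ``config.yaml``
    (full provenance: every parameter plus the seed). Deterministic:
    identical config+seed give byte-identical files.
    """
    from . import cli_io  # local import: cli_io imports types from here

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lengths = dataset.config.scaffold_lengths
    for sc, pos in marker_positions:
        if sc not in lengths or not 1 <= pos <= lengths[sc]:
            raise SimulationError(f"marker position {sc}:{pos} outside any scaffold")

    paths = {
        "variants": outdir / "variants.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "markers": outdir / "markers.tsv",
        "config": outdir / "config.yaml",
    }
    sites = cli_io.to_pooled_sites(dataset)
    cli_io.write_variants_vcf(sites, paths["variants"], config=dataset.config)

    with open(paths["phenotypes"], "w") as fh:
        fh.write("plant_id\tphenotype\tcausal_genotype\n")
        for p in dataset.plants:
            fh.write(f"{p.id}\t{p.phenotype}\t{p.causal_genotype}\n")

    with open(paths["markers"], "w") as fh:
        names = [f"{sc}:{pos}" for sc, pos in marker_positions]
        fh.write("plant_id" + "".join(f"\t{n}" for n in names) + "\n")
        genos = marker_genotypes(dataset.plants, marker_positions)
        for p in dataset.plants:
            fh.write(p.id + "".join(f"\t{g}" for g in genos[p.id]) + "\n")

    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    return paths
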