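"""Coalescent scenario generation for training and evaluation.

Wraps msprime behind ms-like per-bp scalings: simulations are parameterized
directly by the population-scaled rates theta = 4*N0*mu and rho = 4*N0*r per
base pair.  Internally haploid samples are drawn from a reference population
of size 2 (pairwise coalescence rate 1/2 per generation), so mutation and
recombination rates per bp are theta/4 and rho/4 and one ms coalescent time
unit equals 4 generations.

The module provides the constant-rate training grid, the simple and natural
hotspot designs, and the bottleneck-growth demography used by the
demography-aware model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import msprime
import numpy as np

from .alignment import HaplotypeAlignment
from .maps import RecombinationMap, make_hotspot_map

__all__ = [
    "ScenarioGrid",
    "DemographyModel",
    "make_constant_grid",
    "bottleneck_growth_demography",
    "simulate_alignment",
    "simulate_nucleotides",
    "natural_setup_map",
    "SIMPLE_SETUP",
    "standard_grid",
]

#: Reference population size giving the ms scalings above (haploid samples).
_REF_SIZE = 2.0
#: Generations per ms coalescent time unit under the reference size.
_GENS_PER_COAL_UNIT = 4.0

#: The simple one-hotspot designs: parameter sets asserted literally in tests.
SIMPLE_SETUP = {
    "sample_sizes": (10, 16, 20),
    "lengths_bp": (10_000, 20_000),
    "background_rho": tuple(np.linspace(0.001, 0.03, 15)),
    "intensities": (5.0, 10.0, 15.0, 20.0, 40.0),
    "hotspot_length_fractions": (1 / 5, 1 / 10, 1 / 20, 1 / 35, 1 / 50),
}


@dataclass(frozen=True)
class ScenarioGrid:
    """Factorial grid of constant-rate scenarios."""

    sample_sizes: tuple[int, ...]
    lengths_bp: tuple[int, ...]
    rho_values: tuple[float, ...]
    theta: float = 0.01
    demography_tag: str = "neutral"
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if not self.sample_sizes or not self.lengths_bp or not self.rho_values:
            raise ValueError("all factor lists must be non-empty")
        if any(r < 0 for r in self.rho_values):
            raise ValueError("rho values must be non-negative")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.demography_tag not in ("neutral", "bottleneck_growth"):
            raise ValueError(f"unknown demography_tag {self.demography_tag!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_scenarios(self) -> int:
        return (
            len(self.sample_sizes)
            * len(self.lengths_bp)
            * len(self.rho_values)
            * self.replicates
        )


@dataclass(frozen=True)
class DemographyModel:
    """Piecewise-constant relative population size history eta(t).

    ``epoch_boundaries`` are negative coalescent-time breakpoints (ms units,
    looking back from the present at t=0), most recent first;
    ``relative_sizes`` has one entry more than boundaries: the multiplier on
    each epoch, present epoch first.
    """

    epoch_boundaries: tuple[float, ...]
    relative_sizes: tuple[float, ...]
    tag: str = "custom"

    def __post_init__(self):
        if len(self.relative_sizes) != len(self.epoch_boundaries) + 1:
            raise ValueError("need one more size than epoch boundaries")
        if any(s <= 0 for s in self.relative_sizes):
            raise ValueError("relative sizes must be positive")
        b = self.epoch_boundaries
        if any(x >= 0 for x in b) or any(
            b[i] <= b[i + 1] for i in range(len(b) - 1)
        ):
            raise ValueError("boundaries must be negative and decreasing")

    def eta(self, t: float) -> float:
        """Relative size at coalescent time t <= 0."""
        if t > 0:
            raise ValueError("t must be <= 0 (looking back from the present)")
        for boundary, size in zip(self.epoch_boundaries, self.relative_sizes):
            if t > boundary:
                return size
        return self.relative_sizes[-1]

    def to_msprime(self) -> msprime.Demography:
        """msprime demography anchored at the present-day size.

        The reference population size N0 that scales theta, rho and the
        coalescent time unit is the present epoch's size, so only the ratios
        of ``relative_sizes`` matter; eta may be normalized to any epoch
        (conventionally the ancestral one, as in the bottleneck-growth
        model).
        """
        demog = msprime.Demography()
        demog.add_population(name="pop", initial_size=_REF_SIZE)
        eta0 = self.relative_sizes[0]
        for boundary, size in zip(self.epoch_boundaries, self.relative_sizes[1:]):
            demog.add_population_parameters_change(
                time=-boundary * _GENS_PER_COAL_UNIT,
                initial_size=_REF_SIZE * size / eta0,
            )
        return demog


def bottleneck_growth_demography() -> DemographyModel:
    """Recent 100-fold growth preceded by a bottleneck.

    eta(t) = 100 on -0.5 < t <= 0, 0.1 on -0.58 < t <= -0.5, and 1 in the
    ancestral epoch, with time in ms coalescent units.
    """
    return DemographyModel(
        epoch_boundaries=(-0.5, -0.58),
        relative_sizes=(100.0, 0.1, 1.0),
        tag="bottleneck_growth",
    )


def get_demography(tag: str) -> DemographyModel | None:
    if tag == "neutral":
        return None
    if tag == "bottleneck_growth":
        return bottleneck_growth_demography()
    raise ValueError(f"unknown demography tag {tag!r}")


def make_constant_grid(config: ScenarioGrid) -> list[tuple[int, int, float]]:
    """Full factorial list of (n, L, rho) descriptors, replicates included.

    Deterministic order: n, then L, then rho ascending, replicates innermost.
    """
    return [
        (n, length, rho)
        for n, length, rho, _ in itertools.product(
            sorted(config.sample_sizes),
            sorted(config.lengths_bp),
            sorted(config.rho_values),
            range(config.replicates),
        )
    ]


def standard_grid(
    theta: float = 0.01,
    demography_tag: str = "neutral",
    replicates: int = 1,
    seed: int = 0,
) -> ScenarioGrid:
    """The constant-rate design: n in {10,16,20}, L in {1,2,3} kb and 111
    equidistant rho values with positive minimum spanning (0, 0.1]."""
    rho = np.linspace(0.0, 0.1, 112)[1:]
    return ScenarioGrid(
        sample_sizes=(10, 16, 20),
        lengths_bp=(1000, 2000, 3000),
        rho_values=tuple(rho),
        theta=theta,
        demography_tag=demography_tag,
        replicates=replicates,
        seed=seed,
    )


def natural_setup_map(
    length_bp: int = 1_000_000,
    background_rho: float = 0.005,
    n_hotspots: int = 15,
    intensity_range: tuple[float, float] = (8.0, 40.0),
    hotspot_lengths: tuple[int, int] = (1000, 2000),
) -> RecombinationMap:
    """The natural design: evenly distributed hotspots on a 1 Mb background.

    Hotspot i (1-based) is centred at L*i/(n+1); intensities are equidistant
    across ``intensity_range`` in position order and lengths alternate between
    the two given values (1 and 2 kb by default).
    """
    intensities = np.linspace(*intensity_range, n_hotspots)
    hotspots = []
    for i in range(n_hotspots):
        centre = length_bp * (i + 1) / (n_hotspots + 1)
        hlen = hotspot_lengths[i % len(hotspot_lengths)]
        hotspots.append((centre - hlen / 2, hlen, intensities[i]))
    return make_hotspot_map(length_bp, background_rho, hotspots)


def _rate_map(rec_map: RecombinationMap) -> msprime.RateMap:
    return msprime.RateMap(
        position=rec_map.edges, rate=np.maximum(rec_map.rates, 0.0) / 4.0
    )


def _simulate_ts(rec_map, n, theta, demography, seed):
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(1, 2**31 - 1, size=2)
    if demography is None:
        kwargs = {"population_size": _REF_SIZE}
    else:
        kwargs = {"demography": demography.to_msprime()}
    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        sequence_length=rec_map.length_bp,
        recombination_rate=_rate_map(rec_map),
        random_seed=int(seeds[0]),
        **kwargs,
    )
    return msprime.sim_mutations(ts, rate=theta / 4.0, random_seed=int(seeds[1]))


def simulate_alignment(
    rec_map: RecombinationMap,
    n: int,
    theta: float,
    demography: DemographyModel | None = None,
    seed: int = 1,
) -> HaplotypeAlignment:
    """Draw a haplotype alignment from the coalescent with the given map.

    Same seed, same inputs -> identical output.  Sites left multiallelic by
    recurrent mutation are dropped by the alignment's reduction policy.
    """
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if theta <= 0:
        raise ValueError("theta must be positive")
    try:
        ts = _simulate_ts(rec_map, n, theta, demography, seed)
    except Exception as exc:  # pragma: no cover - engine failure context
        raise RuntimeError(
            f"coalescent simulation failed (n={n}, L={rec_map.length_bp}, "
            f"theta={theta}, seed={seed}): {exc}"
        ) from exc
    if ts.num_sites == 0:
        return HaplotypeAlignment(
            np.zeros((n, 0), dtype=np.uint8), np.empty(0, dtype=np.int64),
            rec_map.length_bp,
        )
    geno = ts.genotype_matrix().T  # (n, S) allele indices
    positions = np.array([int(s.position) for s in ts.sites()], dtype=np.int64)
    return HaplotypeAlignment.from_allele_matrix(geno, positions, rec_map.length_bp)


def simulate_nucleotides(
    rec_map: RecombinationMap,
    n: int,
    theta: float,
    demography: DemographyModel | None = None,
    seed: int = 1,
) -> list[tuple[str, str]]:
    """Full-length nucleotide sequences, one ``(id, sequence)`` per haplotype.

    Variant columns carry the simulated nucleotide states; invariant positions
    are filled with 'A' (their state carries no information for the
    segregating-site statistics).
    """
    ts = _simulate_ts(rec_map, n, theta, demography, seed)
    length = rec_map.length_bp
    seqs = np.full((n, length), ord("A"), dtype=np.uint8)
    for var in ts.variants():
        pos = int(var.site.position)
        alleles = [a if a else "N" for a in var.alleles]
        codes = np.array([ord(a[0]) for a in alleles], dtype=np.uint8)
        seqs[:, pos] = codes[var.genotypes]
    return [
        (f"hap_{i}", seqs[i].tobytes().decode("ascii")) for i in range(n)
    ]
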