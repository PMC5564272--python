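"""The recursive evolution loop.

Simulation counterparts of the microfluidic unit operations: a droplet
generator, a size sorter (individual thresholding or binned sub-population
sorting emulating pinched-flow fractionation), a fuser that replenishes
survivors with fresh feedstock, and a splitter that produces two offspring
per survivor.  ``run_generation`` chains them into one
incubate → measure → select → fuse → split → pool cycle, and
``run_recursion`` iterates that cycle while recording the per-generation
traits, fitnesses and parent–offspring maps needed for the Price
decomposition.

Fitness is operationalised as realised offspring count: a droplet whose
end-of-incubation diameter D falls below the size threshold f is discarded
(w = 0); each survivor is fused with one fresh feedstock droplet and split
once, so its fitness is 2 before population-size control.  The heritable
substrate is droplet composition: trapped polymer is passed to offspring,
with sibling-to-sibling variation injected by partition noise at splitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .dynamics import (
    ChemicalSpecies,
    ConfigurationError,
    Droplet,
    Environment,
    L_PER_UM3,
    Population,
    Reaction,
    incubate,
)

__all__ = [
    "CompositionClass",
    "PlatformConfig",
    "GenerationRecord",
    "RecursionResult",
    "generate_droplets",
    "sort_by_size",
    "fuse",
    "split",
    "run_generation",
    "run_recursion",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositionClass:
    """One compositional class of droplets within a generated population.

    ``fraction`` of the droplets are assigned to this class and loaded
    with the given initial concentrations (mol/L per species); species not
    listed start at zero.  A pure-water class is an empty mapping.
    """

    label: str
    fraction: float
    concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.fraction <= 1):
            raise ConfigurationError("class fraction must be in [0, 1]")
        if any(c < 0 for c in self.concentrations.values()):
            raise ConfigurationError("initial concentrations must be >= 0")


@dataclass
class PlatformConfig:
    """Parameters of the recursive selection platform.

    Sizes are µm (``size_threshold_f`` is a *diameter* threshold), times
    are seconds.  ``split_fraction`` is the volume fraction of the first
    child; ``partition_noise_sd`` the relative noise on each species'
    partition fraction at splitting — the source of heritable variation.
    """

    n_droplets: int = 100
    init_radius: float = 6.0
    init_radius_cv: float = 0.02
    composition: tuple[CompositionClass, ...] = (
        CompositionClass("monomer_feed", 1.0, {"monomer": 0.05}),
    )
    feedstock: CompositionClass = CompositionClass(
        "feedstock", 1.0, {"monomer": 0.05}
    )
    incubation_time: float = 60000.0
    dt: float = 50.0
    size_threshold_f: float = 12.0
    selection_mode: str = "individual"
    subpop_bins: int = 4
    split_fraction: float = 0.5
    partition_noise_sd: float = 0.1
    n_generations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 2:
            raise ConfigurationError("n_droplets must be >= 2")
        if not (0 < self.split_fraction < 1):
            raise ConfigurationError("split_fraction must be in (0, 1)")
        if not self.size_threshold_f > 0:
            raise ConfigurationError("size_threshold_f must be > 0")
        if self.init_radius <= 0 or self.init_radius_cv < 0:
            raise ConfigurationError("init_radius must be > 0 and cv >= 0")
        if self.selection_mode not in ("individual", "subpopulation"):
            raise ConfigurationError(
                "selection_mode must be 'individual' or 'subpopulation'"
            )
        if self.subpop_bins < 1:
            raise ConfigurationError("subpop_bins must be >= 1")
        total = sum(c.fraction for c in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("composition class fractions must sum to 1")


@dataclass
class GenerationRecord:
    """Bookkeeping for one generation, feeding the Price decomposition.

    ``z`` maps each parent (droplet alive at the end of incubation) to its
    trait — end-of-incubation diameter, µm.  ``w`` maps parent id to its
    realised offspring count in the next generation's population;
    discarded droplets have w = 0.  ``offspring_traits`` is filled once
    the offspring themselves have been incubated and measured.
    """

    generation: int
    z: dict[str, float]
    w: dict[str, float]
    offspring_map: dict[str, list[str]]
    offspring_traits: dict[str, list[float]]
    delta_e: float
    population_size: int
    n_survivors: int
    s_over_d: float
    mean_z: float


def generate_droplets(
    config: PlatformConfig,
    n: int,
    rng: np.random.Generator,
    species: Sequence[ChemicalSpecies],
    environment: Environment | None = None,
    composition: Sequence[CompositionClass] | None = None,
    id_prefix: str = "d",
    generation: int = 0,
    time: float = 0.0,
) -> Population:
    """Generate ``n`` droplets (the droplet-generator module).

    Radii are drawn from a normal law with mean ``init_radius`` and
    coefficient of variation ``init_radius_cv``, truncated at zero by
    redrawing.  Droplets are assigned to composition classes by largest
    remainder on the class fractions (deterministic), then loaded with the
    class concentrations.  Fully reproducible under a fixed ``rng`` state.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    classes = tuple(composition) if composition is not None else config.composition
    sd = config.init_radius * config.init_radius_cv
    if sd == 0:
        radii = np.full(n, config.init_radius)
    else:
        radii = rng.normal(config.init_radius, sd, size=n)
        for _ in range(100):
            bad = radii <= 0
            if not bad.any():
                break
            radii[bad] = rng.normal(config.init_radius, sd, size=int(bad.sum()))
        else:
            raise ConfigurationError(
                "could not draw positive radii; check init_radius and cv"
            )
    counts = _largest_remainder([c.fraction for c in classes], n)
    known = {sp.name for sp in species}
    droplets: list[Droplet] = []
    i = 0
    for cls, count in zip(classes, counts):
        unknown = set(cls.concentrations) - known
        if unknown:
            raise ConfigurationError(
                f"composition class {cls.label!r} references undefined species "
                f"{sorted(unknown)}"
            )
        for _ in range(count):
            r = float(radii[i])
            v_l = (4.0 / 3.0) * math.pi * r**3 * L_PER_UM3
            amounts = {name: c * v_l for name, c in cls.concentrations.items() if c > 0}
            droplets.append(
                Droplet(
                    id=f"{id_prefix}{i}",
                    radius=r,
                    amounts=amounts,
                    generation=generation,
                    label=cls.label,
                )
            )
            i += 1
    return Population(droplets, species, environment=environment, time=time)


def _largest_remainder(fractions: Sequence[float], n: int) -> list[int]:
    raw = [f * n for f in fractions]
    counts = [int(math.floor(x)) for x in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def sort_by_size(
    population: Population,
    f: float,
    mode: str = "individual",
    subpop_bins: int = 4,
) -> tuple[Population, Population]:
    """Partition a population by the diameter threshold ``f`` (µm).

    ``individual`` mode keeps every droplet with diameter D >= f (ties
    kept) — the active, per-droplet sorter.  ``subpopulation`` mode bins
    droplets into ``subpop_bins`` equal-width diameter bins and keeps a
    whole bin iff its mean diameter >= f — the passive, fractionation-like
    sorter.  Selected and discarded populations partition the input.
    """
    population._require_nonempty()
    d = population.diameters
    if mode == "individual":
        keep = d >= f
    elif mode == "subpopulation":
        lo, hi = float(d.min()), float(d.max())
        if hi == lo:
            keep = np.full(population.n, d.mean() >= f)
        else:
            edges = np.linspace(lo, hi, subpop_bins + 1)
            which = np.clip(np.digitize(d, edges[1:-1]), 0, subpop_bins - 1)
            keep = np.zeros(population.n, dtype=bool)
            for b in range(subpop_bins):
                in_bin = which == b
                if in_bin.any() and d[in_bin].mean() >= f:
                    keep[in_bin] = True
    else:
        raise ConfigurationError(f"unknown selection mode {mode!r}")
    return population.subset(keep), population.subset(~keep)


def fuse(a: Droplet, b: Droplet, new_id: str | None = None) -> Droplet:
    """Fuse two droplets (the droplet-fuser module).

    Volume and every species amount are strictly additive, so the fused
    radius is the cube root of r_a³ + r_b³; both parents are recorded in
    the lineage.
    """
    radius = (a.radius**3 + b.radius**3) ** (1.0 / 3.0)
    amounts = dict(a.amounts)
    for name, n in b.amounts.items():
        amounts[name] = amounts.get(name, 0.0) + n
    return Droplet(
        id=new_id if new_id is not None else f"({a.id}+{b.id})",
        radius=radius,
        amounts=amounts,
        generation=max(a.generation, b.generation),
        parent_ids=(a.id, b.id),
        label=a.label,
    )


def split(
    droplet: Droplet,
    fraction: float,
    noise_sd: float,
    rng: np.random.Generator,
    child_ids: tuple[str, str] | None = None,
) -> tuple[Droplet, Droplet]:
    """Split a droplet into two children (the droplet-splitter module).

    The first child receives exactly ``fraction`` of the volume.  Each
    species is partitioned with fraction φ·(1+η), η ~ N(0, noise_sd²),
    clamped to [0, 1] so neither child goes negative; the two children's
    amounts sum to the parent's exactly.  Partition noise is the platform's
    source of heritable variation between siblings.  Children advance the
    generation counter and record the parent in their lineage.
    """
    if not (0 < fraction < 1):
        raise ConfigurationError("split fraction must be in (0, 1)")
    if child_ids is None:
        child_ids = (f"{droplet.id}.0", f"{droplet.id}.1")
    r1 = droplet.radius * fraction ** (1.0 / 3.0)
    r2 = droplet.radius * (1.0 - fraction) ** (1.0 / 3.0)
    names = sorted(droplet.amounts)
    eta = rng.normal(0.0, noise_sd, size=len(names)) if noise_sd > 0 else np.zeros(
        len(names)
    )
    amounts1: dict[str, float] = {}
    amounts2: dict[str, float] = {}
    for k, name in enumerate(names):
        frac_k = float(np.clip(fraction * (1.0 + eta[k]), 0.0, 1.0))
        n = droplet.amounts[name]
        n1 = n * frac_k
        n2 = n - n1
        # enforce bitwise-exact complementarity: a rounded (n1, n - n1) pair
        # can miss n by one ulp when summed, so nudge until it closes
        for _ in range(5):
            if n1 + n2 == n:
                break
            n1 = n - n2
            n2 = n - n1
        amounts1[name] = n1
        amounts2[name] = n2
    common = dict(
        generation=droplet.generation + 1,
        parent_ids=(droplet.id,),
        label=droplet.label,
    )
    return (
        Droplet(id=child_ids[0], radius=r1, amounts=amounts1, **common),
        Droplet(id=child_ids[1], radius=r2, amounts=amounts2, **common),
    )


def run_generation(
    population: Population,
    config: PlatformConfig,
    reactions: Sequence[Reaction],
    rng: np.random.Generator,
    generation_index: int = 0,
) -> tuple[Population, GenerationRecord]:
    """One full platform cycle on ``population``.

    Pipeline: incubate → record traits z_i (end-of-incubation diameters) →
    size-sort at threshold f → fuse each survivor with one fresh feedstock
    droplet → split each fused droplet into two offspring → pool offspring
    and restore the population to ``n_droplets`` (uniform subsampling if
    over, fresh feedstock top-up if under).  The returned record carries
    z, w (realised offspring counts) and the parent→offspring map; its
    ``offspring_traits`` are filled by the caller once the offspring have
    been incubated and measured (see :func:`run_recursion`).

    If no droplet passes the threshold the next generation is founded from
    fresh feedstock only (with a warning); the population never empties.
    """
    species = population.species
    pop_end, _ = incubate(
        population,
        config.incubation_time,
        sample_every=config.incubation_time,
        dt=config.dt,
        reactions=reactions,
    )
    z = {did: float(d) for did, d in zip(pop_end.ids, pop_end.diameters)}
    selected, discarded = sort_by_size(
        pop_end, config.size_threshold_f, config.selection_mode, config.subpop_bins
    )
    n_sel = selected.n
    gnext = generation_index + 1
    if n_sel == 0:
        logger.warning(
            "generation %d: no droplet passed the size threshold f=%.3g µm; "
            "restarting from fresh feedstock",
            generation_index,
            config.size_threshold_f,
        )
        offspring: list[Droplet] = []
        parent_of: dict[str, str] = {}
    else:
        feed = generate_droplets(
            config,
            n_sel,
            rng,
            species,
            composition=[CompositionClass(config.feedstock.label, 1.0,
                                          config.feedstock.concentrations)],
            id_prefix=f"g{gnext}f",
            generation=gnext - 1,
        )
        offspring = []
        parent_of = {}
        for k, (surv, fresh) in enumerate(zip(selected.droplets, feed.droplets)):
            fused = fuse(surv, fresh, new_id=f"g{gnext}x{k}")
            c1, c2 = split(
                fused,
                config.split_fraction,
                config.partition_noise_sd,
                rng,
                child_ids=(f"g{gnext}d{2 * k}", f"g{gnext}d{2 * k + 1}"),
            )
            offspring.extend([c1, c2])
            parent_of[c1.id] = surv.id
            parent_of[c2.id] = surv.id

    if len(offspring) > config.n_droplets:
        keep_idx = rng.choice(len(offspring), size=config.n_droplets, replace=False)
        offspring = [offspring[i] for i in sorted(keep_idx)]
    elif len(offspring) < config.n_droplets:
        topup = generate_droplets(
            config,
            config.n_droplets - len(offspring),
            rng,
            species,
            composition=[CompositionClass(config.feedstock.label, 1.0,
                                          config.feedstock.concentrations)],
            id_prefix=f"g{gnext}t",
            generation=gnext,
        )
        offspring = offspring + topup.droplets

    w = {did: 0.0 for did in pop_end.ids}
    offspring_map: dict[str, list[str]] = {did: [] for did in pop_end.ids}
    for child in offspring:
        parent = parent_of.get(child.id)
        if parent is not None:
            w[parent] += 1.0
            offspring_map[parent].append(child.id)

    env = pop_end.environment
    new_env = Environment(
        k_w=env.k_w,
        k_s=env.k_s,
        mw_ref=env.mw_ref,
        e_state=env.e_state + env.delta_e,
        delta_e=env.delta_e,
    )
    next_pop = Population(offspring, species, environment=new_env, time=pop_end.time)
    record = GenerationRecord(
        generation=generation_index,
        z=z,
        w=w,
        offspring_map=offspring_map,
        offspring_traits={},
        delta_e=env.delta_e,
        population_size=pop_end.n,
        n_survivors=n_sel,
        s_over_d=(
            metrics.polydispersity(pop_end.radius).ratio if pop_end.n >= 2 else float("nan")
        ),
        mean_z=float(np.mean(list(z.values()))) if z else float("nan"),
    )
    logger.info(
        "generation %d: %d/%d survivors, %d extinctions so far, clipped mass %.3g g",
        generation_index,
        n_sel,
        record.population_size,
        len(pop_end.extinct_log),
        pop_end.clipped_mass_g,
    )
    return next_pop, record


@dataclass
class RecursionResult:
    """Full output of a multi-generation run."""

    records: list[GenerationRecord]
    price: list[metrics.PriceTerms | None]
    summary: pd.DataFrame
    droplets: pd.DataFrame
    lineage: pd.DataFrame
    trend: metrics.TrendReport | None


def run_recursion(
    config: PlatformConfig,
    species: Sequence[ChemicalSpecies],
    reactions: Sequence[Reaction] = (),
    environment: Environment | None = None,
    trend_cutoff: float = 0.6,
) -> RecursionResult:
    """Run ``n_generations`` platform cycles from a fresh population.

    A single seeded random stream (``config.seed``) is threaded through
    every stochastic operation in a fixed order (initial generation, then
    per generation: feedstock draws, partition noise, subsampling), so the
    whole run is reproducible from the top-level seed.  After the last
    cycle the final offspring are incubated and measured once more so that
    every generation record has offspring traits and a complete Price
    decomposition.

    Returns per-generation records, Price terms, a tidy per-droplet table,
    a generation summary table, a lineage table (child id → parent ids)
    and the evolution-trend report on the mean-trait series.
    """
    if config.n_generations < 1:
        raise ConfigurationError("n_generations must be >= 1")
    rng = np.random.default_rng(config.seed)
    pop = generate_droplets(
        config, config.n_droplets, rng, species, environment=environment,
        id_prefix="g0d", generation=0,
    )
    records: list[GenerationRecord] = []
    droplet_tables: list[pd.DataFrame] = []
    lineage_rows: list[dict] = []

    def _harvest_lineage(p: Population) -> None:
        for d in p.droplets:
            if d.parent_ids:
                lineage_rows.append(
                    {
                        "child_id": d.id,
                        "parent_ids": ";".join(d.parent_ids),
                        "generation": d.generation,
                    }
                )

    for g in range(config.n_generations):
        pop, record = run_generation(pop, config, reactions, rng, generation_index=g)
        if records:
            _fill_offspring_traits(records[-1], record.z)
        records.append(record)
        _harvest_lineage(pop)

    # one extra incubation to measure the last generation's offspring
    final_pop, _ = incubate(
        pop,
        config.incubation_time,
        sample_every=config.incubation_time,
        dt=config.dt,
        reactions=reactions,
    )
    final_z = {did: float(d) for did, d in zip(final_pop.ids, final_pop.diameters)}
    _fill_offspring_traits(records[-1], final_z)

    droplet_tables = [_record_to_frame(rec, rec.generation) for rec in records]

    price: list[metrics.PriceTerms | None] = []
    for rec in records:
        try:
            price.append(metrics.price_decomposition(rec))
        except metrics.UndefinedDecompositionError:
            price.append(None)

    summary = pd.DataFrame(
        {
            "generation": [r.generation for r in records],
            "n_droplets": [r.population_size for r in records],
            "n_survivors": [r.n_survivors for r in records],
            "z_bar": [r.mean_z for r in records],
            "w_bar": [p.w_bar if p else float("nan") for p in price],
            "delta_z_bar": [p.delta_z_bar if p else float("nan") for p in price],
            "cov_term": [p.cov_term if p else float("nan") for p in price],
            "transmission_term": [
                p.transmission_term if p else float("nan") for p in price
            ],
            "delta_e": [r.delta_e for r in records],
            "s_over_d": [r.s_over_d for r in records],
            "identity_residual": [
                p.identity_residual if p else float("nan") for p in price
            ],
        }
    )
    trend = None
    if len(records) >= 3:
        trend = metrics.evolution_trend(
            [r.mean_z for r in records], cutoff=trend_cutoff
        )
    return RecursionResult(
        records=records,
        price=price,
        summary=summary,
        droplets=pd.concat(droplet_tables, ignore_index=True)
        if droplet_tables
        else pd.DataFrame(),
        lineage=pd.DataFrame(
            lineage_rows, columns=["child_id", "parent_ids", "generation"]
        ),
        trend=trend,
    )


def _fill_offspring_traits(record: GenerationRecord, next_z: Mapping[str, float]) -> None:
    """Fill a record's offspring traits from the next generation's measured z.

    Offspring that did not survive to measurement (extinct during the next
    incubation) drop out of both the trait lists and the fitness counts, so
    w always equals the number of measured offspring.
    """
    traits: dict[str, list[float]] = {}
    for parent, children in record.offspring_map.items():
        measured = [next_z[c] for c in children if c in next_z]
        traits[parent] = measured
        record.w[parent] = float(len(measured))
    record.offspring_traits = traits


def _record_to_frame(record: GenerationRecord, g: int) -> pd.DataFrame:
    ids = list(record.z)
    return pd.DataFrame(
        {
            "generation": g,
            "droplet_id": ids,
            "z_diameter_um": [record.z[i] for i in ids],
            "w_offspring": [record.w.get(i, 0.0) for i in ids],
        }
    )
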