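"""Physical core of the droplet-evolution simulator.

Water-in-oil microdroplets co-incubating in the same chamber exchange
material through the continuous oil phase.  Two coupled transport processes
drive the population dynamics:

* **Osmotic water exchange** — droplets with above-average osmolarity draw
  water from their neighbours and grow at their expense (coarsening).
* **Solute exchange** — dissolved species permeate between droplets at a
  rate inversely proportional to their molecular weight, so small monomers
  re-equilibrate quickly while high-molecular-weight polymers stay trapped
  in the droplet that produced them.

On top of transport, each droplet is an autonomous microreactor: an
arbitrary mass-action reaction network (by default an autocatalytic
polymerization that condenses monomers into a trapped polymer) runs inside
every droplet.  A droplet that polymerizes faster accumulates trapped
osmotically active product, gains osmolarity relative to the population
mean, and therefore grows — physical size becomes a readout of internal
chemistry.

Unit conventions (fixed throughout the package):

========  =========================================
geometry  µm (radius), µm² (area), µm³ (volume)
amounts   mol per droplet
conc.     mol/L for reporting/kinetics (1 µm³ = 1e-15 L)
time      s
========  =========================================

Transport uses a mean-field bath: every droplet exchanges with the
area-weighted population mean osmolarity/concentration.  This conserves
total volume and per-species totals exactly (up to float rounding) and
reproduces the qualitative coarsening of a packed monolayer without
modelling droplet positions.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChemicalSpecies",
    "Droplet",
    "Environment",
    "Reaction",
    "Population",
    "Trajectory",
    "ConfigurationError",
    "InvalidDropletError",
    "osmolarity",
    "water_exchange_rates",
    "solute_exchange_rates",
    "reaction_rates",
    "stability_dt_max",
    "step",
    "incubate",
    "default_species",
    "default_reactions",
]

#: litres per cubic micrometre
L_PER_UM3 = 1e-15

#: droplets shrinking below this radius are removed (extinction floor), µm
EXTINCTION_RADIUS_UM = 0.5

#: relative tolerance for the monomer-equivalent mass balance of a reaction
MASS_BALANCE_RTOL = 1e-9


class ConfigurationError(ValueError):
    """A species/reaction/parameter definition is inconsistent."""


class InvalidDropletError(ValueError):
    """A droplet violates its geometric or stoichiometric invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChemicalSpecies:
    """A solute type.

    Parameters
    ----------
    name : str
        Unique label.
    molecular_weight : float
        g/mol; sets the inter-droplet permeation rate via the inverse
        molecular-weight law.
    exchangeable : bool
        Whether the species permeates between droplets at all.  A trapped
        (non-exchangeable) species never transfers.
    osmotically_active : bool
        Whether the species counts toward droplet osmolarity.
    """

    name: str
    molecular_weight: float
    exchangeable: bool = True
    osmotically_active: bool = True

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ConfigurationError(
                f"species {self.name!r}: molecular_weight must be > 0"
            )


@dataclass
class Droplet:
    """A single compartmentalised unit.

    ``amounts`` maps species name to absolute amount in mol (all >= 0).
    ``generation`` and ``parent_ids`` are lineage metadata maintained by the
    platform operators (fusion, splitting); ``label`` is a free-form class
    tag (e.g. ``"glycylglycine"`` vs ``"water"``) used for reporting only.
    """

    id: str
    radius: float
    amounts: dict[str, float] = field(default_factory=dict)
    generation: int = 0
    parent_ids: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise InvalidDropletError(f"droplet {self.id!r}: radius must be > 0")
        for name, n in self.amounts.items():
            if n < 0:
                raise InvalidDropletError(
                    f"droplet {self.id!r}: amount of {name!r} is negative"
                )

    @property
    def volume(self) -> float:
        """Volume in µm³."""
        return (4.0 / 3.0) * math.pi * self.radius**3

    @property
    def surface_area(self) -> float:
        """Surface area in µm²."""
        return 4.0 * math.pi * self.radius**2

    @property
    def diameter(self) -> float:
        """Diameter D = 2·radius, µm — the selection trait."""
        return 2.0 * self.radius


@dataclass
class Environment:
    """Shared chamber parameters and the abstract environment scalar.

    ``k_w`` is the water permeability in µm·L·mol⁻¹·s⁻¹ (volume flux per
    unit area per unit osmolarity difference); ``k_s`` the solute exchange
    base rate in µm/s at the reference molecular weight ``mw_ref``.
    ``e_state`` is a dimensionless environment coordinate and ``delta_e``
    the per-generation change applied to it by the platform; both are
    bookkeeping for the evolution metrics, not dynamical quantities.
    """

    k_w: float = 0.01
    k_s: float = 0.001
    mw_ref: float = 100.0
    e_state: float = 0.0
    delta_e: float = 0.0

    def __post_init__(self) -> None:
        if self.k_w < 0 or self.k_s < 0:
            raise ConfigurationError("permeabilities k_w, k_s must be >= 0")
        if self.mw_ref <= 0:
            raise ConfigurationError("mw_ref must be > 0")


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction with optional catalyst.

    rate = rate_constant · Π_reactants c^order · c_catalyst (if set),
    with concentrations in mol/L, so the rate is in mol·L⁻¹·s⁻¹ and the
    rate constant carries the units appropriate to the total kinetic
    order.  By default the kinetic order of each reactant equals its
    stoichiometric count (elementary mass action); ``orders`` overrides
    this for lumped reactions — e.g. a condensation written as 10 M → P
    whose empirical rate law is k·[M]² — while the stoichiometric counts
    still govern how amounts change.

    The stoichiometry must conserve monomer-equivalent mass:
    Σ reactant count·MW == Σ product count·MW (relative 1e-9).
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_constant: float
    catalyst: str | None = None
    orders: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        # freeze the mappings so Reaction stays hashable and immutable
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))
        if self.orders is not None:
            object.__setattr__(self, "orders", dict(self.orders))

    @property
    def kinetic_orders(self) -> dict[str, float]:
        return dict(self.orders) if self.orders is not None else {
            name: float(c) for name, c in self.reactants.items()
        }

    def validate(self, species: Mapping[str, ChemicalSpecies]) -> None:
        named = set(self.reactants) | set(self.products) | set(self.kinetic_orders)
        if self.catalyst is not None:
            named.add(self.catalyst)
        unknown = named - set(species)
        if unknown:
            raise ConfigurationError(
                f"reaction references undefined species: {sorted(unknown)}"
            )
        m_in = sum(c * species[s].molecular_weight for s, c in self.reactants.items())
        m_out = sum(c * species[s].molecular_weight for s, c in self.products.items())
        scale = max(abs(m_in), abs(m_out), 1e-300)
        if abs(m_in - m_out) / scale > MASS_BALANCE_RTOL:
            raise ConfigurationError(
                f"reaction is not mass balanced: {m_in} g/mol in, {m_out} g/mol out"
            )


def default_species() -> tuple[ChemicalSpecies, ChemicalSpecies]:
    """The default two-species chemistry: a glycylglycine-like monomer and
    a chain-length-10 condensation polymer.

    The monomer (MW 132 g/mol) exchanges between droplets; the polymer
    (MW 1320 g/mol) is treated as trapped and osmotically active, so
    polymerization converts shared feedstock into a private osmotic
    advantage.
    """
    return (
        ChemicalSpecies("monomer", 132.0, exchangeable=True, osmotically_active=True),
        ChemicalSpecies(
            "polymer", 1320.0, exchangeable=False, osmotically_active=True
        ),
    )


def default_reactions(
    k_init: float = 2e-6, k_auto: float = 3.5e-4
) -> tuple[Reaction, Reaction]:
    """Default polymerization network: 10 M → P, twice.

    Initiation has an empirical rate law k_init·[M]² (slow, seeds the
    catalyst); growth is autocatalytic with rate k_auto·[M]·[P].  At
    50 mM monomer the defaults give ~0.1 mM polymer per 6·10⁴ s
    incubation from initiation alone, and the autocatalytic channel
    multiplies inherited polymer by e^(k_auto·[M]·T) ≈ 2.9 per
    incubation — enough to outpace the two-fold dilution at
    fusion/splitting, so polymer compounds steadily over a ten-generation
    run instead of saturating immediately.  See the methods note.
    """
    return (
        Reaction({"monomer": 10}, {"polymer": 1}, rate_constant=k_init,
                 orders={"monomer": 2}),
        Reaction({"monomer": 10}, {"polymer": 1}, rate_constant=k_auto,
                 orders={"monomer": 1}, catalyst="polymer"),
    )


class Population:
    """An ordered co-incubating set of droplets plus chamber environment.

    Internally stores per-droplet state as numpy arrays (radius vector and
    an ``(n, n_species)`` amounts matrix) so the integrator is vectorised;
    :attr:`droplets` materialises :class:`Droplet` views on demand.
    """

    def __init__(
        self,
        droplets: Sequence[Droplet],
        species: Sequence[ChemicalSpecies],
        environment: Environment | None = None,
        time: float = 0.0,
    ) -> None:
        droplets = list(droplets)
        ids = [d.id for d in droplets]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("droplet ids must be unique")
        self.species: tuple[ChemicalSpecies, ...] = tuple(species)
        self.species_index: dict[str, int] = {
            sp.name: i for i, sp in enumerate(self.species)
        }
        if len(self.species_index) != len(self.species):
            raise ConfigurationError("species names must be unique")
        for d in droplets:
            unknown = set(d.amounts) - set(self.species_index)
            if unknown:
                raise ConfigurationError(
                    f"droplet {d.id!r} carries undefined species {sorted(unknown)}"
                )
        self.environment = environment if environment is not None else Environment()
        self.time = float(time)
        self.ids: list[str] = ids
        self.generations = np.array([d.generation for d in droplets], dtype=int)
        self.parent_ids: list[tuple[str, ...]] = [tuple(d.parent_ids) for d in droplets]
        self.labels: list[str] = [d.label for d in droplets]
        self.radius = np.array([d.radius for d in droplets], dtype=float)
        self.amounts = np.zeros((len(droplets), len(self.species)), dtype=float)
        for i, d in enumerate(droplets):
            for name, n in d.amounts.items():
                self.amounts[i, self.species_index[name]] = n
        # cumulative integrator bookkeeping, carried across steps
        self.clipped_mass_g: float = 0.0
        self.extinct_log: list[dict] = []

    # -- basic views --------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def volumes(self) -> np.ndarray:
        """Per-droplet volume, µm³."""
        return (4.0 / 3.0) * np.pi * self.radius**3

    @property
    def areas(self) -> np.ndarray:
        """Per-droplet surface area, µm²."""
        return 4.0 * np.pi * self.radius**2

    @property
    def diameters(self) -> np.ndarray:
        return 2.0 * self.radius

    @property
    def droplets(self) -> list[Droplet]:
        out = []
        for i, did in enumerate(self.ids):
            amounts = {
                sp.name: float(self.amounts[i, j])
                for j, sp in enumerate(self.species)
                if self.amounts[i, j] != 0.0
            }
            out.append(
                Droplet(
                    id=did,
                    radius=float(self.radius[i]),
                    amounts=amounts,
                    generation=int(self.generations[i]),
                    parent_ids=self.parent_ids[i],
                    label=self.labels[i],
                )
            )
        return out

    def copy(self) -> "Population":
        new = object.__new__(Population)
        new.species = self.species
        new.species_index = self.species_index
        new.environment = replace(self.environment)
        new.time = self.time
        new.ids = list(self.ids)
        new.generations = self.generations.copy()
        new.parent_ids = list(self.parent_ids)
        new.labels = list(self.labels)
        new.radius = self.radius.copy()
        new.amounts = self.amounts.copy()
        new.clipped_mass_g = self.clipped_mass_g
        new.extinct_log = list(self.extinct_log)
        return new

    def subset(self, mask: np.ndarray) -> "Population":
        """New population holding the droplets where ``mask`` is True."""
        idx = np.flatnonzero(mask)
        new = self.copy()
        new.ids = [self.ids[i] for i in idx]
        new.generations = self.generations[idx]
        new.parent_ids = [self.parent_ids[i] for i in idx]
        new.labels = [self.labels[i] for i in idx]
        new.radius = self.radius[idx]
        new.amounts = self.amounts[idx]
        return new

    # -- derived physical quantities ----------------------------------------

    def concentrations(self) -> np.ndarray:
        """Per-droplet, per-species concentration in mol/L, shape (n, k)."""
        v_l = self.volumes[:, None] * L_PER_UM3
        return self.amounts / v_l

    def osmolarities(self) -> np.ndarray:
        """Per-droplet osmolarity Π in mol/L (osmotically active species)."""
        active = np.array([sp.osmotically_active for sp in self.species], dtype=bool)
        if not active.any():
            return np.zeros(self.n)
        v_l = self.volumes * L_PER_UM3
        return self.amounts[:, active].sum(axis=1) / v_l

    def total_mass_g(self) -> float:
        """Total monomer-equivalent mass of all solutes, in grams."""
        mw = np.array([sp.molecular_weight for sp in self.species])
        return float((self.amounts @ mw).sum())

    def monomer_mass_per_droplet(self) -> np.ndarray:
        mw = np.array([sp.molecular_weight for sp in self.species])
        return self.amounts @ mw

    def to_frame(self) -> pd.DataFrame:
        """Snapshot as a tidy table: one row per droplet."""
        data = {
            "time_s": self.time,
            "droplet_id": self.ids,
            "label": self.labels,
            "generation": self.generations,
            "radius_um": self.radius,
        }
        for j, sp in enumerate(self.species):
            data[f"{sp.name}_mol"] = self.amounts[:, j]
        return pd.DataFrame(data)

    def _require_nonempty(self) -> None:
        if self.n == 0:
            raise InvalidDropletError("population is empty")


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------


def osmolarity(droplet: Droplet, species: Iterable[ChemicalSpecies]) -> float:
    """Osmolarity Π of a single droplet, mol/L.

    Sum of the amounts of osmotically active species divided by droplet
    volume (µm³ converted to litres).
    """
    if not (droplet.radius > 0):
        raise InvalidDropletError("droplet radius must be > 0")
    v_l = droplet.volume * L_PER_UM3
    active = {sp.name for sp in species if sp.osmotically_active}
    n_tot = sum(n for name, n in droplet.amounts.items() if name in active)
    return n_tot / v_l


def _water_exchange_array(pop: Population) -> np.ndarray:
    """dV_i/dt in µm³/s for every droplet (mean-field osmotic flux).

    dV_i/dt = k_w · A_i · (Π_i − Π̄), with Π̄ the area-weighted mean.
    For a population with identical osmolarities the rates are exactly
    zero (the mean of a constant vector is taken to be that constant),
    so an unmixed control never drifts.
    """
    pi = pop.osmolarities()
    if pop.n == 1 or np.ptp(pi) == 0.0:
        return np.zeros(pop.n)
    areas = pop.areas
    pi_bar = float(np.dot(areas, pi) / areas.sum())
    return pop.environment.k_w * areas * (pi - pi_bar)


def water_exchange_rates(population: Population) -> dict[str, float]:
    """Osmotic volume-exchange rate per droplet, µm³/s, keyed by id.

    Rates sum to zero: water is only redistributed, never created.
    """
    population._require_nonempty()
    rates = _water_exchange_array(population)
    return dict(zip(population.ids, map(float, rates)))


def _solute_exchange_array(pop: Population) -> np.ndarray:
    """dn_ik/dt in mol/s, shape (n, k).

    For an exchangeable species of molecular weight MW the permeation
    coefficient is k_s·(mw_ref/MW) µm/s — the inverse molecular-weight
    law — and each droplet relaxes toward the area-weighted mean
    concentration:  dn_ik/dt = k_s·(mw_ref/MW_k)·A_i·(c̄_k − c_ik),
    with concentrations in mol/µm³ internally.  Non-exchangeable species
    get exactly zero.
    """
    env = pop.environment
    rates = np.zeros_like(pop.amounts)
    if pop.n == 1:
        return rates
    areas = pop.areas
    a_sum = areas.sum()
    conc = pop.amounts / pop.volumes[:, None]  # mol/µm³
    for j, sp in enumerate(pop.species):
        if not sp.exchangeable:
            continue
        c = conc[:, j]
        if np.ptp(c) == 0.0:
            continue
        c_bar = float(np.dot(areas, c) / a_sum)
        coef = env.k_s * (env.mw_ref / sp.molecular_weight)
        rates[:, j] = coef * areas * (c_bar - c)
    return rates


def solute_exchange_rates(population: Population) -> dict[tuple[str, str], float]:
    """Solute permeation rate dn/dt (mol/s) keyed by (droplet id, species).

    Per species, rates sum to zero (solute is redistributed).
    """
    population._require_nonempty()
    arr = _solute_exchange_array(population)
    out: dict[tuple[str, str], float] = {}
    for i, did in enumerate(population.ids):
        for j, sp in enumerate(population.species):
            out[(did, sp.name)] = float(arr[i, j])
    return out


def _reaction_rate_arrays(
    pop: Population, reactions: Sequence[Reaction]
) -> np.ndarray:
    """Per-droplet species production rates dn/dt (mol/s), shape (n, k).

    Mass-action kinetics evaluated on mol/L concentrations; concentration
    rates are converted to amount rates with the droplet volume in litres.
    """
    k = len(pop.species)
    dndt = np.zeros((pop.n, k))
    if not reactions:
        return dndt
    conc = pop.concentrations()  # mol/L
    v_l = pop.volumes * L_PER_UM3
    for rxn in reactions:
        rxn.validate({sp.name: sp for sp in pop.species})
        rate = np.full(pop.n, rxn.rate_constant)
        for name, order in rxn.kinetic_orders.items():
            rate = rate * conc[:, pop.species_index[name]] ** order
        if rxn.catalyst is not None:
            rate = rate * conc[:, pop.species_index[rxn.catalyst]]
        net = np.zeros(k)
        for name, count in rxn.products.items():
            net[pop.species_index[name]] += count
        for name, count in rxn.reactants.items():
            net[pop.species_index[name]] -= count
        dndt += (rate * v_l)[:, None] * net[None, :]
    return dndt


def reaction_rates(
    droplet: Droplet,
    reactions: Sequence[Reaction],
    species: Sequence[ChemicalSpecies],
) -> dict[str, float]:
    """Net production rate dn/dt (mol/s) per species for one droplet."""
    pop = Population([droplet], species)
    arr = _reaction_rate_arrays(pop, reactions)
    return {sp.name: float(arr[0, j]) for j, sp in enumerate(species)}


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def stability_dt_max(population: Population) -> float:
    """Largest time step the explicit Euler splitting tolerates.

    Water: dt ≤ 0.1 · min_i V_i / (k_w·A_i·Π_max + ε) — no droplet may
    lose more than ~10% of its volume per step at the worst-case osmotic
    gradient.  Solutes: dt ≤ 0.1 · min_i V_i / (coef_k·A_i) for the
    fastest-permeating species, the same criterion applied to the
    concentration-relaxation time, so a dilute population cannot be
    destabilised through the solute channel.
    """
    population._require_nonempty()
    env = population.environment
    pi_max = float(population.osmolarities().max(initial=0.0))
    denom = env.k_w * population.areas * pi_max + 1e-30
    bound = float(0.1 * (population.volumes / denom).min())
    coef_max = max(
        (
            env.k_s * env.mw_ref / sp.molecular_weight
            for sp in population.species
            if sp.exchangeable
        ),
        default=0.0,
    )
    if coef_max > 0:
        tau_solute = float((population.volumes / population.areas).min()) / coef_max
        bound = min(bound, 0.1 * tau_solute)
    return bound


def step(population: Population, dt: float, reactions: Sequence[Reaction] = ()) -> Population:
    """Advance the population by one explicit-Euler step of length ``dt``.

    Operator splitting: the reaction network is advanced first within each
    droplet, then the exchange fluxes (water and solutes) are applied.
    Amounts are clipped at zero with the clipped monomer-equivalent mass
    accumulated in ``clipped_mass_g``; droplets shrinking below the
    extinction floor (radius 0.5 µm) are removed and logged in
    ``extinct_log``, never allowed to reach negative volume.
    """
    population._require_nonempty()
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if dt > stability_dt_max(population) * (1 + 1e-12):
        raise ValueError(
            f"dt={dt} exceeds the stability bound "
            f"{stability_dt_max(population):.6g} s for this population"
        )
    pop = population.copy()
    volumes_before = pop.volumes
    radius_before = pop.radius.copy()
    mw = np.array([sp.molecular_weight for sp in pop.species])

    # 1) chemistry within each droplet
    if reactions:
        dndt = _reaction_rate_arrays(pop, reactions)
        pop.amounts = pop.amounts + dndt * dt
        neg = pop.amounts < 0
        if neg.any():
            pop.clipped_mass_g += float((-pop.amounts[neg] * mw[np.where(neg)[1]]).sum())
            pop.amounts[neg] = 0.0

    # 2) exchange fluxes
    dvdt = _water_exchange_array(pop)
    dndt_x = _solute_exchange_array(pop)
    volumes = volumes_before + dvdt * dt
    pop.amounts = pop.amounts + dndt_x * dt
    neg = pop.amounts < 0
    if neg.any():
        pop.clipped_mass_g += float((-pop.amounts[neg] * mw[np.where(neg)[1]]).sum())
        pop.amounts[neg] = 0.0

    # 3) geometry update and extinction handling
    v_floor = (4.0 / 3.0) * np.pi * EXTINCTION_RADIUS_UM**3
    extinct = volumes < v_floor
    if extinct.any():
        for i in np.flatnonzero(extinct):
            pop.extinct_log.append(
                {
                    "time_s": pop.time + dt,
                    "droplet_id": pop.ids[i],
                    "volume_um3": float(max(volumes[i], 0.0)),
                    "amounts_mol": pop.amounts[i].copy(),
                }
            )
        keep = ~extinct
        pop.ids = [pop.ids[i] for i in np.flatnonzero(keep)]
        pop.generations = pop.generations[keep]
        pop.parent_ids = [pop.parent_ids[i] for i in np.flatnonzero(keep)]
        pop.labels = [pop.labels[i] for i in np.flatnonzero(keep)]
        pop.amounts = pop.amounts[keep]
        volumes = volumes[keep]
        volumes_before = volumes_before[keep]
        radius_before = radius_before[keep]
    # avoid the volume→radius round-trip for droplets that did not move:
    # a population with no gradients is an exact fixed point
    new_radius = (3.0 * volumes / (4.0 * np.pi)) ** (1.0 / 3.0)
    pop.radius = np.where(volumes == volumes_before, radius_before, new_radius)
    pop.time = population.time + dt
    return pop


Trajectory = namedtuple("Trajectory", ["droplets", "summary"])
"""Sampled incubation history.

``droplets``: tidy per-droplet table (time_s, droplet_id, label,
generation, radius_um, one *_mol column per species).
``summary``: one row per sample (time_s, n_droplets, mean_radius_um,
s_over_d, total_volume_um3).
"""


def incubate(
    population: Population,
    duration: float,
    sample_every: float | None = None,
    dt: float = 10.0,
    reactions: Sequence[Reaction] = (),
    ddof: int = 1,
) -> tuple[Population, Trajectory]:
    """Run the population forward for ``duration`` seconds.

    Steps use ``dt`` but are automatically subdivided whenever ``dt``
    exceeds the stability bound, so the call never fails on a population
    that has developed steep gradients.  The trajectory is sampled at
    t = 0, sample_every, 2·sample_every, … and always at the final time.
    """
    from . import metrics  # local import: metrics depends on nothing here

    if not duration > 0:
        raise ValueError("duration must be > 0")
    if sample_every is None:
        sample_every = duration
    pop = population
    snapshots = [pop.to_frame()]
    summaries = [_summary_row(pop, ddof)]
    n_samples = int(round(duration / sample_every))
    sample_times = [min(sample_every * k, duration) for k in range(1, n_samples + 1)]
    if not sample_times or sample_times[-1] < duration:
        sample_times.append(duration)
    t = 0.0
    for t_target in sample_times:
        while t < t_target - 1e-9 * duration:
            h = min(dt, t_target - t)
            h_max = stability_dt_max(pop)
            if h > h_max:
                n_sub = int(math.ceil(h / h_max))
                h_sub = h / n_sub
                for _ in range(n_sub):
                    pop = step(pop, h_sub, reactions)
            else:
                pop = step(pop, h, reactions)
            t += h
        snapshots.append(pop.to_frame())
        summaries.append(_summary_row(pop, ddof))
    droplets_df = pd.concat(snapshots, ignore_index=True)
    summary_df = pd.DataFrame(summaries)
    return pop, Trajectory(droplets=droplets_df, summary=summary_df)


def _summary_row(pop: Population, ddof: int = 1) -> dict:
    from . import metrics

    if pop.n >= 2:
        s_over_d = metrics.polydispersity(pop.radius, ddof=ddof).ratio
    else:
        s_over_d = float("nan")
    return {
        "time_s": pop.time,
        "n_droplets": pop.n,
        "mean_radius_um": float(pop.radius.mean()) if pop.n else float("nan"),
        "s_over_d": s_over_d,
        "total_volume_um3": float(pop.volumes.sum()),
    }
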