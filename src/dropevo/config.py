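"""Run configuration: YAML schema, validation, scenario presets.

A run is described by one structured YAML file.  Unknown keys anywhere in
the file are rejected (typo safety) and schema violations are reported
with the offending key path.  A minimal file needs only a scenario name
and a seed; every other field is filled from the named scenario's preset,
so::

    scenario: coarsening_mixed
    seed: 1

is a complete configuration.  ``load_config → dump_config → load_config``
round-trips to an identical configuration.

Built-in scenarios
------------------
``coarsening_mixed``
    A mixed but monodisperse population: half the droplets carry 50 mM
    glycylglycine, half pure water, co-incubated for 7500 s (125 min).
    The osmotic-exchange demonstration.
``coarsening_unmixed_glycylglycine`` / ``coarsening_unmixed_water``
    The unmixed controls: identical composition everywhere, no coarsening.
``evolution``
    100 droplets of 50 mM monomer running the autocatalytic
    polymerization network through 10 generations of threshold selection,
    feedstock fusion and splitting.
``neutral_control``
    The evolution scenario with chemistry, size variation and partition
    noise all switched off: no heritable variation, no trend.
"""

from __future__ import annotations

import copy
import hashlib
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .dynamics import (
    ChemicalSpecies,
    ConfigurationError,
    Environment,
    Reaction,
)
from .platform import CompositionClass, PlatformConfig

__all__ = ["RunConfig", "load_config", "dump_config", "scenario_names", "config_hash"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpeciesCfg(_StrictModel):
    name: str
    molecular_weight: float
    exchangeable: bool = True
    osmotically_active: bool = True


class ReactionCfg(_StrictModel):
    reactants: dict[str, int]
    products: dict[str, int]
    rate_constant: float
    catalyst: Optional[str] = None
    orders: Optional[dict[str, float]] = None


class EnvironmentCfg(_StrictModel):
    k_w: float = 0.01
    k_s: float = 0.001
    mw_ref: float = 100.0
    e_state: float = 0.0
    delta_e: float = 0.0


class CompositionClassCfg(_StrictModel):
    label: str
    fraction: float
    concentrations: dict[str, float] = Field(default_factory=dict)


class PlatformCfg(_StrictModel):
    n_droplets: int = 100
    init_radius: float = 6.0
    init_radius_cv: float = 0.02
    composition: list[CompositionClassCfg] = Field(
        default_factory=lambda: [
            CompositionClassCfg(
                label="monomer_feed", fraction=1.0, concentrations={"monomer": 0.05}
            )
        ]
    )
    feedstock: CompositionClassCfg = Field(
        default_factory=lambda: CompositionClassCfg(
            label="feedstock", fraction=1.0, concentrations={"monomer": 0.05}
        )
    )
    incubation_time: float = 60000.0
    dt: float = 50.0
    size_threshold_f: float = 12.0
    selection_mode: str = "individual"
    subpop_bins: int = 4
    split_fraction: float = 0.5
    partition_noise_sd: float = 0.1
    n_generations: int = 10


class ImagingCfg(_StrictModel):
    scale_um_per_px: float = 2.0
    frame_size: int = 768
    noise_sd: float = 8.0
    #: render a frame every k-th trajectory sample; None disables rendering
    render_every: Optional[int] = None


class MetricsCfg(_StrictModel):
    #: delta-degrees-of-freedom of the radius standard deviation in s/d
    std_ddof: int = 1
    trend_cutoff: float = 0.6


class RunConfig(_StrictModel):
    """Fully validated configuration for one run."""

    scenario: str = "coarsening_mixed"
    seed: int = 0
    output_dir: str = "runs"
    species: list[SpeciesCfg] = Field(default_factory=list)
    reactions: list[ReactionCfg] = Field(default_factory=list)
    environment: EnvironmentCfg = Field(default_factory=EnvironmentCfg)
    platform: PlatformCfg = Field(default_factory=PlatformCfg)
    sample_every: float = 500.0
    imaging: ImagingCfg = Field(default_factory=ImagingCfg)
    metrics: MetricsCfg = Field(default_factory=MetricsCfg)

    # -- conversion to domain objects ---------------------------------------

    def build_species(self) -> list[ChemicalSpecies]:
        return [
            ChemicalSpecies(
                s.name, s.molecular_weight, s.exchangeable, s.osmotically_active
            )
            for s in self.species
        ]

    def build_reactions(self) -> list[Reaction]:
        return [
            Reaction(
                reactants=r.reactants,
                products=r.products,
                rate_constant=r.rate_constant,
                catalyst=r.catalyst,
                orders=r.orders,
            )
            for r in self.reactions
        ]

    def build_environment(self) -> Environment:
        e = self.environment
        return Environment(
            k_w=e.k_w, k_s=e.k_s, mw_ref=e.mw_ref, e_state=e.e_state,
            delta_e=e.delta_e,
        )

    def build_platform_config(self) -> PlatformConfig:
        p = self.platform
        return PlatformConfig(
            n_droplets=p.n_droplets,
            init_radius=p.init_radius,
            init_radius_cv=p.init_radius_cv,
            composition=tuple(
                CompositionClass(c.label, c.fraction, dict(c.concentrations))
                for c in p.composition
            ),
            feedstock=CompositionClass(
                p.feedstock.label, p.feedstock.fraction, dict(p.feedstock.concentrations)
            ),
            incubation_time=p.incubation_time,
            dt=p.dt,
            size_threshold_f=p.size_threshold_f,
            selection_mode=p.selection_mode,
            subpop_bins=p.subpop_bins,
            split_fraction=p.split_fraction,
            partition_noise_sd=p.partition_noise_sd,
            n_generations=p.n_generations,
            seed=self.seed,
        )

    # -- cross-field validation ---------------------------------------------

    def validate_references(self) -> None:
        """Every species referenced anywhere must be defined exactly once."""
        names = [s.name for s in self.species]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigurationError(f"species defined more than once: {sorted(dupes)}")
        defined = set(names)
        species_map = {sp.name: sp for sp in self.build_species()}
        for i, r in enumerate(self.reactions):
            used = set(r.reactants) | set(r.products) | set(r.orders or {})
            if r.catalyst:
                used.add(r.catalyst)
            missing = used - defined
            if missing:
                raise ConfigurationError(
                    f"reactions[{i}] references undefined species: {sorted(missing)}"
                )
            self.build_reactions()[i].validate(species_map)
        for where, classes in (
            ("platform.composition", self.platform.composition),
            ("platform.feedstock", [self.platform.feedstock]),
        ):
            for c in classes:
                missing = set(c.concentrations) - defined
                if missing:
                    raise ConfigurationError(
                        f"{where} class {c.label!r} references undefined species: "
                        f"{sorted(missing)}"
                    )


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

_GLY = {
    "name": "glycylglycine",
    "molecular_weight": 132.12,
    "exchangeable": True,
    "osmotically_active": True,
}

_COARSEN_PLATFORM = {
    "n_droplets": 100,
    "init_radius": 30.0,
    "init_radius_cv": 0.0,
    "composition": [
        {"label": "glycylglycine", "fraction": 0.5,
         "concentrations": {"glycylglycine": 0.05}},
        {"label": "water", "fraction": 0.5, "concentrations": {}},
    ],
    "feedstock": {"label": "feedstock", "fraction": 1.0,
                  "concentrations": {"glycylglycine": 0.05}},
    "incubation_time": 7500.0,  # 125 min, the span of the imaging experiment
    "dt": 5.0,
    "size_threshold_f": 60.0,
}

_DEFAULT_CHEM_SPECIES = [
    {"name": "monomer", "molecular_weight": 132.0,
     "exchangeable": True, "osmotically_active": True},
    {"name": "polymer", "molecular_weight": 1320.0,
     "exchangeable": False, "osmotically_active": True},
]

_DEFAULT_CHEM_REACTIONS = [
    {"reactants": {"monomer": 10}, "products": {"polymer": 1},
     "rate_constant": 2e-6, "orders": {"monomer": 2}, "catalyst": None},
    {"reactants": {"monomer": 10}, "products": {"polymer": 1},
     "rate_constant": 3.5e-4, "orders": {"monomer": 1}, "catalyst": "polymer"},
]

SCENARIOS: dict[str, dict] = {
    "coarsening_mixed": {
        "species": [_GLY],
        "reactions": [],
        "platform": _COARSEN_PLATFORM,
        "sample_every": 500.0,
    },
    "coarsening_unmixed_glycylglycine": {
        "species": [_GLY],
        "reactions": [],
        "platform": {
            **_COARSEN_PLATFORM,
            "composition": [
                {"label": "glycylglycine", "fraction": 1.0,
                 "concentrations": {"glycylglycine": 0.05}},
            ],
        },
        "sample_every": 500.0,
    },
    "coarsening_unmixed_water": {
        "species": [_GLY],
        "reactions": [],
        "platform": {
            **_COARSEN_PLATFORM,
            "composition": [{"label": "water", "fraction": 1.0,
                             "concentrations": {}}],
        },
        "sample_every": 500.0,
    },
    "evolution": {
        "species": _DEFAULT_CHEM_SPECIES,
        "reactions": _DEFAULT_CHEM_REACTIONS,
        "platform": {},  # PlatformCfg defaults are the evolution defaults
        "sample_every": 10000.0,
        "imaging": {"scale_um_per_px": 0.5, "frame_size": 768, "noise_sd": 8.0,
                    "render_every": None},
    },
    "neutral_control": {
        "species": _DEFAULT_CHEM_SPECIES,
        "reactions": [],
        # size threshold just below the monodisperse diameter so the control
        # imposes no selection differential (a tie at the threshold can be
        # broken by one ulp of fuse/split round-off)
        "platform": {"init_radius_cv": 0.0, "partition_noise_sd": 0.0,
                     "size_threshold_f": 11.9},
        "sample_every": 10000.0,
    },
}


def scenario_names() -> list[str]:
    return sorted(SCENARIOS)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def _from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigurationError("config must be a mapping")
    scenario = data.get("scenario", "coarsening_mixed")
    if scenario not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; choose one of {scenario_names()}"
        )
    merged = _deep_merge(SCENARIOS[scenario], data)
    merged.setdefault("scenario", scenario)
    try:
        cfg = RunConfig.model_validate(merged)
    except ValidationError as err:
        lines = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ConfigurationError(
            "invalid configuration:\n  " + "\n  ".join(lines)
        ) from None
    cfg.validate_references()
    return cfg


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    The named scenario's preset supplies defaults; keys in the file
    override it.  Unknown keys and dangling species references are errors.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return _from_dict(data)


def dump_config(config: RunConfig, path=None) -> str:
    """Serialise a resolved configuration back to YAML.

    Loading the dumped text yields an identical configuration.
    """
    text = yaml.safe_dump(config.model_dump(), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the resolved configuration (for output headers).

    The output directory is excluded: it locates artifacts but does not
    affect what is computed.
    """
    payload = config.model_dump()
    payload.pop("output_dir", None)
    text = yaml.safe_dump(payload, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
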