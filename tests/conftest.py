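import math

import numpy as np
import pytest

from dropevo.dynamics import (
    ChemicalSpecies,
    Droplet,
    Environment,
    Population,
    L_PER_UM3,
)


def amounts_at(radius_um: float, **conc_mol_per_l: float) -> dict[str, float]:
    """Amounts (mol) that give the requested concentrations at this radius."""
    v_l = (4.0 / 3.0) * math.pi * radius_um**3 * L_PER_UM3
    return {name: c * v_l for name, c in conc_mol_per_l.items()}


@pytest.fixture
def gly():
    """Glycylglycine-like small solute, exchangeable."""
    return ChemicalSpecies("glycylglycine", 132.12, exchangeable=True,
                           osmotically_active=True)


@pytest.fixture
def trapped_solute():
    """A solute that never leaves its droplet."""
    return ChemicalSpecies("trapped", 1000.0, exchangeable=False,
                           osmotically_active=True)


@pytest.fixture
def mixed_population(gly):
    """50 mM glycylglycine droplets co-incubated with pure-water droplets."""
    drops = []
    for i in range(10):
        if i % 2 == 0:
            am = amounts_at(30.0, glycylglycine=0.05)
            label = "glycylglycine"
        else:
            am, label = {}, "water"
        drops.append(Droplet(f"d{i}", 30.0, am, label=label))
    return Population(drops, [gly], Environment())


def uniform_population(species, n=5, radius=20.0, conc=0.05):
    """Identical droplets: the null control (no gradients anywhere)."""
    name = species[0].name
    drops = [
        Droplet(f"u{i}", radius, amounts_at(radius, **{name: conc}))
        for i in range(n)
    ]
    return Population(drops, species, Environment())
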