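"""Evolution metrics: Price-equation decomposition, polydispersity, and the
trend test used to flag adaptive change.

The central quantity is the Price identity for one generation,

    w̄ · Δz̄ = Cov(w, z) + E(w · Δz),

where ``w_i`` is realised fitness (offspring count), ``z_i`` a quantitative
trait (here: end-of-incubation droplet diameter), ``Δz_i`` the difference
between the mean trait of droplet *i*'s offspring and its own trait, and
all moments are population moments (divide by n).  The covariance term
captures selection, the expectation term captures transmission bias.  The
per-generation environment change Δe is carried alongside the transmission
term as an annotation — it is reported with the decomposition but not
folded into the algebra, since no quantitative coupling is defined.

A population is flagged as *evolving* when the trait change shows a
successive increase over generations: positive rank correlation between
generation index and the tracked series, with at least a configurable
fraction of strictly increasing successive steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PolydispersityStat",
    "PriceTerms",
    "TrendReport",
    "UndefinedDecompositionError",
    "polydispersity",
    "price_decomposition",
    "evolution_trend",
]


class UndefinedDecompositionError(ValueError):
    """Raised when the Price decomposition is undefined (no parent has
    surviving offspring, so mean fitness is zero)."""


@dataclass(frozen=True)
class PolydispersityStat:
    """Droplet-size dispersion: s = std of radius, d = mean radius, ratio = s/d."""

    s: float
    d: float
    ratio: float


def polydispersity(radii: Sequence[float], ddof: int = 1) -> PolydispersityStat:
    """Polydispersity s/d of a set of droplet radii.

    ``s`` is the standard deviation of the radii (sample convention,
    n−1 denominator, by default; set ``ddof=0`` for the population
    convention), ``d`` the arithmetic mean radius.  The ratio is the
    dimensionless coarsening readout tracked over time: it is zero iff
    all radii are equal and is invariant under uniform rescaling.
    """
    r = np.asarray(radii, dtype=float)
    if r.size < 2:
        raise ValueError("polydispersity needs at least 2 radii")
    if not np.all(r > 0):
        raise ValueError("radii must all be > 0")
    s = float(np.std(r, ddof=ddof))
    d = float(np.mean(r))
    return PolydispersityStat(s=s, d=d, ratio=s / d)


@dataclass(frozen=True)
class PriceTerms:
    """One generation's Price decomposition.

    ``identity_residual`` is w̄·Δz̄ − Cov(w,z) − E(wΔz); it vanishes to
    rounding when the fitness-weighted offspring mean is computed from the
    same record, and is reported as a numerical self-check.
    """

    w_bar: float
    z_bar_parent: float
    z_bar_offspring: float
    delta_z_bar: float
    cov_term: float
    transmission_term: float
    delta_e: float
    identity_residual: float
    n_parents: int


def price_decomposition(record) -> PriceTerms:
    """Decompose one generation's trait change into selection + transmission.

    Parameters
    ----------
    record
        Any object with attributes ``z`` (mapping droplet id → parent
        trait), ``w`` (mapping droplet id → offspring count, >= 0),
        ``offspring_traits`` (mapping droplet id → sequence of offspring
        traits, present for every id with w > 0) and ``delta_e`` (float).
        The platform's ``GenerationRecord`` satisfies this.

    Raises
    ------
    UndefinedDecompositionError
        If every parent has zero fitness.
    """
    ids = list(record.z)
    z = np.array([record.z[i] for i in ids], dtype=float)
    w = np.array([record.w.get(i, 0.0) for i in ids], dtype=float)
    if np.any(w < 0):
        raise ValueError("fitness values must be >= 0")
    n = len(ids)
    if n == 0 or not np.any(w > 0):
        raise UndefinedDecompositionError(
            "all parents have zero fitness; mean fitness is zero"
        )
    # per-parent offspring trait mean; only defined where w > 0
    z_off = np.zeros(n)
    for k, i in enumerate(ids):
        if w[k] > 0:
            traits = list(record.offspring_traits[i])
            if len(traits) == 0:
                raise UndefinedDecompositionError(
                    f"parent {i!r} has w > 0 but no recorded offspring traits"
                )
            z_off[k] = float(np.mean(traits))
    w_bar = float(np.mean(w))
    z_bar = float(np.mean(z))
    # population moments (divide by n) — required for the identity to hold;
    # centered form so uniform fitness gives an exactly zero covariance
    cov = float(np.mean((w - w_bar) * (z - z_bar)))
    dz = np.where(w > 0, z_off - z, 0.0)
    trans = float(np.mean(w * dz))
    z_bar_off = float(np.sum(w * z_off) / np.sum(w))
    delta_z_bar = z_bar_off - z_bar
    residual = w_bar * delta_z_bar - cov - trans
    return PriceTerms(
        w_bar=w_bar,
        z_bar_parent=z_bar,
        z_bar_offspring=z_bar_off,
        delta_z_bar=delta_z_bar,
        cov_term=cov,
        transmission_term=trans,
        delta_e=float(getattr(record, "delta_e", 0.0)),
        identity_residual=residual,
        n_parents=n,
    )


@dataclass(frozen=True)
class TrendReport:
    """Result of the successive-change test over generations."""

    direction: int  # sign of the rank correlation: -1, 0, +1
    n_increases: int  # strictly increasing successive pairs
    fraction_increasing: float
    rank_correlation: float  # Kendall tau vs generation index
    evolving: bool


def evolution_trend(values: Sequence[float], cutoff: float = 0.6) -> TrendReport:
    """Test a per-generation series for a successive increase.

    Reports the fraction of strictly increasing successive pairs and the
    Kendall rank correlation of the series with generation index; the
    population is flagged *evolving* when the correlation is positive and
    the fraction of increases reaches ``cutoff`` (default 0.6).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("trend test needs at least 3 generations")
    diffs = np.diff(v)
    n_inc = int(np.sum(diffs > 0))
    frac = n_inc / diffs.size
    tau = stats.kendalltau(np.arange(v.size), v).statistic
    if tau is None or np.isnan(tau):  # constant series
        tau = 0.0
    tau = float(tau)
    direction = int(np.sign(tau))
    return TrendReport(
        direction=direction,
        n_increases=n_inc,
        fraction_increasing=frac,
        rank_correlation=tau,
        evolving=bool(tau > 0 and frac >= cutoff),
    )
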