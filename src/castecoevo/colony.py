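"""Colony-level accounting for an annual eusocial haplodiploid with sperm parasitism.

The life cycle: virgin queens mate with ``m`` males, each allospecific with
probability ``eta`` (the queen's hybridization trait) and conspecific
otherwise.  Mated queens found monogynous colonies and lay a large number of
eggs, a proportion ``f`` diploid.  Hybrid (allospecific-sired) daughters
always develop into workers; nonhybrid daughters develop into workers with
probability ``omega`` (their own genetic caste-determination trait) and into
virgin queens otherwise.  A fraction ``c`` of daughters may instead be
produced by thelytokous parthenogenesis (clones of the queen, counted as
nonhybrid).  Colony workforce weights hybrid workers by an efficiency ``e``,
and the survival of the colony's sexuals scales as workforce**gamma.

This module holds the parameter/trait containers, the deterministic
expected-share bookkeeping (:func:`brood_composition`) and the closed-form
results for fixed hybridization: the caste-determination equilibrium
``omega* = 1/3 - 2*e*eta / (3*(1-eta))`` and the complete worker-loss
threshold ``eta >= 1/(1+2e)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "INFINITE",
    "ModelParams",
    "TraitPair",
    "MateComposition",
    "ColonyOutput",
    "brood_composition",
    "plasticity_equilibrium",
    "worker_loss_threshold",
    "PlasticityEquilibrium",
]

#: Sentinel for an effectively infinite mate number (per-egg independent siring).
INFINITE = math.inf


def _is_infinite(m) -> bool:
    return m is None or m == math.inf


@dataclass(frozen=True)
class ModelParams:
    """Fixed ecological and genetic parameters of a scenario.

    Parameters
    ----------
    m:
        Queen mate number, a positive integer or :data:`INFINITE` (``None``
        is also accepted and normalized to :data:`INFINITE`).
    e:
        Hybrid-worker efficiency relative to nonhybrid workers (>= 0).
        ``e < 1`` models outbreeding depression, ``e > 1`` hybrid vigor.
    f:
        Proportion of diploid (female) eggs, in (0, 1).
    c:
        Fraction of female progeny produced by thelytokous parthenogenesis,
        in [0, 1].  Parthenogenetic daughters are clones of the queen.
    gamma:
        Productivity exponent in (0, 1]; sexual survival scales as
        workforce**gamma.  ``gamma = 1`` is the linear-returns baseline,
        ``gamma < 1`` gives diminishing returns to workforce.
    """

    m: float = INFINITE
    e: float = 1.0
    f: float = 0.5
    c: float = 0.0
    gamma: float = 1.0

    def __post_init__(self):
        m = INFINITE if self.m is None else self.m
        object.__setattr__(self, "m", m)
        if not _is_infinite(m):
            if m < 1 or int(m) != m:
                raise ValueError(f"mate number m must be a positive integer or infinite, got {m}")
            object.__setattr__(self, "m", int(m))
        if self.e < 0:
            raise ValueError(f"hybrid efficiency e must be >= 0, got {self.e}")
        if not 0 < self.f < 1:
            raise ValueError(f"diploid egg proportion f must be in (0, 1), got {self.f}")
        if not 0 <= self.c <= 1:
            raise ValueError(f"parthenogenesis fraction c must be in [0, 1], got {self.c}")
        if not 0 < self.gamma <= 1:
            raise ValueError(f"productivity exponent gamma must be in (0, 1], got {self.gamma}")

    @property
    def infinite_m(self) -> bool:
        return _is_infinite(self.m)


@dataclass(frozen=True)
class TraitPair:
    """A resident or mutant phenotype: (omega, eta).

    ``omega`` is the probability that a nonhybrid female larva develops as a
    worker; ``eta`` the probability that a queen's mate is allospecific.
    """

    omega: float
    eta: float

    def __post_init__(self):
        if not 0 <= self.omega <= 1:
            raise ValueError(f"omega must be in [0, 1], got {self.omega}")
        if not 0 <= self.eta <= 1:
            raise ValueError(f"eta must be in [0, 1], got {self.eta}")

    def as_array(self):
        import numpy as np

        return np.array([self.omega, self.eta])


@dataclass(frozen=True)
class MateComposition:
    """Realized mate composition of a queen.

    ``k`` is the number of conspecific mates among ``m``.  Under infinite
    mate number, pass ``conspecific_fraction`` (= 1 - eta) instead of ``k``.
    """

    k: int | None = None
    m: float = INFINITE
    conspecific_fraction: float | None = None

    def __post_init__(self):
        if _is_infinite(self.m):
            if self.conspecific_fraction is None:
                raise ValueError("infinite m requires conspecific_fraction")
            if not 0 <= self.conspecific_fraction <= 1:
                raise ValueError("conspecific_fraction must be in [0, 1]")
        else:
            if self.k is None:
                raise ValueError("finite m requires k")
            if not 0 <= self.k <= self.m:
                raise ValueError(f"k must be in 0..m, got k={self.k}, m={self.m}")

    @property
    def fraction(self) -> float:
        """Conspecific fraction of the sperm supply."""
        if _is_infinite(self.m):
            return float(self.conspecific_fraction)
        return self.k / self.m


@dataclass(frozen=True)
class ColonyOutput:
    """Expected per-egg shares of colony members and the derived workforce."""

    hybrid_workers: float
    nonhybrid_workers: float
    new_queens: float
    males: float
    workforce: float = field(default=0.0)
    survival_weight: float = field(default=0.0)


def brood_composition(
    traits: TraitPair,
    comp: MateComposition,
    params: ModelParams,
    mother_omega: float | None = None,
) -> ColonyOutput:
    """Expected per-egg composition of a colony.

    ``traits.omega`` is the brood-average worker probability of fertilized
    nonhybrid larvae (equal to the resident omega in a monomorphic
    population); ``traits.eta`` is unused here since the realized mate
    composition ``comp`` already fixes the sperm supply.  Parthenogenetic
    daughters are clones of the mother and develop by ``mother_omega``
    (defaults to ``traits.omega``).
    """
    p = params
    omega_bar = traits.omega
    om_mother = traits.omega if mother_omega is None else mother_omega
    if not 0 <= om_mother <= 1:
        raise ValueError("mother_omega must be in [0, 1]")
    con = comp.fraction
    hybrid = p.f * (1 - p.c) * (1 - con)
    fert = p.f * (1 - p.c) * con
    parth = p.f * p.c
    nonhyb_workers = fert * omega_bar + parth * om_mother
    queens = fert * (1 - omega_bar) + parth * (1 - om_mother)
    males = 1 - p.f
    workforce = p.e * hybrid + nonhyb_workers
    return ColonyOutput(
        hybrid_workers=hybrid,
        nonhybrid_workers=nonhyb_workers,
        new_queens=queens,
        males=males,
        workforce=workforce,
        survival_weight=workforce**p.gamma,
    )


class PlasticityEquilibrium(NamedTuple):
    unclipped: float
    clipped: float


def plasticity_equilibrium(eta: float, e: float) -> PlasticityEquilibrium:
    """Caste-determination equilibrium omega* under fixed hybridization.

    With queens mating with effectively infinitely many males, a fixed
    allospecific fraction ``eta`` and hybrid efficiency ``e``, the worker
    probability of nonhybrid larvae evolves to

        omega* = 1/3 - 2*e*eta / (3*(1 - eta))

    clipped below at 0 (complete worker loss).  ``eta = 1`` is a domain
    error: with no conspecific sperm there are no nonhybrid larvae whose
    development could equilibrate.
    """
    if not 0 <= eta < 1:
        raise ValueError(f"eta must be in [0, 1), got {eta}")
    if e < 0:
        raise ValueError(f"e must be >= 0, got {e}")
    unclipped = 1 / 3 - 2 * e * eta / (3 * (1 - eta))
    return PlasticityEquilibrium(unclipped, max(0.0, unclipped))


def worker_loss_threshold(e: float) -> float:
    """Minimal fixed hybridization eta at which worker loss (omega* = 0) evolves.

    Setting the unclipped equilibrium to zero gives ``eta = 1/(1 + 2e)``:
    with worthless hybrids (e -> 0) only complete hybridization removes
    workers, while efficient hybrids (large e) substitute for nonhybrid
    workers at low hybridization already.
    """
    if e < 0:
        raise ValueError(f"e must be >= 0, got {e}")
    return 1 / (1 + 2 * e)
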