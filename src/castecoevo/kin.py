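"""Kin-selection decomposition of the selection gradients.

The total selection gradient on each trait is split into direct and
relatedness-weighted indirect fitness components in the marginal-fitness
(Taylor-Frank) style.  Rather than assembling relatedness coefficients and
reproductive values by independent bookkeeping, the decomposition
differentiates the same normalized carrier-class transmission matrix that
defines invasion fitness, weighting each entry's perturbation by the left
(reproductive value) and right (class frequency) eigenvectors at
neutrality.  Because every appearance of a mutant phenotype in the matrix
is attributed to exactly one component, the components sum to the total
gradient by construction.

Components follow the recipient classes of the life cycle:

* caste determination (omega, expressed in a larva):
  - ``via self``: the carrier larva's own caste decision (direct);
  - ``via related queens``: the carrier larvae's workforce contribution as
    it changes the survival of sibling queens;
  - ``via related males``: the same workforce contribution as it changes
    the survival of brothers reared in the focal colony.
* hybridization (eta, expressed in a queen):
  - ``via daughter queens``: her mate composition's effect on the
    production and survival of carrier daughter queens;
  - ``via sons``: its effect on the production and survival of her sons.

Pedigree regression-relatedness coefficients are also provided
(:func:`relatedness`); they are descriptive companions -- the decomposition
itself does not consume them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .colony import ModelParams, TraitPair
from .invasion import GRAD_STEP, _Machine, selection_gradient

__all__ = ["RelatednessSet", "FitnessDecomposition", "relatedness", "decompose_gradient"]


@dataclass(frozen=True)
class RelatednessSet:
    """Regression relatedness coefficients under mate number m and thelytoky c.

    Derived from haplodiploid pedigree rules in an outbred population
    (random conspecific mating keeps the equilibrium inbreeding coefficient
    at zero even with clonal parthenogenesis, which preserves but does not
    create identity).  A fraction ``c`` of daughters are clones of their
    mother; sexual full sisters share a father with probability ``1/m``.
    """

    mother_daughter: float
    mother_son: float
    larva_sibling_queen: float
    larva_brother: float


def relatedness(params: ModelParams) -> RelatednessSet:
    """Pedigree regression relatedness for the life cycle's actor-recipient pairs."""
    c = params.c
    # probability two sexual sisters share their (haploid) father
    p_same_father = 0.0 if params.infinite_m else 1.0 / params.m
    mother_daughter = (1 - c) * 0.5 + c * 1.0
    mother_son = 0.5
    # kinship phi between a larva and a sibling, by parthenogenesis status
    phi_both_clonal = 0.5  # two copies of the mother
    phi_mixed = 0.25  # clone of mother vs sexual daughter
    phi_both_sexual = 0.125 + 0.25 * p_same_father  # half sisters + paternal identity
    phi_sib = (
        c * c * phi_both_clonal
        + 2 * c * (1 - c) * phi_mixed
        + (1 - c) ** 2 * phi_both_sexual
    )
    larva_sibling_queen = 2 * phi_sib
    # brother carries one maternal allele; a clonal larva relates to him as the mother does
    larva_brother = (1 - c) * 0.25 + c * 0.5
    return RelatednessSet(mother_daughter, mother_son, larva_sibling_queen, larva_brother)


@dataclass(frozen=True)
class FitnessDecomposition:
    """Labeled additive components of one trait's selection gradient."""

    trait: Literal["omega", "eta"]
    components: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))


def _eigenvectors(a_qq: float, a_qm: float, a_mq: float) -> tuple[np.ndarray, np.ndarray]:
    """Right (class frequency) and left (reproductive value) eigenvectors at lambda=1."""
    u = np.array([a_qm, 1.0 - a_qq])  # (A - I) u = 0 with a_mm = 0
    v = np.array([1.0, a_qm])  # v A = v
    return u, v


def decompose_gradient(
    resident: TraitPair,
    params: ModelParams,
    trait: Literal["omega", "eta"],
    step: float = GRAD_STEP,
) -> FitnessDecomposition:
    """Decompose the selection gradient on ``trait`` at a resident phenotype.

    Each component is the eigenvector-weighted marginal effect of one
    expression pathway of the mutant allele, computed by perturbing only
    that pathway's slot in the transmission matrix (central differences on
    the allelic value, one-sided at trait boundaries).
    """
    mach = _Machine(resident, params)
    a0 = mach.entries()
    A0 = a0.as_array()
    u, v = _eigenvectors(a0.queen_from_queen, a0.queen_from_male, a0.male_from_queen)
    vu = float(v @ u)

    x = resident.omega if trait == "omega" else resident.eta

    def dA(slot: str) -> np.ndarray:
        def at(d: float) -> np.ndarray:
            kw = {slot: d}
            return mach.entries(**kw).as_array() - A0

        h = step
        if h <= x <= 1 - h:
            d1 = (at(h) - at(-h)) / (2 * h)
            d2 = (at(h / 2) - at(-h / 2)) / h
            return (4 * d2 - d1) / 3
        if x < h:
            return (4 * at(h) - at(2 * h)) / (2 * h)
        return -(4 * at(-h) - at(-2 * h)) / (2 * h)

    if trait == "omega":
        d_caste = dA("d_omega_caste")
        d_work = dA("d_omega_work")
        via_self = float(v @ d_caste @ u) / vu
        # workforce pathway split by recipient class of the entry
        queen_mask = np.array([[1.0, 1.0], [0.0, 0.0]])  # rows: into queens / into males
        via_queens = float(v @ (d_work * queen_mask) @ u) / vu
        via_males = float(v @ (d_work * (1 - queen_mask)) @ u) / vu
        comps = {
            "via self": via_self,
            "via related queens": via_queens,
            "via related males": via_males,
        }
    else:
        d_eta = dA("d_eta")
        daughters = np.zeros((2, 2))
        daughters[0, 0] = d_eta[0, 0]  # carrier queen -> daughter queens
        sons = np.zeros((2, 2))
        sons[1, 0] = d_eta[1, 0]  # carrier queen -> sons
        comps = {
            "via daughter queens": float(v @ daughters @ u) / vu,
            "via sons": float(v @ sons @ u) / vu,
        }
    return FitnessDecomposition(trait, comps)
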