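"""Individual-based forward simulation of the caste/hybridization life cycle.

The population is a fixed census of N mated queens.  Each queen carries two
allelic values at each of two unlinked-by-default loci (the caste trait
omega and the hybridization trait eta; phenotype = allelic mean) plus m
sperm slots, each either an allospecific marker or the haploid genome of a
conspecific male.  A generation:

1. expected caste shares per colony from the realized sperm slots
   (hybrid daughters are workers; fertilized nonhybrid daughters develop by
   their own genotype; parthenogenetic daughters are clones of the queen);
2. N daughter queens sampled across colonies with weight
   (queen share x workforce**gamma); within a colony, parthenogenetic vs
   fertilized origin is drawn proportionally, and a fertilized daughter's
   genotype (maternal meiotic product and sire) is drawn conditional on her
   developing as a queen -- a uniform proposal over conspecific slots and
   maternal alleles accepted with probability (1 - omega_larva), which is
   what puts caste under larval genetic control;
3. N males sampled with weight workforce**gamma, one maternal meiotic
   product each;
4. each daughter queen fills her m sperm slots: allospecific with
   probability equal to her own eta phenotype, else a male drawn uniformly
   with replacement from the pool (under infinite m, the pool is stored and
   sires are drawn per egg at the next step);
5. every transmitted allele mutates independently (probability
   ``MutationSpec.rate``, Gaussian effect, clipped to [0, 1]); frozen loci
   skip mutation.

Egg-laying is treated as deterministic expected shares ("a large number of
eggs"); demographic stochasticity enters through colony-level sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .colony import ModelParams

__all__ = [
    "MutationSpec",
    "Population",
    "ExtinctionError",
    "initialize",
    "step",
    "run",
    "RunResult",
    "detect_polymorphism",
]

_LOCI = ("omega", "eta")


class ExtinctionError(RuntimeError):
    """All colonies have zero queen-channel weight; the population is extinct."""

    def __init__(self, generation: int):
        super().__init__(f"population extinct at generation {generation}")
        self.generation = generation


@dataclass(frozen=True)
class MutationSpec:
    """Per-allele per-transmission mutation: probability, effect SD, clipping."""

    rate: float = 0.01
    sd: float = 0.02

    def __post_init__(self):
        if not 0 <= self.rate <= 1:
            raise ValueError(f"mutation rate must be in [0, 1], got {self.rate}")
        if self.sd <= 0:
            raise ValueError(f"mutation effect sd must be > 0, got {self.sd}")


@dataclass
class Population:
    """State of the simulated population: N mated queens (and, under
    infinite m, the male pool from which eggs are sired)."""

    queen_omega: np.ndarray  # (N, 2) allelic values
    queen_eta: np.ndarray  # (N, 2)
    sperm_omega: np.ndarray | None  # (N, m), NaN in allospecific slots
    sperm_eta: np.ndarray | None  # (N, m)
    allo: np.ndarray | None  # (N, m) bool, True = allospecific slot
    pool_omega: np.ndarray | None  # (N,) male pool, infinite m only
    pool_eta: np.ndarray | None
    params: ModelParams
    rng: np.random.Generator
    generation: int = 0
    recombination: float = 0.5

    @property
    def size(self) -> int:
        return self.queen_omega.shape[0]

    @property
    def omega_phenotype(self) -> np.ndarray:
        return self.queen_omega.mean(axis=1)

    @property
    def eta_phenotype(self) -> np.ndarray:
        return self.queen_eta.mean(axis=1)


def initialize(
    N: int,
    omega0: float,
    eta0: float,
    params: ModelParams,
    seed: int,
    recombination: float = 0.5,
) -> Population:
    """Monomorphic population at (omega0, eta0), queens pre-mated consistently
    with eta0, fully determined by ``seed``."""
    if N < 100:
        raise ValueError(f"population size must be >= 100, got {N}")
    if not 0 <= omega0 <= 1 or not 0 <= eta0 <= 1:
        raise ValueError("initial traits must be in [0, 1]")
    if params.c == 0 and eta0 == 0 and omega0 == 0:
        raise ValueError(
            "inviable start: omega=0, eta=0, c=0 colonies have no workers "
            "and zero expected workforce"
        )
    rng = np.random.default_rng(seed)
    q_o = np.full((N, 2), float(omega0))
    q_e = np.full((N, 2), float(eta0))
    if params.infinite_m:
        pop = Population(
            q_o, q_e, None, None, None,
            pool_omega=np.full(N, float(omega0)),
            pool_eta=np.full(N, float(eta0)),
            params=params, rng=rng, recombination=recombination,
        )
    else:
        m = int(params.m)
        allo = rng.random((N, m)) < eta0
        s_o = np.where(allo, np.nan, float(omega0))
        s_e = np.where(allo, np.nan, float(eta0))
        pop = Population(
            q_o, q_e, s_o, s_e, allo, None, None,
            params=params, rng=rng, recombination=recombination,
        )
    return pop


def _mutate(rng, values: np.ndarray, mut: MutationSpec, frozen: bool) -> np.ndarray:
    if frozen or mut.rate == 0:
        return values
    hit = rng.random(values.shape) < mut.rate
    if not hit.any():
        return values
    out = values.copy()
    out[hit] = np.clip(out[hit] + rng.normal(0.0, mut.sd, int(hit.sum())), 0.0, 1.0)
    return out


def _colony_stats(pop: Population):
    """Per-colony expected shares and weights from realized sperm slots."""
    p = pop.params
    om_q = pop.omega_phenotype
    eta_q = pop.eta_phenotype
    if p.infinite_m:
        con = 1.0 - eta_q
        pool_mean = float(pop.pool_omega.mean())
        om_fert = (om_q + pool_mean) / 2  # mean over maternal alleles and pool sires
    else:
        m = int(p.m)
        k = m - pop.allo.sum(axis=1)
        con = k / m
        sire_sum = np.nansum(pop.sperm_omega, axis=1)
        sire_mean = np.divide(sire_sum, k, out=np.zeros_like(sire_sum), where=k > 0)
        om_fert = np.where(k > 0, (om_q + sire_mean) / 2, 0.0)
    hybrid = p.f * (1 - p.c) * (1 - con)
    fert_w = p.f * (1 - p.c) * con * om_fert
    parth_w = p.f * p.c * om_q
    W = p.e * hybrid + fert_w + parth_w
    S = W**p.gamma
    queen_fert = p.f * (1 - p.c) * con * (1 - om_fert)
    queen_parth = p.f * p.c * (1 - om_q)
    return queen_fert, queen_parth, S


def _sample_fertilized(pop: Population, mothers: np.ndarray):
    """Caste-conditioned draw of (maternal omega-allele index, sire) per daughter.

    Uniform proposal over the mother's two omega alleles and her conspecific
    sperm slots (or the male pool under infinite m), accepted with
    probability 1 - omega_larva so that queen-destined daughters are
    enriched for queen-biasing genotypes.
    """
    rng = pop.rng
    n = len(mothers)
    a_idx = np.zeros(n, dtype=np.int64)
    sire_o = np.zeros(n)
    sire_e = np.zeros(n)
    pending = np.ones(n, dtype=bool)
    p = pop.params
    if not p.infinite_m:
        m = int(p.m)
        # conspecific slot indices packed to the front, column-stable
        order = np.argsort(pop.allo, axis=1, kind="stable")
        k = m - pop.allo.sum(axis=1)
    for _ in range(10_000):
        idx = np.flatnonzero(pending)
        if idx.size == 0:
            break
        mom = mothers[idx]
        a = rng.integers(0, 2, idx.size)
        if p.infinite_m:
            s = rng.integers(0, pop.pool_omega.size, idx.size)
            s_om = pop.pool_omega[s]
            s_et = pop.pool_eta[s]
        else:
            slot = order[mom, rng.integers(0, k[mom])]
            s_om = pop.sperm_omega[mom, slot]
            s_et = pop.sperm_eta[mom, slot]
        om_larva = (pop.queen_omega[mom, a] + s_om) / 2
        accept = rng.random(idx.size) >= om_larva
        acc = idx[accept]
        a_idx[acc] = a[accept]
        sire_o[acc] = s_om[accept]
        sire_e[acc] = s_et[accept]
        pending[acc] = False
    else:  # pragma: no cover - requires a brood with all-queen-proof genotypes
        raise RuntimeError("fertilized-daughter sampling failed to converge")
    return a_idx, sire_o, sire_e


def step(
    pop: Population,
    mut: MutationSpec | None = None,
    freeze: Sequence[str] = (),
) -> Population:
    """Advance the population one generation in place-free fashion."""
    mut = mut or MutationSpec()
    p = pop.params
    rng = pop.rng
    N = pop.size
    freeze = tuple(freeze)
    for locus in freeze:
        if locus not in _LOCI:
            raise ValueError(f"unknown locus to freeze: {locus!r}")

    queen_fert, queen_parth, S = _colony_stats(pop)
    queen_weight = (queen_fert + queen_parth) * S
    total_q = queen_weight.sum()
    if not total_q > 0:
        raise ExtinctionError(pop.generation)

    mothers = rng.choice(N, size=N, p=queen_weight / total_q)
    p_parth = np.zeros(N)
    nz = queen_weight[mothers] > 0
    p_parth[nz] = (queen_parth[mothers] * S[mothers])[nz] / queen_weight[mothers][nz]
    is_parth = rng.random(N) < p_parth

    new_q_o = np.empty((N, 2))
    new_q_e = np.empty((N, 2))
    # parthenogenetic daughters: exact clones of the mother
    pi = np.flatnonzero(is_parth)
    if pi.size:
        new_q_o[pi] = pop.queen_omega[mothers[pi]]
        new_q_e[pi] = pop.queen_eta[mothers[pi]]
    fi = np.flatnonzero(~is_parth)
    if fi.size:
        a_idx, sire_o, sire_e = _sample_fertilized(pop, mothers[fi])
        mom = mothers[fi]
        # maternal eta allele: same chromatid as the omega allele unless recombined
        swap = rng.random(fi.size) < pop.recombination
        b_idx = np.where(swap, 1 - a_idx, a_idx)
        new_q_o[fi, 0] = pop.queen_omega[mom, a_idx]
        new_q_o[fi, 1] = sire_o
        new_q_e[fi, 0] = pop.queen_eta[mom, b_idx]
        new_q_e[fi, 1] = sire_e
    new_q_o = _mutate(rng, new_q_o, mut, "omega" in freeze)
    new_q_e = _mutate(rng, new_q_e, mut, "eta" in freeze)

    # male pool: one son (maternal meiotic product) per sampled colony
    total_s = S.sum()
    if not total_s > 0:
        raise ExtinctionError(pop.generation)
    fathers_of = rng.choice(N, size=N, p=S / total_s)
    a2 = rng.integers(0, 2, N)
    swap2 = rng.random(N) < pop.recombination
    b2 = np.where(swap2, 1 - a2, a2)
    pool_o = pop.queen_omega[fathers_of, a2]
    pool_e = pop.queen_eta[fathers_of, b2]
    pool_o = _mutate(rng, pool_o, mut, "omega" in freeze)
    pool_e = _mutate(rng, pool_e, mut, "eta" in freeze)

    # mating of the new queens
    eta_phen = new_q_e.mean(axis=1)
    if p.infinite_m:
        return Population(
            new_q_o, new_q_e, None, None, None, pool_o, pool_e,
            params=p, rng=rng, generation=pop.generation + 1,
            recombination=pop.recombination,
        )
    m = int(p.m)
    allo = rng.random((N, m)) < eta_phen[:, None]
    mate = rng.integers(0, N, (N, m))
    s_o = np.where(allo, np.nan, pool_o[mate])
    s_e = np.where(allo, np.nan, pool_e[mate])
    return Population(
        new_q_o, new_q_e, s_o, s_e, allo, None, None,
        params=p, rng=rng, generation=pop.generation + 1,
        recombination=pop.recombination,
    )


@dataclass
class RunResult:
    """Per-generation trait summaries and periodic haplotype samples."""

    traits: pd.DataFrame  # generation, mean_omega, sd_omega, mean_eta, sd_eta
    haplotypes: pd.DataFrame  # generation, haplotype_id, omega_allele, eta_allele
    extinct: bool = False
    extinct_generation: int | None = None


def _sample_haplotypes(pop: Population, n: int) -> np.ndarray:
    """n maternal meiotic products (omega, eta allelic values) from random queens."""
    rng = pop.rng
    who = rng.choice(pop.size, size=n, replace=False)
    a = rng.integers(0, 2, n)
    swap = rng.random(n) < pop.recombination
    b = np.where(swap, 1 - a, a)
    return np.column_stack([pop.queen_omega[who, a], pop.queen_eta[who, b]])


def run(
    params: ModelParams,
    mut: MutationSpec | None = None,
    N: int = 1000,
    generations: int = 1000,
    omega0: float = 0.5,
    eta0: float = 0.0,
    sample_every: int = 100,
    sample_size: int = 20,
    seed: int = 0,
    freeze: Sequence[str] = (),
    recombination: float = 0.5,
) -> RunResult:
    """Simulate ``generations`` steps and collect summaries; reproducible from seed."""
    pop = initialize(N, omega0, eta0, params, seed, recombination)
    mut = mut or MutationSpec()
    rows = []
    haplo = []
    extinct = False
    extinct_gen = None
    for g in range(generations + 1):
        om, et = pop.omega_phenotype, pop.eta_phenotype
        rows.append(
            (pop.generation, om.mean(), om.std(), et.mean(), et.std())
        )
        if sample_every and g % sample_every == 0:
            hap = _sample_haplotypes(pop, min(sample_size, pop.size))
            for i, (ho, he) in enumerate(hap):
                haplo.append((pop.generation, i, ho, he))
        if g == generations:
            break
        try:
            pop = step(pop, mut, freeze)
        except ExtinctionError as err:
            extinct = True
            extinct_gen = err.generation
            break
    traits = pd.DataFrame(
        rows, columns=["generation", "mean_omega", "sd_omega", "mean_eta", "sd_eta"]
    )
    haplotypes = pd.DataFrame(
        haplo, columns=["generation", "haplotype_id", "omega_allele", "eta_allele"]
    )
    return RunResult(traits, haplotypes, extinct, extinct_gen)


def _two_means_split(values: np.ndarray) -> tuple[float, float]:
    """Optimal 1-D two-cluster split (minimum within-cluster sum of squares)."""
    x = np.sort(values)
    n = len(x)
    if n < 2 or np.ptp(x) == 0:
        return float(x.mean()), float(x.mean())
    csum = np.cumsum(x)
    tot = csum[-1]
    best, best_i = np.inf, 1
    for i in range(1, n):
        left = csum[i - 1]
        sse = -(left**2) / i - (tot - left) ** 2 / (n - i)
        if sse < best:
            best, best_i = sse, i
    return float(x[:best_i].mean()), float(x[best_i:].mean())


def detect_polymorphism(
    haplotypes: pd.DataFrame,
    min_distance: float = 0.3,
    fraction: float = 0.8,
    trait: str = "eta_allele",
) -> tuple[bool, tuple[float, float]]:
    """Two-means test for persistent bimodality of haplotype trait values.

    Polymorphic when the two cluster means are more than ``min_distance``
    apart in at least ``fraction`` of the epochs in the final quarter of the
    sampling series.  Returns the flag and the cluster means of the final
    epoch.
    """
    gens = np.sort(haplotypes["generation"].unique())
    if len(gens) < 20:
        raise ValueError(f"need >= 20 sampling epochs, got {len(gens)}")
    modes = {
        g: _two_means_split(haplotypes.loc[haplotypes["generation"] == g, trait].to_numpy())
        for g in gens
    }
    last_quarter = gens[-max(1, len(gens) // 4):]
    split = [abs(modes[g][1] - modes[g][0]) > min_distance for g in last_quarter]
    flag = bool(np.mean(split) >= fraction)
    return flag, modes[gens[-1]]
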