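# castecoevo

Coevolution of genetic caste determination and interspecific sperm
parasitism in annual eusocial haplodiploids (ants and relatives), for
researchers in social evolution and adaptive dynamics.

## The model

A large population of annual, monogynous eusocial haplodiploids. Virgin
queens mate with `m` males; each mate is allospecific with probability `η`
(the queen's hybridization trait) and conspecific otherwise. A proportion
`f` of eggs is diploid. Hybrid (allospecific-sired) daughters can only
develop into sterile workers; nonhybrid daughters develop into workers with
probability `ω` — under the control of the **larva's own genotype** — and
into virgin queens otherwise. A fraction `c` of daughters may instead be
produced clonally by thelytokous parthenogenesis. The colony workforce is

```
W = e·f(1−c)·η̄  +  f(1−c)(1−η̄)·ω̄  +  f·c·ω_queen
```

where `e ≥ 0` weighs hybrid-worker efficiency (outbreeding depression for
`e < 1`, hybrid vigor for `e > 1`), and the probability that any of the
colony's sexuals reaches reproduction scales as `W^γ` (`γ = 1`: linear
returns).

Both traits evolve by rare mutations of weak additive effect. The package
provides:

- **closed forms** (`castecoevo.colony`): with hybridization fixed at `η`,
  caste determination equilibrates at `ω* = 1/3 − 2eη/(3(1−η))`, and
  complete worker loss (`ω → 0`) evolves for `η ≥ 1/(1+2e)`;
- **invasion analysis** (`castecoevo.invasion`): invasion fitness as the
  spectral radius of a 2×2 carrier-class (queen/male) transmission matrix,
  selection gradients and Hessians (including the correlational term),
  trajectory integration, singular-point classification (repellor /
  attractor-ESS / attractor-branching), worker-loss stability, and
  parameter-space outcome maps;
- **kin-selection decomposition** (`castecoevo.kin`): the gradients split
  into direct and relatedness-weighted indirect components (larval caste:
  via self / related queens / related males; queen hybridization: via
  daughter queens / sons), summing exactly to the total gradient;
- **individual-based simulation** (`castecoevo.ibm`): a stochastic
  forward simulator of the full life cycle (diploid queens, stored sperm,
  mutation, caste-conditioned inheritance) with haplotype sampling and a
  bimodality test for queen polymorphism.

## Worked example

```python
from castecoevo import (ModelParams, TraitPair, plasticity_equilibrium,
                        integrate_trajectory, worker_loss_stable)

# fixed hybridization: the caste equilibrium and worker-loss threshold
print(plasticity_equilibrium(0.2, 1.0).clipped)   # 0.16666666666666666
# coevolution with efficient-enough hybrids: an arms race to worker loss
tr = integrate_trajectory(TraitPair(1/3, 0.0), ModelParams(m=None, e=0.7))
print(tr.endpoint)                                 # TraitPair(omega=0.0, eta=0.666666...)
# monandry + parthenogenesis: worker loss with complete hybridization
print(worker_loss_stable(ModelParams(m=1, e=0.9, c=0.4)))
# WorkerLossState(eta_hat=1.0, stable=True, viable=True)
```

The first line is the selected probability that a nonhybrid larva becomes a
worker when a fifth of matings are allospecific and hybrids work as well as
nonhybrids. The trajectory shows the queen–larva arms race: starting from
the no-hybridization baseline `(ω, η) = (1/3, 0)`, hybridization by queens
and royal-cheat alleles in larvae escalate until nonhybrid workers are lost
(`ω = 0`) and hybridization stabilizes at `η = 2/3`. The last line shows
that with thelytoky (`c = 0.4`) even a monandrous species evolves stable
worker loss with complete sperm parasitism (`η = 1`).

The numbered scripts under `analysis/` reproduce the full set of analyses
(equilibrium grids, phase portraits, kin decompositions, outcome maps over
mate number and parthenogenesis, and simulations) and write tab-separated
tables under `results/`. The CLI exposes the same operations:
`castecoevo equilibrium`, `castecoevo phase-portrait --e 0.7`, etc.

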