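# Methods

## Model and assumptions

We model an annual eusocial haplodiploid with nonoverlapping generations,
monogynous colonies and a large population. Two coevolving quantitative
traits: `ω`, the probability that a nonhybrid female larva develops as a
worker (expressed by the larva's own genotype), and `η`, the probability
that any one of a queen's `m` mates is allospecific (expressed by the
queen). Hybrid daughters are obligate workers (assumed fully sterile as
queens); their work is weighted by an efficiency `e`. A fraction `c` of
daughters is produced by thelytokous parthenogenesis, modeled as strictly
clonal: the daughter inherits the mother's full diploid genotype, so her
caste follows the mother's `ω` phenotype and she counts as a nonhybrid.
Egg laying is treated as deterministic expected shares (large broods); a
proportion `f` of eggs is diploid. Sexual survival to reproduction scales
as `W^γ` where `W` is the colony workforce; `γ = 1` (linear returns) is the
default and `γ < 1` implements diminishing returns as a power law — a
deliberately simple stand-in whose qualitative effect (worker loss becomes
easier) is the only claim we test.

Allospecific males are an infinite external pool: hybridization has no
feedback on the partner lineage, and allospecific fathers are outside the
focal gene pool.

## Invasion fitness

Both traits evolve by rare mutations of weak additive effect at two
unlinked loci (one per trait); a heterozygote expresses the mean of its
allelic values. A rare mutant allele occupies two demographic classes —
heterozygous queens and hemizygous males — and its dynamics are linear
while rare. We therefore take invasion fitness as the spectral radius of
the 2×2 between-generation transmission matrix of allele copies:

- a carrier queen's mate composition is binomial, `k ~ Bin(m, 1 − η_x)`
  with `η_x` her heterozygote phenotype (deterministic fractions under
  infinite `m`, realized as per-egg independent siring);
- she passes the allele to half her fertilized daughters, to all her
  parthenogenetic daughters and to half her sons. Within her brood, half
  the fertilized nonhybrid larvae carry the allele and develop by the
  heterozygote `ω` phenotype, so both the carrier caste factors and the
  brood-average workforce use the within-brood mixture;
- a carrier male fathers heterozygous daughters in resident colonies. His
  expected matings are proportional to `m(1 − η)`; conditional on
  occupying one slot, the queen's other `m − 1` slots are conspecific with
  probability `1 − η` each, and each fertilized egg takes him as sire with
  probability `1/m`. His daughters' caste uses the heterozygote phenotype
  and their (infinitesimal at infinite `m`, 1/m-weighted at finite `m`)
  work contribution enters the colony workforce;
- males have no sons (arrhenotoky), so the male→male entry is zero and
  the spectral radius is available in closed form;
- every output is weighted by the natal colony's `W^γ` and divided by the
  corresponding resident class total, which makes the resident allele
  exactly neutral (spectral radius 1 to machine precision) for all
  parameter values — our core correctness check.

Colonies whose queen-production weight is zero (for example `ω = 0` with
only conspecific sperm and `c = 0`) contribute only through sons; if the
entire resident queen channel (or male channel) vanishes, the resident is
inviable and the engine raises an explicit error. This reproduces the
biological statement that under monandry without parthenogenesis a
worker-lost population cannot exist: a conspecifically mated queen then
produces only queen-destined larvae and no workers.

Derived consequences we verified against the model's closed forms: the
fixed-hybridization equilibrium `ω* = 1/3 − 2eη/(3(1−η))` and its
worker-loss boundary `η = 1/(1+2e)`; the selected hybridization at worker
loss `η̂ = 2/3` (infinite `m`, `c = 0`); destabilization of `η = 0` at
`e = 1/2` and worker-loss stability from `e = 1/4` (infinite `m`); and the
finite-`m` baseline `ω*(η=0) = (m+1)/(3m+1)`, which we derived analytically
from the same matrix and froze as an independent test oracle (monandry
gives 1/2 — queen and larval interests align — and `m → ∞` recovers 1/3).

## Gradients, stability, trajectories

Selection gradients are derivatives of `log λ` with respect to the mutant
allelic value, by Richardson-extrapolated central differences with step
1e-4 on the allelic scale; at trait boundaries we use second-order
one-sided stencils restricted to feasible mutant directions. The mutant
Hessian (including the mixed, correlational-selection term) uses central
second differences with step 1e-3: the second-difference roundoff at step
1e-4 (~1e-8) would be uncomfortably close to the smallest branching
eigenvalues we need to resolve (~1e-4 near the monandry threshold), while
1e-3 keeps truncation near 1e-6 and roundoff near 1e-10.

Convergence stability is judged by the eigenvalues of the Jacobian of the
gradient field in resident space; evolutionary stability by negative
semidefiniteness of the mutant Hessian (tolerance 1e-6 on the leading
eigenvalue). Trait-substitution trajectories are Euler paths along the raw
gradient (equal, unbiased mutational input on both traits — the model
states no asymmetry), step 1e-2 by default, clipped to the unit square,
terminating when the boundary-projected gradient norm falls below 1e-6.
Singular points are found by multistart root-finding (`scipy.optimize.root`,
hybr) from an interior grid, deduplicated at 1e-4, with interior defined by
a 5e-3 margin.

Region maps label each parameter cell by analytic conditions, in priority
order: *internal-attractor* if an interior convergence-stable point exists;
*worker-loss-always* if the worker-loss state is uninvadable **and** `η = 0`
is unstable; *bistable* if worker loss is uninvadable but `η = 0` is
stable; *plasticity-maintained* otherwise. These conditions are the
definitions of the outcomes, so we use them directly; an optional
`confirm_bistable` mode additionally verifies bistable cells by integrating
trajectories from a 5×5 grid of initial conditions (exercised in tests on
sample cells rather than at full map scale, where it is redundant).

## Kin-selection decomposition

The decomposition differentiates the same transmission matrix, weighting
entry perturbations with the left (reproductive value) and right (class
frequency) eigenvectors at neutrality — the marginal-fitness form
`dλ = v·dA·u / (v·u)`. Each appearance of the mutant phenotype in the
matrix belongs to exactly one pathway: for `ω`, the carrier larva's own
caste factors (*via self*), its workforce contribution inside
queen-producing entries (*via related queens*) and inside the son entry
(*via related males*); for `η`, the queen's mate composition inside the
daughter-queen entry (*via daughter queens*) and the son entry (*via
sons*). Components therefore sum to the total gradient by construction
(verified to 1e-6 against the independently computed gradient).
Relatedness enters implicitly through carrier frequencies among recipients;
the explicit pedigree coefficients exposed by `relatedness()` (outbred
regression relatedness; clonal parthenogenesis preserves but does not
create identity, so equilibrium inbreeding is zero under random conspecific
mating) are descriptive companions. Note that the mother→son coefficient
is 1/2 independent of `c`, since sons are always arrhenotokous.

## Individual-based simulator

The simulator is the stochastic oracle for the analytic engine and the
package's synthetic-data generator. A population is exactly N mated queens;
each queen stores two allelic values per locus and `m` sperm slots
(allospecific marker or a conspecific male's haploid genome). Colony
expected shares follow the deterministic accounting with the realized
slots; N daughter queens are sampled across colonies with weight
(queen share × `W^γ`), and N males with weight `W^γ`.

Within a colony, a queen-destined fertilized daughter's genotype is drawn
*conditional on her becoming a queen*: a uniform proposal over maternal
`ω` alleles and conspecific sires is accepted with probability
`1 − ω_larva` (rejection sampling). This conditioning is what implements
larval genetic control of caste — without it, selection on `ω` would act
only between colonies and the no-hybridization equilibrium would sit at
the queen optimum 1/2 instead of 1/3. The acceptance step uses
pre-mutation allelic values; the resulting bias is of order
(mutation rate × effect SD) ≈ 2e-4 per generation and is ignored.

Mutation: each transmitted allele mutates with probability 0.01, Gaussian
effect with SD 0.02, clipped to [0, 1]; these rates equilibrate runs within
~10^4 generations at N = 1000–2000, the scale used throughout the tests.
Free recombination (0.5) between the loci is the default, configurable down
to full linkage; haplotype samples report maternal meiotic products (20
every 100 generations by default). Under infinite `m`, sires are drawn per
egg from the stored previous-generation male pool. All runs are fully
reproducible from a single seed.

What the simulator does and does not emulate: it reproduces the model's
life cycle exactly (including demographic stochasticity and mutation-
selection-drift balance at two loci), but real colonies have environmental
caste determination, finite broods, overlapping generations, spatial
structure and responsive partner species, none of which are represented.
Agreement between simulation and analytics therefore validates the
derivation, not the model's realism.

Problem sizes: analytic agreement is tested at N = 2000 over 4000
generations (fixed hybridization) and N = 1000 over 8000 generations
(coevolution endpoints), where time-averaged trait means match predictions
within 0.05. Evolutionary branching under monandry with efficient hybrids
is a weak disruptive effect (leading Hessian eigenvalue ~5e-3 at e = 1.5):
at N ≤ 2000 incipient branches are repeatedly erased by drift, and
persistent coexistence of the two queen types (η modes near 0.1 and 0.9)
emerges at N = 10,000 with linked loci over ~4×10^4 generations — the
`--paper-scale` option of `analysis/06_simulations.py`. The test suite
asserts the branching *conditions* (invadable attractor, positive
correlational term) analytically and validates the bimodality detector on
constructed series.

## Known limitations

- The diminishing-returns productivity function is a power law chosen for
  simplicity; only the qualitative enlargement of the worker-loss region
  is claimed or tested.
- Stability at trait boundaries is assessed through one-sided derivatives;
  degenerate cases where the gradient vanishes identically along a
  boundary are classified as stable.
- The interior-attractor bound at `m ≤ 4` is grid-resolved (efficiency
  grids of step ≤ 0.1); we did not attempt a symbolic proof.
- No evolution of `m`, `f` or `c`; no worker reproduction, polygyny or
  inquiline parasitism; epistatic caste architectures are outside the
  model's additive framework.
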