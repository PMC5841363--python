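# Methods

## Model

A well-mixed haploid population of fixed size `N`. Individual `i` is a
triplet `(H_i, S_i, K_i)`: expressed phenotype, behavioral strategy
(cooperate `S=1` / defect `S=0`), and capacitor volume. Capacitors are
nested — volume `K` means phenotypes `{1, …, K}` — so a strain of larger
volume can always express every phenotype of a smaller one. This convention
is what produces the phenotype-matching probabilities used throughout: a
mutant of volume `K_Y` expresses the resident's phenotype with probability
`1/K_Y` when `K_Y ≥ K_X`, and covers it at all with probability `K_Y/K_X`
when `K_Y < K_X` (resident phenotypes are uniform over their capacitor at
state formation).

Individuals expressing the same phenotype form a subpopulation. Public
goods games of group size `g` happen only inside subpopulations, and only
when the subpopulation size `n` reaches `g`. Each member of such a
subpopulation plays `χ(n) = slope · n` games in expectation, each with
`g − 1` co-players drawn uniformly without replacement from the other
`n − 1` members. With `j` cooperators among `n`, the expected per-game
payoffs are the hypergeometric averages

    cooperator:  (r/g) · c · (1 + (g−1)(j−1)/(n−1)) − c
    defector:    (r/g) · c · (g−1) j/(n−1)

Every individual additionally pays the capacitor cost `θ K_i`. Fitness is
`f_i = e^{β π_i}`. Updating is Moran: fitness-proportional birth, uniform
death over all `N` incumbents (including the reproducer), constant `N`.
With probability `μ` the offspring is a fresh mutant (uniform strategy,
uniform volume on `{1…M}`, uniform phenotype within the new capacitor);
otherwise it inherits the parent's full triplet, *including the expressed
phenotype*. Heritable expression is essential: it is what makes phenotype
membership lineage-stable between mutations, so that a pairwise competition
stays in one of exactly two regimes (shared phenotype or disjoint
phenotypes) until it resolves. We verified the alternative —
re-expression from the capacitor at every birth — destroys the assortment
mechanism entirely (cooperation collapses to ~0.27 at μ=0.01 under the
default conditions), which contradicts everything else the model predicts.

## Fixation probabilities

For a single mutant strain vs a monomorphic resident, the number of mutants
is a birth–death chain with

    T_{i,i+1} = i f_A / (i f_A + (N−i) g_B) · (N−i)/N
    T_{i,i−1} = (N−i) g_B / (i f_A + (N−i) g_B) · i/N

where the payoffs entering `f_A = e^{βP_A}`, `g_B = e^{βP_B}` depend on the
regime. Shared phenotype: both types sit in one subpopulation of size `N`
and the hypergeometric formulas above apply with `(n, j)` determined by
`(N, i)` and the two strategies. Disjoint phenotypes: two subpopulations of
sizes `i` and `N − i`, each a pure group, so `P_A = χ(i)(r−1) c S_A ·
1[i ≥ g] − θK_A` and symmetrically for the resident.

The fixation probability of one mutant is the classical product formula,
evaluated as

    φ_1 = 1 / Σ_{l=0}^{N−1} exp( β Σ_{k≤l} (P_B(k) − P_A(k)) )

with the inner sums accumulated directly and the outer sum done by
`logsumexp`. No fitness value is ever exponentiated on its own, so large
`β` or large interaction rates (χ slope 5 gives payoffs of order 400)
cannot overflow. Identical strains give a term-by-term zero exponent and
hence exactly `1/N`, bit-stably. Two independent oracles guard this module:
defector–defector competitions admit the closed form
`(1 − e^{βθΔK}) / (1 − e^{NβθΔK})` (constant selection), and arbitrary
queries are checked against a dense solve of the full first-step linear
system.

## Embedded strain chain

In the rare-mutation limit the population hops between `2M` monomorphic
strain states (defector/cooperator × volume `1…M`; defectors at odd
1-based positions `2K−1`, cooperators at even `2K`). The rate from resident
`X` to mutant strain `Y` mixes the two fixation regimes by the
phenotype-matching probabilities above, carries the factor ½ for the
uniform strategy draw, and (uniform volume draw and `μ` being common to all
off-diagonal entries) is scaled by `1/M` so that row sums stay ≤ 1 — a
global scale provably cancels in the stationary distribution, and a test
confirms invariance. Diagonal entries complete each row to 1.

The stationary distribution is taken as the left eigenvector with
eigenvalue closest to 1 (negatives below 1e−12 clipped, renormalized) and
must agree to 1e−8 with an independent bordered null-space solve of
`πᵀ(A − I) = 0, Σπ = 1`; the residual `‖πA − π‖∞` must stay below 1e−10 or
the routine raises. The overall cooperation level is the mass on
cooperative strains; the optimal cooperator volume is the mode of the
cooperative mass profile. A Monte-Carlo jump-chain simulation serves as an
end-to-end oracle in the tests.

The volume cap `M = 50` is the default strain-space bound; cooperation
levels change by under 10⁻³ when `M` is moved to 40 or 60 at θ = 0.12
because large-volume strains carry negligible stationary mass whenever
θ > 0 (the acceptance tests scan this).

## Agent-based simulator

The simulator realizes the full process for any `μ` and doubles as the
package's synthetic-data generator: its defaults are the study conditions
`N=40, r=3.2, g=5, c=1, β=0.1, θ=0.12, M=50, χ(x)=0.1x`. Two payoff
realizations are provided.

* **sampled** (default): each subpopulation of size `n ≥ g` holds
  `χ(n)·n/g` explicit games per step (fractional counts rounded
  stochastically), each with `g` members drawn uniformly without
  replacement; a member therefore plays `χ(n)` games in expectation and the
  realized payoff is an unbiased draw around the expected-payoff formulas
  (a test verifies unbiasedness). This is the physical process the analytic
  machinery approximates and the mode used for all finite-mutation results.
* **expected**: every individual deterministically receives the
  composition-averaged payoff. This mode matches the payoff functions
  inside the analytic transition probabilities term by term, so empirical
  fixation frequencies are unbiased estimates of the analytic fixation
  probabilities; it is the mode used for the simulator-vs-theory oracle
  tests. It is also roughly 3× faster.

The distinction matters quantitatively away from the rare-mutation limit.
At μ = 0.01 a mutant arrives every ~100 steps while a selective sweep takes
thousands, so several mutant lineages segregate concurrently and the
embedded-chain picture (at most two strains at a time) is already strained.
Under these conditions the expected-payoff mode equilibrates near 0.88
mean cooperator fraction, the sampled mode near 0.85–0.86, and the
rare-mutation chain predicts 0.820 — game-sampling noise weakens the
per-step selection signal and moves the simulator toward the analytic
prediction. Either way the deviation from the chain is a genuine
finite-mutation effect, not a discretization artifact: in pairwise
competitions (the regime the chain is built from) the simulator reproduces
the analytic fixation probabilities within three binomial standard errors.

Run lengths: the mutation-robustness numbers use 10⁶ burn-in plus 10⁷
measured steps per seed and three seeds; at those sizes the across-seed
standard deviation of the μ = 0.01 cooperation level is about 0.01–0.02
(the macro-state sojourns are long), while μ = 0.5 is stable to ±0.001.
Seeded runs are bit-reproducible; the hot loop uses numba's MT19937 stream
seeded per run.

## Coarse diversity states

Average capacitor volumes are classified Low/Middle/High on the half-open
intervals `(0, 5]`, `(5, 40]`, `(40, 50]` (defaults matching `M = 50`;
edges configurable). The simulator reports time occupancy of
strategy × band states; single-trajectory transition statistics between
those coarse states are deliberately not summarized further — they are
run-specific and depend strongly on the aggregation window, so only the
interval classifier itself is part of the tested surface.

## Numerical and design choices

* `H(0) = 1` in the volume-comparison branch of the transition rate (a tie
  uses the `α_Y = 1/K_Y` matching branch).
* Within a pairwise competition the phenotype regime is fixed for the whole
  sweep `i = 1…N−1`; regimes can only change through mutation, which the
  fixation calculation excludes by construction.
* The cooperation cost `c` is kept explicit (default 1).
* χ is linear with configurable slope; payoff formulas take χ values, so a
  different functional form only requires replacing `ModelParams.chi`.
* Config `precision` controls significant digits in TSV/CSV output
  (default 6); outputs are byte-identical across re-runs of the same
  config and seed.
* Degenerate inputs are rejected loudly: mutant counts outside `[1, N−1]`,
  volumes outside `[1, M]`, `r` outside `(1, g)`, row sums exceeding 1,
  negative stationary entries beyond clip tolerance, and solver
  disagreement all raise.

## What the tests do and do not show

The test suite validates the analytic machinery against independent
oracles, the simulator against the analytic machinery in the pairwise
regime, and both against the reference cooperation levels at the study
conditions. The model itself is deliberately stylized: a well-mixed
population, one expressed phenotype per individual, linear capacitor costs,
uniform mutation over the whole strain space, and expected- or
sampled-payoff public goods games without spatial or group structure.
Agreement at the study conditions therefore says nothing about structured
populations, biased mutation kernels, or nonlinear cost schedules; those
are outside the implemented scope.

Known limitation: at intermediate mutation rates (μ around 0.01–0.05) the
simulated cooperation level sits a few hundredths above the rare-mutation
chain value and is sensitive to run length because macro-state sojourns
are long; comparisons at those rates should use several seeds and ≥10⁷
steps, as the acceptance script does.
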