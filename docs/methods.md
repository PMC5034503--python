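# Methods

## The problem

Models that couple metabolism with macromolecular expression (ME-type
models) extend the steady-state flux balance `S v = 0, v^L <= v <= v^U`
with *dilution constraints*: at specific growth rate `mu` (1/h), every
macromolecule pool (ribosomes, RNA polymerase, charged tRNA, enzyme
complexes) is diluted by growth, so its synthesis flux must cover
`mu x abundance`, where abundance is itself proportional to the fluxes
the molecule supports.  Each such constraint has the form

    b_i' v - mu c_i' v  {=, >=}  0,

bilinear in `(mu, v)`.  Growth maximization is therefore a nonlinear
program.  Two structural facts make it tractable:

1. **Quasilinearity.**  For fixed `mu` each constraint is linear, and
   the set of feasible growth rates is an interval `[0, mu*]`: the
   ratio `b_i'v / c_i'v` has convex level sets, so feasibility can only
   be lost, never regained, as `mu` rises.  Any convergent ascent
   scheme therefore finds the *global* optimum.
2. **Multiscale coefficients.**  Machinery coefficients (peptide
   lengths over catalytic constants, inverse effective rate constants)
   span 12+ orders of magnitude, and optimal fluxes span comparably
   many.  Standard double-precision LP tolerances (~1e-9) are close to
   the magnitude of meaningful fluxes, which produces false
   infeasibilities and corrupted variability ranges.  The package
   therefore solves everything in software extended precision.

## Machinery constraint families

`model_core.build_dilution_rows` instantiates four families from
per-reaction annotations and a constant set `(c_ribo, kappa_tau, r0,
k_eff, c_tRNA, c_mRNA)`; the growth-rate dependence `(mu +
r0*kappa_tau)` of the machinery rows expands into a constant part
(entering `b`) and a `mu`-proportional part (entering `c`):

| family   | b-coefficient on the driving flux    | c-coefficient                  |
|----------|--------------------------------------|--------------------------------|
| ribosome | `-l_p,i r0 / c_ribo` on translation  | `l_p,i / (c_ribo kappa_tau)`   |
| RNAP     | `-l_TU,i r0 / (3 c_ribo)` on transcription | `l_TU,i / (3 c_ribo kappa_tau)` |
| tRNA j   | `-r0 / c_tRNA,j` on charging         | `1 / (kappa_tau c_tRNA,j)`     |
| enzyme j | (none; +1 on the dilution flux only) | `1 / k_eff_ij` on usage        |

Every row carries `+1` on its dilution reaction in `b` and defaults to
sense `>=` (synthesis may exceed dilution); `=` is selectable per row.
`c_mRNA` has no displayed machinery row of its own; the package uses it
for the generic `mu`-proportional mRNA-dilution rows emitted by the
synthetic generator, exercising the "additional mu-affine constraint"
hook.  Only coefficients affine in `mu` are supported; empirically
fitted non-affine growth dependencies are out of scope.

All model coefficients are exact rationals (`gmpy2.mpq`) and are
serialized as decimal strings (or exact `p/q` strings when the value
has no finite decimal expansion), so file round-trips never round.

## Fixed-growth reduction

`fix_mu` substitutes `mu` into every dilution row and **pins the growth
reaction's flux to `mu`** by intersecting its bounds with `[mu, mu]`
(an empty intersection yields an infeasible LP).  Pinning is essential:
growth demand must scale with the candidate `mu`, otherwise `v = 0`
would be feasible at every growth rate and feasibility search would be
vacuous.  The objective maximizes the growth flux (constant under
pinning, and the natural objective when a caller relaxes the pin).

## Extended-precision simplex (`xlp`)

A deterministic two-phase bounded-variable revised simplex over
`gmpy2.mpfr` arithmetic.  The `ArithmeticContext` fixes the precision
(34 significant digits by default, the precision of IEEE binary128)
and the feasibility/optimality tolerances (1e-15 extended, 1e-9 in the
native-double mode).  Numerical choices:

* **Phase 1** minimizes the total bound violation of basic variables
  with the textbook piecewise-linear costs (+/-1 on violated basics);
  this needs no artificial columns and warm-starts naturally.  Big-M
  was rejected: a penalty large enough to dominate a 12-order
  coefficient range would itself poison the arithmetic.
* **Pricing** is Dantzig's rule, switching to Bland's rule after 50
  consecutive degenerate pivots and back after any real step; ratio-test
  ties break toward the lowest variable index.  Determinism everywhere.
* The **basis inverse** is dense, refreshed by Gauss-Jordan elimination
  every 60 pivots (and at every warm start).  Dense is the right trade
  at the intended scale (hundreds of columns); with ~1e-34 unit
  roundoff the product-form updates lose nothing measurable between
  refreshes.
* **Warm starts** repair rather than reject: statuses are retained
  (mapped by structural/slack position when shapes differ), surplus
  basics are demoted, rank-deficient basic sets are completed by slacks
  in row order, and dependent columns found during factorization are
  replaced by slacks of uncovered rows.
* **Scaling** mode "2" is iterative geometric-mean row/column scaling
  (up to 10 alternating passes or until factors move < 10 %), followed
  by a final column pass normalizing the largest entry per column, with
  all factors rounded to powers of two so scaling is exactly
  invertible.  In extended precision scaling is objective-neutral (a
  tested property); it exists for parity with double-precision runs.
* Every `optimal` solution carries a **residual report** (primal row
  residual, bound violation, dual infeasibility, complementarity)
  recomputed against the *unscaled* input data; the test suite asserts
  the report against the context tolerances on every solve it makes.

`vertex_oracle` is the independent correctness reference: exact
rational enumeration of all active-set candidates for LPs with at most
8 variables/rows, with missing bounds replaced by a huge exact box (an
optimum that moves when the box is enlarged is reported unbounded).  It
shares no code path with the simplex.

## Growth search (`bisect_search`)

`feasible_at` wraps the fixed-`mu` LP; its infeasibility measure is the
phase-1 objective.  `bisect_me` brackets `mu*` from a default interval
of `[0, 2]` 1/h:

* **binary**: exactly `ceil(log2((b-a)/eps))` halvings, one LP each,
  every LP warm-started from the previous basis.  From `[0, 2]` to
  `eps = 1e-15` this is 51 iterations, which is why bisection alone is
  a poor route to full precision.
* **golden**: golden-section search needs a scalar objective, but the
  underlying problem is pure feasibility.  The package maximizes the
  surrogate `f(mu) = mu - 1e6 * infeasibility(mu)`: `f` rises with unit
  slope on the feasible interval and falls steeply beyond it (the
  phase-1 infeasibility grows with `mu`), so `f` is unimodal with
  maximizer `mu*`.  The surrogate is this package's reconstruction of
  how a section search can drive a feasibility sequence; probe points
  are quantized to 160-bit dyadic rationals so exact coefficient
  arithmetic stays cheap.

An unexpectedly feasible upper bracket is extended by doubling (at most
four times); an infeasible lower bracket is an error.

## High-precision refinement (`nlp_solve`)

`solve_me` is coarse search + sequential linearization (SLP):

1. `bisect_me` (golden by default) to `decimals_coarse` (default 1)
   yields `mu0` strictly below `mu*` plus a compatible basis.  One
   coarse decimal is the default because more coarse work buys little:
   the refinement converges from any underestimate, just faster from a
   near one.  Zero decimals also works (tested) but wastes refinement
   steps.
2. Each major iteration linearizes `g_i = b_i'v - mu c_i'v` about the
   current `(mu_k, v_k)`, giving the row
   `(b_i - mu_k c_i)'v - (c_i'v_k)(mu - mu_k) {sense} 0`, adds `mu` as
   a column bounded by a trust region, links `v_growth = mu`, and
   maximizes `mu`.
3. A proposed `mu_c` is **accepted only after a feasibility-restoration
   LP at fixed `mu_c` succeeds**; the accepted point then satisfies
   every nonlinear row to the solver feasibility tolerance by
   construction.  Rejections halve the `mu` trust region (init
   `0.5 * max(mu0, 0.1)`, doubled after two consecutive full steps).
   Restoration-based acceptance was chosen over testing the bilinear
   residual at the raw linearized point: the latter forces trust
   regions of order sqrt(tol) and cannot reach 1e-15 in realistic time,
   while both schemes share the same fixed points (at convergence the
   linearization is exact in `v` and the step is zero).
4. The *next expansion point* is the linearized LP's own solution, not
   the restoration vertex: the restoration objective is degenerate
   (growth is pinned), and an arbitrary feasible vertex can carry a
   wastefully large dilution load `c_i'v`, which appears as the `mu`
   coefficient of the next linearized row and throttles the step.  The
   linearized LP, maximizing `mu`, selects a dilution-efficient `v`.
   The restoration solution is still what `v_star` reports, so the
   returned point is certified feasible.
5. Convergence: `|mu_{k+1} - mu_k| <= mu_tol` (default 1e-15), with a
   forward feasibility probe before exit so a stalled linearization
   cannot cause a premature stop; alternatively the trust region
   collapsing below `mu_tol/4` pins `mu*` within tolerance directly.

Starting at `mu0 > mu*` makes the first restoration infeasible; the
solver restarts from `mu0/2`, at most five times, and reports the
restart count.  Starting at `mu0 = 0` converges, only more slowly —
both safeguard paths are exercised in the tests.  This SLP scheme
replaces a full projected-Lagrangian NLP code on purpose: the only
nonlinearity is the single scalar `mu`, so the heavier machinery has
nothing to add at the fixed point.

## Variability, knockouts, magnitudes (`variability`)

`vary_me` fixes `mu = fraction * mu*` (growth pinned through the
bounds) and solves min/max per reaction — exactly two LPs per reaction,
basis chained linearly in model column order (no reordering
heuristics).  Warm and cold modes provably return the same ranges
(tested to 1e-12); warm mode just pivots less.  Because `mu*` is
certified feasible only to `feas_tol`, pinning at exactly `mu*` can sit
a hair beyond the true optimum and make boundary subproblems chatter
between verdicts; on such a failure the target is backed off by
`8 * feas_tol` (at most twice) — a perturbation far below reporting
precision.

`knockout_screen` zeroes both bounds of a gene's translation reactions
and solves one feasibility LP per gene at a fixed `mu_test` (default
use: half the wild-type optimum; the package makes no claim about the
"right" viability threshold).  A baseline-infeasible `mu_test` is
reported as `no_growth_baseline` for every gene rather than declaring
everything essential.

`flux_magnitude_summary` filters `|v| > feas_tol`, reports per-category
floor-of-log10 exponents for the smallest and largest surviving flux,
the median and mean, and the global `log10(max/min)` span.

## Design scan (`design_scan`)

The three-step overproduction protocol: (1) growth maximization of the
knockout strain; (2) FVA restricted to the two pathway
complex-formation reactions at growth fixed to a small fraction
(default 0.05) of the mutant optimum, giving each pathway's expression
capacity; (3) an 11 x 11 grid (default fractions 0.05..0.95) of forced
lower bounds on the two complex-formation fluxes, re-maximizing growth
at each point.  Recorded per point: `mu_max`, product exchange flux,
**molar** yield (product flux over absolute substrate uptake — the
mass-based alternative would just rescale by a molecular-weight ratio),
the pathway translation-flux ratio, and proteome sector mass fractions
(translation rate x molecular weight, normalized).  Infeasible grid
points are recorded and skipped.

## Synthetic models (`synthetic`)

The generator exists to give every solver component a fixture with a
known answer:

* **analytic** — four reactions, one enzyme dilution row, closed form
  `mu* = U / (a_bio + m U / k_eff)`; defaults `U=10, a_bio=10, m=1,
  k_eff=100` give `mu* = 10/10.1`.  The closed form is derived by
  making the uptake bound and the dilution row simultaneously tight.
* **coupled complex** — two translation products whose only sink is a
  1:1 complex that catalyzes uptake; any feasible point has equal
  translation fluxes, so FVA must return identical ranges, and at
  `mu*` the whole expression chain is uniquely determined (zero
  variability).  Deterministic.
* **two pathway** — an essential uptake enzyme plus two redundant
  energy pathways that co-secrete a product (growth-coupled
  production); exercises essential/nonessential verdicts and the grid
  scan.  The pathway complex-formation fluxes carry a finite capacity
  bound so that forcing both to 95 % of capacity stays inside the
  substrate budget and the full 121-point grid is feasible.
* **multiscale** — a seeded random model instantiating all four
  machinery families plus generic mRNA-dilution rows.  Uptake is
  bounded at 1000 mmol/gDW/h (the free-uptake convention, so proteome
  cost — not an arbitrary uptake limit — caps growth); `a_bio` is set
  to `1000 / mu_cap` with `mu_cap` drawn in [0.5, 1.2], which makes the
  model feasible at `mu = 0`, infeasible at `mu = 2`, and `mu*` land
  inside the default bracket.  Peptide lengths are uniform on 50..1500
  amino acids; `k_eff` is log-uniform with the top decade pinned at
  `10^(span-5)` so the flux span reaches the requested
  `magnitude_span_orders` (default 14) deterministically.  Feasibility
  is by construction, not rejection sampling: the balance system with
  all dilution rows tight and growth pinned at `mu_cap/4` is square and
  is solved *exactly* in rationals at generation time; a negative
  template flux or uptake above its bound is a generator error.  The
  seed and the template's observed span are stored in the metadata, and
  identical seeds produce byte-identical JSON.

What the generator does **not** emulate: real stoichiometry (the
network is a demand tree, not a genome-scale graph), degenerate
alternative optima at `mu*` beyond what the coupled fixture encodes,
mRNA degradation, non-affine growth dependence of machinery
coefficients, and thermodynamic or regulatory constraints.  Passing
tests therefore demonstrate numerical correctness of the solution
stack on models with the right *structure and conditioning*, not
biological accuracy of any particular prediction.

## Problem sizes and tolerances used in the shipped checks

The bundled test suite and the reproduction script run the multiscale
family at its defaults (8 peptides, 4 transcription units, 3 tRNAs, 4
enzymes: 38 reactions, 37 constraint rows, coefficients spanning >= 12
orders), 200 random exact-oracle LPs with 2-5 variables, 20 random
analytic-fixture parameter draws, and an 11 x 11 expression grid on the
two-pathway fixture — sizes chosen so the whole battery completes in a
few minutes on one core while still exercising the multiscale
conditioning the package exists for.  All extended-precision runs use
feasibility and optimality tolerances of 1e-15 at 34 significant
digits; exact-rational routes (model data, oracle, templates) have no
tolerance at all.

## Known limitations

* Dense basis handling puts a practical ceiling of a few thousand
  columns; genome-scale ME models need a sparse LU and are out of
  scope at desk scale.
* The golden-section surrogate penalty (1e6) is heuristic; a model
  whose phase-1 infeasibility grows extremely slowly in `mu` could in
  principle distort the section search (bisection and the SLP refiner
  are unaffected).
* `solve_me` reports `mu*` feasible to `feas_tol`; callers pinning
  growth at exactly that value inherit the boundary-chatter issue that
  `vary_me` handles via its backoff.
* Double-precision mode exists for comparison, not production: on the
  multiscale fixtures it exhibits exactly the pathologies (false
  infeasibility near `mu*`, crossed FVA ranges) that motivate extended
  precision.
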