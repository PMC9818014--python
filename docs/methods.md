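# Methods

This note documents the model conventions, numerical choices and known
limitations of `fjordweb`. Units throughout: biomass in t·km⁻², rates
in year⁻¹, flows in t·km⁻²·year⁻¹.

## Input conventions and the bundled data set

A model is two tables: a group table (`name, role, biomass, pb, qb,
ee, landings`, optionally `unassimilated`, `biomass_accumulation`) and
a prey-by-predator diet table. Empty biomass/EE cells are unknowns for
the balance solver; at most one of the two per living group.

The bundled Francisco Coloane tables give the diet matrix in absolute
consumption units. Three of its printed column totals (Fuegian sprat
66.08, squat lobster 158.8, mesozooplankton 844.3) exceed the
consumption implied by the same source's `B·(Q/B)` by 9–19%. The
package therefore treats the matrix as defining diet *proportions*
only — each consumer column is normalized by its own total — and takes
absolute consumption from `B·(Q/B)`. This convention reproduces the
source's own whole-system consumption (1470.6), every one of its
estimated biomasses, and all twenty trophic levels to ±0.01; the
`validate` function reports the three inconsistent columns as
warnings. The printed flow-to-detritus column is kept for cross-checks
only.

Defaults: unassimilated fraction 0.2 for consumers, 0 otherwise (the
conventional value, and the one that reproduces the source's
flow-to-detritus entries, e.g. killer whales 0.109); biomass
accumulation and migration 0 (the model represents a 2007–2017 steady
state); a single detritus pool with trophic level 1; diet imports
supported (assigned trophic level 1) but zero in the bundled data.

## Mass balance

All unknown biomasses satisfy one linear system (predators of an
unknown-biomass prey may themselves have unknown biomass); remaining
EEs follow by substitution. A solved `B ≤ 0` or `EE ∉ [0, 1]` raises an
"unbalanced model" error naming the group, as does negative
respiration `(1−GS)Q − P < 0`. The global solve makes the result
independent of group ordering (tested by permutation) and gives a
clean singularity diagnostic. Balance residuals on exactly balanced
synthetic webs are < 1e−8 relative; the bundled tables, printed to
three decimals, close to ~0.1%.

Derived EEs for groups whose only mortality is a tiny printed flow
(seabirds, penguins: predation entries of 0.001 on a production of
order 0.001–0.02) inherit the full rounding error of those cells and
can differ substantially from the source's internal values; they feed
nothing downstream that is reported.

Detritus is balanced last: inflow = Σ(GS·Q + (1−EE)·P), outflow =
detritivory + export, with the surplus reported as export.

## Trophic levels and the Lindeman spine

The trophic-level fixed point is solved as a linear system with
producers/detritus pinned at 1; cannibalistic diet entries (benthos,
cephalopods, long-tailed hake in the bundled web) stay in the system.
The discrete-level decomposition iterates the diet recursion ~200
steps beyond the cap so that mass circulating in cannibal loops is
assigned, then folds the remainder into the cap level; rows sum to 1
within 1e−9. Aggregate per-level flow weights each group's fraction by
its throughflow (consumption for consumers, production for producers,
inflow for detritus). When no mass reaches the cap, the
fraction-weighted mean level equals the fractional trophic level
exactly (tested).

## Network indicators

Total system throughput (TST) is consumption + respiration + flows to
detritus + exports. Finn's cycling index uses the structure matrix
`S = (I − G)⁻¹` of the inflow-normalized flow network (predation flows
plus flows into the detritus pool; external inputs are primary
production and imports): recycled throughput is
`Σ_j (S_jj − 1)/S_jj · T_j` and FCI is its percentage of TST. Finn's
mean path length is TST/(primary production + imports). The
detritus-flow bookkeeping of the original GUI tools is not exactly
recoverable from printed tables, so FCI on the bundled web is treated
as accurate to a few tenths of a percentage point.

## Mixed trophic impacts

Direct impact of `i` on `j` combines the bottom-up benefit (fraction
of `i` in `j`'s diet) and the top-down cost (`i`'s share of `j`'s
total mortality, catches included when the fleet node is on). The
detritus pool "consumes" each group's detrital flow (inflow shares)
and exerts no mortality; the fleet node (on by default when landings
exist) has the landings composition as its diet. Total impacts are the
closed form `(I − q)⁻¹ − I`. On webs with strong plankton–detritus
loops the spectral radius of `q` can exceed 1 — the impact-chain
series then diverges term-by-term while the closed form remains
well-conditioned and is the conventional quantity; the implementation
errors only when `I − q` is numerically singular. On the bundled web
this matrix reproduces the reported impact structure of both forage
species (sign and approximate magnitude of every stated interaction).

## Centrality

The trophic graph is binary and undirected over living groups
(detritus excluded, `link_threshold = 0`); directed prey/predator
counts feed the degree index (self-loops counted once). Closeness is
`1/Σd` with unreachable pairs excluded; betweenness is the standard
pair-fraction sum. Raw scores are emitted alongside mean-normalized
degree, `(n−1)/Σd` and max-rescaled closeness, and pair-normalized
betweenness. The standardizations used by the GUI network tool behind
the source's printed table are not documented and are not reproduced;
note that in the consumption matrix itself the mid-web groups
(cephalopods 17 links, southern hake 16, squat lobster 15) are more
connected than the apex predator (killer whales, 10), so rankings that
place the apex predator first in degree/closeness/betweenness cannot
be derived from these inputs. In this package's graph the squat
lobster is the top betweenness node with the Fuegian sprat second, and
the squat lobster leads the forage groups in closeness.

## Dynamics

Per-link consumption uses the foraging-arena form
`C_ij = a v B_i B_j / (2v + a B_j)` with exchange rate
`v_ij = X·Q⁰_ij/B⁰_i` and `a_ij` calibrated so each link reproduces
its balanced flow at baseline. The vulnerability multiplier `X`
(default 2, must exceed 1) caps each predator's per-capita intake at
`X` times baseline: `X → ∞` recovers mass action, `X → 1` total donor
control. Producers grow as `P⁰·2x/(1+x)` (`x = B/B⁰`; equal to
baseline production at baseline, saturating at twice it); consumer
production is growth efficiency `P⁰/Q⁰` times realized consumption;
non-predation mortality is `P⁰(1−EE)/B⁰`. The detritus pool is
integrated alongside the groups with an arbitrary standing stock
(default 10 t·km⁻²; the calibration absorbs its scale) and a linear
export closing its baseline budget. With this calibration the balanced
model is an exact, locally stable equilibrium of the unforced system
(Jacobian leading eigenvalue −0.02 yr⁻¹ on the bundled web).

Integration is fixed-step RK4 on the reporting step (default 1/12 yr)
with automatic substepping so that `(P/B + Q/B)·h ≤ 0.5` — the
plankton groups turn over at 150–200 yr⁻¹ and dictate the substep.
Biomass is floored at 1e−6 of baseline; a group that touches the floor
is reported as collapsed. Halving the step changes 10-year outcomes by
< 0.5% (tested).

Fishery scenarios: "removal of x% of the biomass" is implemented by
default as a constant annual yield of `x·B⁰` (t·km⁻²·yr⁻¹), so a
shrinking stock faces rising effective mortality — under this reading
the 50% squat-lobster scenario drives the stock to collapse within a
few years while the 10% and 25% scenarios find depressed equilibria,
matching the qualitative behaviour reported for this system. The
alternative reading, a constant fishing mortality `F = −ln(1−x)`, is
available (`standard_scenarios(..., mode="rate")`); with the default
vulnerability it produces depletion without collapse, because the
arena form lets per-capita food intake at most double. Scenario
magnitudes depend on the unreported vulnerabilities and should be read
as directions, not predictions. Forcings start at year 1 by default.

## Synthetic webs

The generator draws a cascade topology (ordered groups, consumers eat
strictly lower-ranked groups; optional mild cannibalism capped so
self-consumption cannot outrun production; optional detritivory by the
lowest consumers), Dirichlet diet fractions, rates from user ranges
(consumption floored at 1.3·(P/B)/0.8 to keep respiration positive),
and assigns biomasses from the top down so each preyed-upon group's EE
falls in a target interval — the result balances exactly by
construction. A masked variant hides a recoverable subset of
biomasses for solver-recovery tests (groups whose EE arises purely
from cannibalism are never masked; their balance row is degenerate).
What these webs do not emulate: the empirical rate correlations,
size-structured diet breadth, multiple detritus pools or import-fed
diets of real systems — passing recovery tests on them demonstrates
algebraic correctness of the solver, not realism of any particular
parameterization. Default sizes (8–10 groups) keep the test suite
fast; the pipeline itself has no size constraint of that order.

## Reported problem sizes

The acceptance script and test suite run the full 21-group bundled
model for all steady-state quantities; dynamic scenarios run the
21-group model for 30 years at the default step; property tests use
6–10-group synthetic webs and graphs of up to 12 nodes (where
exhaustive path enumeration is practical as an oracle).
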