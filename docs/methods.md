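# Methods

## The cell model

`ductsim` models the epithelium of a milk duct as a single layer of cells on
a cylindrical square lattice: rings of `circumference` cells (default 15)
stacked axially, each cell with four neighbors (ring-left, ring-right, and
the same position in the two adjacent rings). Periodic axial boundaries
(a torus) are the default so that every cell keeps exactly four neighbors
and all cells are statistically identical — the symmetry that makes the
deterministic approximations one- and two-cell computations instead of
whole-lattice ones. Demonstration grids use a 20×20 torus for the same
reason.

Each cell is in one of nine states: healthy `H`, mutated `M1`–`M6`
(1–6 growth-relevant mutations), cancerous `C` (the seventh mutation,
absorbing — a single surviving cancerous cell is taken to found a tumour),
or dead `D` (removed and replaced by a healthy cell at the next renewal
step). Three per-timestep probabilities drive the dynamics:

| parameter | meaning | units |
|---|---|---|
| `p_mut` | next growth-relevant mutation occurs and is stable | per timestep |
| `p_die` | cell death (apoptosis, mitotic catastrophe, immune removal) | per timestep |
| `p_spr` | spreading weight per neighbor mutation: a neighbor in `M_n` takes the cell over with weight `n·p_spr` | per timestep |

The stay probability is always derived, `s = 1 − (p_mut + p_die)`. The
timestep is one month; a lifetime horizon (ages 0–89) is 1080 steps.

**Local update rule.** Intrinsic transitions and overgrowth compete through
competing-rates normalization: with total neighborhood spreading weight
`W = Σ_j n_j·p_spr` and `γ = 1/(1+W)`, the cell follows its intrinsic
column with weight `γ` and is overgrown by neighbor `j` with probability
`γ·n_j·p_spr`. Cancerous and dead cells cannot be overgrown; cancerous
cells do not spread (spreading a state that already decides the outcome
would not change the quantity of interest). Overgrowth copies the
neighbor's state regardless of the current one, so a heavily mutated cell
can be overwritten by a less mutated neighbor.

A deliberate consequence of this choice: the printed mean-field recursion
(below) treats overgrowth events as independent per-neighbor firings,
which differs from the competing-rates lattice rule at second order in
`p_spr`. The lattice rule is the model definition here; both
approximations are judged against it.

## Monte Carlo engine

Synchronous update: every cell's next state is drawn from the local update
distribution applied to the previous configuration. Each trial owns an RNG
stream spawned from the master seed (`numpy` `SeedSequence`), so
trajectories are reproducible and unchanged when the trial count grows.
One uniform draw per cell per step suffices: scaled to `(0, 1+W)` it
selects intrinsic-vs-overgrowth and the within-branch outcome exactly.
Correctness is tested against brute-force enumeration of all configuration
paths on a 3-cell ring.

## Single-cell (mean-field) approximation

Tracks one cell's marginal `P_t(s)` under the independence assumption
(inter-cell correlations dropped, interactions kept):

    P_t(s) = Σ_r P_{t−1}(r) · (u_s + ρ[s,r]·v)
    u_s = 1 − (1 − P_{t−1}(s)·τ_s)^4        τ_s = n·p_spr for s = M_n
    v   = (1 − Σ_q P_{t−1}(q)·τ_q)^4

applied to overgrowable source states; `C` and `D` follow the intrinsic
table alone. The u/v decomposition double-counts simultaneous multi-state
overgrowth events (an `O(p_spr²)` effect), so the step renormalizes its
output; in the two-state demo the decomposition is exactly normalized and
renormalization is a no-op. With `p_spr = 0` the recursion is the exact
single-cell Markov chain, verified against matrix powers to 1e-10 at
t = 240.

Counts follow from exchangeability: `E[N_s] = N·p_s`,
`Var[N_s] = N·p_s(1−p_s)`, and the full count distribution is
`Binomial(N, p_s)` — the default family for overlap comparisons because it
is the exact consequence of the independence assumption.

## Neighboring-cells (pair) approximation

Keeps the joint distribution `P(q, r)` of an ordered pair of adjacent
cells besides the marginal. Longer-range joints close by the decoherence
assumption — a Markov chain along a path of neighboring cells:

    P(y_1, …, y_m) = Π_i P(y_i, y_{i+1}) / Π_interior P(y_i)

The pair update is not uniquely determined by that closure; the
construction used here is: each cell of the pair updates with a
conditional kernel `T(a | r; y)` in which the partner's state `y` is known
exactly and the three outer neighbors are drawn iid from the conditional
neighbor law `P(z | r)` implied by the pair table. The competing-rates
local rule is averaged *exactly* over those outer configurations
(enumerating state multisets), rather than through the independent-firing
shortcut — with the γ-normalized lattice rule as ground truth this is the
consistent choice, and on the strong-interaction demo it is what brings
the predicted mean within a fraction of a Monte Carlo standard deviation.
The joint then updates as

    P'(a, b) = Σ_{r,y} P(r, y) · T(a|r; y) · T(b|y; r)

which keeps the table symmetric and exactly marginal-consistent, after
clipping negatives (roundoff) and renormalizing. With `p_spr = 0` the
method collapses to the exact chain with independent pairs.

**Count variance.** The full pairwise sum over the tissue is truncated at
lattice distance `D = 4` (`M_d = 4d` cells at distance `d` on the
four-neighbor cylinder). For each `d` the closed-chain probability
`P(X_1 = s, X_{1+d} = s)` is evaluated through the decoherence chain
product — efficiently as `(P·K^{d−1})[s,s]` with `K[y,y'] = P(y,y')/p_y` —
and the independent-cells product `p_s²` is subtracted inside the sum, so
the independence limit returns exactly `N·p_s(1−p_s)`. Divisors are
floored at 1e-15 and a zero interior marginal carrying nonzero pair mass
raises a closure-degeneracy error. The pair count distribution for overlap
comparisons is a discretized normal with this variance (only moments are
available). On a 15×3 torus the truncated variance lands within a few
percent of the Monte Carlo variance in the weak-interaction regime.

## Demo comparisons

The two-state model {H, C} (internal transition `ρ_CH`, spreading `τ_CH`,
C absorbing and — unlike the nine-state model — spreading) exercises the
approximations: *weak* interaction (ρ = 0.05, τ = 0.01) and *strong*
interaction (ρ = 0.01, τ = 0.05), compared against 1000 Monte Carlo
trials of a 20×20 torus at t = 20. Agreement is scored by the
Bhattacharyya coefficient on unit-width integer bins over the shared
support, with no smoothing of the empirical histogram. Under these
conditions the weak regime scores ≈0.98–0.99 for both methods and the
strong regime ≈0.95–0.96 for the pair method, while the single-cell
method fails by design in the strong regime (its mean is several standard
deviations high because it ignores the clustering of cancerous cells,
which wastes spreading on already-cancerous neighbors); its unit-bin
overlap score is ≈0.02–0.04, additionally depressed by the sparseness of
a 1000-trial histogram relative to a smooth prediction.

## Incidence layer

The observed reference is the 2018 Japanese registry of breast-cancer
cases per 100,000 by 5-year age group. A fixed 5-year lag separates the
first stable cancerous cell from diagnosis, so the observed table is
shifted down one group before use. The lagged rates are summarized by the
smooth fit

    λ(a) = 300 · a⁸/(35⁸ + a⁸) · exp[−(a/85)⁶]

(cases per 100,000 per year; Hill-type rise to a mid-life plateau of
~255–266 around ages 45–62, then senescent decline) and radiation
exposure multiplies it by `1 + R(a, d)` with the dose-linear excess
relative risk

    R(a, d) = 5.2 · d · 25/(a − 10)

applied only once attained age reaches exposure age + lag (the
age-at-menarche-12 scenario). Scenario tables evaluate each group at its
integer midpoint `age_low + 2` and round; groups entirely before the
exposure age keep the observed rates. These conventions reproduce the
exposed reference table (0.1 Gy at age 30) integer-for-integer from group
30–34 through the open 85– group.

Model output maps to incidence through the first-event CDF
`F(t) = 1 − (1 − P_C(t))^N` (cells exchangeable; computed via `log1p` /
`expm1` for tiny `P_C` and large `N`), shifted by the lag; a group's rate
is `100000·[F(end) − F(start)] / width` — i.e. rates are interpreted as
annual first-event incidence per 100,000. Any constant convention factor
here is absorbed by the calibration.

## Calibration

`steepest_descent_fit` minimizes the summed squared *relative* difference
between predicted and target group rates (a per-100k squared-difference
mode is also available) over `(p_mut, p_die, p_spr)`, or over the
exposure-window triple with the baseline fixed. The descent runs in
log-parameter space: the probabilities span orders of magnitude and the
boundary `p_mut = 0` is a degenerate stationary point in raw space (the
all-zero prediction) that otherwise captures the iteration. Gradients are
central finite differences (`h = 1e-3` in log units), the line search
backtracks from twice the previously accepted step (initial step 0.15 log
units), box constraints are projected after the exponential map, and the
loss trace is monotone non-increasing by construction.

The loss surface has at least two distinct basins: a degenerate one whose
prediction is a flat rate matching the harmonic level of the data, and a
clonal-expansion basin in which mutant clones grow slowly
(`p_spr` near-critical against `p_die`), producing a rate curve that rises
over decades. The clonal-expansion basin is narrow and is reached reliably
from starts whose prediction *overshoots* the data (the relative loss then
pulls the level down along the valley), whereas undershooting starts
descend into the flat basin; the default starting point (0.003, 0.3, 0.03)
is therefore placed in the supercritical overshoot regime — a natural
choice for what is in essence a lattice-quantified two-stage
clonal-expansion model. Seeded log-normal multi-start (`n_starts`,
spread 0.5 around `x0`) is available for unfamiliar targets. Fitted this
way the baseline prediction rises monotonically toward the oldest groups
and therefore overestimates them while underestimating ages 35–49: the
model family cannot reproduce the observed post-menopausal decline in
incidence, as expected from its constant renewal and time-independent
transition probabilities.

The strongest available correctness evidence for the optimizer is
parameter recovery on self-generated targets (tested on a reduced horizon,
ages 0–50 with N = 10⁵, from a perturbed start). Published fitted values
for this kind of model are not reproduction targets: optimizer
conventions are not part of the model, and reported parameter/loss pairs
in the source material are internally inconsistent.

## Problem sizes and numerical choices

* Monte Carlo demos: 1000 trials, 400 cells, 20 steps; enumeration oracle:
  3-cell ring, 2 steps, 10⁵ trials, 4-standard-error band.
* Deterministic engines: lifetime horizon 960–1080 monthly steps; the pair
  step enumerates 165 outer-neighbor multisets for k = 9 (4 for k = 2) and
  costs ~0.5 ms.
* Calibration experiments: N = 10⁶ cells, pair engine, 14 age groups
  (15–19 … 80–84; the open 85– group is excluded from fitting), ~25
  descent iterations per start.
* Tolerances: state distributions renormalized each step and checked to
  1e-10; pair marginal consistency holds to machine precision by
  construction; degenerate conditional rows fall back to the singles
  vector.

## What the generator does and does not emulate

Synthetic inputs are generated by the model itself (all-healthy start,
fixed parameters, optional exposure window), so passing tests demonstrate
internal consistency of engines, closures and calibration — not biological
realism. Known limitations, deliberate here: a single epithelial cell
type on a fixed regular lattice; constant renewal with no age dependence;
time-independent probabilities outside the exposure window; spreading as
instantaneous neighbor replacement; all breast cancer treated as ductal
carcinoma arising in this one tissue; no dose-rate or radiation-quality
structure beyond the linear ERR scenario.
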