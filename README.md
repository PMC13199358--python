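# ductsim

A cell-based model of radiation-induced breast carcinogenesis in the milk
duct, with fast deterministic approximations of its stochastic dynamics.

Ductal carcinoma develops in the epithelial monolayer lining the milk
ducts. `ductsim` idealizes that layer as a cylindrical square lattice of
cells, each in one of nine states — healthy (`H`), carrying 1–6
growth-relevant mutations (`M1`–`M6`), cancerous (`C`, absorbing), or dead
(`D`, renewed to healthy). Per monthly timestep a cell mutates with
probability `p_mut`, dies with probability `p_die`, keeps its state with
`s = 1 − (p_mut + p_die)`, and can be overgrown by a mutated neighbor in
state `M_n` with weight `n·p_spr` (clonal expansion on a fixed lattice),
resolved by competing-rates normalization `γ = 1/(1 + ΣW)`.

The package provides, for this model family:

* a synchronous **Monte Carlo** engine (the ground truth),
* the **single-cell approximation** — mean-field propagation of one cell's
  marginal `P(X(t)=s)` under the independence assumption,
* the **neighboring-cells (pair) approximation** — propagation of adjacent
  pair joints under the decoherence closure, with a distance-truncated
  count variance,
* an **incidence layer** — 5-year lag shift, fitted baseline hazard
  `λ(a) = 300·a⁸/(35⁸+a⁸)·exp[−(a/85)⁶]`, dose-linear excess relative risk
  `R(a,d) = 5.2·d·25/(a−10)`, and the map from per-cell cancer probability
  to annual incidence per 100,000 via `F(t) = 1 − (1 − P_C(t))^N`,
* a **steepest-descent calibration** of `(p_mut, p_die, p_spr)` against an
  incidence table.

It is aimed at modellers studying multistage carcinogenesis and at anyone
who wants moment-closure approximations of lattice interacting-particle
dynamics validated against exact simulation.

## Worked example

Compare both approximations against Monte Carlo on the two-state demo
model (healthy/cancerous, internal transition ρ, spreading τ), 1000
trials of a 20×20 torus evaluated at t = 20:

```python
import ductsim as d

for scenario in ("weak", "strong"):          # (rho, tau) = (0.05, 0.01) / (0.01, 0.05)
    for method in ("single-cell", "pair"):
        r = d.run_demo(scenario, method, trials=1000, seed=7)
        print(f"{scenario:6s} {method:12s} BC={r.bc:.3f} "
              f"mean={r.mean:.1f} var={r.variance:.1f}")
```

```
weak   single-cell  BC=0.981 mean=296.3 var=76.8
weak   pair         BC=0.989 mean=293.8 var=98.4
strong single-cell  BC=0.027 mean=283.0 var=82.8
strong pair         BC=0.959 mean=214.7 var=307.7
```

`BC` is the Bhattacharyya overlap between the Monte Carlo histogram of the
cancerous-cell count and the approximation's predicted count distribution
(1 = identical). In the weak-interaction regime both approximations track
the simulation closely. In the strong-interaction regime the single-cell
method fails by design — ignoring inter-cell correlations, it overshoots
the mean by several standard deviations (283 vs ≈210 cells) — while the
pair closure repairs both the mean and most of the correlation-inflated
variance (307 vs ≈470, against 83 under independence).

The incidence layer reproduces the exposed-scenario reference table
(0.1 Gy at age 30, menarche at 12, 5-year lag) exactly:

```python
lagged = d.lag_shift(d.load_table("japan_breast_2018"), 5)
d.exposed_rates(lagged, dose_gy=0.1, exposure_age=30).df
#  age 30-34: 98, 35-39: 269, 45-49: 360, 70-74: 250, 80-84: 158, ...
```

A command-line interface mirrors the library: `ductsim simulate`,
`ductsim approx`, `ductsim fit`, `ductsim demo` (see `--help`).

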