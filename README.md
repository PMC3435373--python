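# roadecol

Individual-level spatial responses of wildlife to a highway, rebuilt as a
tested Python pipeline.  The motivating system is VHF radio-tracking of two
road-casualty-prone nocturnal species — the barn owl (*Tyto alba*) and the
stone marten (*Martes foina*) — living beside a fenced four-lane highway:
every road impact (barrier effect or road-kill) is the outcome of one
individual decision, to avoid the road or to cross it.  The package
estimates, from telemetry:

1. **Home ranges** — minimum convex polygons (MCP) and k-NNCH/LoCoH local
   convex hulls with 100/60/20 % quantile isopleths (HR1–HR3), plus an
   incremental-area stability check.
2. **Habitat selection** — a used-vs-available design (locations thinned to
   serial independence with the Schoener ratio t²/r², matched 1:1 with
   random points in the 100 % isopleth) analysed with binomial
   random-intercept GLMMs, `logit P(used) = x'β + σu_individual`, under AIC
   multimodel inference; the headline covariate is the interaction
   D_highway × Traffic (m · vehicles/h).
3. **Movement directionality** — consecutive 30 ± 15-min fixes labelled
   TOW/AWA (toward/away from the highway); the logistic fit on starting
   distance gives the 50 % indifference distance −β₀/β₁.
4. **Crossings and mortality risk** — crossing events as chord–polyline
   intersections of fixes < 1 h apart; crossing sites vs random highway
   sites and vs road-kill registry sites (verge width, grade class,
   vegetation, traffic by vehicle class); exposure-based rates
   `crossings/day = n / (hours/12)`, per-crossing kill probability
   `r = kills / (rate × days)`, and mortality extrapolation
   `M = density × strip × road km × rate × 365 × r`.

A built-in simulator (`roadecol.simulate`) generates landscapes, diurnal
traffic around a target AADT, step-selection trajectories with
traffic-scaled road avoidance, telemetry error, and Bernoulli kills per
crossing, so the full pipeline is testable without any field download.

The GLMM engine (`roadecol.glmm`) is written here: maximum likelihood via
the Laplace approximation with an adaptive Gauss–Hermite high-accuracy
mode, Wald inference, AIC tables and Akaike weights, forward selection
with a |r| > 0.5 collinearity screen, zero-substitution model averaging,
and a permutation-envelope Moran correlogram for residual spatial
autocorrelation.

## Worked example

```python
from roadecol import RunConfig, run_pipeline, report

cfg = RunConfig(species="barn_owl", seed=7, n_individuals=6, days=60,
                movement={"kill_prob": 0.02})
run_pipeline(cfg, "runs/owls")
rep = report("runs/owls")
print(rep["risk"])
```

prints a risk summary like

```
{'crossings_observed': 65, 'tracked_hours': 3871.5, 'activity_hours_per_day': 12.0,
 'rate_per_day': 0.2015, 'kills_confirmed': 1, 'kills_with_disappeared': 1,
 'tracking_days_total': 323, 'r_confirmed': 0.0154, 'r_upper': 0.0154,
 'mortality_confirmed_per_road': 54.2, ...}
```

meaning: six simulated owls tracked 60 nights crossed the highway 65
times over 3871.5 tracking hours — 0.20 crossings per 12-h activity day —
one was killed, giving an estimated per-crossing kill probability of
0.0154 and, at 0.24 owls/km² in a 2-km roadside strip, an extrapolated
54 kills per 100 km of highway per year (the `_upper` scenario also
counts disappeared individuals as road-kills).  The same run directory
holds the home-range table
(`homeranges.csv`), the habitat/directionality/crossing model rankings
(AIC, ΔAIC, Akaike weights) and averaged coefficients.

The same stages are available from the shell:

```bash
roadecol run --seed 7 --outdir runs/owls
roadecol report runs/owls
```

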