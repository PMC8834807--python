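# hevindex

Composite-indicator scenario assessment of climate-related potential impact
on urban public-health service networks.

Local public-health planners need to know how floods and water scarcity,
coupled with urban development change, will affect their facilities and
their service network as a whole — and whether planned measures move them
toward an acceptable risk level. `hevindex` operationalizes that question
with the IPCC AR5 risk decomposition

```
potential impact = Hazard × Exposure × Vulnerability
```

computed bottom-up through a three-layer indicator hierarchy (pillar →
indicator → sub-indicator). Sub-indicators are normalized by distance to
target (`x / target`, uncapped), aggregated additively with proportionate
weights (equal, budget-allocation, or rank-order), and the three pillar
scores multiply — so a zero in any pillar annihilates the impact
(non-compensability). Impacts on [0, 1] classify into four bands whose
boundaries are the cubes of the quarter-points of a unit pillar scale:
very low [0, 0.016], low (0.016, 0.125], medium (0.125, 0.422],
high (0.422, 1].

The package ships:

* a validated, hand-editable YAML **indicator catalog** (built-in: the
  Khon Kaen city catalog — 3 hazard, 2 exposure, 17 vulnerability
  indicators with sensitivity / coping-capacity / adaptive-capacity
  components over 9 + 40 sub-indicators);
* **survey I/O** for facility questionnaire tables (CSV in, CSV + JSON
  results out) with located, actionable validation errors;
* a **scenario engine**: trend-vs-desirable storylines as hazard levels
  plus group-addressable response overrides, evaluated per facility, for
  the city area, and for a hospital-led CUP service network (host, units,
  combined), with comparison against an acceptability bandwidth;
* a **robustness suite**: Cronbach's alpha, corrected item-total
  correlations, KMO, Bartlett's sphericity, correlation-matrix PCA with
  direct-oblimin (Kaiser-normalized) rotation, and |0.4|-loading drop
  suggestions;
* a seeded **synthetic survey generator** reproducing the study
  conditions (36 facilities, 25/36 response rate, one CUP host,
  zone-dependent hazards, heterogeneous sensitivity/coping blocks vs. a
  near-homogeneous adaptive block);
* a `hevindex` **CLI**: `validate`, `score`, `compare`, `robustness`,
  `simulate`.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

The built-in worked example evaluates a Thai medium-sized city's public
health service under a business-as-usual *trend* scenario and a
stakeholder-preferred *desirable* scenario, in area-based and
service-network views:

```python
from hevindex import khon_kaen
from hevindex.scoring import round_display

for (scenario, view), res in khon_kaen.full_assessment().items():
    print(f"{scenario:>9} / {view:<7}  H={res.hazard.value:.3f}  "
          f"E={round_display(res.exposure.value):.3f}  "
          f"V={round_display(res.vulnerability.value):.3f}  "
          f"impact={round_display(res.impact):.3f}  class={res.klass}")
```

prints

```
    trend / area     H=0.827  E=0.659  V=0.461  impact=0.251  class=medium
    trend / network  H=0.840  E=0.549  V=0.426  impact=0.196  class=medium
desirable / area     H=0.827  E=0.326  V=0.105  impact=0.028  class=low
desirable / network  H=0.840  E=0.324  V=0.130  impact=0.035  class=low
```

Reading: under the trend scenario the city's potential impact is *medium*
(0.251); the desirable scenario's sector-internal measures (zeroed capacity
deficits, relocated working systems) bring it down to *low* (0.028) — but
not to the *very low* target, because hazard levels are unchanged: reaching
very low would additionally require city-wide hazard mitigation and
exposure avoidance, which no public-health-internal measure can substitute
for. That is the non-compensable product doing its job.

The same pipeline runs on your own data from the shell:

```
hevindex simulate --n 36 --seed 42 --out survey.csv     # or your own survey
hevindex score --survey survey.csv \
    --scenario scenario_trend.yaml --scenario scenario_desirable.yaml \
    --view all --out-dir results
hevindex robustness --survey survey.csv --scenario scenario_trend.yaml \
    --out results/robustness.json
```

`score` writes per-scenario result tables plus a trend-vs-desirable
comparison report; `robustness` emits the full reliability / sampling
adequacy / PCA report (and warns that n = 25 is a small sample for
data-driven statistics).

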