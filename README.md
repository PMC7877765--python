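# farmstyles

An agent-based model of how *styles of farming* shape hunger and
rural-health-supporting conditions in a smallholder community under
climate change.

Global climate–nutrition models treat farms as homogeneous producers and
people as homogeneous consumers. This package takes the opposite
standpoint: a community of 250 producer-consumer households farming a
21×21 grid of 1-ha plots, where subsistence ("orphan") farmers may
develop either by adopting **agroecology** — a peasant style that
intensifies labour and on-farm ecological processes, avoids credit and
seeks autonomy — or an **entrepreneurial** style that relies on
purchased fertilizer, wage labour and credit and seeks return on
investment and expansion. Outcomes are simulated over 50 annual steps
under scenarios crossing style preferences, agricultural policy,
global-to-local price transmission and climate-change severity. It is
aimed at climate-health and food-security modellers who want farm
heterogeneity — who is farming, and how — inside the climate–nutrition
causal chain.

## The model in brief

Each year every household chooses a production fraction *q* of its
attainable maximum, where producing *q* requires the fraction *q²* of
each variable input (diminishing returns). Peasants maximise
returns-to-labour (labour is never costed; the labour diet is paid in
kind):

    max_q  p·(A·q − LD·q²) − NI·q²

while entrepreneurs maximise profit with every input costed, family
labour included:

    max_q  p·A·q − (F + W + NI)·q² − D

with *A* the attainable maximum (fertilizer gives entrepreneurial plots
up to 10× their base yield), *LD* the labour diet, *NI* necessary
inputs, *F* fertilizer, *W* wages, *D* debt service. The local food
price is the marketed-surplus-weighted mean of household asking prices,
adjusted each year by the transmission elasticity τ times the change in
an exogenous global price that tends to fall and oscillate but spikes in
drought years. Climate change imposes a linear warming trend (−4%
yield/°C, 10% less under agroecology) and growing drought risk (−20%
under agroecology). Households that cannot provide half a basic diet
(700 kg cereal equivalents/yr for four people) or meet debt obligations
sell assets and ultimately abandon farming.

Tracked outcomes include total production, local price, conversions,
abandonments, orphan nutrition, farm labour (FTE), income Gini, mean net
farm income, and **real land productivity**,

    RLP [$/ha] = (net income / farm size) × endogeneity,
    endogeneity = (GVP − purchased non-labour inputs) / GVP,

an environmentally-sensitive intensity measure that excludes value
merely transferred from purchased inputs.

## Worked example

```
$ farmstyles run --policy peasant --climate high --seed 7 --out demo
year 50: production 2974 t, price 52.2 c/kg, converted 205, abandoned 8
wrote demo/run.csv
```

One 50-year run of the peasant-policy scenario (75% of households prefer
agroecology, transmission 0.25, faster peasant yield increments) under
high climate change: by year 50 the community produces 2974 t of cereal
equivalents (enough basic diets for ~4249 households, versus 250
households fed at year 1), 205 of the 250 original households have
converted to their preferred style, 8 have abandoned farming, and the
local price has risen from 40 to 52 c/kg under climate pressure.
`demo/run.csv` holds the full per-year series (production, prices,
nutrition, labour, Gini, incomes, real land productivity, climate
trace); `demo/config.yaml` echoes the resolved configuration.

Replicate batches and the sensitivity grid:

```
farmstyles batch --policy entrepreneurial --climate no --runs 250 --seed 0 --out batch_out
farmstyles sensitivity --yield-ratio 0.25 --yield-ratio 1.0 --runs 250 --out sens_out
```

The same machinery is available as a library:

```python
from farmstyles.engine import run_batch
mean, sd = run_batch("peasant", "no", n_runs=250, base_seed=0)
print(mean.total_production_t[50], mean.households_feedable[50])
```

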