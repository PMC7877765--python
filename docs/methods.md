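# Model description and methods

`farmstyles` simulates a hypothetical smallholder community of 250
four-person farming households on a 21x21 grid of 1-ha arable plots over
50 annual time steps. Households begin as "orphan" (subsistence) farmers
and may develop along one of two styles — peasant agroecology or
entrepreneurial farming — under scenarios that vary the distribution of
style preferences, agricultural policy, the transmission of global food
prices into the local price, and climate-change severity. The model
tracks total production, the local food price, conversions and
abandonments, and five health-supporting outcomes: orphan-household
nutrition, farm labour, income inequality (Gini), mean net farm income,
and real land productivity.

## The world

**Plots.** Each of the 441 plots has a base maximum yield drawn
uniformly on 1000 kg/yr ± 20% (what one worker with manual tools can
produce), and an agroecology yield multiple drawn from a normal
distribution (mean 4, SD 1.5) truncated to [2, 7] by rejection
sampling. Yields are in kg of cereal equivalents; 4015 kcal/kg (so that
200 kg provides 2200 kcal/day for a year). No plot may yield more than
10 t/ha under any style. Adjacency is 4-neighbour with no wrap-around.

**Households.** Four people, two full-time-equivalent (FTE) workers. A
basic family diet is 700 kg/yr; abandonment occurs if less than half of
it can be provided. Full-effort labour needs an extra 2900 kcal/day over
150 ten-hour days, ~108 kg of cereal per FTE-year ("labour diet").
Households carry two behavioural traits assigned 50/50 at random:

* *Rationing preference* — production-first households sell family-diet
  grain (down to the 50% floor) to pay input bills and to build savings
  toward their conversion goal; nutrition-first households protect the
  diet and let the (deferrable) input bill slide instead.
* *Saving style* — "spend" households consume cash above a goal-oriented
  reserve (the conversion requirement while orphan, the next hectare
  plus working capital once developed, scaled 1.2x for cost growth);
  "hoard" households keep everything.

**Styles.** Orphan farms use manual tools, family labour and the
standard per-ha "necessary inputs" (clothing, tool repair, maintenance —
15% of a low-skilled wage per ha at full production). Agroecology is
entered through a 3-year, savings-financed transition per plot (no
credit) that lifts the plot to its agroecology multiple, with the extra
labour diet and inputs paid up front; a running agroecology farm needs
twice the labour-diet and necessary-input intensity, may grow to 10 ha
and two teams of working animals (savings only, one plot per completed
transition), and never hires labour or borrows. Entrepreneurial farms
raise plot yields up to 10x the base through fertilizer (500 kg/ha at
the maximum), hire wage labour, use credit (short/mid/long-term at
20/15/10%, halved under entrepreneurial policies), and expand by at most
1 ha of land per year plus equipment whenever income and savings cover
half the cost, financing the balance with level-annuity loans (terms 1,
5 and 8 years; 5 is the midpoint of the stated 3-6 band).

## The annual cycle

Climate step → global price step → input-price update → orphan
conversions → farm expansions → price expectations and production
optimization (with entrepreneurial viability checks and fertilizer
purchase) → production realization → asking prices → local price
formation → accounting and distress → yield increments and transition
progress → outcome snapshot. Household order is reshuffled every year
from a dedicated random substream so the climate and price draws do not
shift when the population changes.

**Optimization.** Producing a fraction q of a farm's attainable maximum
requires the fraction q² of each variable input (labour effort and
diet, necessary inputs, fertilizer) — the model's diminishing-returns
assumption. Peasants maximise returns to labour: the value of output
net of the in-kind labour diet and cash inputs, with labour itself never
costed; if the optimum fails the autonomy goal (net income not below
last year's) they escalate production. Entrepreneurs maximise profit
with every input costed at market rates, family labour included; if
profit at the optimum cannot fund the cash half of the next hectare
(their expansion goal) they escalate to the largest non-loss-making
output. Both objectives are concave quadratics in q, so the 0.01-grid
optimum is located exactly from the continuous optimum's two grid
neighbours. A pre-production rationing step caps peasant input
commitments at what savings plus rationable harvest value can fund.

**Prices.** The exogenous global price declines at a random annual rate
(mean 1.5/1.25/1.0%/yr under no/low/high climate change, SD equal to the
mean, truncated to [-2, +4] times it so rises occur), carries an
additive sinusoid of 1.5 cents amplitude and 10-year period, and jumps
by a scenario-specific bump in global-drought years. The local price is
the marketed-surplus-weighted average of household asking prices,
adjusted by the transmission elasticity times the year-on-year global
price change, floored at 1 cent. Asks are the larger of the expected
price and a goal floor: peasants ask at least the price that maintains
their (exponentially smoothed) net income from planned surplus;
entrepreneurs ask at least 1.2x their variable cash cost per kg.
Expectations anchor on the current price (peasants) or project the
transmission-adjusted five-year global trend (entrepreneurs), with ±5%
noise. Wage (180% of a basic diet's cost at the 5-year mean price,
drifting +2%/yr), necessary inputs (15% of a wage/ha), fertilizer (10x
the local price/kg, +1%/yr, minus any subsidy), land (30 t of cereal per
ha) and working animals / tractors (30 / 150 years of the average orphan
farm's ~$77 net income after diets) all derive from the food price.

**Climate.** Warming rises linearly to 0/1/2 °C over 50 years and costs
4% of yield per degree (10% less under agroecology). Drought risk starts
at 5%/yr and grows linearly to 1/1.5/2 times that; a local drought draws
a community mean loss uniform on [0, 2x the scenario mean] truncated at
the scenario maximum (so its expectation equals the stated mean), each
farm perturbs it by ±25%, and agroecology suffers 20% less. Realized
production is the target times the warming and drought factors times
±15% noise. Sensitivity mode replaces both agroecology reductions with a
single relative sensitivity (0.9/1.0/1.1) and can fix the
agroecology:entrepreneurial yield ratio (agroecology potential = ratio x
10x base, no yield growth).

**Distress.** Cash can never go negative. Peasants ration grain or
default on the input bill (deferred maintenance: the farm gains no yield
increment that year); they abandon only if even rationing, purchases
and asset sales cannot reach half a basic diet. Entrepreneurs face hard
wage and debt obligations: viability is checked before planting
(smoothed income plus savings against debt service), distress sells
animals, then tractors, then land (never the last plot) at current
prices, and a farm that still cannot meet its obligations or the diet
floor leaves farming for good. Abandoned plots return to the
unoccupied pool.

**Yield increments.** Optimised peasant farms gain slow productivity on
orphan plots (1%/yr; 1.5%/yr under the peasant policy) and transitioned
agroecology plots (1.5%/yr; 3%/yr), capped at 10 t/ha. A farm that was
rationed below its optimum or defaulted on inputs gains nothing that
year.

## Scenarios and experiments

Policies: *entrepreneurial* (25% prefer agroecology, transmission 0.75,
50% fertilizer subsidy, halved interest), *entrepreneurial eroding*
(same, with supports returning linearly to baseline over 50 years),
*peasant* (75% / 0.25, faster yield increments), *none* (50% / 0.5).
Climates: no / low / high as above. The experiment suite runs
independent replicates per condition (seeds `base + i`) and reports
across-run means: a style-preference sweep (proportion preferring
agroecology x transmission under no policy and no climate change), the
policy x climate grid, and the sensitivity analysis (fixed yield ratios
1:4, 1:2, 3:4, 1:1 x agroecology climate sensitivity 0.9/1.0/1.1).
`scripts/acceptance.py` uses 150 replicates per condition, which bounds
the Monte-Carlo standard error of the across-run means below about 1%,
far inside the tolerance of any quantity compared.

## Design choices where the specification of the original was open

* **Orphan input bills.** Charging subsistence farms the full 15%-of-wage
  necessary-input rate puts the average orphan at roughly zero cash
  margin — exactly "close to the threshold for development" — and makes
  plot heterogeneity split the population into converters, a blocked
  pool and (under climate stress) abandoners. Asset prices still use the
  diets-only ~$77 net income, as the capital-goods pricing rules state.
* **Price formation stability.** An ask-driven market with no demand
  side is knife-edged: trend-extrapolating expectations by the majority
  seller class either crash or ratchet the price. Peasant expectations
  therefore anchor on the current price, entrepreneurial expectations on
  the transmitted global trend, and the peasant income-maintenance floor
  uses smoothed income against planned (not realized) surplus. Weighting
  asks by marketed surplus rather than gross production keeps near-zero
  sellers from setting the price.
* **Diminishing returns** are quadratic (input fraction = q²): the
  simplest convex form with correct endpoints.
* **Equipment allocation** covers area with tractors first (16
  ha/worker), then animal teams (5), then manual labour (1), and the
  agroecology labour doubling applies to the labour diet and input
  intensity, not to area capacity — so two workers with two animal teams
  manage 10 ha, as the style's cap requires.
* **Saving styles and rationing preferences** are named but not defined
  in the source description; the implementations above were chosen once
  for internal coherence (goal-directed saving, diet-versus-farm
  trade-offs) and left alone.

## What the generator does and does not emulate

The synthetic world reproduces the stated initial conditions (uniform
plot yields, truncated-normal agroecology multiples, random placement,
zero savings, all farms at maximum yield) and all stated stochastic
processes. It does not represent family demography, land fragmentation,
migration, soil degradation, value chains or a demand side — prices are
supply-driven and all marketed food clears. Passing tests therefore
demonstrate internal consistency and reproduction of the study's
qualitative patterns, not predictions about any real community.

## Known limitations

The decision rules of the original are specified in full only in an
accompanying ODD+D protocol document that the reimplementation did not
have; the annual-cycle prose, parameter tables and printed results were
the sources. The consequences visible in our outputs: entrepreneurial
farms here retain ~50% gross margins at their production optimum (a
structural property of quadratic costs with interior optima), so the
original's late-run entrepreneurial crisis — mass debt-driven
abandonment under high climate change and production dips around year
20-25 — is reproduced in direction but not magnitude. Climate-driven
production losses under the entrepreneurial policy and the
peasant-versus-entrepreneurial gaps in sensitivity mode are therefore
smaller in this implementation than in the original, while the
style-preference production gaps, the peasant-policy feedable-household
count, nutrition levels, conversion shares and the price orderings
match well. The abandonment-versus-climate ordering holds but with far
smaller counts than the original reports.
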