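# Methods

`housepi` couples a standard two-group SIR epidemic to a minimal model of
household economics, in order to study *a-priori* targeted treatment
policies in resource-limited communities.  Every individual is either a
**producer** (an adult who, while healthy, earns `P_p` money per day for
their household) or a **consumer** (a dependent who costs `C_c` per day and
never earns).  Treatment costs `C_t` per course, can only be purchased at
the onset of an infection, and is only available while the household purse
`M_h` is positive.  A household whose purse is exhausted (`M_h <= 0`,
"bankrupt") suffers elevated transmission — the hatted parameters — through
loss of nutrition and care.

Two engines share one parameter set.

## Discrete agent-based engine

A population of `n_households = 500` households is synthesised from
Bernoulli "arrival" draws: producers per household are
`1 + Binomial(3, 1/3)` (support 1–4, mean 2) and consumers
`Binomial(7, 3/7)` (support 0–7, mean 3), giving `N = 2500` expected
individuals with a 40 %/60 % producer/consumer split.  Households with zero
consumers are kept (no resampling).  One randomly chosen producer starts
infected and untreated.

Each simulated day applies, in this order:

1. **Recovery draws** for every infective — probability `gamma` untreated,
   `gamma_plus` treated.  A treated individual keeps `gamma_plus` even if
   their household later goes bankrupt: the course was already purchased.
2. **Infection draws** for every susceptible, from the composite escape
   probability

   `p = 1 − (1 − beta/(N−1))^{n_out} · (1 − iota)^{n_hh}`

   where `n_out` counts infectives outside the susceptible's household and
   `n_hh` inside it (counted at the start of the day, so same-day
   recoveries still transmit), and `(beta, iota)` switch to the hatted pair
   when the susceptible's own household started the day bankrupt.
3. **Treatment assignment** for the day's new cases: treated iff a
   Bernoulli(`T_role`) coverage draw succeeds *and* the household purse is
   still positive; the cost `C_t` is debited immediately, so several cases
   in one household compete for the same money within a day.
4. **Economy update**: each healthy (S or R) producer adds `P_p`, every
   consumer costs `C_c`.  Sick producers neither produce nor consume.

The update order is fixed deliberately (no configuration switch):
infection must see start-of-day prevalence, and treatment is charged on the
day of onset.  Purses may go negative through consumption but never through
treatment, which requires `M_h > 0` first.

## Continuous switched-ODE engine

The mean-field twin tracks eight compartments
`S_p, I_p, I_p⁺, R_p, S_c, I_c, I_c⁺, R_c` (⁺ marks treated infectives)
plus one collective money variable `M_h`.  Global mixing is
frequency-dependent, `beta S I / N`: the tabulated `beta` are daily
probabilities of order 0.3–0.5, and unscaled mass action at `N = 2500`
would be dimensionally inconsistent and saturate instantly.  Household
pressure enters through the household-weighted prevalences
`Ĩ_x = (|h|/N)(I_x + I_x⁺)` with `|h| = 5`, as `iota S Ĩ`.

While solvent (`M_h > 0`) incident cases split `T : (1−T)` into the
treated/untreated compartments and treated cases recover at `gamma_plus`.
While bankrupt, transmission takes the hatted values, *all* new cases are
untreated, and the treated compartments lose the enhanced rate — they drain
at the baseline `gamma`.  Recovery flows into R mirror whichever rates the
I-compartments are draining at, so producer and consumer totals are
conserved exactly in both branches (any other reading creates individuals
out of nothing while bankrupt).

Money obeys

`dM_h/dt = [P_p(S_p + I_p⁺ + R_p) − C_c(S_c + I_c + I_c⁺ + I_p + R_c) − C_t(I_p⁺ + I_c⁺)] / D`

Two conventions for the divisor `D` are supported because the units of the
collective `M_h` are genuinely ambiguous:

* `money_scale = "per_household"` (**default**): `D = n_households`, so
  `M_h` is the purse of the average household, directly comparable with the
  agent model's per-household `M0 = 500`.  This is the dimensionally
  consistent reading — the flows and the initial value are in the same
  per-household units — and it is the one under which the model actually
  exhibits its bankruptcy-driven phenomenology at the mid-range economies.
* `money_scale = "per_capita"`: `D = N`.  Flows are then per capita while
  `M0` remains per household, which makes the purse roughly `|h|` times
  harder to exhaust; at `C_c = 30, C_t = 250` the economy never goes
  bankrupt at all under this reading.

Note two asymmetries between the engines that follow from taking each
model description at face value: in the continuous model treated sick
producers produce (the `P_p I_p⁺` term) and untreated sick producers
consume (the `C_c I_p` term), while in the agent model sick producers
neither produce nor consume; and the continuous model charges `C_t` per
*day* of treatment while the agent model charges it once at onset.  We
implement each engine as described rather than harmonising them.

### Probability/rate correspondence

`rate_conversion` controls how the tabulated daily probabilities enter the
continuous model:

* `"identity"` (**default**): use them verbatim as daily rates.
* `"exact_exponential"`: convert the recovery probabilities through
  `r = −ln(1 − p)` (recovery only; per-pair transmission probabilities are
  ~1e−4, where the distinction is second order).

The default is also what makes the two engines numerically equivalent: the
discrete engine transmits for a geometric-mean `1/gamma` days at daily
per-pair probability `beta/(N−1)`, matching a continuous duration
`1/gamma` at rate `beta S I/N`.  The cross-check test (well-mixed limit
`iota = 0`, economics off, both engines started from 25 infected
producers to suppress extinction bimodality) finds agreement within
Monte-Carlo error under `identity`, while `exact_exponential` shortens the
continuous infectious period to `1/0.105 ≈ 9.49` days and shifts the final
size by many standard errors.  The converted variant remains available for
sensitivity analysis.

### Integration

The default integrator is an adaptive Dormand–Prince 5(4) pair (compiled
with numba; ~0.2 ms per trajectory, which is what makes the 121 × 441-cell
economic-plane sweeps a desk-scale computation).  The `M_h = 0` crossing is
located by bisection on the cubic-Hermite dense output to 1e−9 day and the
branch switched exactly there; after a switch the integrator commits to the
new branch for at least 1e−6 day, which resolves chattering at grazing
contacts.  Default tolerances `rtol = 1e−8`, `atol = 1e−10`; integration
ends when total infectives fall below 1e−6 or at `t_max = 3000` days
(reaching `t_max` flags the trajectory truncated, and burden readers refuse
truncated trajectories).  A fixed-step day-grid forward-Euler integrator
(`run_ode_euler`) is kept as an independent cross-check; the test-suite
also checks the compiled core against `scipy.solve_ivp` on solvent
dynamics and against a hand-expanded right-hand side at random states.

Burdens are cumulative infections per role: the initial role total
(including index cases) minus the final susceptibles, so the
no-transmission limit yields burdens (1, 0).

## Phenomenon detectors

A *line of demographically proportionate treatment* is the locus
`0.4·T_p + 0.6·T_c = level` (slope −3/2): all its policies administer the
same expected number of treatments under the 40/60 split.  The three named
phenomena are scored on a consumer-burden grid over the `T_p × T_c` plane;
all three are relative measures, invariant to uniform burden rescaling, and
zero on constant grids.

* **Threshold** — the largest relative drop `(max − min)/max` of the
  interpolated burden along any sampled proportionate line, counted only
  when the minimising point is more producer-heavy than the maximising one.
  Drops below 1e−6 are integrator noise.  Because reallocating treatment
  towards producers already helps consumers slightly in the economy-free
  system (a treated producer transmits for 2 days instead of 10), the
  detector accepts an always-solvent baseline sweep of the same plane and
  subtracts its line-by-line drop, leaving the economy-induced excess.
  The baseline costs one extra treatment-plane sweep per economic *plane*
  (not per cell): with zero consumption and free treatment the solvent
  branch never exits, and solvent epidemiology is independent of
  `C_c, C_t`.
* **Weak economy** — the sharpest relative decrease between adjacent
  coverage levels (step 0.05) along the equal-allocation diagonal
  `T_p = T_c`, minus the same quantity on the solvent baseline diagonal,
  reported only when it reaches the documented sharpness cutoff of 0.25
  per step (ordinary smooth improvement is not the phenomenon).
* **Overspending** — the largest relative burden *increase* from any cell
  to its neighbour at strictly higher `(T_p, T_c)`; rises below 1e−3 are
  ignored.  A burden grid monotone in coverage scores 0.

Grid interpolation is bilinear.  Default resolutions — 21 × 21 for the
treatment plane, 11 × 11 for the economic plane over `C_c ∈ [0, 50]`,
`C_t ∈ [0, 500]` — are the package's desk-scale defaults; finer grids are a
configuration away.  The sharpness cutoffs and the baseline subtraction are
this package's operationalisation: only the threshold phenomenon has a
quantitative published definition, the other two are described verbally.

## Randomness and reproducibility

All stochastic runs flow from a single top-level seed expanded through
`numpy.random.SeedSequence.spawn`, so Monte-Carlo replicate *k* is
reproducible in isolation and replicate streams are provably disjoint.
Identical seeds give byte-identical populations, trajectories and CSVs.

## What the synthetic population does and does not emulate

The generator reproduces household-size heterogeneity (the binomial
arrival scheme), the 40/60 role split and per-household finances.  It does
not model demographic turnover (closed epidemic), any contact structure
beyond household + uniform global mixing, age beyond the producer/consumer
dichotomy, disease-induced mortality, or income heterogeneity between
households (all producers earn the same `P_p`).  Conclusions from passing
tests are therefore about this idealised community, not about any specific
outbreak.

## Known limitations

* The continuous household term `iota S Ĩ` never saturates, while real
  (and simulated) households run out of susceptible members; the two
  engines are therefore only directly comparable in the well-mixed limit,
  and the mean-field engine systematically overweights household
  transmission elsewhere.
* Under the tabulated transmission values the solvent system is strongly
  supercritical (per-infective force ≈ 0.63/day against a 10-day untreated
  duration), so attack fractions are high and policy contrasts in final
  size are small once the bankrupt regime engages; the bankruptcy
  *mechanism* (consumer-heavy allocations produce the longest bankruptcy
  spells, producer-heavy the shortest) is robust, but its quantitative
  imprint on final sizes is compressed.
* Monte-Carlo means over single-index-case runs are bimodal (minor
  outbreaks die out); comparisons of mean burdens between policies at
  realistic replicate counts are partly driven by the policies' different
  early-extinction probabilities.
* The non-smooth secondary-outbreak kinks at branch switches are a feature
  of the mean-field formulation (all households hit bankruptcy
  simultaneously); the agent model spreads them out.
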