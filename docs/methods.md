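# Methods

`surf` simulates the weekday daily routines of two demographic groups —
*commuters* and *retired people* — as individual agents moving over a street
network between function-tagged buildings, and counts them at virtual
footfall sensors. Its purpose is to estimate the *ambient* (daytime)
population of a town centre: observed footfall gives only aggregate counts,
while the model attributes footfall to groups, times and activities.

## Behavioural model

Seven activities are modelled: being at home, office work (commuters only),
food shopping, leisure shopping (retired only), lunch out, an evening
food/drink social activity, and sports. Each activity `a` of an agent
carries two motivation components:

* **Background intensity** `B_a(t)`: grows linearly at `r+_a` (units per
  minute) whenever the activity is not being performed — including during
  travel — and drains linearly at `r-_a > r+_a` while it is performed,
  clipped at zero. The background encodes recurrence: an activity's
  motivation accumulates until it wins, and one episode works it off.
* **Time intensity**: a rectangular daily profile equal to an amplitude
  `A_a` inside the activity's characteristic time window (which may wrap
  midnight) and to a baseline (zero for every flexible activity) outside.
  `at_home` is the one activity with a nonzero outside-window baseline
  (0.5): it represents the constant draw of home against which flexible
  activities compete during the day, while its in-window amplitude (1.0,
  evening/night) sends agents home and keeps them there overnight.

At every 5-minute step an agent performs the activity with the highest
**total intensity** `B_a + time_a`, with two stabilisers: the current
activity has a minimal duration before it can be abandoned, and exact ties
keep the current activity (ties among challengers resolve in a fixed
canonical activity order).

### What controls participation, and what controls duration

With linear dynamics, rectangular windows and argmax selection, these two
observables decouple cleanly, which is what makes the model calibratable:

* **Participation** (share of agents doing an activity on a day) is set by
  the ratio of daily background growth to the background drained per
  episode. An agent enters an activity when `B_a` exceeds the *entry
  threshold* — the gap between the strongest competitor (normally the home
  baseline plus home's accumulated background) and `A_a`. One episode
  drains `r-_a × min_duration`, so the activity recurs roughly every
  `drain / daily growth` days.
* **Episode duration** is the minimal-duration lock itself. An analysis of
  the marginal dynamics shows why this must be so: for any activity that
  recurs less than daily, the background must be driven well below its
  entry threshold during the episode (otherwise the agent re-enters the
  next day), and the only mechanism that achieves this over-drain is the
  minimal-duration lock — an agent quitting at the marginal comparison
  leaves its background pinned at the threshold and collapses recurrence to
  daily. Durations above the lock would therefore imply daily recurrence.
  Duration *variability* consequently comes from heterogeneity: each agent
  draws a log-normal per-activity duration factor `L` (sigma 0.8) that
  multiplies its minimal duration and divides its decay rate, so the drain
  per episode — and with it the recurrence interval and participation — is
  independent of how long that agent's episodes last. The factor sigma 0.8
  reproduces the observed mean/median ratio of shopping durations
  (41/30 for commuters, 69/50 for retired people) that a single
  homogeneous duration cannot.

Commuter food shopping uses one further mechanism: its amplitude (0.55)
exceeds the home baseline but its window closes at 17:45, before the home
background accumulated during the workday has drained away. Strongly
motivated agents therefore shop *directly after work*, while the early
window close prevents the degenerate regime in which every agent shops
every evening once home's pull has decayed; participation is then governed
by the refill time to the window-close threshold.

### Stochastic heterogeneity

Four channels, all drawn once per agent at population synthesis except the
last:

| channel | distribution | default |
|---|---|---|
| grow-rate multiplier (per activity) | log-normal | sigma 0.2 |
| decay-rate multiplier (per activity) | log-normal | sigma 0.2 |
| duration factor (per flexible activity) | log-normal | sigma 0.8 |
| window offset (all of an agent's windows) | uniform | ±75 min |
| daily window jitter (per agent, day, activity) | uniform | ±10 min |

The shared window offset preserves each agent's internal schedule structure
(its work end always precedes its shopping window by the same margin) while
spreading the population's timing. ±75 min reproduces the observed spread
of office start times over 07:00–10:00; a narrower offset concentrates
almost all starts into a single hour and makes the morning footfall peak
unrealistically dominant.

Initial backgrounds are drawn uniformly on `[0, drain-per-episode]` — the
stationary distribution of the background sawtooth — so recurrence phases
are spread from day one. Without this, activities recurring every `k` days
would fire in population-wide synchronised bursts.

## Space, movement and sensors

Coordinates are planar metres. Buildings and sensors snap to their nearest
road node; all travel follows the network. Shortest paths come from a
hand-written A* with a Euclidean heuristic (admissible because edge lengths
are validated to be at least the endpoint distance); agents move at a
constant walking speed (1.4 m/s) in 5-minute steps, committed to the
journey, with backgrounds continuing to grow en route and the destination
activity starting on arrival. Flexible activities are allocated to a
uniformly random building of the required function within a search radius
of the agent's current position, doubling the radius (500 m initial, up to
6 doublings) until a candidate exists.

A sensor counts one event whenever an agent's movement polyline *enters*
its detection disc (20 m radius) from outside; dwelling inside does not
re-count. Entries are computed geometrically per cached route and converted
to timestamps from the departure time and walking speed, so a 420 m step
cannot jump over a small disc undetected. Entry geometry treats edges as
straight segments, exact for the synthetic grid towns used here.

## Runs and reporting

A run simulates 14 days and reports only the final day (the first ~2 days
are warm-up; the dynamics settle into their daily cycle quickly because
initial phases are stationary). Replicates (default 50; the scaled desk
protocol uses 10) differ only in their seeds, derived from one master seed;
sensor-hour means are accompanied by percentile-bootstrap confidence
intervals (99%, 1000 resamples; the resampling plan depends only on the
seed so nested levels give nested intervals). The engine updates all agents
synchronously with vectorised array operations — agents do not interact, so
this is exact and bit-reproducible given the replicate seed.

Schedule statistics are computed from the final-day logs: an *episode* is a
maximal constant run of one activity, travel steps break runs and count
toward no activity, and participation is the share of agents with at least
one episode that day, pooled over replicates. The packaged target table
(weekday participation and durations per group and activity) is evaluated
with ±3 percentage points on participation, ±15% on durations and ±30 min
on the 8-hour office day.

Hourly curves are standardised as Z-scores with the population standard
deviation before comparison; RMSE and Pearson correlation are computed on
the Z-scores, and the locally-weighted linear smoother is presentational
only (metrics never use smoothed values — line smoothing can fabricate
features at the day boundaries).

## The synthetic study area

`surf demo` generates the full input set: a grid street town
(7×7 nodes, 150 m spacing by default) whose commercial functions
(supermarkets, restaurants, pubs, leisure shops, sports facilities,
offices) concentrate in the central blocks while the periphery is
residential — the geography of a small market town, and the reason
after-work activity trips pass the town-centre sensors; a commuting
origin–destination table whose workplaces weight toward the centre;
per-zone retired counts; and a pseudo-observed footfall series. The
observed series is a reference simulation of the configured groups plus an
*injected un-modelled component* — a Gaussian-shaped pulse peaking at 15:00
(school exodus) scaled to 30% of peak footfall — plus Poisson noise. The
injection exercises the iterative-diversification workflow: comparing a
configured-groups simulation against the observed series leaves its largest
residual at the injection hour, which is the signal that a demographic
group is missing from the model.

What the synthetic data does *not* emulate: real street topology, building
stock or census geography; Wi-Fi detection physics (probabilistic capture,
MAC randomisation, car passengers); weekends; households or school-age
children. Passing tests therefore demonstrate that the mechanism recovers
the calibrated time-use statistics and qualitative footfall structure under
controlled conditions, not that it predicts any particular real town.

## Numerical and design choices

* Linear background dynamics and rectangular windows: the simplest forms
  with the stated qualitative behaviour, and the ones that make recurrence
  analytically predictable (participation = growth/drain) and testable.
* Step ordering within a 5-minute step: travellers advance and arrivals
  start their activity; backgrounds update (performers drain, all else
  grows); the step is logged; then eligible agents re-decide and switchers
  depart. An agent that decides to switch therefore still performs its old
  activity for that step, and movement begins the following step.
* Degenerate inputs: an empty population yields an all-zero footfall table
  and empty logs; a constant series has no Z-score (error); towns are
  validated on construction (connectivity, edge lengths ≥ Euclidean
  distance, known function tags, buildings inside the network bounding
  box); the engine verifies that every configured flexible activity has at
  least one building of its function.
* Tie-breaks are deterministic everywhere (canonical activity order,
  smallest node id for nearest-node ties).
* Scaled protocol: the shipped statistics are verified at 2,000 commuters +
  2,000 retired agents, 10 replicates and 14 days — the problem size the
  package's own acceptance checks use. Larger populations only narrow the
  sampling noise; rates and thresholds do not change with population size.

## Known limitations

* Durations are floor-controlled by construction (see above); the decay
  rate shapes recurrence, not episode length. A model wanting
  decay-controlled durations needs non-linear dynamics or a quitting
  hysteresis that linear argmax does not provide.
* Retired agents, lacking a fixed anchor activity, tend to do their
  accumulated activities soon after the morning home window opens; the
  intensity framework is known to be better suited to anchored groups.
* No congestion, transport modes, road-type speeds, households, location
  memory or weekend behaviour.
* Per-sensor curves in small synthetic towns are highly correlated because
  the central sensor cluster is compact.
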