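# Methods

## Case model

A branched case is a directed acyclic graph. Each non-endpoint node poses
exactly one form question and owns a unique `question_key`; each answer
option is an edge `(source, option_text, destination, classification)`
with classification `expert`, `tolerable` or `incorrect`. Structural
rules enforced by `validate_case`:

* endpoints have no outgoing edges and no question; every decision node
  has at least one option and exactly one expert-classified option;
* every node is reachable from the start node; the graph is acyclic
  (cases are time-ordered, so a directed cycle is an authoring mistake
  and is reported as error `CYCLE`);
* the expert route — obtained by following the unique expert edge from
  the start until an endpoint — must end at the FINISH node, an endpoint
  placed on the expert row;
* several options may share a destination (endpoint collapsing is legal
  and common: e.g. every premature rescue-dose option routing to the same
  failure ending).

Menu sizes between 8 and 14 options are the range seen in authored
cases; a non-binary menu outside that band draws warning `MENU_SIZE`.
Binary hydration prompts (two options) are exempt. Node order in a
`CaseGraph` is canonicalised (nodes by id, edges by `(source, option)`),
which is what makes serialisation byte-stable and load→save→load the
identity.

Question-to-node assignment follows the published table structure:
timepoint circles pose the binary hydration question (whose options are
expert/tolerable — a hydration choice is not immediately harmful), and
the resulting fluid-state diamonds pose the treatment menus, which carry
all three classes. This is why, reading down a behaviour table, the
incorrect count can only grow on rows that follow a menu decision.

## Replay

Replay starts at the start node and, at each visited decision node, looks
up the recorded answer for that node's question and follows the matching
edge. Matching is exact after whitespace normalisation (trim + collapse
internal runs); there is no fuzzy matching, because survey exports record
option text verbatim. Termination: at an endpoint (`complete=True`) or at
the first visited question with no recorded answer (`complete=False`,
anomaly `MISSING_ANSWER`). If a visited question holds several recorded
values the last submission wins (`MULTI_ANSWER`); answers recorded for
questions the path never visits are reported as `ORPHAN_ANSWER` — the
footprint of a survey back button that cannot be disabled. An answer
matching no option at its node raises `UNMATCHED_OPTION` rather than
guessing.

Incomplete paths are retained by default: they are excluded from endpoint
distributions and route frequencies, but appear in behaviour tables
frozen at their last status, so cohort size stays transparent. A
`strict` flag drops them instead. Duplicate user ids are kept as separate
records suffixed `#2`, `#3`, … — the dialect gives no safe merge rule.

## Behaviour classification

Let the expert route have K checkpoints (K−1 expert edges) and let a
user have made D decisions in total. The status at checkpoint k
(0-based) is computed from the first min(k, D) decisions:

* `incorrect` if any of them is incorrect-classified — absorbing;
* `expert` if they equal the expert route's first min(k, D) edges;
* `tolerable_only` otherwise.

At k = 0 no decisions have been made and every user is expert. Taking
min(k, D) freezes a finished or stalled user at their terminal status for
all later rows. The expert test is prefix equality of the decisions made
so far (rather than requiring exactly k expert decisions); the two
readings differ only for users who stop early while still on the expert
route, and prefix equality is what keeps such users frozen at `expert`
instead of silently demoting them. Only a user who deviates (tolerably or
harmfully) loses expert status, and can never regain it.

Reported tables count `tolerable = expert ∪ tolerable_only`, so every row
satisfies `n_tolerable + n_incorrect = N` and `n_expert ≤ n_tolerable`,
with `n_expert` non-increasing and `n_incorrect` non-decreasing down the
rows. Percentages are rounded half-up to one decimal (`decimal` module,
`ROUND_HALF_UP`), which reproduces the published arithmetic exactly
(e.g. 14/54 → 25.9, 26/54 → 48.1, 28/54 → 51.9). An empty cohort yields
0.0 percentages plus a warning rather than an error.

## Map rendering

`render_dot` emits Graphviz DOT text directly; the toolkit's contract
ends at the text, and any DOT processor can rasterise it. Layout: flow
left-to-right; three invisible cluster bands hold the expert row (in
route order, so it renders as the top spine), the middle tier, and the
failure endings; a note node lists every node id with its display label.
Edge pen width is linear in cohort fraction, `w = w_min + (w_max −
w_min)·f` with defaults 1–8 pt (`w_max < w_min` is an error), and expert
spine edges get a high layout weight so they render straight.

Edges are coloured by their role in the graph, not by the status of the
users on them (one drawn line can carry users of mixed status):
incorrect-classified edges magenta; edges joining consecutive expert
route nodes black; edges from an off-route node back onto the route teal
(re-joins); everything else orange (deviations); any edge with zero
traffic gray. Incorrect is checked first so a harmful edge is never
painted black even if it happens to connect consecutive route nodes. The
palette and shapes are plain dataclass fields and fully overridable.
Determinism: nodes and edges are emitted in canonical sorted order, so
identical inputs give byte-identical text; comparison maps share the
same node statements and differ only in edge styling and title.

## Synthetic cohorts

`make_demo_case(n_treatment_stages, options_per_menu)` builds a
structurally realistic case: an expert spine of timepoint circles (24 h,
then 42 h and 6-hourly — the published cadence) each followed by a fluid
diamond; the non-expert hydration choice leads to a parallel middle-tier
diamond; each menu has one expert option (next level in 6 h), tolerable
options collapsing onto an early-check detour circle that can rejoin the
spine one stage later, and incorrect options collapsing onto at most four
shared failure endings; one FINISH at the end of the spine. Defaults
(5, 8) mirror the published scenario's shape: an 11-checkpoint expert
route and menus at the small end of the 8–14 range.

`simulate_cohort` draws, at each decision node, a class from the
profile's `(p_expert, p_tolerable, p_incorrect)` mixture — renormalised
over the classes the node actually offers — then an option uniformly
within the class. Default mixture 0.8/0.15/0.05: a cohort that is mostly
sensible, deviates regularly, and errs harmfully occasionally, which
produces tables spanning all three columns at realistic cohort sizes.
Each user's generator is seeded with `SeedSequence([cohort_seed,
user_index])`, so cohorts are bit-reproducible and enlarging a cohort
never reshuffles earlier users. An optional `p_backtrack` leaves one
stray answer per affected user at an unvisited node, emulating
back-button artifacts; replay must (and does) recover the true path and
flag exactly the injected strays.

What the simulator does *not* model: learning or fatigue across a case,
correlation between a user's choices (draws are independent per node),
option-level preference within a class, response times, or any fit to
real participants. Passing tests therefore demonstrate the pipeline's
correctness and the table/map semantics, not claims about human cohorts.

Calibration checks use the mixture (0.8, 0.2, 0.0). With zero incorrect
mass the renormalisation over present classes is the identity at every
node — binary hydration prompts offer no incorrect option — so the
probability of an expert choice is a uniform 0.8 per decision, the
expected expert fraction at checkpoint k is exactly 0.8^k, and the
per-decision MLE (expert choices / decision encounters on route nodes)
recovers 0.8. Checks run at N = 2000 with a 3-standard-error band.

## Numerical and interface choices

* Percentages: `Decimal` half-up rounding; exports print exactly one
  decimal. Counts are exact integers throughout.
* Tie-breaks: all orderings are canonical (node id, option text, route
  order; route tallies by descending count then lexicographic route), so
  every artifact is deterministic byte-for-byte.
* Case files are YAML with sorted, fixed-order keys; response logs are
  CSV/TSV (dialect by extension, UTF-8 with BOM tolerated), with `.xlsx`
  as a convenience reader. A question answered twice is written as
  duplicate identically-headed columns in submission order.
* Exit codes of the `casemap` CLI: 0 success, 2 validation failure,
  3 input-format failure.
* Archetype cohorts (`make_archetype_cohort`) are deterministic users of
  three kinds — fully expert; tolerably deviating at the first prompt
  then locally expert (rejoining and finishing unharmed); expert once
  then harmful — used to construct cohorts with an exact behavioural
  composition.

## Problem sizes

The default verification suite works at the demo case's published shape
(5 stages, 8-option menus, 25 nodes, 105 edges) with cohorts of 5–60
users for exact/oracle checks, 200 random case-cohort pairs for the
invariant sweep, and 1500–2000 users for stochastic calibration; the
exhaustive path-enumeration oracle runs on 2-stage cases (≤ 200
root-to-leaf paths).

## Known limitations

* The checkpoint rule scores users by decision count, not by case-clock
  hours; a time-aligned alternative would need per-node timepoints for
  every off-route node and is not implemented.
* Whether a fluid-checkpoint row counts the hydration decision itself or
  the arrival state is a genuine ambiguity of the published table; the
  first-k-decisions rule makes the specific choice described above.
* DOT output encodes tier bands as invisible clusters; exact vertical
  ordering within the middle band is left to the layout engine.
* `compare_groups` reports descriptive tables only; no inferential
  statistics between arms are computed.
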