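# casemap

Toolkit for mapping multi-step clinical decision-making in branched
("choose your own adventure") case studies.

Branched cases — diagnostic branched trees, CYOA-style virtual patients —
let a learner manage a simulated patient through a sequence of prompts
where every choice routes them to a different continuation or ending.
They produce far richer behavioural data than single-best-answer
questions, but that data arrives as a sparse wide spreadsheet (one column
per form question, most cells blank because of branching) that is
painful to interpret by hand. `casemap` turns such logs into:

* **replayed paths** — each respondent's actual route through the case
  graph, with back-button artifacts and missing answers flagged;
* **behaviour tables** — at every checkpoint of the expert route, the
  number and percentage of users whose decisions so far were *expert*
  (exactly the specialists' choices), *tolerable* (harmless so far) or
  *incorrect* (at least one harmful choice; absorbing);
* **traffic maps** — deterministic Graphviz DOT renderings of the case
  with edge thickness proportional to the fraction of the cohort taking
  each route, coloured by role (expert spine black, deviations orange,
  re-joins teal, harmful choices magenta, untravelled routes gray);
* **group comparisons** — per-arm tables and layout-identical maps for
  side-by-side reading (e.g. flowchart-guided vs decision-support-guided
  cohorts), including disaggregation by role;
* **synthetic cohorts** — a seeded simulator that walks stochastic users
  through any case with a configurable expert/tolerable/incorrect choice
  mixture, so every pipeline stage is testable without participant data.

## The model

A case is a DAG. Non-endpoint nodes pose one question each — circles are
timepoint treatment prompts, diamonds hydration-state prompts, squares
endings — and each answer option is a classified edge
(`expert | tolerable | incorrect`). Exactly one option per decision node
is expert, so following expert edges from the start traces a unique
*expert route* ending at the *FINISH* node; its nodes are the checkpoints
of the behaviour table.

A user's status at checkpoint *k* is computed from their first
min(*k*, *D*) decisions (*D* = decisions made in total): **incorrect** if
any was a harmful option, **expert** if they are exactly the first
decisions of the expert route, **tolerable** otherwise. This makes the
table arithmetic exact at every row: `tolerable + incorrect = N` (the
reported *tolerable* column includes expert users), `expert ≤ tolerable`,
expert counts non-increasing and incorrect counts non-decreasing down the
table. Percentages are round-half-up to one decimal.

## Worked example

Simulate a 54-user cohort on the built-in demo case (5 timepoint stages,
8-option treatment menus) and summarise it:

```
$ casemap simulate --demo --n 54 --seed 7 --group-label SOC \
    -o cohort.csv --write-case demo.yaml
$ casemap summarize demo.yaml cohort.csv --out-dir out
wrote 4 tables to out (N=54)
$ cat out/behavior_table.tsv
node_id  label          n_tolerable  pct_tolerable  n_expert  pct_expert  n_incorrect  pct_incorrect
T24      24Hr           54           100.0          54        100.0       0            0.0
F24      24Hr fluid     54           100.0          49        90.7        0            0.0
T42      42Hr           51           94.4           40        74.1        3            5.6
F42      42Hr fluid     50           92.6           35        64.8        4            7.4
T48      48Hr           49           90.7           27        50.0        5            9.3
F48      48Hr fluid     48           88.9           24        44.4        6            11.1
T54      54Hr           45           83.3           20        37.0        9            16.7
F54      54Hr fluid     45           83.3           16        29.6        9            16.7
T60      60Hr           42           77.8           10        18.5        12           22.2
F60      60Hr fluid     42           77.8           7         13.0        12           22.2
FINISH   FINISH 66Hr    42           77.8           6         11.1        12           22.2
```

Read down the `pct_expert` column: every user starts expert (no decisions
yet at the 24-h prompt), 90.7% still match the specialists after the
first hydration choice, and only 11.1% made *exactly* the expert choice
at all ten decisions. 77.8% never chose a harmful option
(`pct_tolerable` at FINISH), while 22.2% crossed an incorrect edge and
are counted incorrect from that point on. The companion tables show where
everyone ended up and how:

```
$ cat out/endpoint_distribution.tsv
endpoint  n_users
End1      2
End2      3
End3      4
End4      3
FINISH    42
```

Render the traffic map (any Graphviz `dot` binary turns it into an
image; the text itself is the stable artifact):

```
$ casemap map demo.yaml -r cohort.csv -o traffic.dot
$ dot -Tsvg traffic.dot -o traffic.svg   # optional
```

Compare study arms recorded in a `group` column with
`casemap compare demo.yaml cohort.csv --group-col group`, which writes a
behaviour table and a layout-identical map per arm. Everything is also
available as a library:

```python
from casemap import (make_demo_case, simulate_cohort, CohortSpec,
                     behavior_table, edge_usage, render_dot)

case = make_demo_case(5, 8)
res = simulate_cohort(case, CohortSpec(n_users=54, seed=7))
table = behavior_table(case, res.paths)          # pandas via .to_frame()
dot = render_dot(case, edge_usage(case, res.paths))
```

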