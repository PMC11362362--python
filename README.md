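# ideaspark

Word recommendations from a semantic memory network, for breaking
creative impasse in divergent-thinking experiments.

When people generate alternative uses for an object (the classic
divergent-thinking task: "name creative uses for a brick") they
eventually get stuck — a creative impasse. One account of why is that
idea search is a traversal of semantic memory, and the searcher has
gotten trapped in one neighbourhood of it. `ideaspark` implements a
network-science tool built on that account: it models semantic memory as
a word graph estimated from free-association norms, and when a
participant declares an impasse it recommends a word at a *controlled
location* in that graph — at a chosen shortest-path distance from the
task object, and directed either towards or away from the participant's
own prior ideas. Because the location of every prompt is quantified, the
effect of prompt distance and direction on subsequent fluency and
originality becomes measurable.

It is a library plus a CLI, aimed at researchers running or simulating
prompted idea-generation experiments.

## The model in brief

- **Network.** Nodes are words; an edge joins $\{a,b\}$ when the pooled
  association count $C(a{\to}b) + C(b{\to}a) \ge m$ (default $m = 10$
  people). The graph is unweighted and restricted to its largest
  connected component. Distances are shortest-path edge counts $d(u,v)$.
- **Idea space.** A participant's responses are lower-cased, stripped of
  punctuation, stop-word filtered, and intersected with the network's
  node set, giving the token set $S$.
- **Recommendation.** For object $o$, distance $\delta \in \{1..4\}$ and
  direction, candidates are the exact ring
  $R_\delta(o) = \{w : d(o,w) = \delta\}$, scored by
  $\bar d(w,S) = \tfrac{1}{|S|}\sum_{s \in S} d(w,s)$. Towards picks
  $\arg\min \bar d$, away picks $\arg\max \bar d$; already-used words,
  the object, and previously shown recommendations are skipped for the
  next best candidate. Ties break lexicographically; every pick is a
  deterministic function of its inputs and the seed.
- **Measures.** Per trial: fluency before/after impasse, binary impasse
  break, idea-order coding (last pre-impasse response = 0, first
  post-recommendation response = 1), response times, close/far
  dichotomization of distance (1–2 vs 3–4), and response adherence
  (mean path length from a response's tokens to the shown
  recommendation).

See `docs/methods.md` for assumptions, parameters, edge cases, and what
the synthetic fixtures do and do not emulate.

## Worked example

A six-pair association file reproduces the canonical toy network
(brick–wall–house–garden–flower and brick–fire–flare):

```sh
$ cat assoc.csv
cue,response,count
brick,wall,12
wall,house,11
house,garden,10
garden,flower,13
brick,fire,12
fire,flare,10

$ ideaspark build-net --input assoc.csv --output net.tsv
wrote 7 nodes, 6 edges to net.tsv
```

A participant asked for creative uses of a brick answered "build a wall"
and is stuck. A distance-2 recommendation directed *away* from that idea:

```sh
$ echo "build a wall" > responses.txt
$ ideaspark recommend --network net.tsv --object brick \
    --distance 2 --direction away --responses responses.txt
flare
# distance=2 direction=away avg_distance_to_idea_space=3.0 rank=0 fallback=none
```

Both distance-2 candidates (house, flare) sit two steps from brick; the
idea space is {wall} ("build" and "a" are off-network/stop-words), and
flare is the candidate farthest from it (mean path length 3.0 vs 1.0).
Flipping `--direction towards` prints `house` with
`avg_distance_to_idea_space=1.0` — the prompt closest to what the
participant already said.

Simulated studies and scoring:

```sh
$ ideaspark simulate --out logs.jsonl --n-participants 10 --n-trials 5 --seed 1
wrote 10 sessions (50 trials) to logs.jsonl
$ ideaspark score --logs logs.jsonl --out trials.csv
wrote 50 trial rows to trials.csv
$ head -3 trials.csv
participant_id,trial_id,object,distance,direction,close_far,fluency_before,fluency_after,impasse_break,fallback_used,recommendation,mean_adherence,originality_pre,originality_post
p000,p000-t0,w008,1,away,close,3,0,0,none,w022,,,
p000,p000-t1,w036,1,away,close,3,1,1,none,w019,,,
```

Each row is one trial: the condition it was randomized into, how many
ideas came before and after the impasse, and whether the recommendation
broke it (`impasse_break`). The same operations are available as library
functions (`build_network`, `recommend`, `simulate_study`,
`trial_table`, ...).

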