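# Methods

## The model

`ideaspark` operationalizes semantic memory as an undirected, unweighted
word graph built from free-association norms. Let $C(a \to b)$ be the
number of participants who produced word $b$ as a free association to cue
$a$. An edge joins the unordered pair $\{a, b\}$ when the pooled count

$$C(a \to b) + C(b \to a) \ge m$$

with threshold $m = 10$ people by default. Association frequency is used
only for thresholding, never as an edge weight: all distances are
unweighted shortest-path edge counts $d(u, v)$, following the convention
in the cognitive-network literature where path length up to about four
steps tracks judged relatedness. Words that never reach the threshold on
any pair are dropped (they could never be recommended and have no finite
path), and the graph is restricted to its largest connected component so
every pairwise distance is finite.

Directed counts are pooled because "a pair of words" is unordered; the
alternative reading — either single directed count alone reaching the
threshold — is available as `count_mode="either_direction"`. Ties between
equal-size largest components are broken in favour of the component
containing the lexicographically smallest label, so construction is a
deterministic function of the records.

## The recommendation rule

A recommendation request consists of an in-network object word $o$ (the
divergent-thinking cue), a distance $\delta \in \{1, 2, 3, 4\}$, a
direction (towards/away), and the participant's idea space $S$ — the set
of in-network tokens extracted from their prior responses. The candidate
set is the exact-distance ring

$$R_\delta(o) = \{ w : d(o, w) = \delta \},$$

a ring and not a ball: words strictly closer than $\delta$ are excluded.
Each candidate is scored by its mean distance to the idea space,

$$\bar d(w, S) = \frac{1}{|S|} \sum_{s \in S} d(w, s),$$

and the pick is $\arg\min_w \bar d(w, S)$ for a towards recommendation,
$\arg\max_w$ for away, skipping excluded words in score order ("the next
best word"). The exclusion set is deliberately a superset of "words the
participant already used": all post-stoplist response tokens (including
out-of-network ones), the object itself, and any recommendation already
shown in the trial, so the tool cannot echo the prompt back.

Ties in $\bar d$ are broken lexicographically. The score is a mean over a
*set* of idea-space tokens by default; `idea_space_mode="multiset"`
instead weights tokens by their number of occurrences across responses.
Set semantics is the default because multiset averaging lets a
participant who types one word three times dominate the direction score.

Degenerate inputs are handled explicitly rather than silently:

- **Empty idea space.** Participants must give at least one pre-impasse
  response, but all of its tokens may be out-of-network. The score is then
  undefined for every candidate, so the recommendation is a uniform draw
  from the eligible ring using the caller's seeded generator, recorded as
  `fallback_used = empty_idea_space_random`.
- **Empty or exhausted ring.** A hard error by default — silently changing
  the distance condition would corrupt an experiment. With the explicit
  `fallback_distance` flag, $\delta - 1$ then $\delta + 1$ are tried and
  the shift is recorded (`fallback_used = nearest_distance`,
  `distance_used`).

## Text preprocessing

Responses are lower-cased, stripped of punctuation, whitespace-collapsed,
split on whitespace, and filtered against a stop-word list — a plain
bag-of-words pipeline with no lemmatization, stemming, or spell
correction. Internal hyphens and apostrophes are removed rather than
split ("don't" → "dont", "well-known" → "wellknown"), keeping
contractions as single tokens. The operation is idempotent, which makes
stored processed responses safe to re-process.

The stop-word list is a frozen snapshot of the standard NLTK English list,
bundled as a data file so results cannot drift with library versions; it
can be replaced with `--stoplist FILE`. Stop-list entries pass through the
same normalization as responses so entries like "don't" match their
processed form.

## Trial measures

A trial is: pre-impasse responses → explicit impasse → one recommendation
→ optional post responses. Measures, each computable independently from
the event log:

- **Fluency** — the pair (number of PRE responses, number of POST
  responses).
- **Impasse break** — 1 iff at least one POST response exists; requires
  that a recommendation was actually shown.
- **Idea order** — serial position with the last PRE response at 0
  (earlier ones −1, −2, …) and the first POST response at 1, so the
  PRE/POST boundary sits between codes 0 and 1 regardless of trial length.
- **Response time** — per response, first keystroke minus slot start,
  where the slot starts at the trial start, the previous response's end,
  or the recommendation display. Times are seconds to millisecond
  precision on a monotone clock; a negative interval raises a clock-skew
  error rather than being clamped.
- **Close/far** — distances 1–2 code as close, 3–4 as far, for
  dichotomized analyses.
- **Adherence** — mean path length from the shown recommendation to the
  response's in-network tokens; missing when the response has none.
- **Originality** — human ratings in [1, 5] are pass-through inputs; the
  package stores them per response and averages per phase, but never
  computes them.

Conditions are assigned per trial by independent uniform draws over
distance × direction. Session logs are append-only JSON Lines; the trial
table is a pure function of the log (round-tripping a session through the
log changes no measure), exported as CSV in a fixed column order.

## Synthetic data

Real free-association norms are large external downloads, so the test
substrate is synthetic and generated at run time:

- **Toy 7-node tree** (`toy_network_T1`): brick–wall–house–garden–flower
  plus brick–fire–flare. Small enough that every distance is checkable by
  hand; with idea space {wall} the distance-2 towards/away picks are
  house (mean distance 1) and flare (mean distance 3).
- **Planted graphs**: connected Erdős–Rényi graphs (default n = 30,
  p = 0.12, regenerated until connected) emitted as association records —
  pooled counts ≥ m on planted edges, 1 … m−1 on a controlled set of
  non-edges — so that thresholded reconstruction is exactly the planted
  edge set. This makes the "at least m people" rule testable as a
  round-trip identity and a sharpness probe (decrementing one pooled count
  from m to m−1 removes exactly that edge).
- **Random-walk agent**: pre-impasse responses are labels visited by a
  seeded walk from the object, restarting at the object with probability
  0.2 per step to emulate topic-tethered search (3 responses per trial by
  default, matching a typical pre-impasse fluency of a few ideas); after
  the recommendation the agent responds with probability `p_break`,
  drawing from the recommendation's network neighbourhood. The agent is a
  testing device: it exercises every code path and gives exact expected
  break rates at `p_break` ∈ {0, 1} and binomial behaviour in between,
  but it models no cognition — passing tests say the machinery is correct,
  not that human fluency or originality effects would reproduce.

One seeded random stream drives an entire simulated study, so a session
is exactly replayable; logs and trial CSVs are byte-identical across runs
with the same seed. The agent enables the nearest-distance fallback so
that small-diameter planted graphs cannot abort a study; every shift is
visible in the logged `fallback_used`/`distance_used` fields.

What the synthetic data does **not** emulate: real association norms'
heavy-tailed degree distribution and clustering, multi-word responses,
typos, and the semantic coherence of human idea sequences. Conclusions
about human behaviour require the real norms and real participants.

## Numerical and scale choices

- Verification sizes: 100 random graphs (n ≤ 40) for the brute-force
  distance oracle, 200 instances for recommender optimality by exhaustive
  enumeration, 1,000 randomized picks for constraint satisfaction, 8,000
  draws for condition uniformity (chi-square GOF, α = 0.001), 2,000
  simulated trials for the binomial break-rate check (3 standard errors).
  All scores are exact rationals of small integers, so every comparison
  in those checks is exact equality, not tolerance-based.
- The distance range {1, …, 4} follows the finding that word pairs up to
  roughly four steps apart are still judged related; it is configurable.
- `scripts/acceptance.py` re-runs all of the above from scratch at those
  sizes (about 4 s on one CPU) and writes the measured rates as JSON.

## Known limitations

- Shortest-path BFS on each query is fine for networks of ~10⁴ nodes but
  the candidate scoring does one BFS per idea-space token; very large
  idea spaces (unbounded session transcripts) would warrant caching.
- The raw-dialect reader treats missing-response sentinel strings as
  configuration because they vary across dataset releases; reproducing a
  specific published network additionally requires knowing which response
  columns (first-only vs all three) that build used. Both are exposed as
  options.
- Adherence is defined here as mean path length to the response's
  in-network tokens; other operationalizations (minimum distance,
  embedding similarity) are plausible and would need their own validation.
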