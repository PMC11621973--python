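# Methods

`packsocial` analyses the social system of a small canid group (the
motivating case is a golden jackal, *Canis aureus*, pack monitored by
camera traps) from a stream of coded behavioural events. This note
documents the models and procedures, the choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish.

## Observation model

The unit of observation is a short (~30 s) camera-trap recording, coded
against a fixed 13-behaviour ethogram into one or more events. Two
behaviours are directed (aggression, submission); all others, including
scent marking, are coded with an actor only. Each event carries the set of
individuals identified in its recording; **co-occurrence in the same
recording is the operational definition of association** throughout. The
alternative — requiring simultaneous frames within a recording — is not
representable in an event table and was not adopted.

Failed identifications are recorded with the `UNIDENTIFIED` actor
sentinel. Such rows are retained in the log (they still count as
detections for activity and temporal-independence diagnostics) but are
excluded from dominance tallies (and counted in a skipped-event tally) and
contribute nothing to association edges, since edges require identities.

Group tenure (entry/exit dates in the roster) encodes the composition
timeline; membership at an event's time is the roster filtered by tenure.

## Reliability diagnostics

*Cohen's kappa.* Identification is observer work, so a sample of
detections is re-identified in a second round and agreement is scored with
unweighted kappa, κ = (p_o − p_e)/(1 − p_e), where p_o is the diagonal
fraction of the round-1 × round-2 confusion table and p_e the agreement
expected from the marginals. κ is undefined when p_e = 1 (all mass in one
row-column pair); this raises an error rather than returning a number.
Weighted and multi-rater variants are out of scope (one observer, two
rounds).

*Temporal independence.* The autocorrelated series is the per-bin count of
recording starts, with a configurable bin width defaulting to one day —
the event table does not preserve anything finer that is comparable across
cameras. The estimator is the standard biased sample ACF (denominator over
the full series); default maximum lag is min(30, n/4), the usual guidance
for short series. A constant series raises a zero-variance error.

## Dominance hierarchy

Win rules, applied per event: aggression credits the aggressor with one
win over the recipient; submission credits the *recipient of the display*
with one win over the displayer; a scent mark credits the marker with one
win over **each** other adult in the group at the event's time (tenure
based). The fan-out reading of the scent-mark rule is the default; a
variant worth one aggregate point (1/k against each of k others) sits
behind `scent_mark_fanout=False`. Because of that variant the win matrix
container admits non-negative reals; the default rules always produce
integers.

From the win matrix, dyadic proportions P_ij = s_ij/(s_ij + s_ji), with
P_ij = 0 for unobserved dyads (the plain proportion convention). David's
score DS = w + w2 − l − l2 combines direct (w, l) and opponent-weighted
(w2, l2) win/loss proportions; NormDS = (DS + N(N−1)/2)/N maps onto
[0, N−1]. Two exact identities follow algebraically and are enforced as
invariants: ΣDS = 0 and ΣNormDS = N(N−1)/2. The sample-size-corrected
dyadic index D_ij = P_ij − (P_ij − 0.5)/(n_ij + 1) (de Vries et al. 2006)
is available via `correction="dij"`; it is *not* the default because the
plain form is the textbook definition and its sum identities are exact.

Only adults enter the matrix. Ranks sort NormDS descending with a
deterministic tie-break chain — more raw wins, then fewer raw losses, then
lexicographic id — recorded per individual in the output, so identical
printed scores still yield a reproducible order.

## Association network

Sightings are tallied per recording: n_i recordings containing i, x_ij
containing both. Edge weights are raw counts (default) or the simple-ratio
index SRI = x/(n_i + n_j − x) ∈ [0, 1]; both are exposed because either is
defensible for sociograms and they give the same topology at different
scales. A collapse map can merge ids into one node (e.g. a pup cohort into
"Pups"); a recording containing several merged individuals counts once for
the merged node.

*Eigenvector centrality* is the leading eigenvector of the weight matrix,
scaled so the maximum is exactly 1. It is computed by power iteration from
the uniform vector on the shifted matrix A + cI with c = max row sum.
The shift is a numerical necessity, not a modelling choice: on
bipartite-like graphs (a star is the canonical case) A's extreme
eigenvalues are ±λ and plain power iteration oscillates forever; adding
cI preserves the Perron eigenvector while making its eigenvalue strictly
dominant. Tolerance 1e−12 in max-norm on successive normalised iterates,
cap 10⁵ iterations, no randomness. Disconnected networks are an error by
default (`largest_component=True` restricts to the largest component);
silent analysis of fragments is a common source of wrong centralities.

*Modularity* is the weighted Newman form
Q = (1/2m) Σ_ij (A_ij − k_i k_j/2m)[c_i = c_j]. *Clustering* is
Clauset–Newman–Moore fast-greedy agglomeration: from singleton
communities, repeatedly merge the connected pair with the largest ΔQ,
breaking ties by the lexicographically smallest pair of community labels
(a community is labelled by its smallest member id) so runs are
bit-reproducible. The returned partition is the trace maximum; the
all-in-one partition (Q = 0) always terminates the trace, so the reported
Q is never negative. Q > 0.3 sets the conventional `strong_structure`
flag. At the group sizes this package targets (≤ a few dozen nodes) the
O(N³) dictionary implementation is more than fast enough, and its greedy
optimum is verified against exhaustive partition search on small planted
graphs.

## Synthetic study generator

The generator emulates the data-generating process of a single-group
camera-trap study, with defaults fixed to the motivating study's
conditions:

| parameter | default | meaning |
|---|---|---|
| `n_adults` | 7 | adults at study start |
| `latent_strengths` | (2.0, 1.8, 0.6, 0.5, 0.4, 0.3, 0.2) | dominant pair well above homogeneous subordinates |
| `beta` | 1.5 | steepness of the logistic win curve σ(β(s_i − s_j)) |
| `dyadic_rate` | 0.05/day | Poisson rate of agonistic events per dyad |
| `scent_mark_rates` | 0.1/day dominants, 0.02 others | per-adult Poisson marking rates |
| `p_in`, `p_out` | 0.5, 0.35 | within/between-cluster co-detection probabilities (weak structure) |
| `recordings_per_day`, `n_days` | 5, 290 | ~1450 detection recordings over ~9.5 months |
| `dispersal_ids`, `dispersal_day` | 3 subordinates, day 140 | mid-study dispersal |
| `pup_count`, `pup_day` | 6, day 170 | juvenile cohort entry |
| `misid_accuracy` | 0.9 | per-detection re-identification accuracy (yields κ ≈ 0.85) |

Agonistic encounters per present dyad per day are Poisson (memoryless,
matching sparse camera-trap detections); the winner follows the logistic
model, and the event is emitted as aggression by the winner or, with
probability `submission_fraction` (0.3), as submission by the loser — the
two encodings are win-equivalent by construction and tested to build
identical dominance matrices. Detection recordings pick a uniform anchor
among present members and co-detect every other member with probability
p_in/p_out by cluster; pups join the dominant pair's cluster. All
randomness flows from the single config seed through one
`numpy.random.default_rng`.

**What the generator does not emulate:** camera placement and detection
heterogeneity in space, diel activity rhythms, recording-quality loss,
misidentification inside the analysis log (noise enters only the
re-identification table), and any territorial/spatial process. Passing
recovery tests therefore show that the estimators invert this idealised
process, not that they are robust to field artefacts.

## Recovery experiments (problem sizes)

The test suite and acceptance script run: 1000 random win matrices
(N = 2..10) for the score identities; hierarchy recovery over 100 seeds
(7 adults, equally spaced strengths 3.0..0.0, β = 1.5, ~25 interactions
per dyad over 100 days — passes in ≈98/100); planted two-cluster recovery
over 100 seeds (8 nodes, p_in = 0.8, p_out = 0.1, 200 recordings —
≈100/100); kappa monotonicity in accuracy q over {0.5, 0.7, 0.9, 1.0}
averaged over 50 seeds; and a full-pipeline run at the default study
scale. These sizes keep the whole suite under a couple of minutes while
leaving the statistical margins wide.

## Known limitations

- The dominance matrix pools the whole study period; a tenure-weighted or
  period-split hierarchy is the caller's job via `restrict_log`.
- The ACF diagnostic is descriptive; no significance bands beyond the
  ±2/√n convention used in tests.
- Fast-greedy agglomeration is a heuristic; it is exact on the planted
  structures tested here but can miss the global modularity optimum on
  adversarial graphs.
- SRI assumes detection homogeneity across individuals; raw counts
  confound gregariousness with detectability. Both are reported rather
  than adjudicated.
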