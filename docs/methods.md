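# Methods

`netweave` analyses seasonal time series of weekly plant-pollinator
networks: it aligns networks by species' structural roles, quantifies how
unique and how variable species' positions are, clusters positions into
recurring groups, and fits a Bayesian model of species' movement among
those groups.  This note records the model choices, the parameters that
matter, and the limits of what the synthetic tests demonstrate.

## Weekly networks

Interaction records (season, week, plant, pollinator, count) are
aggregated into one weighted bipartite network per sampled week; an edge
weight is the total number of interaction events observed for that species
pair in that week.  Species appear in a week only if they interacted in
it.  Week indices are taken as recorded and may be non-contiguous; the
season length `W` counts *sampled* weeks, and all relative times are
week position divided by `W`.  Binary (qualitative) networks set every
weight to 1; they carry strictly less information, and position uniqueness
is correspondingly lower on them.

## Motif roles

A motif is a connected guild-labeled bipartite graph on 3-5 species;
plants and pollinators are never interchangeable, so a plant star and a
pollinator star are distinct motifs.  For sizes 3/4/5 there are 2/4/10
motifs with 4/10/30 node orbits (positions), 44 positions in all; the
catalog is verified in the test suite against brute-force enumeration
with networkx isomorphism testing.  Motif occurrences are counted on
connected *induced* subgraphs, the standard convention in bipartite motif
analysis.  A species' role vector counts its appearances in each position;
in weighted mode each occurrence credits the arithmetic mean of that
occurrence's edge weights (the simplest strength-aware generalization;
`sum` and `geometric_mean` are available behind the same switch).
Canonical motif encodings (lexicographically minimal adjacency bitmasks
over guild-preserving relabelings) make position indices stable across
networks and runs.

## Alignment

Two networks are aligned by a guild-respecting one-to-one pairing that is
maximal within each guild.  The cost is

    C = sum over pairs (1 - c_ij) + penalty * #unpaired,

with `c_ij` the Pearson correlation between role vectors (0 when either
vector has no variance) and `penalty` defaulting to 1.0 — equivalent to
pairing with a fully uncorrelated partner.  Each species left unmatched,
on either network's side, contributes one penalty term.  This cost form
is this package's own definition: it is zero at perfect self-alignment,
monotone in role similarity, and handles unequal guild sizes explicitly.

The optimizer is simulated annealing over pairings (partner-swap moves,
geometric cooling with T0 = 1.0, factor 0.995 per sweep, 500 sweeps by
default, greedy 2-swap descent from the best state visited).  A run
returns the best pairing it encountered.  Because equally optimal
pairings are common — any structural symmetry produces them — an
alignment is always an *ensemble* of independent restarts (default 100),
and every downstream statistic is computed over the ensemble.  Since the
cost is a sum over pairs, the per-guild optimum is an assignment problem;
the test suite uses the Hungarian algorithm and exhaustive enumeration as
independent oracles and verifies that 100 restarts reach the exact
optimum on small instances.  A deterministic assignment solver is *not*
used as the implementation because a single optimal solution would hide
the degenerate optima that the uniqueness and variability statistics are
designed to expose.

## Position statistics

* **Uniqueness** of a species in a network: the share of repeated
  self-alignments pairing it to itself.  A structurally unique species
  scores 1; `k` mutually symmetric species score about `1/k` each.
* **Variability** of a species across a season: over all (network pair,
  run) alignments between weeks that both contain it, the share in which
  it is *not* paired to itself.  Being paired to another species and
  being left unpaired both count as changed position; each (pair, run)
  observation has equal weight.
* **Fixed-pair loss**: best constrained cost (species forced to pair with
  itself) minus best unconstrained cost, each over the same number of
  restarts.  Raw values are reported; they are non-negative up to
  optimizer noise.
* Threshold summaries ("fraction of positions with score > 0.9") are
  computed over species-network occurrences, per guild.

## Alignment matrix and position groups

All ensembles are compiled into an occurrence-by-occurrence matrix `M`
(an occurrence is a (weekly network, species) pair).  The entry between
(A, i) and (B, j) is pairing frequency times the mean positive role
correlation of those pairings — a bounded frequency-times-quality score
in [0, 1]; a frequency-only mode exists for sensitivity checks.
Self-alignment blocks are symmetrized by averaging the two pairing
directions.  `M` is exactly block-diagonal by guild, so plants and
pollinators are partitioned independently with the walktrap
("short random walks") algorithm, 4 steps by default, taking the
modularity-optimal cut of the merge tree.  Partitions from different
algorithms are compared with normalized mutual information
(arithmetic-mean entropy normalization, configurable).

Group labels are ordered by descending group mean of the most-connected-
partner relative degree, ties by mean relative degree — so the
"attached to generalists" groups come first.  Group character is
described with three per-occurrence statistics computed in the
occurrence's own weekly network: relative degree `k_i = l_i / l_max`
(distinct partners over the network maximum), the relative degree of the
most connected partner, and the mean partner relative degree.  Two side
analyses probe robustness: random removal of interaction events (degree
sensitivity) and an OLS regression of relative degree on abundance, whose
headline number is the unexplained variance share `1 - R^2`.

## Transition model

Weekly group memberships become state trajectories over the n groups
plus `pre` (not yet entered) and `post` (exited, absorbing).  A step's
relative time is the destination week position divided by `W`.  A
presence-absence-presence pattern within a species' activity period is
treated as likely sampling error: the step into the gap, any steps inside
it, and the re-entry step are all excluded from the likelihood.  A
species present in the final sampled week contributes no exit transition
(right-censored); nothing observed distinguishes staying from leaving
after sampling stops.

Transition probabilities are a softmax over per-destination scores linear
in relative time.  Structural zeros are enforced as restricted choice
sets: group origins choose among all groups and `post`; the `pre` origin
chooses among all groups and staying `pre`; `post` is absorbing.  One
score per origin row is fixed to zero (the exit cell for group rows; the
stay cell for the `pre` row — the exit state is unreachable from `pre`,
so it cannot serve as that row's reference).  The free parameters are one
intercept and, in the time-dependent form, one slope per free cell — a
one-to-one linear reparameterization of writing each score as a global
intercept plus origin-specific offsets.  Every parameter gets an
independent N(0, 10) prior.

Sampling uses the affine-invariant ensemble sampler (emcee) with
differential-evolution moves, `max(2*ndim + 2, 32)` walkers, 2000 steps
by default with the first half discarded and thinning by 4.  Convergence
is monitored with split R-hat across walker groups plus the mean
acceptance fraction; values above 1.1 raise a warning.  Walker-based
R-hat is a conservative heuristic — walkers are not independent chains —
so borderline values call for longer runs rather than alarm.  Model forms
(time-dependent vs constant, and season-replicate variants fitted by
passing per-season trajectory subsets) are compared with
WAIC = -2(lppd - p_waic), computed from pointwise posterior
log-likelihoods.

## Synthetic data

The generator emulates the empirical shape of such studies — defaults are
three seasons of 12/15/16 sampled weeks, 46 plants and 93 pollinators,
three latent groups.  Latent dynamics are primary: every species runs the
configured transition law as a Markov chain from `pre`, so phenology
windows (entry and exit weeks) *emerge* from the law and no-re-entry
holds by construction.  Edges follow the latent groups: pollinators draw
a group-dependent number of plant partners with a group-dependent
preference exponent over plant attractiveness (positive = preferential
attachment to generalist-like plants, negative = avoidance), weights are
geometric counts with mean 3, abundance is a lognormal mark coupled to
degree with configurable strength (default exponent 0.5, so degree is
abundance-correlated but not abundance-determined), and a 5% per
species-week detection dropout hides observations strictly inside
activity periods to exercise the gap rule.

What the synthetic tests do **not** show: real communities have
phenological structure (seasonal entry waves, species-specific windows),
taxon-specific interaction preferences, and sampling designs that no
Markov-plus-preference generator reproduces.  Passing the recovery tests
demonstrates that the pipeline's statistics measure what they claim under
known ground truth — not that any particular empirical community has
three groups or a particular transition structure.

A related ceiling is worth naming: the pipeline groups *realized weekly
positions*, while the generator plants *latent* memberships.  A latent
generalist that happens to realize only two interactions in some week
genuinely occupies a specialist-like position that week, so at the
reduced network sizes used for fast reproduction the occurrence-level
grouping is finer than (and only moderately informative about) the three
planted latent groups.  The planted-partition test on the alignment
matrix itself — where the block structure is explicit — is what isolates
the correctness of the group detector; end-to-end group counts at small
scale are honest outputs of the realization process, not detector
errors.

## Problem sizes used in reproduction

`scripts/acceptance.py` runs the full pipeline on a generated study of 3
seasons with 8/9/10 sampled weeks, 16 plants and 26 pollinators, 25
alignment restarts per network pair (annealing shortened to 200 sweeps),
and up to 2500 sampler steps per model form (automatically reduced when a
large detected group count inflates the parameter space, to keep the
stored chain within ~1 GiB).  The transition model is fitted for the
pollinator guild, the headline analysis; the library fits both guilds.  These sizes keep a complete
from-scratch reproduction fast while leaving every stage's behaviour
qualitatively identical to the full-scale defaults; the test suite
separately verifies the optimizer and sampler at their default settings
on small instances.  Recovery studies in the acceptance tests use 150
species-seasons (constant-law calibration) and 250-300 species-seasons
(time-trend sign recovery), with trend designs centred at mid-season so
every transition cell retains observations across the time range.

## Numerical choices and edge cases

* Role correlation falls back to 0 for zero-variance vectors (species in
  networks too small to contain any 3-species subgraph have zero role
  vectors).
* Softmax is overflow-safe via max subtraction; impossible destinations
  carry a score of -inf and exactly zero probability.
* Alignment costs are clamped at 0 against accumulated float error on
  perfect alignments.
* Ties among equal-cost pairings are resolved by whatever each annealing
  run finds; the restart ensemble, not a tie-break rule, is the device
  that exposes symmetric alternatives.
* Walktrap singletons (occurrences with no positive similarity to their
  guild block) become their own groups; group labels are relabeled by
  size and then by group properties as described above.

## Known limitations

* The annealing optimizer is exact only in expectation over restarts;
  very large guilds may need more sweeps or restarts than the defaults.
* The cost function and the frequency-times-quality matrix entry are this
  package's declared forms; other monotone combinations are plausible and
  the config exposes the main alternatives.
* The transition model conditions on the detected grouping; uncertainty
  in the grouping itself is not propagated into the posterior.
* Season-replicate model variants share the cell parameterization and
  differ only in which trajectories they see; no random effects across
  seasons are implemented.
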