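# Methods

This note documents the models and algorithms implemented in `cutevo`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Trait data

The packaged table compiles the predominant cutting preference of every
valid leaf-cutting ant species (46 records: 28 *Acromyrmex*, 3
*Amoimyrmex*, 15 *Atta*). Free-text annotations are normalized
case-insensitively to `{dicot, grass, dicot_grass}` plus two bookkeeping
categories:

- **Question-marked annotations** ("Grass?", "Dicot?-Grass") resolve to the
  stated state with `uncertain=True` and count toward that state in
  summaries. This rule is forced by the table's own arithmetic: the printed
  per-state totals (27 dicot, 12 grass, 4 dicot-grass) are reproduced only
  if uncertain species count toward their stated preference.
- **`unknown`** is reserved for a bare "?" or an empty cell (no documented
  preference at all: *A. evenkul*, *A. pubescens*). Unknown species are
  excluded from phylogenetic analysis by default; a flag admits them as
  fully ambiguous tips.
- **`parasite`**: the social parasite *A. ameliae* is kept as a distinct
  bookkeeping state but enters likelihood computations as a fully ambiguous
  observation (all-ones vector). A fourth Markov state with a single tip
  would be unestimable; the species-level override set is configurable, so
  a 4-state analysis remains possible by supplying custom state labels.

Tip labels are `Genus_species` with underscores (newick-safe); table lookup
is case-insensitive. A known data caveat: the source's running text is
internally inconsistent about the number of species available for
phylogenetic analysis (33 vs 34 and 20/21 per genus); the package follows
the table's inclusion column, which yields 34 (20 *Acromyrmex*, 3
*Amoimyrmex*, 11 *Atta*).

## Trees

`Chronogram` is a rooted tree with nonnegative branch lengths in absolute
time. Newick and NEXUS parsing/writing go through dendropy; node ids are
assigned in postorder and are deterministic for identical input text, so
node-indexed reports are reproducible. Polytomies are supported everywhere
(pruning, ASR, mapping); zero-length branches are allowed and get identity
transition matrices.

Ultrametricity is validated with a relative tolerance of 1e-6 × root age by
default — real chronograms carry rounding noise. Two time coordinates are
used and always labelled: *age* (time before present, tips at 0) and
*forward time* t_f = root_age − age (the accumulation grid's axis).

Pruning a tree to a taxon subset removes unkept tips and suppresses the
resulting degree-2 nodes with branch lengths summed, which preserves
patristic distances among retained tips exactly.

Stochastic maps serialize to SIMMAP-dialect newick
(`tip:{state,dur:state,dur}`, segments in parent-to-child order). No
installed library reads or writes this dialect, so the serializer and a
small dedicated parser live in `tree_io`; round-trips preserve segment
structure to 1e-9.

## Mk model and likelihood

The character evolves as a k-state CTMC (k = 3 here). Under equal rates
(ER), Q has off-diagonals q and diagonal −(k−1)q, and P(t) has a closed
form (see README); the closed form is used on the ER path and verified
against `scipy.linalg.expm` in tests, with `expm` retained as the general
fallback for any future non-ER Q.

The likelihood is computed by Felsenstein pruning with **per-node scaling**:
each node's partial-likelihood vector is divided by its maximum and the log
scalers accumulated, so trees up to ~10^4 tips cannot underflow. Tip data
enter as observation vectors — indicators for known states, all-ones for
ambiguous tips — and an all-zero vector is rejected as an impossible
observation.

`fit_er_rate` maximizes log L over log q with bounded Brent optimization on
the bracket [1e-8/T, 1e3/T] (T = root age), a scale-free interval covering
effectively-frozen through saturated regimes in any time unit. If every tip
shares one certain state the likelihood is monotone decreasing in q; the
function warns and returns the lower bound. The workflow fits q once and
conditions ancestral states and mapping on q̂ (the standard empirical-Bayes
practice); q is not re-optimized per node or per map.

The root prior defaults to uniform, which equals the ER stationary
distribution and makes the model time-reversible — the property the
re-rooting method requires. A non-reversible prior is refused by the ASR
functions rather than silently accepted.

## Marginal ancestral states

For a reversible model with stationary root prior, the marginal posterior
of node n's state is the root marginal of the tree re-rooted at n. The
production implementation is the O(n) inside–outside algorithm: the
postorder pass yields inside vectors D_n, a preorder pass yields outside
vectors E_n, and the marginal is ∝ π_s D_n(s) E_n(s). A literal
re-root-and-recompute oracle (`marginal_asr_direct`, O(n²), independently
coded on an undirected adjacency view) ships alongside, and the test suite
binds the two together to 1e-8 per entry on batteries of random instances.

Marginals are reported at tips too: a known tip yields its indicator, while
ambiguous tips (parasite/unknown) get a genuinely reconstructed
distribution, flagged as imputed in reports. Ties in the modal-state report
are broken by state-label order and flagged explicitly.

## Stochastic mapping

Maps are drawn exactly in two stages. Joint node states: root from
π·D_root, then each child preorder from P_{parent,s}(t)·D_child(s); tips
with known states receive them automatically. Branch paths: endpoint-
conditioned CTMC bridges by **uniformization** — dominating rate
Λ = max|Q_ii|, jump count drawn from the endpoint-conditioned Poisson
mixture, jump states bridged through powers of R = I + Q/Λ, jump epochs as
uniform order statistics. Virtual (self) jumps are merged away: histories
are identifiable only up to real transitions. Uniformization was chosen
over rejection sampling for its bounded runtime when the endpoint pair is
improbable; a forward-simulation rejection sampler exists in the test suite
as an independent oracle, and the two agree in distribution (chi-square on
transition counts at 10^5 draws).

Reproducibility: one root seed; history i uses spawn i of
`numpy.random.SeedSequence(seed)`, so output is byte-stable and independent
of execution order.

## Accumulation curves

From each map, every state-change event is extracted with its forward time
(branch start + cumulative segment durations). For each state, the
cumulative count of transitions *into* that state is evaluated on a uniform
grid of 200 points spanning root to present (both endpoints included), and
averaged across maps. Events exactly on a grid point count at that point
(closed-left convention). The final grid value per state therefore equals
the mean per-map transitions-into count — a conservation identity the tests
assert against the independent map summaries.

The protocol's prose ("lineages possessing each trait") and its extraction
step (transition timings) suggest two different statistics; the implemented
curve is cumulative transitions-into-state, consistent with the extraction
step and the figure legend it reproduces. The standing-lineage variant
(live branches in state s at time t) is provided separately as
`standing_lineage_curves` and is deliberately not called an accumulation
curve.

## Synthetic data

The dated tree the empirical analysis used is a Bayesian chronogram not
shipped with the package, so all testing runs on simulated stand-ins:

- `simulate_bd_tree`: forward birth–death from a crown pair with complete
  pruning of extinct lineages, conditioned on reaching n extant tips; the
  run stops uniformly inside the waiting time to the next event so terminal
  branches have positive length, and the tree is rescaled to a target root
  age if requested. Output is always ultrametric.
- `simulate_mk_history`: forward CTMC down every branch, recording the full
  true history.
- `study_scenario`: the frozen study-scale regime — 34 tips, root age 16.72
  time units, dicot root state, ER rate q = 0.03 per time unit. Birth and
  death rates (0.25, 0.05 per lineage per time unit) were chosen once as a
  moderate-extinction regime producing crown-clade structure at this scale;
  q = 0.03 yields a handful of transitions across the ~150 time units of
  total branch length, matching the sparse-transition character of the
  empirical table. The trait simulation retries on successive RNG
  substreams until realized tip counts fall within ±30% of the empirical
  included-species composition (21 dicot : 9 grass : 3 dicot-grass of 33
  classifiable tips), then one dicot tip is masked as an ambiguous
  social-parasite analog. The scenario is deterministic per seed.

What passing on synthetic data shows: the estimators are correct under the
model that generated the data (exact likelihoods, exact conditional
sampling, calibrated rate recovery). What it does not show: robustness to
features real chronograms and trait tables have that the generator lacks —
dating error and node-age uncertainty, non-birth–death tree shape,
state-dependent diversification, classification error in the trait
compilation, and rate heterogeneity across lineages (the ER model has a
single rate by design, matching the analysis it implements).

## Problem sizes and numerics

Default test/acceptance sizes: enumeration oracles on trees with ≤ 6
internal nodes (100+ instances), ASR oracle batteries at 4–50 tips (100
instances), rate recovery on 50 replicates of 200-tip trees, distributional
map checks at 10^4 maps / 10^5 branch draws, and the end-to-end pipeline at
the study defaults (100 maps, 200-point grid). These sizes make the full
suite run in a couple of minutes while keeping Monte-Carlo standard errors
well inside the asserted tolerances.

Key tolerances: pruning vs enumeration 1e-10 relative; two-pass vs direct
ASR 1e-8 per entry; closed form vs expm 1e-10; ultrametric check 1e-6
relative; SIMMAP segment sums 1e-8 relative; optimizer `xatol` 1e-10 on
log q.

## Known limitations

- Equal-rates only; no SYM/ARD, hidden-rate, or state-dependent
  diversification models.
- The re-rooting method (and hence the ASR module) requires reversibility;
  non-uniform root priors are refused rather than approximated.
- Marginal (not joint) reconstructions; per-node vectors are not a single
  coherent history — the stochastic maps serve that purpose.
- The birth–death simulator conditions on tip count by stopping at the
  n-th extant lineage, a standard but slightly biased scheme relative to
  exact conditioned samplers; for oracle-testing purposes only tree shape
  realism at this level is required.
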