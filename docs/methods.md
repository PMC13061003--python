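# Methods

`netpharm` implements a network-pharmacology drug-repurposing workflow:
drugs are scored by the topological proximity of their protein targets to
disease gene modules in a genome-wide gene–gene interaction network,
per-module rankings are merged by Markov-chain rank aggregation, the merged
ranking is validated against clinical development phases, selected drugs are
tested in a Bayesian dose–response framework, and short mechanistic paths
from drugs to disease genes are enumerated. This note records the models,
the defaults and why they were chosen, what the synthetic study conditions
do and do not emulate, and the numerical choices that matter.

## Drug–target network construction

Raw bioactivity records carry concentration-type standard values. For each
(drug, gene) pair we compute the mean pActivity, the arithmetic average of
the per-measurement −log10 molar activities over all n measurements of the
pair (duplicates included; all measurement types pooled). Pairs with mean
pActivity ≥ 5 — activity at ≤ 10 µM — are retained. Raw values are assumed
to be in nM (the common repository convention); the unit is an argument
(`nM | uM | M`) because upstream sources differ. Records containing
non-positive values cannot be log-transformed and are rejected with a
warning rather than aborting the build.

## Network proximity (closest measure)

For target set T and disease gene set S in interactome G,

    d(S, T) = (1/|T|) Σ_{t∈T} min_{s∈S} d(s, t),

with d(s, t) the unweighted shortest-path length. Implementation notes:

- One multi-source BFS per gene set (sources = the module) is reused across
  all drugs, rather than |S|·|T| single-source searches.
- Targets unreachable from every disease gene contribute +∞, making the
  drug's proximity +∞ (those drugs rank last). A `drop_unreachable` mode
  averages over reachable targets only.
- Gene sets are restricted to interactome nodes before scoring; genes
  outside the network are dropped with a logged warning because disease
  gene sets routinely mix sources and identifier vintages.
- Per-column ranks are strict permutations: ties in d are broken
  lexicographically by drug id. Average ranks would create non-strict
  orders, which the Markov-chain aggregation downstream cannot consume.
- No degree-preserving randomization z-score is computed; the statistic is
  the raw closest distance.

The implementation is checked for exact agreement against a brute-force
oracle (explicit all-pairs shortest-path table plus literal evaluation of
the formula) on 100 random graphs per run.

## Rank aggregation

Per-module rankings are merged with the classical Markov-chain schemes.
From current item u a candidate v is proposed uniformly among the n items;
among the input lists ranking both items, let f be the fraction that rank v
above u. MC1 moves iff f > 0, MC2 iff f > 1/2, MC3 moves with probability
f. Off-diagonal transition mass is the move probability divided by n;
remaining mass stays on the diagonal. A teleportation mixture with weight
0.05 toward the uniform distribution guarantees irreducibility. Items are
ordered by descending stationary probability, computed by power iteration
to an L∞ tolerance of 1e−10 (validated against a left-eigenvector oracle).
Borda (mean-rank) aggregation is included as a deterministic baseline.

Algorithm selection minimizes the mean modified Kendall distance between
each candidate consensus and the input lists. The distance compares top-k
prefixes: pairs ordered by both prefixes (an item absent from a prefix
counts as below every present item) contribute 1 when discordant; pairs
whose relative order one prefix leaves fully undetermined (both items
absent from it) contribute a penalty p, default 0.5 (neutral); the sum is
normalized by the number of evaluated pairs. Ties in the selection fall to
the fixed precedence MC3 > MC2 > MC1 > Borda. On all 36 3-item/2-list
instances the selected consensus attains the exhaustive-permutation
optimum.

Lists are aggregated at full length with uniform weights; the reported
consensus may be truncated for presentation but truncation is not part of
the method.

## Rediscovery rate

For indication i with per-drug maximum clinical phase ϕ(d, i) ∈ {0..4}
(0 = never investigated, 4 = approved; pairs absent from the phase table
are 0), the rediscovery rate of the top-k versus bottom-l drugs of a
ranking is the ratio of mean phases r_l(k, i) = ϕ̄_top / ϕ̄_bottom. A zero
bottom mean makes the ratio undefined; it is reported as such (NaN with
both means), never as +∞. The default bottom-list size is 1808 when the
ranking has at least twice that many drugs, otherwise ⌊n/3⌋ — the historic
constant is specific to screens of a few thousand compounds. Indications
enter the multi-indication report when at least 100 drugs reach phase ≥ 1
(configurable). The statistic is descriptive; no significance test is
attached.

## Bayesian dose–response model

For one drug–assay pair with doses x (µM) and bioactivity y:

    y ~ Normal(μ, σ·μ),   μ = y1 + (y0 − y1) / (1 + exp(k·(x′ − EC50)))

with x′ = log10(dose) by default. The tested concentrations span decades,
and only on a log axis does the logistic's x′ → −∞ limit recover y0 as
"bioactivity at zero dose"; a raw-axis variant is available. The noise
scale is proportional to the mean (heteroscedastic), with unitless
multiplier σ. The effect size is the fold change FC = y1/y0 with prior
FC ~ Gamma(shape 5, rate 5), mean 1 (no effect).

Each dataset is first standardized so 10 units equal one sample standard
deviation (scaling only, no centering); the factor is stored for exact
back-transformation.

Parameterization and priors: y0 and FC are sampled and y1 = FC·y0 derived,
so the Gamma prior sits directly on the effect. y0 has a truncated-normal
prior centered on the lowest-dose sample mean with scale three sample
standard deviations, truncated at 0; positivity of y0 and FC confines μ
between the two asymptotes and keeps σ·μ a valid scale. k ~ half-normal(5)
(positive: benefit direction is carried by the data, not the slope sign);
EC50 ~ uniform over the observed log-dose range padded by one decade;
σ ~ half-normal(0.5). Only the FC prior is substantive; the rest are
weakly-informative defaults recorded here.

Sampling uses an affine-invariant ensemble MCMC sampler with
differential-evolution moves (80% DE, 20% snooker), which traverse the
weakly identified k–EC50 ridge far better than stretch moves on these
posteriors. Defaults: 32 walkers, 6,000 warmup + 6,000 kept steps thinned
by 6. For diagnostics the exchangeable walkers are grouped into 4
pseudo-chains and rank-normalized split-R̂, bulk effective sample size and
the Monte Carlo standard error are computed. The convergence gate fails a
fit when any parameter has R̂ > 1.01, ESS < 400, or MCSE > 0.1 posterior
sd; failed datasets are excluded from interpretation, never re-tuned. The
defaults were sized so that well-specified data passes this gate reliably
(10/10 pilot seeds); everything is deterministic under the configured seed.

### Hypothesis testing

The FC axis is partitioned at the 0.2 and 0.8 quantiles of the Gamma(5,5)
prior, giving prior masses (0.2, 0.6, 0.2) for protective / neutral /
adverse. For assays where benefit means decreased bioactivity the
protective tail is FC < q(0.2); for increased bioactivity, FC > q(0.8).
The quantile construction is the unique prior-mass-symmetric choice
consistent with those probabilities. Posterior probabilities are fractions
of posterior FC draws per interval; the Bayes factor is reported as the
posterior odds BF = P(protective|D)/P(neutral|D) — deliberately not
divided by the prior odds of 1/3; a prior-odds-corrected column is
emitted alongside. Evidence is graded on 2·ln(BF) (natural log): ≤ 2
none, (2, 6] moderate, (6, 10] strong, > 10 very strong. When no posterior
draw is neutral the BF is +∞ with a finite-sample caveat flag.

## Mechanistic paths

Paths have the form drug →1 target →2 mediator →3 disease gene; the
drug→target link counts as the first edge. A 1-edge path is a target that
is itself a disease gene; 2-edge, a target adjacent to one; 3-edge, a
target–mediator–disease-gene route whose mediator is neither a disease
gene (such routes already exist as shorter paths; configurable) nor the
path's target. Paths are simple. Mediator summaries count, per gene set,
the distinct set members adjacent to each mediator, as a count and as a
fraction of the full set size (not the in-network restriction), so the
fraction reflects the set as curated. Enumeration is validated against
exhaustive DFS on random instances.

## Synthetic study conditions

The generator provides every input with known ground truth, at desk scale:

- **Interactome**: preferential attachment (default 800 genes, 3 edges per
  new node), chosen over Erdős–Rényi because proximity statistics are
  degree-sensitive and honest testing requires heavy-tailed degrees. Real
  interactomes are an order of magnitude larger (~11k genes) with
  hub-biased study effort; the generator emulates topology class, not
  curation bias.
- **Disease module**: a snowball-sampled connected subgraph (default 40
  genes), matching the size range of curated disease gene sets (tens to a
  few hundred genes).
- **Drugs** (default 120, 3 targets each): with probability
  `proximity_signal` a drug samples targets from the module and its first
  neighborhood (closest proximity ≤ 1 by construction); otherwise
  uniformly. Retained mean pActivities are drawn uniformly in [5, 9].
- **Phases**: with probability `phase_signal` the phase is tied to the
  planted label (proximal → 4, distal → 1 — the floor of 1 keeps bottom
  means positive so rates stay defined); otherwise uniform on {0..4}, so
  zero signal gives expected rate 1 and full signal a closed-form rate of
  4 for aligned rankings.
- **Dose–response**: observations drawn from the model's own generative
  process at three concentrations per drug (default 1/3/10 µM, 5
  replicates), mirroring typical three-dose assay designs.

Everything is deterministic under the scenario seed (per-stage
independent substreams), and ground truth is written to a sidecar JSON so
downstream checks never reach into generator internals. What passing tests
on these conditions do **not** show: robustness to interactome
incompleteness and false edges, identifier mismatch across sources,
assay-specific systematic error, or correlated replicates — none of which
the generator emulates.

## Calibration studies and problem sizes

The replicated studies (shared by the test suite and the reproduction
script) use a reduced sampler — 16 walkers, 800 + 800 steps thinned by 8 —
which supplies ample effective draws for rank and tail-probability
statistics at a fraction of the cost of the full analysis settings:

- Simulation-based calibration: 200 replicates at 3 doses × 3 replicates;
  parameters drawn from the exact fitted priors (the y0 prior is pinned to
  (30, 10) on the standardized scale for this purpose); rank of the true
  FC among 19 thinned posterior draws; chi-square uniformity test at 0.01.
- Evidence rates: 50 replicates each at FC = 0.3 (protective truth, σ =
  0.02) and FC = 1 (flat truth), counting 2·ln(BF) > 2.
- Null rediscovery: 200 rankings of 60 drugs with i.i.d. phases; mean rate
  compared to 1 (ratio-of-means Jensen bias at these set sizes is ~2–3%,
  inside the stated tolerance of 0.08).

## Known limitations

- The Bayes factor is posterior odds under unequal prior odds; users
  wanting a conventional Bayes factor should read the corrected column.
- R̂/ESS on walker-grouped pseudo-chains can be optimistic when all
  walkers are trapped in the same mode; the gate catches mixing failure,
  not multimodality missed by every walker. Posterior-curve inspection
  remains advisable for real data.
- Proximity has no degree-preserving null model; absolute distances are
  not comparable across drugs with very different target-degree profiles.
- Rank aggregation assumes full-length strict rankings over a shared item
  universe; partial lists are handled by the Kendall penalty but the MC
  chains treat missing comparisons as absent evidence.
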