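# Methods

This note documents the models implemented in `cocktailnet`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that make runs reproducible.

## Background network

Three edge sources are merged into one undirected graph: protein–protein
interactions with an evidence count (number of distinct experimental
methods), protein–DNA interactions and signaling-pathway edges.  PPI
records are cleaned first — self-interactions dropped, duplicate pairs
collapsed keeping the maximum evidence count, pairs below `min_methods`
(default 2) removed.  Integration deduplicates edges across sources,
keeping the contributing source types as an edge attribute for provenance
only.  The graph is then restricted to genes observed in the expression
data and reduced to its largest connected component.

Protein–DNA and signaling edges are directional in their source databases,
but the network stores unordered pairs: the flow model below routes flow in
both directions along every interaction, so only undirected reachability is
ever used.  Component-size ties break toward the component containing the
lexicographically smallest gene symbol, making assembly deterministic.

## Expression profiles and node weights

Probe-level matrices are collapsed to genes in two steps: each distinct
symbol string (including composites such as `HSPA1A /// HSPA1B`) gets the
mean of its probes, then each true gene averages over every symbol string
that equals it or contains it as a `///`-separated token.

Sample filtering follows the conventions of large perturbation compendia:
the historically split batches "2" and "2a" are merged first, batches whose
treated samples contain a single distinct perturbagen are removed entirely
(reading "one single drug" as one distinct perturbagen per batch — the
alternative reading, one dose, would remove almost nothing), and only
samples from the configured cell line (default MCF7) are kept.

Within a batch, each case is compared against the arithmetic mean of its
linked controls; replicate cases and their control means are averaged;
per-batch values are then averaged across batches.  The per-gene ratio
T_i/C_i is the basic signal.  Genes whose control value falls at or below a
floor of 1e-6 are dropped (logged) rather than allowed to blow up the
ratio.

The node weight is `w_i = |log2(T_i / C_i)|`: non-negative, zero exactly at
no change, symmetric between induction and repression (w(r) = w(1/r)), and
the standard magnitude scale for fold changes.  The function is pluggable
(`weight_fn` config key); because every score downstream is a ratio of
weight sums, any rescaling of the weight function cancels out.

When a drug was profiled at several doses, its single representative
profile is the gene-wise mean of the per-dose ratio profiles; a fixed dose
can be configured instead.  Averaging was chosen because no principled
single dose exists across drugs with different potency ranges.

## Predicting combination profiles

For doses near zero, a first-order Taylor expansion of the expression value
under n simultaneous drugs, rewritten in case/control ratios (which cancels
the unequal baselines of separately run experiments), gives the additive
rule

    F_i = 1 + sum_j (r_ij - 1).

When all members push a gene the same way the linear sum overshoots — and
for strong co-repression goes negative — so the default *saturating* mode
caps the combined deviation at the most extreme member deviation:

    F_i = 1 + s * max_j |r_ij - 1|   (s the shared sign),

falling back to the additive form when member deviations disagree in sign.
This is the simplest rule that saturates co-directional effects and can
never produce a negative ratio from co-repression.  Predicted ratios are
clipped from below at 0.01 (log-weights require positivity) with the clip
recorded per gene; both modes are exposed so either convention can be
compared side by side.  Predictions are defined on the intersection of the
member gene sets so that every predicted gene has a weight.

## Affected-subnetwork detection

A drug's effect starts at its targets and propagates, so the affected genes
are modelled as a connected subgraph containing all targets.  Selection is
encoded as a single-commodity flow program over the background graph plus a
dummy drug node S with one arc to each target:

    maximise    sum_i w_i x_i
    subject to  sum_k Z_{S,H_k} = R
                inflow(i) - outflow(i) = x_i      for every gene i
                Z_ij <= R x_i,  Z_ij <= R x_j     for every non-dummy arc
                x_{H_k} = 1                       for every target
                Z >= 0,  x in {0,1}  (relaxed to [0,1])

R units of flow enter the targets and each selected gene absorbs exactly
one unit, so summing the conservation constraints forces `sum x_i = R`, and
a gene can only be selected if a chain of selected genes links it back to a
target.  Note the feasible selections are those in which *every connected
component contains a target*: with multiple targets the dummy node may feed
disjoint regions, which is the intended behaviour for drug combinations
whose targets sit in different parts of the network.  R is the tightest
valid capacity constant for the coupling constraints.

The binary program is NP-hard, so by default x is relaxed to [0,1] and the
LP is solved with HiGHS (`scipy.optimize.linprog`); every gene with
x > 1e-6 is taken into the subnetwork, whose size can therefore exceed R
somewhat, and a flag records whether the solution was integral (on the
instances exercised here it almost always is).  Components of the extracted
set containing no target — possible only through numerical noise — are
discarded.  Exact binary mode (`scipy.optimize.milp`, HiGHS branch-and-cut)
is kept for small instances and is validated against exhaustive enumeration
in the test suite.

Because the right subnetwork size is unknown, R is scanned from R_min — the
number of distinct nodes on one deterministic (lexicographic-BFS) shortest
path per unordered target pair, the smallest selection that can connect all
targets — to R_max = max(R_min, floor(0.1 |V|)), on the grounds that one
drug perturbs only a small fraction of the system.  Candidates are compared
by the Z-score-like normalised score `sum_{i in S} w_i / sqrt(|S|)`, which
penalises padding a subnetwork with low-weight genes; ties prefer the
smaller gene set, then the lexicographically smallest gene tuple, so
results are fully deterministic.  The scan step is configurable (`r_step`,
default 1) for large networks.

## Scoring and verdicts

With SD/BD the disease genes in the subnetwork/background and ED/EB the
essential-but-not-disease genes in the subnetwork/background,

    S_eff = lambda * (sum_SD w / sum_BD w) - (1 - lambda) * (sum_ED w / sum_EB w).

Both terms are normalised by background weight sums, so they lie in [0, 1],
S_eff lies in [-1, 1], is non-decreasing in lambda, and is invariant to
rescaling all weights.  Essential genes that are also disease genes are
excluded from both ED and EB: hitting them is therapeutic intent, not
collateral damage.  Every treatment is scored with its own weights — member
drugs with their single-drug profiles, combinations with their predicted
profiles — because the weights *are* the treatment's effect.

A combination is declared effective when its S_eff strictly exceeds that of
every member drug.  The default lambda is 0.5 (efficacy and side effect
weighted equally); the lambda scan (step 0.05, 21 rows) shows how the
verdict depends on the balance.  An S_eff comparison at one lambda can flip
at another unless one treatment dominates in both terms.

Drugs with any target outside the background network are excluded from the
screen with a warning rather than failing the run — expression platforms do
not cover every target gene.

## Synthetic data

The generator emulates the full input stack at miniature scale with planted
ground truth.  Defaults (the study conditions for all property tests):
200-node Barabási–Albert network (2 edges per new node), 5 drugs with 1–2
targets each, planted connected modules of 8 genes grown breadth-first from
the targets, effect size 1.5 on the log2 scale decaying by 0.85 per hop,
log-normal expression noise with log2 SD 0.2, 20 disease genes, 30
essential genes of which 3 are also disease genes, control intensity fixed
at 100 units.  Rationale for the key choices:

* *module size 8*: a single drug's module is ~4 % of the network, so the
  union of two modules stays below the 10 % subnetwork-size cap — matching
  the real-data regime where affected subnetworks are far smaller than the
  network.  A module union larger than R_max would make combination
  subnetworks physically unable to cover both members' effects.
* *effect 1.5, decay 0.85, noise 0.2*: the faintest module gene still sits
  ≥ 3 noise SD above baseline, the regime in which module recovery is
  expected to succeed; replicate averaging (2 batches × 2 cases × 2 probes)
  reduces the effective noise further.
* two probes per gene plus one composite `"A /// B"` probe, batches "2" and
  "2a", a second cell line, and a zero-effect decoy perturbagen are always
  emitted so every preprocessing rule is exercised on every fixture.  The
  decoy also prevents a standalone single-drug fixture from being erased by
  the single-perturbagen batch filter.
* controls sit exactly at baseline, so at zero noise the preprocessing
  chain recovers planted ratios exactly — the basis of the exactness tests.

Gene-set placement relative to the planted modules is configurable:
`mixed` (default; some disease and essential genes in each module, rest
elsewhere), `in_modules`, `outside_modules`.  The effective-combination
benchmark plants disease genes inside both members' modules and essential
genes outside (the combination then covers strictly more disease weight at
no extra essential load); the negative benchmark puts disease genes outside
all modules with essential genes inside, so combinations only accumulate
side-effect load.

Combination ground truth is additive on ratio deviations, optionally with a
synergy boost (≥ 1.5, default 2) multiplying disease-gene deviations.  At
zero noise the additive-mode prediction from recovered member profiles
equals the additive truth to floating-point precision.

What the generator does **not** emulate: array-hybridisation physics, probe
GC bias and platform-specific probe effects, correlated (batch-structured)
noise, incomplete probe coverage of network genes, dose–response
nonlinearity within a drug, and the sheer scale of real compendia.  Passing
the synthetic benchmarks therefore demonstrates the pipeline's correctness
and its statistical behaviour under the stated noise model — not
performance on any real drug screen.

## Numerical conventions and degenerate inputs

* LP/MILP backend: HiGHS via scipy; selection threshold 1e-6, integrality
  tolerance 1e-6.
* Control-intensity floor 1e-6; predicted-ratio floor 0.01; score ties
  compared at 1e-12.
* Empty network into component selection → empty network with a warning;
  all-control or fully filtered sample tables → empty table with a warning;
  a case sample with no linked controls, a missing (drug, dose), a target
  absent from the model's network, an infeasible subnetwork size, or lambda
  outside [0, 1] → errors naming the offending entity.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give byte-identical
  fixtures and pipeline outputs.

## Problem sizes used in the checks

The solver validation uses exhaustive enumeration, which is only tractable
on small graphs: 200 random instances with up to 12 nodes, 1–3 targets and
feasible R.  Recovery and verdict benchmarks use the 200-node default
scenario with 50 replicates each — large enough for the scale-free
structure and noise model to matter, small enough that the full suite runs
in minutes on one CPU.

## Known limitations

* The subnetwork model fixes R per solve and compares sizes post hoc via
  the normalised score; a fully joint size-and-selection optimisation is
  out of scope.
* The LP relaxation carries no approximation guarantee; near-degenerate
  weight ties can yield fractional solutions whose thresholded gene set
  exceeds R noticeably.  Integrality is logged per solve.
* The saturating combination rule is one defensible convention among
  several; both it and the additive rule are reported so either can be
  used downstream.
* Scores depend on the completeness of the disease and essential gene
  lists; absent genes silently reduce the corresponding term.
* Verdicts compare a combination only against its own members, not against
  other combinations or dosing schedules.
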