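# Methods

`bnepi` implements discrete Bayesian-network analysis for case-control
gene-environment-disease studies: structure learning, decomposable scoring,
EM for incomplete records, Markov-blanket-centred association discovery, and
exact prognostic queries, together with a synthetic generator that makes the
whole pipeline testable at desk scale.

## Model

A network is a DAG `G` over categorical variables plus one conditional
probability table (CPT) per node. The Markov condition licenses the
factorization

    P(x1, ..., xn) = prod_i P(xi | pa(xi))

which is the basis of everything downstream: the factored free-parameter
count is `sum_i (r_i - 1) q_i` (r_i states, q_i parent configurations),
against `prod_i r_i` cells for the unfactored joint — the package exposes
both conventions (`count_free_parameters`, `raw_joint_size`) because both
numbers are conventionally quoted (12 vs 64 for the six-node binary
exemplar).

Conditional independence is read off the graph by d-separation. We compute
it by the ancestral-moral-graph reduction (restrict to ancestors of the
query sets, moralize, delete the conditioning set, test undirected
separation); the test suite cross-checks this against an explicit
path-enumeration oracle that applies the serial/divergent/convergent
blocking rules directly, on every conditioning triple of random graphs up
to six nodes. Equivalence classes (CPDAGs) are computed by marking
v-structure edges compelled and closing under Meek's orientation rules; on
all 3- and 4-node DAGs the resulting partition provably coincides with the
partition by d-separation relations (checked exhaustively).

## Scores

Four decomposable scores on (possibly fractional) sufficient statistics
`N_ijk`:

* log-likelihood `sum N_ijk ln(N_ijk / N_ij)` (MLE = relative frequencies;
  `0 ln 0 = 0`, empty configurations contribute 0);
* AIC `loglik - n_p` and BIC `loglik - (n_p / 2) ln N`, with `n_p` the free
  parameter count over all nodes, including zero-count configurations;
* log-K2, the marginal likelihood under uniform Dirichlet(1, ..., 1)
  priors, written with log-gamma functions so that the fractional counts
  produced by EM score cleanly; on integer counts it equals the factorial
  form to 1e-9, and it equals a numerically integrated Dirichlet integral
  oracle to the same tolerance.

All logarithms are natural. The MLE of an unseen parent configuration is
uniform, and its likelihood contribution is zero — this keeps every score
finite without pseudo-counts.

## Structure learning

**Constraint-based.** Grow-Shrink and IAMB estimate each node's Markov
blanket from chi-square CI tests at level alpha (default 0.05). GS fixes
the candidate order once, descending marginal association (the static
variant of the published ordering heuristics); IAMB re-ranks dynamically by
conditional mutual information given the current blanket. Compilation into
one graph uses the conservative AND rule for asymmetric findings, removes
spousal links by searching conditioning subsets of the smaller blanket
(ascending size, capped at 3 — configurable; the cap is logged), orients
v-structures whose middle node is absent from the recorded separating set
*and* whose conditioning actually creates the dependency, propagates with
Meek's rules, and repairs any directed cycle by undirecting the edge with
the weakest supporting chi-square statistic first. Degenerate test strata
(zero margins) are collapsed with degrees of freedom reduced; a test with
no remaining degrees of freedom reports independence with a logged flag.

**Score-based.** Hill-climbing over single-edge additions, deletions and
reversals, locally evaluated via decomposability with a persistent
(node, parent-set) score cache. Ties are broken deterministically
(additions before deletions before reversals, lexicographic edges).
Restarts perturb the incumbent best by a stated number of random admissible
single-edge changes and re-ascend; the perturbation operator is our own
choice — the restart/perturbation *counts* follow the standard protocol
(100 restarts x 5 perturbations in the workflow defaults) but no canonical
operator exists. Default start is the empty graph. On every seeded <= 4
node dataset in the suite, 25 restarts recover the exhaustive-enumeration
optimum over all 25 / 543 candidate DAGs.

**Hybrid.** MMHC: a Max-Min Parents-and-Children skeleton (forward
max-min-association selection with the association minimized over
conditioning subsets capped at size 3, backward CI pruning, AND-rule
symmetrization), then hill-climbing with additions restricted to skeleton
pairs.

Blacklists are hard constraints in all learners: a forbidden directed edge
is never emitted; orientation steps that would force one leave the edge
undirected and log a warning. The workflow derives the blacklist from
variable *roles* (outcome / demographic / behavior / exposure / snp) rather
than hard-coded names: nothing parents a demographic, the outcome and
exposures do not parent behaviors, non-genetic variables do not parent
SNPs. The "non-causal" (diagnostic) stage relaxes exactly the rules in
which the outcome is the parent, which is what lets case-control data
express SNPs as *children* of disease and widens the detectable blanket.

## Missing data

Parameter EM for a fixed structure, exact E-step: every completion of a
record's missing cells is enumerated (cap: 12 missing cells per record,
configurable; records beyond the cap are dropped with a warning) and
weighted by its posterior under the current parameters. The M-step takes
weighted relative frequencies. Initialization is the complete-case MLE
(uniform where unseen; all-uniform with a warning if no complete records
exist). Convergence: maximum absolute CPT-entry change below 1e-6, at most
500 iterations; non-convergence is flagged but the result returned. The
observed-data log-likelihood is traced and asserted non-decreasing (slack
1e-8). A record whose observed cells have probability zero under the
current parameters receives uniform completion weights, with a log entry —
this arises naturally when complete-case initialization contains hard
zeros.

Expected scores after EM are computed from the expected sufficient
statistics (fractional counts), not by averaging scores over completions;
with zero missingness they reduce exactly to the complete-data scores.

The candidate-structure comparison enumerates the ways a focal variable T
could enter the outcome Y's Markov blanket — parent of Y, child of Y, or
co-parent of each of Y's children — plus the null, EM-fits each, and
tabulates expected log-likelihood / AIC / log-K2 / BIC with per-metric
winners. Cycle-creating or blacklisted candidates are dropped with a log
entry. Structural EM (search inside EM) is deliberately out of scope.

## Inference

Queries are exact: the factorized joint is summed over unobserved nodes
(vectorized enumeration). This is a declared deviation from sampling-based
query engines — at tens of binary nodes exactness is cheap and it makes
posteriors reproducible to 1e-9 against the brute-force oracle. Odds
ratios compare a profile against a reference profile via two exact queries;
the "case" state defaults to the lexicographically last state label
(e.g. "1" in 0/1 coding) and is overridable. `log_odds_to_or` converts
externally fitted logistic-regression coefficients to ORs with normal-
theory CIs; the regression itself is out of scope.

## Synthetic data

The generator states a world and sticks to it: ancestral sampling from a
fixture network; outcome-conditional rejection sampling to exact
case/control quotas (the sample's outcome marginal is the quota ratio by
construction — the defining distortion of case-control designs, which the
tests document); MCAR holes at a per-cell rate with protected columns,
concentrated in SNP columns by convention (15% default in the simulator
CLI; real cohorts' per-variable rates are not published, so this is a
repository convention). One root seed spawns independent sampling and
missingness streams.

Fixture CPTs are arbitrary documented constants chosen for qualitative
realism — effect sizes >= 0.2-0.3 probability difference so that desk-scale
n suffices for recovery, a gene-gene v-structure at XRCC3_241 producing
marginal independence with conditional dependence (Simpson-pattern), and an
arsenic variant (`bladder11_arsenic`) adding a TOENAIL_AS -> XRCC3_241
gene-environment interaction. They are not estimates of any cohort. Two
11-node fixtures exist because the no-arsenic structure has outcome blanket
{GENDER, SMOKER, XRCC3_241, XRCC3_04} while the arsenic variant adds
TOENAIL_AS to it; tests pick whichever world they need. What a green test
establishes is therefore recoverability under MCAR missingness, binary
coding, and moderate effect sizes — not performance under informative
missingness, rare variants, or linkage-disequilibrium haplotype structure,
none of which the generator emulates.

## Numerical and determinism choices

* Variable iteration order everywhere is declaration order; CPT rows are
  row-major over parents in declaration order — serialization is bit-exact.
* Cycle detection is depth-first in declaration order and reports one
  explicit offending cycle.
* Hill-climb move acceptance requires a gain > 1e-9 to avoid float-noise
  cycling; accepted-move traces are strictly increasing.
* Chi-square tests use no continuity correction; CI tests list-wise delete
  rows with missing values among the tested columns.
* EM is deterministic; seeds only ever affect synthetic inputs.
* CI-test counts per learner run are logged for comparison tables, but
  published test counts from other implementations are order-dependent and
  are never targeted.

## Known limitations

No latent variables, no continuous nodes, no structural EM, no
BDe/posterior model averaging, no PC/FCI-style latent-confounder
orientation. Exhaustive DAG enumeration is capped at 5 nodes; the exact
E-step caps enumerable missing cells per record. Constraint learners
require complete-case input (the workflow stages them accordingly).
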