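# bnepi

Discrete Bayesian networks for gene-environment-disease association
studies. `bnepi` is aimed at genetic-epidemiology analyses of
case-control cohorts with a modest number of pre-coded categorical
variables — disease status, demographics, behavior, an environmental
exposure, and a handful of SNPs — where the questions are: which
variables belong in the disease's Markov blanket, do gene-gene or
gene-environment interactions hide behind marginal null results, and
what prognostic risk does a given profile carry?

It provides:

* **Structure learning** — constraint-based (Grow-Shrink, IAMB with
  chi-square / mutual-information CI tests), score-based (hill-climbing
  with random restarts and edge perturbations), and hybrid (MMHC), all
  under hard blacklist constraints;
* **Decomposable scores** — maximized log-likelihood, AIC
  (`loglik − n_p`), BIC (`loglik − (n_p/2) ln N`), and log-K2 (uniform-
  Dirichlet marginal likelihood, log-gamma form) on complete or
  fractionally completed data;
* **Missing data** — exact parameter EM for a fixed structure
  (probabilistic record completion / expected-frequency re-estimation),
  plus an enumerated candidate-structure comparison asking whether a
  focal variable belongs in the outcome's Markov blanket;
* **Exact inference** — posteriors by joint enumeration, prognostic
  odds-ratio tables against a reference profile, and a log-odds → OR/CI
  conversion utility;
* **A case-control simulator** — ancestral and outcome-conditional
  sampling from documented fixture networks with MCAR missingness, so
  the whole pipeline is testable end to end at desk scale.

The graph model (d-separation, Markov blankets, moralization, CPDAG
equivalence classes, free-parameter counting) is exact and oracle-tested.

## Worked example

Simulate a 650-subject case-control cohort (226 cases / 424 controls)
from the 11-variable fixture with a true arsenic → XRCC3_241 edge, with
15% of SNP cells missing, then ask by EM whether TOENAIL_AS belongs in
CANCER's Markov blanket — starting from the base structure that lacks
the arsenic edge:

```sh
$ bnepi simulate --network fixture:bladder11_arsenic \
    --cases 226 --controls 424 --missing-rate 0.15 \
    --protect CANCER,GENDER,AGE,SMOKER,TOENAIL_AS --seed 7 -o data.csv
wrote 650 records x 11 columns to data.csv

$ bnepi em-compare data.csv --base fixture:bladder11 \
    --target TOENAIL_AS --outcome CANCER
added_edge	loglik	aic	log_k2	bic
none	-4453.5	-4474.5	-4509.9	-4521.5
TOENAIL_AS -> CANCER	-4453.3	-4476.3	-4513.1	-4527.7
CANCER -> TOENAIL_AS	-4452.7	-4475.7	-4513.7	-4527.2
TOENAIL_AS -> SMOKER	-4450.4	-4475.4	-4512.2	-4531.4
TOENAIL_AS -> XRCC3_241	-4447.3	-4472.3	-4509.5	-4528.3
winner[loglik]	TOENAIL_AS -> XRCC3_241
winner[aic]	TOENAIL_AS -> XRCC3_241
winner[bic]	none
winner[k2]	TOENAIL_AS -> XRCC3_241
```

Each row is one candidate way of pulling TOENAIL_AS into CANCER's
blanket (plus the null), EM-fitted on *all* 650 records including the
incomplete ones; columns are expected scores after convergence. Here
the true route — arsenic as a co-parent of the XRCC3_241 SNP, i.e. a
gene-environment interaction — wins the expected log-likelihood, AIC
and K2 scores, while the more conservative BIC still prefers the null:
exactly the tension you should expect at this sample size.

Exact prognostic queries read risk straight off a fitted network:

```sh
$ bnepi query --network fixture:bladder11_arsenic --target CANCER \
    --evidence GENDER=1,SMOKER=1,TOENAIL_AS=1,XRCC3_241=1,XRCC3_04=0
P(CANCER=0 | GENDER=1,SMOKER=1,TOENAIL_AS=1,XRCC3_241=1,XRCC3_04=0)	0.276382
P(CANCER=1 | GENDER=1,SMOKER=1,TOENAIL_AS=1,XRCC3_241=1,XRCC3_04=0)	0.723618
```

`bnepi or-table` turns such queries into a full odds-ratio table against
a reference profile, and `bnepi workflow` chains all four stages
(blacklisted four-algorithm comparison → non-causal relearn and blanket
extraction → EM candidate comparison → OR table) from one CSV. The same
functionality is available as a library (`import bnepi`); see
`docs/methods.md` for the model, algorithms, and design decisions.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds the six-node exemplar network (three SNPs, exposure, biomarker,
cancer) from its edge list and recomputes its factored free-parameter
count at run time, writing the result as JSON.
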