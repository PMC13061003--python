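# netpharm

Network-pharmacology drug repurposing: given a genome-wide gene–gene
interaction network (interactome), a drug–target network derived from
bioactivity records, and one or more disease gene modules, `netpharm`
screens drugs by how topologically close their targets sit to the disease
modules, merges the per-module rankings into one consensus, validates that
consensus against clinical development phases, quantifies experimental
dose–response evidence with Bayes factors, and enumerates short mechanistic
paths from drugs to disease genes. It is aimed at computational biologists
running in-silico repurposing screens — originally for Alzheimer's disease
modules, but nothing is disease-specific.

## The methods in brief

**Proximity screen.** A drug with target set T is scored against a disease
gene set S by the closest measure

d(S, T) = (1/|T|) Σ_{t∈T} min_{s∈S} d(s, t),

the average over targets of the shortest-path distance to the nearest
disease gene. Drugs are ranked per gene set (rank 1 = most proximal).

**Rank aggregation.** Per-module rankings are merged with Markov-chain rank
aggregation (MC1/MC2/MC3, plus a Borda baseline): a chain over drugs moves
between items according to how the input lists order them, and drugs are
ranked by stationary probability. The algorithm whose consensus minimizes
the mean modified Kendall distance to the inputs is selected (MC3 wins
ties).

**Rediscovery validation.** For an indication with per-drug maximum
clinical phase ϕ ∈ {0..4}, the rediscovery rate r = mean phase of top-k
drugs / mean phase of bottom-l drugs. Rates above 1 mean the screen's top
ranks are enriched in clinically investigated compounds.

**Dose–response evidence.** Each drug–assay dataset is standardized (10
units = 1 sd) and fitted with a Bayesian heteroscedastic sigmoid,
y ~ Normal(μ, σ·μ) with μ = y1 + (y0 − y1)/(1 + exp(k(x − EC50))) on the
log10-dose axis. The fold change FC = y1/y0 carries a Gamma(5, 5) prior
(mean 1 = no effect); the FC axis is partitioned at the prior's 0.2/0.8
quantiles into protective/neutral/adverse hypotheses with prior masses
(0.2, 0.6, 0.2). Evidence for a protective effect is the posterior odds
BF = P(protective|D)/P(neutral|D), graded on 2·ln(BF). Poorly converged
fits (R̂, ESS, MCSE thresholds) are excluded rather than interpreted.

**Mechanistic paths.** Simple paths drug →1 target →2 mediator →3 disease
gene (at most three edges, the drug→target link included) are enumerated,
with per-mediator counts of adjacent disease genes per gene set.

A synthetic-data module generates all inputs with known ground truth
(scale-free interactome, planted disease module, drugs placed at controlled
proximity, phases coupled to proximity, dose–response data from the model's
own generative process), so every stage is testable without external data.
See `docs/methods.md` for model details and assumptions.

## Worked example

Generate a planted scenario, screen, validate, and test dose–response
evidence:

```python
from netpharm import SyntheticScenario, DoseResponseTruth, write_scenario
from netpharm.pipeline import RunConfig, run_screen, run_validation, run_doseresponse

scenario = SyntheticScenario(
    seed=42, n_genes=300, n_drugs=40, n_disease_genes=20,
    proximity_signal=0.7, phase_signal=0.7,
    dose_response_truth=(
        DoseResponseTruth("D0001", "abeta_clearance", fc_true=0.3),
        DoseResponseTruth("D0002", "abeta_clearance", fc_true=1.0),
    ),
)
write_scenario(scenario, "demo/data")

cfg = RunConfig(
    interactome="demo/data/interactome.tsv",
    gene_sets="demo/data/gene_sets.gmt",
    drug_targets="demo/data/drug_targets.tsv",
    phases="demo/data/phases.csv",
    dose_response="demo/data/dose_response.csv",
    outdir="demo/results",
    k_values=(5, 10), bottom_l=10,
)
run_screen(cfg)
print(run_validation(cfg).to_string(index=False))
grid = run_doseresponse(cfg)
print(grid[["drug", "assay", "two_log_bf", "evidence_grade", "excluded"]]
      .to_string(index=False))
```

Output:

```
        indication  k  l  phi_top  phi_bottom     rate  defined
planted_indication  5 10      3.2         1.2 2.666667     True
planted_indication 10 10      3.3         1.2 2.750000     True
 drug           assay  two_log_bf evidence_grade  excluded
D0001 abeta_clearance    6.304638         strong     False
D0002 abeta_clearance   -2.245679           none     False
```

Reading it: 70% of the synthetic drugs were planted with targets near the
disease module and phases coupled to that placement, so the top-5 and
top-10 drugs of the consensus carry mean clinical phase 3.2–3.3 versus 1.2
in the bottom 10 — rediscovery rates of about 2.7×, the enrichment a
working screen should show. Drug D0001 was simulated with a true fold
change of 0.3 in an assay where decreased bioactivity is beneficial:
2·ln(BF) ≈ 6.3 is strong evidence for a protective effect. D0002 was
simulated flat (FC = 1) and correctly earns no evidence (2·ln(BF) < 2).
Neither fit tripped the convergence gate.

The same stages are available from a shell:

```sh
netpharm simulate --seed 42 --outdir demo/data
netpharm screen --config run.yaml
netpharm validate --config run.yaml
netpharm doseresponse --config run.yaml
netpharm paths --config run.yaml
```

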