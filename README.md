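# prisafe

Safety-risk management for **low-molecular-weight process-related
impurities (LMW PRIs)** in monoclonal-antibody manufacturing: media
components, buffers, antifoams, detergents and other small reagents that a
process introduces and downstream purification must remove.

Biologics fall outside the small-molecule impurity guidelines, and routine
lot testing of every small reagent is neither realistic nor necessary.
`prisafe` implements the risk-assessment-guided alternative used by process
development and CMC teams: categorise each impurity by its toxicological
evidence, assess the worst case against a health-based limit, test only
what fails, and account for the clearance the downstream process provides.

## The model

**Dose calculus.** The permitted daily exposure is derived from a
no-observed-effect level with the standard modifying factors

    PDE = NOEL × BW / (F1·F2·F3·F4·F5)        [μg/day]

(F2 = 10 for inter-individual variability; F5 > 1 required when a LOEL is
the point of departure).  The impurity amount delivered in one product dose
is

    PRI dose = (C_PRI / C_protein) × D        [μg]

and, when no PDE is derivable, the impurity safety factor ISF =
toxicity dose / PRI dose (LD50 scaled to a per-patient dose) is compared
against a configured threshold.  Impurities with severe toxicity or no
data at all are held to the threshold of toxicological concern
(TTC, 1.5 μg/day lifelong).  All comparisons are strict: a dose exactly at
its limit fails.

**Decision tree.** Step 1 assigns Category A (known-safe:
metabolite/GRAS/approved-excipient evidence), B1/B2 (medium risk, without/
with a derivable PDE) or C (genotoxic/carcinogenic, or no data).  Category A
is eliminated; Step 2a assesses the rest assuming full co-purification (no
clearance credit); failures enter a testing plan, and Step 2b re-assesses
them from the in-process result — with the assay limit of detection (LOD)
substituted for non-detects, making every pass a bound-based one.

**Clearance accounting.** A step's clearance fold is the ratio of
impurity-to-protein mass ratios across it,

    fold = (C_PRI,in / C_prot,in) / (C_PRI,out / C_prot,out),

folds compose multiplicatively across steps, and LOD-substituted results
propagate as "greater-than" lower bounds.  A conservative platform budget
of 100-fold (Protein A) × 10-fold (bind-elute CEX) × 5-fold
(diafiltration) = **5,000-fold** is provided.

**Diafiltration.** Constant-volume diafiltration washes a freely
permeating solute out exponentially, `C = C0·exp(−N·S)` with N diavolumes
and sieving coefficient S.  The package fits S to measured profiles
(nonlinear least squares, log-linear initialiser, R² acceptance at 0.95),
predicts clearance `exp(N·S)`, plans `N = ln(fold)/S` for a target, and
warns when a surfactant is spiked above its critical micelle concentration
(micelles do not pass the membrane, so the model will not hold).

## Worked example

```python
from prisafe import FixtureSpec, generate_example_inventory, run_workflow

data = generate_example_inventory(FixtureSpec(seed=0))
report = run_workflow(data.inventory, data.tox_map,
                      data.dose_context, data.measurements)
print(report.category_counts)
print(report.disposition_counts)
print([e.pri_id for e in report.testing_plan])
```

prints

```
{'A': 96, 'B1': 0, 'B2': 9, 'C': 0}
{'no_safety_risk': 105, 'testing_required': 0, 'action_required': 0}
['B007', 'B008', 'B009']
```

Of 105 impurities, 96 carry known-safe evidence and leave at Step 1; the
9 medium-risk impurities have derivable PDEs (Category B2); 6 pass the
worst-case assessment outright and 3 need in-process testing; all three
test non-detect, and the LOD-based Step 2b doses sit far below their PDEs,
so the whole inventory ends with no safety risk.

The same flow is available from the shell:

```sh
prisafe fixtures --out-dir example --seed 0
prisafe assess --inventory example/inventory.csv --config example/config.yaml \
    --tox example/toxicity.json --measurements example/measurements.csv \
    --out report.json --markdown report.md
prisafe diafilt fit --profile example/profile_msx.csv
prisafe diafilt plan --fold 100 --s 0.81
```

The last two print `S = 1.0200 …, accepted` and
`5.69 diavolumes for 100-fold clearance at S = 0.81`.

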