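# sifkit

Systemic impact factors for missense mutations: combine a mutation's
protein-stability change with the control structure of the pathway it
sits in, and get a single number (or a three-component vector) for how
much that mutation should perturb the cell.

## The problem

A missense mutation acts at two levels. At the protein level it changes
a folding or binding free energy by ΔΔG (kcal/mol). At the pathway
level the affected protein participates in reactions whose rate
constants the mutation effectively perturbs. Neither level alone
predicts the cellular phenotype: a large ΔΔG in a parameter the system
is insensitive to does little, and a hypersensitive parameter barely
perturbed does little too. The **systemic impact factor** multiplies
the two:

    SIF = ΔΔG_max · C^S_p ,     C^S_p = ((S′ − S)/S) / δ

where ΔΔG_max is the mutation's maximum free-energy change over the
protein states considered, and C^S_p is the normalized control
coefficient of a pathway readout S with respect to the perturbed
parameter group (evaluated at a total relative perturbation δ = 0.1,
split across rate terms by per-mutation weights).

Two reduced ODE systems are built in:

* **G2-M transition (fission yeast)** — the Cdk1/CycB–Wee1–Cdc25
  mitotic switch. Readout: total cyclin B at the moment active MPF
  first reaches 2.0 (mitotic entry). Since fission yeast grows linearly
  in length through G2, this readout maps onto cell length at
  septation, so SIF scores can be checked against measured lengths of
  mutant strains (a phenotype table for eight Cdk1/CycB
  temperature-sensitive mutants ships with the package).
* **Reduced MAPK cascade (human)** — ShcGS → Ras → Raf → Mek → Erk with
  negative feedback, 12 rate constants. Readout: amplitude, duration
  and peak time of the transient active-Erk pulse, giving each mutation
  a three-component SIF vector.

Also included: local sensitivity sweeps over channels and initial
conditions, Boltzmann-weighted ΔΔG ensemble averaging, replica-exchange
(parallel-tempering) Monte Carlo calibration of model parameters
against time courses, score–phenotype correlation statistics, and
seeded synthetic-data generators. Intended users: computational
biologists studying genotype–phenotype relationships who want a small,
inspectable pipeline rather than a black box.

## Worked example

```python
import sifkit as sk

model = sk.g2m_model()                      # published constants built in
S = sk.g2m_readout(model)                   # 2.1046  (cyclin at MPF = 2.0)

specs = sk.g2m_mutation_specs(delta=0.1)    # the three mutation channels
for label, spec in specs.items():
    c = sk.control_coefficient(model, sk.g2m_readout, spec,
                               wild_type_value=S)
    print(label, round(c.value, 4))
# kd_CycB     0.0036    (structural CycB mutations: 0.3/0.7 degradation mix)
# kd_Cdk1     0.0094    (structural Cdk1 mutations: MPF degradation)
# J_combined  0.0123    (functional Cdk1 mutations: 0.9/0.1 Michaelis mix)
```

All three coefficients are positive: each perturbation delays the
switch, so cells divide longer. Scoring the packaged mutant panel and
correlating with measured cell lengths (`examples/score_and_correlate.py`):

```
mutation   class  max_ddG   SIF(table-C)  SIF(model-C)
G43E         S    24.90         0.274       0.2350
C67Y         S     3.17         0.035       0.0299
...
25C: r2 = 0.048, two-tailed p = 0.603 (n = 8)
30C: r2 = 0.451, two-tailed p = 0.068 (n = 8)
```

The scores track cell length at the semi-restrictive temperature
(30 °C), where the mutant proteins are compromised, and not at the
permissive 25 °C — exactly the pattern expected if SIF captures the
systemic consequence of the mutations. Each script in `examples/`
demonstrates one capability (switch readout, control coefficients,
scoring + correlation, MAPK pulse metrics, REMC fitting, synthetic
panels) and prints a line on what its numbers mean.

A thin CLI mirrors the library: `sifkit models | simulate | sensitivity
| score | fit | correlate | make-fixtures`.

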