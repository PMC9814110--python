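# sensipod

**Nonanimal skin-sensitization potency assessment: assay endpoints, LLNA
reference curation, and neural-network points of departure.**

Skin sensitizers are regulated by potency, not just hazard, and the classical
potency metric is the murine local lymph node assay (LLNA) **EC3** — the
concentration (% w/v) estimated to produce a stimulation index of 3, the
threshold positive proliferative response. Quantitative risk assessment needs
such a point of departure, but modern regulatory practice increasingly relies
on nonanimal methods. `sensipod` implements a defined approach (DA) that
derives EC3 estimates entirely from three internationally harmonized
nonanimal assays spanning the first key events of the skin-sensitization
adverse outcome pathway:

* **DPRA** (direct peptide reactivity assay) — covalent protein binding,
  quantified as mean cysteine/lysine peptide depletion (*Avg.Lys.Cys*, %);
* **KeratinoSens** — keratinocyte Nrf2/ARE reporter activation, quantified as
  maximum fold induction (*Imax*) and the 1.5-fold induction concentration
  (*EC1.5*, μM);
* **h-CLAT** (human cell line activation test) — dendritic-cell activation on
  THP-1 cells, quantified as the minimum induction threshold (*MIT*, μg/mL):
  the lower of the CD86 ≥ 150% and CD54 ≥ 200% RFI crossings.

The integration model is a small feed-forward neural network,
input → 5 → 2 → 1 with logistic activations throughout. Inputs and the EC3
target are log₁₀-transformed and min–max scaled; training is full-batch
backpropagation with momentum for 10,000 iterations. Two variants exist:

* **D_hC** — inputs (Avg.Lys.Cys, MIT);
* **D_hC_KS** — inputs (Avg.Lys.Cys, MIT, Imax).

Because the fit depends on random initialization, a DA prediction is an
ensemble statistic: the network is trained **100 times** from independent
seeds and the reported EC3 is the arithmetic mean of the per-run predictions,
with a 95% interval from the 2.5th/97.5th percentiles of the run
distribution.

The package also curates in vivo reference values for validation: per-study
EC3 interpolation (linear in concentration), the Ryan acceptability criteria
for extrapolated EC3 values, a study-quality checklist, and two aggregation
approaches (most potent acceptable study in a preferred solvent; mean of all
acceptable studies with a zero-censored t-based 95% CI). GHS subcategories
follow EC3 ≤ 2% → 1A, EC3 > 2% → 1B, negative → NC, and EC3 converts to an
applied dose per skin area as μg/cm² = 250 × EC3% for comparison against
human no-expected-sensitization-induction levels (NESILs).

## Worked example

Train a 25-run ensemble on a synthetic 80-chemical population with a known
monotone endpoint–potency relationship and predict a held-out chemical
(`examples/04_ann_prediction.py`):

```python
from sensipod import (ANNConfig, ANNEnsemble, SyntheticSpec, benchmark,
                      generate_training_table)

table = generate_training_table(SyntheticSpec(n_chemicals=80, seed=7))
ensemble = ANNEnsemble.fit(table, ANNConfig(variant="D_hC_KS",
                                            iterations=5000, seed=17),
                           n_runs=25)
print(benchmark(ensemble, table, split="test"))
```

Output:

```
held-out benchmark (n=20): R^2 = 0.95, RMSE_log10 = 0.25
chemical SYN009: predicted EC3 = 1.233% (95% CI 0.484-1.414, 25 runs)
observed EC3 = 0.827%  ->  GHS 1A predicted vs 1A observed
```

The benchmark is computed between predicted and observed EC3 in log₁₀ space;
an RMSE_log10 of 0.25 means typical predictions are within ~1.8-fold of the
observed potency, and the ensemble interval spans only the variability
introduced by random weight initialization.

The other scripts in `examples/` demonstrate endpoint derivation from raw
assay tables, the mixture concentration arithmetic (weighted molecular
weight 141.36 g/mol and corrected starting concentration 401.8 μM for the
3:1 CMIT/MIT biocide mixture), LLNA reference curation, and the end-to-end
pipeline. A thin CLI mirrors the stages:

```sh
sensipod simulate --seed 0 --out fixtures
sensipod endpoints --dpra fixtures/dpra.csv --hclat fixtures/hclat.csv \
    --keratinosens fixtures/keratinosens.csv
sensipod run --seed 3 --out pipeline_out
```

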