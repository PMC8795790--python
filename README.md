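# pqsar

Peptide QSAR modeling of domain–peptide binding affinities.

Peptide-recognition domains — SH3, PDZ, 14-3-3 — bind short linear motifs
(SLiMs) on partner proteins, and SPOT peptide arrays can screen thousands
of candidate peptides per domain, reporting binding as an arbitrary light
intensity (Boehringer light units, BLU).  `pqsar` is a toolkit for anyone
who wants to ask: *how much of that signal can a sequence-based regression
model actually capture?*  It provides:

* **Descriptor encoding** — an L-mer peptide with an m-dimensional
  amino-acid descriptor (AAD) table becomes an L·m feature vector
  (positionwise substitution).  VHSE ships with the package alongside
  stand-ins for the MolSurf / ST_scale / VSGETAWAY descriptor families.
* **Four regressors** behind one fit/predict contract, each with its
  selection protocol: PLS (NIPALS; components added while cumulative
  cross-validated q² rises by ≥ 0.097), ε-SVR with RBF kernel and RF
  (grid search minimizing cross-validation RMSE), and GP (squared
  exponential + noise; hyperparameters by restarted marginal-likelihood
  maximization).
* **The three-way validation design** — R²fit/RMSE_fit on the training
  set, seeded 10-fold cross-validation (R²cv/RMSE_cv, pooled out-of-fold),
  and external blind prediction (R²prd/RMSE_prd) on a held-out ~1/3 split.
  R² is 1 − RSS/TSS throughout.
* **A synthetic SLiM-panel generator** that plants a known signal in
  descriptor space under a chosen explained-variance ceiling — the tool
  for asking what an R²prd of 0.7 does or does not mean when the assay
  itself is noisy.
* **Benchmark orchestration and a CLI** (`pqsar encode | benchmark |
  subset | simulate`) for panels × descriptors × methods grids, sample-size
  experiments and scatter-data export.

## Worked example

```python
import pqsar

# a synthetic PDZ-like panel: 6-mer C-terminal motif, 2000 peptides,
# 70% of LogBLU variance carried by a planted linear signal
spec = pqsar.SyntheticPanelSpec(motif="xxxTxV", n=2000, seed=0,
                                target_r2=0.7)
panel, truth = pqsar.generate_panel(spec)
print(f"signal fraction {truth.realized_signal_fraction:.3f}")

panel, report = pqsar.filter_valid(panel)
split = pqsar.split_panel(panel, seed=0)          # ~2/3 train, ~1/3 test
table = pqsar.get_table(spec.table_name)
config = pqsar.RegressorConfig(method="pls", seed=0)
stats = pqsar.evaluate(panel, table, config, split)
print(f"NLV={stats.params['nlv']}  R2fit={stats.r2_fit:.3f}  "
      f"R2cv={stats.r2_cv:.3f}  R2prd={stats.r2_prd:.3f}")
```

Output:

```
signal fraction 0.700
NLV=1  R2fit=0.678  R2cv=0.660  R2prd=0.662
```

The generator planted exactly 70% recoverable variance; PLS selects a
single latent variable and its blind-test R²prd lands at 0.662 — the model
recovers essentially the whole planted ceiling, and the residual ~0.04 is
estimation shrinkage, not missed signal.  On real SPOT panels the same
protocol quantifies how far below the assay's noise ceiling a
sequence-based model sits.

From the shell, the same grid at scale:

```bash
pqsar simulate --out panels/                 # 18 reference-shaped panels
pqsar benchmark --panels panels/ --aads VHSE,MolSurf \
    --methods pls,gp --seed 1 --out results/
```

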