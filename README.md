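# riboratio

Ribosomal-protein stoichiometry ("ratio-omics") analysis for quantitative
proteomics.

## The problem

The eukaryotic ribosome carries ~80 conserved ribosomal proteins (RPs), but
its composition is not fixed: tissues, developmental stages and disease
states remodel the relative amounts of individual RPs and of paralogs such
as RPL10L and RPL39L. Raw protein intensities cannot expose this —
absolute ribosome abundance differences between samples swamp the
compositional signal. The stoichiometry barcode solves this by working on
each RP's *share* of the ribosome pool.

For sample *s* with detected RP set *D(s)* and iBAQ-style intensity
*x<sub>is</sub>* (proportional to molar amount):

```
r_is = x_is / Σ_{j ∈ D(s)} x_js
```

Each sample becomes a point on the simplex (non-missing ratios sum to 1),
invariant to loading, cell count and instrument response. `riboratio`
computes these barcodes and runs the standard downstream inference on them:

- **PCA with SVD imputation** — rows (RPs) centered and unit-variance
  scaled, missing entries filled by iterative rank-*k* SVD reconstruction,
  per-group 95% prediction ellipses (small-sample F quantile).
- **Pearson correlation matrices** between sample barcodes
  (pairwise-complete).
- **Hierarchical clustering** with correlation distance (d = 1 − r) and
  unweighted average linkage (UPGMA), for rows and columns, with tree
  cutting and cluster/group composition tables.
- **Differential stoichiometry**: per-RP two-tailed t-tests (Student or
  Welch), Benjamini–Hochberg correction, calls at adjusted p < 0.05,
  volcano tables. A *level* mode tests raw intensities instead, which sees
  overall ribosome abundance shifts that ratios are blind to.
- **Synthetic data**: a generator with planted stoichiometry effects,
  Dirichlet biological variability, lognormal noise and abundance-dependent
  dropout, with presets mirroring five study designs (six tissues × 3;
  four testis ages × 3; 3 vs 3 neuron culture; 82 vs 58 cohort; 10 vs 38
  single cells) and ground-truth tables for recovery scoring.

Input is delimited text: a generic genes × samples TSV/CSV, or MaxQuant
`proteinGroups.txt` (`iBAQ <sample>` columns, reverse/contaminant rows
dropped), plus a two-column sample→group metadata table.

## Worked example

```python
import riboratio as rr

spec = rr.preset("macrophage_sc", seed=42)   # 10 control vs 38 LPS cells
quant, truth = rr.generate_dataset(spec)

qc = rr.detected_rp_counts(quant, threshold=50)
ratios = rr.compute_ratios(quant)
diff = rr.differential_ratio(ratios, "LPS", "control")
print(diff.summary())
print(rr.evaluate_recovery(diff, truth))
```

prints

```
{'group_a': 'LPS', 'group_b': 'control', 'mode': 'ratio',
 'variant': 'student', 'alpha': 0.05, 'n_tested': 71, 'n_up': 9, 'n_down': 9}
{'n_planted_up': 9, 'n_planted_down': 9, 'recovered_up': 9,
 'recovered_down': 9, 'sensitivity_up': 1.0, 'sensitivity_down': 1.0,
 'false_positives': 0, 'n_calls': 18, 'fdp': 0.0}
```

All 71 RPs were testable; the 9 planted 2-fold stoichiometry increases and
9 decreases are each recovered exactly, with no false calls. The
`examples/` directory has one narrative script per capability (tissue
barcodes and correlation, development PCA with ellipses, cohort
clustering, single-cell differential testing); each prints its numbers
with a note on what they mean.

The same analyses run from the shell:

```bash
riboratio simulate --preset gastric_cohort --seed 7 --out sim/
riboratio run --input sim/quant.tsv --meta sim/groups.tsv --out results/ --k 2
```

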