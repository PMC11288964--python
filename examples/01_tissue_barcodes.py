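"""Stoichiometry barcodes across six simulated tissues.

Simulates the six-tissue monosome design (3 samples per tissue, 82 RPs),
computes each sample's ribosomal-protein ratio barcode, and shows that
within-tissue barcodes correlate far more strongly than between-tissue
ones — the signature of tissue-specific ribosome composition.
"""

import numpy as np

import riboratio as rr

spec = rr.preset("tissues6", seed=42)
quant, truth = rr.generate_dataset(spec)
ratios = rr.compute_ratios(quant)
print(f"panel: {quant.n_proteins} RPs x {quant.n_samples} samples")

corr = rr.pearson_correlation(ratios)
labels = ratios.group_labels()
within, between = [], []
for i, a in enumerate(corr.sample_ids):
    for b in corr.sample_ids[i + 1:]:
        (within if labels[a] == labels[b] else between).append(
            corr.r.loc[a, b]
        )
print(f"min within-tissue correlation : {np.min(within):.3f}")
print(f"max between-tissue correlation: {np.max(between):.3f}")
# Within-tissue r should exceed ~0.85 while distinct tissues fall lower,
# i.e. each tissue carries its own reproducible ribosome barcode.
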