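"""Simulate a small CROP-seq-like CRISPRi screen with known ground truth.

The generator draws negative-binomial UMI counts over a log-normal gene
universe, knocks the target gene down in every gRNA-targeted cell (with
per-cell efficiency), and plants a short log2-fold-change signature in a
fraction of those cells — the "actually perturbed" ones.
"""

import numpy as np

from cropsae import SimConfig, simulate_cropseq

config = SimConfig(n_control=100, n_targeted=100, n_genes=200, n_signature=6,
                   signature_lfc=(1.5, -1.5, 1.5, -1.5, 1.5, -1.5),
                   frac_perturbed=0.7, knockdown_factor=0.1, seed=0)
counts, annotations, truth = simulate_cropseq(config)

print(f"matrix: {counts.n_cells} cells x {counts.n_genes} genes, "
      f"{np.count_nonzero(counts.values)} nonzero entries")
print(f"controls: {sum(a.is_control for a in annotations)}, "
      f"targeted: {sum(not a.is_control for a in annotations)}")
print(f"target gene index {truth.target_gene_index} "
      f"(knocked down to ~{config.knockdown_factor:.0%} of baseline)")
print(f"truly perturbed targeted cells: {truth.perturbed_mask.sum()} "
      f"of {config.n_targeted} (planted fraction {config.frac_perturbed})")
print(f"signature genes (index, direction): "
      f"{list(zip(truth.signature_gene_indices, truth.signature_directions))}")
# The perturbed mask and signature list are the ground truth every later
# stage is scored against; real screens provide no such truth.
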