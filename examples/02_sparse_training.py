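"""Train the sparse supervised autoencoder and inspect gene selection.

Double-descent training: a first projected-gradient phase finds which gene
rows of the input layer survive the l1,1 constraint, the weights are
rewound to their initial values with dead rows frozen at zero, and a second
phase retrains the pruned network.  The surviving rows are the selected
genes; eta controls how many survive.
"""

from cropsae import (SimConfig, TrainConfig, assemble_dataset,
                     simulate_cropseq, train_double_descent)
from cropsae.projection import selected_feature_fraction
from cropsae.model import forward, accuracy_f1

sim = SimConfig(n_control=100, n_targeted=100, n_genes=200, n_signature=6,
                signature_lfc=(1.5, -1.5, 1.5, -1.5, 1.5, -1.5), seed=0)
counts, annotations, truth = simulate_cropseq(sim)
dataset = assemble_dataset(counts, annotations, sim.target_gene, sim.condition)

for eta in (2.0, 10.0, 40.0):
    config = TrainConfig(eta=eta, hidden_dim=32, epochs_phase1=60,
                         epochs_phase2=60, seed=1)
    result = train_double_descent(dataset, config, seed=1)
    out = forward(result.weights, dataset.X)
    acc, _ = accuracy_f1(out.scores, dataset.Y)
    frac = selected_feature_fraction(result.weights.W1)
    in_support = result.support[truth.target_gene_index]
    print(f"eta={eta:5.1f}: {frac:6.1%} of genes kept "
          f"({result.support.sum():3d}/{sim.n_genes}), "
          f"training accuracy {acc:.3f}, target gene kept: {in_support}")
# Small eta keeps only the strongest discriminant genes (the knocked-down
# target should always be among them); larger eta trades sparsity for
# capacity.  Accuracy is flat over a wide range — the basis of tuning eta
# at the peak of that concave curve.
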