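"""Which residues drive a prediction? Integrated gradients + attention.

Trains a small transformer on the synthetic corpus, attributes the
predicted ACP probability of one peptide to its tokens, summarizes
attribution per amino acid over the positive test peptides, and pulls the
first-layer attention maps.
"""

import numpy as np

from pepclr import (
    EncoderConfig,
    LossWeights,
    TrainConfig,
    build_dual_model,
    extract_attention,
    integrated_gradients,
    split_train_val,
    summarize_attributions,
    train,
)
from pepclr.records import PeptideDataset
from pepclr.simulate import SignalSpec, generate_labeled_peptides

train_set, _ = generate_labeled_peptides(300, SignalSpec(), seed=51)
test_set, _ = generate_labeled_peptides(60, SignalSpec(), seed=52)

config = TrainConfig(
    epochs=12, seed=0,
    model=EncoderConfig(architecture="transformer", embed_dim=32,
                        hidden_dim=64, n_layers=1, n_heads=4, proj_dim=32,
                        max_len=52),
    weights=LossWeights(alpha=0.1, beta=0.5, tau=0.2),
)
tr, val = split_train_val(train_set, 0.1, 0)
model = build_dual_model(config.model, 0)
train(model, tr, val, config)

positives = PeptideDataset([r for r in test_set if r.label == 1])
example = positives[0]
res = integrated_gradients(model, example, tower=1, n_steps=128)
print(f"{example.id}: predicted ACP probability {res.predicted_prob:.3f}")
print(f"completeness gap {res.completeness_gap:.2e} "
      f"(attributions sum to F(x) - F(baseline) up to this residual)")
top = np.argsort(-res.per_position_scores)[:5]
print("top attributed positions:",
      ", ".join(f"{res.tokens[i]}@{i}" for i in top))

results = [integrated_gradients(model, r, tower=1, n_steps=64)
           for r in positives]
summary = summarize_attributions(results, positives)
print("residues ranked by mean attribution over positive test peptides:")
for aa, mean in summary.ranked()[:6]:
    print(f"  {aa}: {mean:+.4f} (n={summary.count[aa]})")
print("K/W/L should rank high: the generator enriches them in positives, "
      "and the model learned to read exactly that signal.")

matrices, labels = extract_attention(model, example, tower=1, layer=0)
print(f"first-layer attention: {len(matrices)} heads, "
      f"{matrices[0].shape[0]}x{matrices[0].shape[1]} row-stochastic maps; "
      f"row sums ~ {matrices[0].sum(axis=1)[0]:.3f}")
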