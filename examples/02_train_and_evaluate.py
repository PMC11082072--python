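"""Train the dual-tower model on a synthetic corpus and evaluate it.

Generates a labeled corpus with a planted composition signal (positives
enriched in K/W/L, negatives in D/S/Y), trains with the blended
objective L_final = (1-α)·L_CE + α·L_CL, and reports test metrics for
both classification heads.
"""

from pepclr import (
    EncoderConfig,
    LossWeights,
    TrainConfig,
    build_dual_model,
    evaluate_model,
    split_train_val,
    train,
)
from pepclr.simulate import SignalSpec, generate_labeled_peptides

train_set, _ = generate_labeled_peptides(400, SignalSpec(), seed=11)
test_set, _ = generate_labeled_peptides(100, SignalSpec(), seed=12)

config = TrainConfig(
    epochs=20,
    seed=0,
    model=EncoderConfig(architecture="cnn", embed_dim=32, hidden_dim=64,
                        n_layers=1, proj_dim=32, max_len=52),
    weights=LossWeights(alpha=0.1, beta=0.5, tau=0.2),
)

tr, val = split_train_val(train_set, config.val_fraction, config.seed)
print(f"split: {len(tr)} train / {len(val)} validation (seeded, stratified)")

model = build_dual_model(config.model, config.seed)
record = train(model, tr, val, config)
last = record.history[-1]
print(f"final epoch losses: L_CE={last['l_ce']:.4f} "
      f"L_CL={last['l_cl']:.4f} L_final={last['l_final']:.4f}")

for head in (1, 2):
    m = evaluate_model(model, test_set, classifier=head)
    print(f"classifier {head}: accuracy={m.accuracy:.3f} "
          f"sensitivity={m.sensitivity:.3f} specificity={m.specificity:.3f} "
          f"MCC={m.mcc:.3f} AUC={m.auc:.3f}")
print("MCC near 1 means the planted composition signal was recovered; "
      "head 1 reads the single-residue tower, head 2 the pair tower.")
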