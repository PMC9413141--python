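"""Train a small model on phantoms and evaluate it on held-out data.

Uses a reduced run (60 training phantoms, 10 epochs) so it finishes in a
couple of minutes on one CPU; the desk preset used for the full end-to-end
check is the same pipeline with 200 phantoms and 30 epochs.
"""

import lcanet

train_set, val_set, test_set = lcanet.desk_dataset(
    n_train=60, n_val=16, n_test=16, seed=0
)
net_cfg = lcanet.desk_net_config()
train_cfg = lcanet.desk_train_config(epochs=10, seed=0)

print(f"training depth-{net_cfg.depth} net (widths {net_cfg.widths}) on "
      f"{len(train_set)} phantoms for {train_cfg.epochs} epochs ...")
result = lcanet.train(train_set, val_set, net_cfg, train_cfg)

print(f"{'epoch':>5} {'train loss':>11} {'val loss':>9} {'val dice %':>10}")
for h in result.history:
    print(f"{h['epoch']:>5} {h['train_loss']:>11.4f} {h['val_loss']:>9.4f} "
          f"{h['val_dice']:>10.2f}")

rows, summary = lcanet.evaluate(result.model, test_set)
print(f"\nheld-out test ({len(rows)} phantoms): dice {summary.dice:.2f}%, "
      f"pixel accuracy {summary.pa:.2f}%, jaccard {summary.jaccard:.2f}%")
print(f"precision {summary.precision:.3f}, recall {summary.recall:.3f}")
# dice is the primary overlap score; the validation dice column shows the
# learning trend the best-checkpoint selection acts on.
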