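"""Tune the recurrent classifier's hyperparameters with HASCA.

One tuning run at the six-agent / eight-iteration budget on the default
binary dataset (a couple of minutes on one CPU).  The optimizer searches over
learning rate, dropout, epoch budget, layer count and per-layer widths;
the objective is validation classification error.  The winning
configuration is retrained and scored on the held-out test split.
"""

from neurotune import HyperparamSpec, make_synthetic_dataset, run_campaign

frame, _ = make_synthetic_dataset(
    n_classes=2, windows_per_class=25, channels=8, seed=42
)
campaign = run_campaign(
    "hasca", HyperparamSpec.for_experiment(1), frame,
    runs=1, N=6, T=8, base_seed=7,
)

record = campaign.best_record()
print(f"best validation error: {record['best_objective']:.4f}")
print(f"best hyperparameters:  {record['best_hyperparams'].to_dict()}")
print(f"test accuracy:         {100 * record['test_accuracy']:.2f}%")
print(f"test Cohen's kappa:    {record['test_kappa']:.4f}")
print("(error is 1 - accuracy on the validation split; kappa corrects for chance)")
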