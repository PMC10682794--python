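"""Hyperparameter tuning of the recurrent EEG classifier.

The genotype is a 6-dimensional continuous vector
``[learning_rate, dropout, epochs, layers, neurons1, neurons2]``; the
decoder rounds the integer dimensions (half away from zero) and clamps
into range.  Note the genotype always carries a width for a second
recurrent layer, even when the decoded layer count is 1 — the second
width is then decoded but inert, which keeps the search space fixed-size
regardless of architecture.

The objective is the classification error (1 - accuracy) of a model
trained with the decoded hyperparameters, measured on the validation
split by default (a flag switches to the test split).  A campaign is a
set of independent seeded optimizer runs over this objective; each run's
winning configuration is retrained and scored on the held-out test split
for reporting.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .eeg import SupervisedFrame
from .metrics import MetricReport, build_confusion, classification_metrics
from .optimizers import OPTIMIZERS, HASCAConfig
from .rnn import ElmanRNNClassifier
from .space import RunResult, SearchSpace, spawn_rng

__all__ = [
    "HyperparamSpec",
    "RNNHyperparams",
    "TrainedModel",
    "CampaignResult",
    "spec_to_search_space",
    "decode_hyperparams",
    "train_rnn",
    "objective_classification_error",
    "make_objective",
    "run_campaign",
]

#: default minibatch size; small model + CPU vectorization favor larger
#: batches than the GPU-era convention.
DEFAULT_BATCH_SIZE = 256


@dataclass(frozen=True)
class HyperparamSpec:
    """Search ranges for the six tunable quantities.

    The neuron ranges derive from the lag count: [lags/3, lags] for the
    binary experiment and [lags/2, 2*lags] for the multi-class one,
    rounded to honest integer ranges ([5, 15] and [8, 30] at lags=15).
    """

    learning_rate_range: tuple[float, float] = (0.0001, 0.01)
    dropout_range: tuple[float, float] = (0.05, 0.2)
    epochs_range: tuple[int, int] = (30, 60)
    layers_range: tuple[int, int] = (1, 2)
    neurons_range: tuple[int, int] = (5, 15)
    lags: int = 15

    @classmethod
    def for_experiment(cls, experiment: int, lags: int = 15) -> "HyperparamSpec":
        if experiment == 1:
            return cls(
                epochs_range=(30, 60),
                neurons_range=(round(lags / 3), lags),
                lags=lags,
            )
        if experiment == 2:
            return cls(
                epochs_range=(50, 150),
                neurons_range=(math.ceil(lags / 2), 2 * lags),
                lags=lags,
            )
        raise ValueError("experiment must be 1 or 2")


@dataclass(frozen=True)
class RNNHyperparams:
    learning_rate: float
    dropout: float
    epochs: int
    num_layers: int
    neurons: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "dropout": self.dropout,
            "epochs": self.epochs,
            "num_layers": self.num_layers,
            "neurons": list(self.neurons),
        }


def spec_to_search_space(spec: HyperparamSpec) -> SearchSpace:
    """6-d box: lr, dropout, epochs, layers, neurons1, neurons2."""
    lower = [
        spec.learning_rate_range[0],
        spec.dropout_range[0],
        spec.epochs_range[0],
        spec.layers_range[0],
        spec.neurons_range[0],
        spec.neurons_range[0],
    ]
    upper = [
        spec.learning_rate_range[1],
        spec.dropout_range[1],
        spec.epochs_range[1],
        spec.layers_range[1],
        spec.neurons_range[1],
        spec.neurons_range[1],
    ]
    return SearchSpace(
        lower=np.array(lower),
        upper=np.array(upper),
        integer_dims=frozenset({2, 3, 4, 5}),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def decode_hyperparams(position: np.ndarray, spec: HyperparamSpec) -> RNNHyperparams:
    """Continuous genotype -> concrete hyperparameters.

    Continuous dimensions pass through; integer dimensions are rounded
    half-away-from-zero and clamped into their range.
    """
    x = np.asarray(position, dtype=float)
    if x.shape != (6,):
        raise ValueError(f"expected a 6-d genotype, got shape {x.shape}")

    def as_int(v: float, rng: tuple[int, int]) -> int:
        return int(np.clip(_round_half_away(v), rng[0], rng[1]))

    return RNNHyperparams(
        learning_rate=float(np.clip(x[0], *spec.learning_rate_range)),
        dropout=float(np.clip(x[1], *spec.dropout_range)),
        epochs=as_int(x[2], spec.epochs_range),
        num_layers=as_int(x[3], spec.layers_range),
        neurons=(
            as_int(x[4], spec.neurons_range),
            as_int(x[5], spec.neurons_range),
        ),
    )


@dataclass
class TrainedModel:
    """Fitted classifier handle plus its training trace."""

    model: ElmanRNNClassifier
    params: RNNHyperparams
    seed: int

    @property
    def stopped_epoch(self) -> int:
        return self.model.stopped_epoch

    @property
    def history(self) -> dict:
        return self.model.history

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)


def train_rnn(
    params: RNNHyperparams,
    data: SupervisedFrame,
    seed: int,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> TrainedModel:
    """Train the recurrent classifier under the given hyperparameters.

    Architecture: ``num_layers`` simple recurrent layers (the second
    width is ignored at one layer), dropout after each, softmax output.
    Early stopping monitors validation loss with patience
    floor(epochs/3) and restores the best-validation weights.
    """
    X_train, y_train = data.subset("train")
    X_val, y_val = data.subset("val")
    if np.unique(y_train).size < 2:
        raise ValueError("training split contains a single class")
    hidden = (
        (params.neurons[0],)
        if params.num_layers == 1
        else (params.neurons[0], params.neurons[1])
    )
    model = ElmanRNNClassifier(
        input_dim=data.channels,
        n_classes=data.n_classes,
        hidden=hidden,
        dropout=params.dropout,
        learning_rate=params.learning_rate,
        epochs=params.epochs,
        batch_size=batch_size,
        patience=params.epochs // 3,
        seed=seed,
    )
    model.fit(X_train, y_train, X_val, y_val)
    return TrainedModel(model=model, params=params, seed=seed)


def objective_classification_error(
    position: np.ndarray,
    spec: HyperparamSpec,
    data: SupervisedFrame,
    seed: int,
    fitness_split: str = "val",
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> float:
    """1 - accuracy of the decoded configuration on the fitness split.

    Training failures are absorbed into a +inf objective so one bad
    configuration cannot abort an optimizer run.
    """
    try:
        params = decode_hyperparams(position, spec)
        trained = train_rnn(params, data, seed, batch_size=batch_size)
        X, y = data.subset(fitness_split)
        accuracy = float(np.mean(trained.predict(X) == y))
        return 1.0 - accuracy
    except Exception as exc:  # noqa: BLE001 - objective must stay alive
        warnings.warn(f"training failed ({exc}); objective = +inf", stacklevel=2)
        return float("inf")


def make_objective(
    spec: HyperparamSpec,
    data: SupervisedFrame,
    seed: int,
    fitness_split: str = "val",
    batch_size: int = DEFAULT_BATCH_SIZE,
):
    """Bind the classification-error objective for an optimizer run."""

    def objective(position: np.ndarray) -> float:
        return objective_classification_error(
            position, spec, data, seed,
            fitness_split=fitness_split, batch_size=batch_size,
        )

    return objective


@dataclass
class CampaignResult:
    """Outcome of a multi-run tuning campaign for one optimizer."""

    optimizer: str
    spec: HyperparamSpec
    records: list[dict] = field(default_factory=list)

    def objectives(self) -> np.ndarray:
        return np.array([r["best_objective"] for r in self.records])

    def kappas(self) -> np.ndarray:
        return np.array([r["test_kappa"] for r in self.records])

    def test_accuracies(self) -> np.ndarray:
        return np.array([r["test_accuracy"] for r in self.records])

    def best_record(self) -> dict:
        return min(self.records, key=lambda r: r["best_objective"])

    def to_json(self) -> str:
        out = []
        for r in self.records:
            row = dict(r)
            row["best_hyperparams"] = r["best_hyperparams"].to_dict()
            row["run_result"] = json.loads(r["run_result"].to_json())
            row["test_report"] = r["test_report"].to_dict()
            out.append(row)
        return json.dumps({"optimizer": self.optimizer, "records": out})


def run_campaign(
    optimizer: str,
    spec: HyperparamSpec,
    data: SupervisedFrame,
    runs: int = 30,
    N: int = 6,
    T: int = 8,
    base_seed: int = 0,
    fitness_split: str = "val",
    batch_size: int = DEFAULT_BATCH_SIZE,
    config: HASCAConfig | None = None,
) -> CampaignResult:
    """Independent seeded tuning runs of one optimizer.

    Run k draws its own rng stream from (base_seed, k) and trains with a
    derived integer seed, so the whole campaign is reproducible run by
    run.  Each run's best genotype is decoded, retrained, and scored on
    the test split.
    """
    if optimizer not in OPTIMIZERS:
        raise ValueError(
            f"unknown optimizer {optimizer!r}; registered: "
            f"{sorted(OPTIMIZERS)}"
        )
    cfg = config or HASCAConfig(N=N, T=T)
    space = spec_to_search_space(spec)
    result = CampaignResult(optimizer=optimizer, spec=spec)
    for k in range(runs):
        run_seed = (base_seed * 1009 + k) % (2**31)
        rng = spawn_rng(base_seed, k)
        objective = make_objective(
            spec, data, run_seed,
            fitness_split=fitness_split, batch_size=batch_size,
        )
        run: RunResult = OPTIMIZERS[optimizer](
            space, objective, cfg, rng, seed=run_seed
        )
        best_params = decode_hyperparams(run.best_position, spec)
        final = train_rnn(best_params, data, run_seed, batch_size=batch_size)
        X_test, y_test = data.subset("test")
        pred = final.predict(X_test)
        report = classification_metrics(
            build_confusion(y_test, pred, K=data.n_classes)
        )
        result.records.append(
            {
                "seed": run_seed,
                "best_objective": run.best_fitness,
                "best_hyperparams": best_params,
                "run_result": run,
                "test_accuracy": report.accuracy,
                "test_kappa": report.kappa,
                "test_report": report,
            }
        )
    return result
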