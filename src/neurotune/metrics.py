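"""Classification metrics, run aggregation, and statistical validation.

Metrics are computed from the confusion matrix: per-class one-vs-rest
precision/recall/F1, overall accuracy, error = 1 - accuracy, and Cohen's
kappa — the chance-corrected agreement (p_o - p_e) / (1 - p_e), which is
robust to class imbalance where raw accuracy is not.

Multi-run campaigns are condensed to best/worst/mean/median/std/var
summaries, and method comparisons follow a two-stage protocol: a
Shapiro-Wilk normality check per method, then (when normality is
rejected for any method) the paired two-sided Wilcoxon signed-rank test
of every competitor against the control method.  The signed-rank test is
exact (full sign enumeration) for small samples and uses the
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "RunSummary",
    "SignificanceReport",
    "build_confusion",
    "classification_metrics",
    "cohens_kappa",
    "summarize_runs",
    "shapiro_wilk_p",
    "wilcoxon_signed_rank_p",
    "compare_methods",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] < 2:
            raise ValueError("counts must be a square K x K matrix, K >= 2")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def K(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def build_confusion(
    true_labels, predicted_labels, K: int | None = None,
    class_names: tuple[str, ...] = (),
) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.size == 0 or t.shape != p.shape:
        raise ValueError("need equal-length, non-empty label sequences")
    if K is None:
        K = int(max(t.max(), p.max())) + 1
    if t.min() < 0 or p.min() < 0 or t.max() >= K or p.max() >= K:
        raise ValueError(f"labels outside 0..{K - 1}")
    counts = np.zeros((K, K), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts, class_names=class_names)


@dataclass(frozen=True)
class MetricReport:
    """Accuracy, error, kappa, and per-class + weighted P/R/F1."""

    accuracy: float
    error: float
    kappa: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    class_names: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "error": self.error,
            "kappa": self.kappa,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "class_names": list(self.class_names),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def to_text(self) -> str:
        names = self.class_names or tuple(
            f"class {k}" for k in range(self.precision.size)
        )
        lines = [f"Accuracy (%)      {100 * self.accuracy:.4f}"]
        for kind, per_class, weighted in (
            ("Precision", self.precision, self.weighted_precision),
            ("Recall", self.recall, self.weighted_recall),
            ("F1-score", self.f1, self.weighted_f1),
        ):
            for name, v in zip(names, per_class):
                lines.append(f"{kind} {name:<10} {v:.6f}")
            lines.append(f"W. Avg. {kind:<10} {weighted:.6f}")
        lines.append(f"Cohen's kappa     {self.kappa:.6f}")
        return "\n".join(lines)


def classification_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Per-class one-vs-rest metrics plus weighted averages.

    Zero-denominator precision/recall is reported as 0 (the convention
    for classes never predicted / never present).  Weighted averages use
    the true-class support, so weighted recall always equals accuracy.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    if total < 1:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c)
    support = c.sum(axis=1)
    predicted = c.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    accuracy = float(tp.sum() / total)
    w = support / total
    return MetricReport(
        accuracy=accuracy,
        error=1.0 - accuracy,
        kappa=cohens_kappa(cm),
        precision=precision,
        recall=recall,
        f1=f1,
        weighted_precision=float(np.sum(w * precision)),
        weighted_recall=float(np.sum(w * recall)),
        weighted_f1=float(np.sum(w * f1)),
        class_names=cm.class_names,
    )


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    p_o is the observed accuracy; p_e the agreement expected from the
    row/column marginals.  When p_e = 1 (all mass in a single cell) the
    statistic is undefined and 0 is returned with a warning.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    if total < 1:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(c) / total
    p_e = float(np.sum(c.sum(axis=1) * c.sum(axis=0)) / total**2)
    if np.isclose(p_e, 1.0):
        warnings.warn("kappa undefined (p_e = 1); returning 0", stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass(frozen=True)
class RunSummary:
    """Best/Worst/Mean/Median/Std/Var over per-run scores."""

    best: float
    worst: float
    mean: float
    median: float
    std: float
    var: float

    def to_dict(self) -> dict:
        return {
            "best": self.best,
            "worst": self.worst,
            "mean": self.mean,
            "median": self.median,
            "std": self.std,
            "var": self.var,
        }

    def to_row(self, name: str) -> str:
        return (
            f"{name:<12} {self.best:.6f}  {self.worst:.6f}  {self.mean:.6f}  "
            f"{self.median:.6f}  {self.std:.2E}  {self.var:.2E}"
        )


def summarize_runs(objectives, minimize: bool = True) -> RunSummary:
    """Campaign summary; sample (n-1) standard deviation.

    With ``minimize=True`` (objective values) best is the minimum; for
    scores like kappa pass ``minimize=False``.
    """
    x = np.asarray(objectives, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if x.size == 1:
        warnings.warn("single-run sample; std reported as 0", stacklevel=2)
        std = 0.0
    else:
        std = float(np.std(x, ddof=1))
    best = float(x.min() if minimize else x.max())
    worst = float(x.max() if minimize else x.min())
    return RunSummary(
        best=best,
        worst=worst,
        mean=float(x.mean()),
        median=float(np.median(x)),
        std=std,
        var=std**2,
    )


def shapiro_wilk_p(sample) -> float:
    """Shapiro-Wilk normality p-value (3 <= n <= 5000)."""
    x = np.asarray(sample, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    return float(stats.shapiro(x).pvalue)


def _signed_ranks(diff: np.ndarray) -> np.ndarray:
    return stats.rankdata(np.abs(diff))


def wilcoxon_signed_rank_p(control_sample, competitor_sample) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped.  For n <= 12 (after zero removal) the
    p-value comes from exact enumeration of all 2^n sign assignments of
    the (tie-averaged) ranks; larger samples use the normal
    approximation with tie correction.
    """
    a = np.asarray(control_sample, dtype=float)
    b = np.asarray(competitor_sample, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("samples must be equal-length 1-d vectors")
    diff = b - a
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    ranks = _signed_ranks(diff)
    w_plus = float(ranks[diff > 0].sum())
    if n <= 12:
        # exact two-sided: enumerate every sign assignment of the ranks
        lo = hi = 0
        count = 0
        for signs in itertools.product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            lo += w <= w_plus
            hi += w >= w_plus
            count += 1
        p = 2.0 * min(lo, hi) / count
        return float(min(1.0, p))
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_plus - mu) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class SignificanceReport:
    """Outcome of the normality-then-signed-rank comparison protocol."""

    shapiro_p: dict[str, float]
    wilcoxon_p: dict[str, float]
    control: str
    alpha: float = 0.05
    used_nonparametric: bool = True
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "shapiro_p": self.shapiro_p,
            "wilcoxon_p": self.wilcoxon_p,
            "control": self.control,
            "alpha": self.alpha,
            "used_nonparametric": self.used_nonparametric,
            "notes": self.notes,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def compare_methods(
    samples: dict[str, np.ndarray],
    control: str,
    alpha: float = 0.05,
) -> SignificanceReport:
    """Two-stage comparison of per-run objective samples.

    Runs Shapiro-Wilk on every method's sample first; if any method's
    normality is rejected at ``alpha``, parametric testing is not safe
    and every competitor is compared with the control by the paired
    Wilcoxon signed-rank test.  (The non-parametric branch is also used
    when a sample is constant, where Shapiro-Wilk is undefined.)
    """
    if control not in samples:
        raise ValueError(f"control {control!r} not among {sorted(samples)}")
    shapiro: dict[str, float] = {}
    notes: list[str] = []
    any_reject = False
    for name, sample in samples.items():
        try:
            shapiro[name] = shapiro_wilk_p(np.asarray(sample))
        except ValueError as exc:
            shapiro[name] = float("nan")
            notes.append(f"shapiro({name}): {exc}")
            any_reject = True
            continue
        if shapiro[name] < alpha:
            any_reject = True
    wilcoxon: dict[str, float] = {}
    if any_reject:
        ctrl = np.asarray(samples[control], dtype=float)
        for name, sample in samples.items():
            if name == control:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wilcoxon[name] = wilcoxon_signed_rank_p(
                    ctrl, np.asarray(sample, dtype=float)
                )
    else:
        notes.append(
            "no normality rejection; parametric testing would be "
            "admissible (not performed here)"
        )
    return SignificanceReport(
        shapiro_p=shapiro,
        wilcoxon_p=wilcoxon,
        control=control,
        alpha=alpha,
        used_nonparametric=any_reject,
        notes=notes,
    )
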