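"""Repeated cross-validated random-forest evaluation of molecular descriptors.

The protocol: a random forest (500 trees, max_features = 0.3 of the columns)
is evaluated by ten-times-repeated 10-fold cross-validation, giving 100
held-out metric values per representation.  Regression is scored with the
coefficient of determination R^2 and RMSE (a squared-Pearson variant of R^2
is also reported); classification with balanced accuracy and ROC AUC from
class-1 probabilities.  Baselines predict the training mean (regression) or
the training majority class (classification).

Two representations fitted with the same configuration share fold
partitions, so per-fold relative metrics (ratio minus 1) are well defined,
and their pooled per-fold metric distributions can be compared with a
two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import (
    balanced_accuracy_score,
    mean_squared_error,
    r2_score,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold

from .featurize import FeatureMatrix

__all__ = [
    "BenchmarkConfig",
    "CVReport",
    "ComparisonResult",
    "MeanBaselineRegressor",
    "MajorityBaselineClassifier",
    "baseline_predictor",
    "reference_features",
    "repeated_cv",
    "relative_metric",
    "compare_mannwhitney",
    "plot_metric_bars",
]

REGRESSION_METRICS = ("r2", "rmse", "pearson_r2")
CLASSIFICATION_METRICS = ("balanced_accuracy", "roc_auc")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Settings of one repeated-CV evaluation."""

    task: str = "regression"  # or "classification"
    n_estimators: int = 500
    max_features_fraction: float = 0.3
    n_folds: int = 10
    n_repeats: int = 10
    random_seed: int = 0
    metrics: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("need n_folds >= 2 and n_repeats >= 1")
        if not 0 < self.max_features_fraction <= 1:
            raise ValueError("max_features_fraction must lie in (0, 1]")
        if not self.metrics:
            default = REGRESSION_METRICS if self.task == "regression" else CLASSIFICATION_METRICS
            object.__setattr__(self, "metrics", tuple(default))


class MeanBaselineRegressor:
    """Predicts the training-set mean for every input."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


class MajorityBaselineClassifier:
    """Predicts the training majority class; ties go to the smaller label.

    ``predict_proba`` returns the constant training class frequencies, so a
    probability-ranked metric such as ROC AUC sees a label-independent score.
    """

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        # argmax takes the first maximum; classes_ is sorted, so ties break low
        self.majority_ = self.classes_[np.argmax(counts)]
        self.frequencies_ = counts / counts.sum()
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.majority_)

    def predict_proba(self, X):
        n = np.asarray(X).shape[0]
        return np.tile(self.frequencies_, (n, 1))


def baseline_predictor(task: str, training_targets: Sequence[float]):
    """Fit the protocol's baseline on the given training targets."""
    y = np.asarray(training_targets)
    if y.size == 0:
        raise ValueError("cannot fit a baseline on empty targets")
    if task == "regression":
        return MeanBaselineRegressor().fit(None, y)
    if task == "classification":
        return MajorityBaselineClassifier().fit(None, y)
    raise ValueError(f"unknown task {task!r}")


_FP_SCHEMES = ("morgan", "atom_pairs_classic", "topological_torsion", "path_fingerprint")
REFERENCE_SCHEMES = _FP_SCHEMES + ("descriptor_panel",)


def reference_features(
    molecules: Sequence[str],
    scheme: str,
    n_bits: int = 2048,
    radius: int = 2,
    ids: Optional[Sequence[str]] = None,
) -> FeatureMatrix:
    """Standard RDKit reference representations for the benchmark.

    Count-folded Morgan, classic atom-pair and topological-torsion
    fingerprints, the RDKit path fingerprint, or the full RDKit descriptor
    panel (descriptor columns with non-finite values are dropped).
    """
    from rdkit.Chem import Descriptors, rdFingerprintGenerator

    from .pairs import mol_from_smiles

    if scheme not in REFERENCE_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(REFERENCE_SCHEMES)}")
    if ids is None:
        ids = [str(i) for i in range(len(molecules))]
    mols = []
    for mol_id, smiles in zip(ids, molecules):
        try:
            mols.append(mol_from_smiles(smiles))
        except ValueError as exc:
            raise ValueError(f"molecule {mol_id!r}: {exc}") from exc

    if scheme == "descriptor_panel":
        names = [name for name, _ in Descriptors._descList]
        rows = np.array(
            [[float(fn(m)) for _, fn in Descriptors._descList] for m in mols]
        ) if mols else np.empty((0, len(names)))
        finite = np.all(np.isfinite(rows), axis=0) if len(mols) else np.ones(len(names), bool)
        return FeatureMatrix(
            row_ids=[str(i) for i in ids],
            feature_names=[f"rdkit_desc|{n}" for n, k in zip(names, finite) if k],
            values=rows[:, finite],
        )

    generators = {
        "morgan": lambda: rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits),
        "atom_pairs_classic": lambda: rdFingerprintGenerator.GetAtomPairGenerator(fpSize=n_bits),
        "topological_torsion": lambda: rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=n_bits),
        "path_fingerprint": lambda: rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits),
    }
    gen = generators[scheme]()
    rows = np.array(
        [gen.GetCountFingerprintAsNumPy(m) for m in mols], dtype=float
    ) if mols else np.empty((0, n_bits))
    return FeatureMatrix(
        row_ids=[str(i) for i in ids],
        feature_names=[f"{scheme}|bit{k}" for k in range(n_bits)],
        values=rows,
    )


@dataclass
class CVReport:
    """Per-fold metric values of one (representation, dataset) evaluation."""

    representation: str
    config: BenchmarkConfig
    per_fold: Dict[str, np.ndarray]  # metric -> (n_repeats, n_folds)

    def __post_init__(self) -> None:
        shape = (self.config.n_repeats, self.config.n_folds)
        for metric, values in self.per_fold.items():
            self.per_fold[metric] = np.asarray(values, dtype=float)
            if self.per_fold[metric].shape != shape:
                raise ValueError(f"metric {metric!r} has shape "
                                 f"{self.per_fold[metric].shape}, expected {shape}")

    def values(self, metric: str) -> np.ndarray:
        """All n_repeats x n_folds held-out values of one metric, flattened."""
        return self.per_fold[metric].ravel()

    def summary(self) -> Dict[str, Dict[str, float]]:
        """Mean and normal-approximation 95% CI of each metric."""
        out = {}
        for metric, values in self.per_fold.items():
            flat = values.ravel()
            half = 1.96 * flat.std(ddof=1) / np.sqrt(flat.size) if flat.size > 1 else 0.0
            out[metric] = {
                "mean": float(flat.mean()),
                "ci95_low": float(flat.mean() - half),
                "ci95_high": float(flat.mean() + half),
            }
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "representation": self.representation,
                "config": asdict(self.config),
                "per_fold": {m: v.tolist() for m, v in self.per_fold.items()},
                "summary": self.summary(),
            },
            indent=1,
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: Union[str, Path]) -> "CVReport":
        doc = json.loads(Path(path).read_text())
        cfg = doc["config"]
        cfg["metrics"] = tuple(cfg.get("metrics", ()))
        return cls(
            representation=doc["representation"],
            config=BenchmarkConfig(**cfg),
            per_fold={m: np.asarray(v) for m, v in doc["per_fold"].items()},
        )


def _make_model(config: BenchmarkConfig, model: str, seed: int):
    if model == "baseline":
        if config.task == "regression":
            return MeanBaselineRegressor()
        return MajorityBaselineClassifier()
    if model != "random_forest":
        raise ValueError(f"unknown model {model!r}")
    if config.task == "regression":
        return RandomForestRegressor(
            n_estimators=config.n_estimators,
            max_features=config.max_features_fraction,
            random_state=seed,
            n_jobs=1,
        )
    return RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_features=config.max_features_fraction,
        random_state=seed,
        n_jobs=1,
    )


def _score(metric: str, y_true, y_pred, y_score) -> float:
    if metric == "r2":
        return r2_score(y_true, y_pred)
    if metric == "rmse":
        return float(np.sqrt(mean_squared_error(y_true, y_pred)))
    if metric == "pearson_r2":
        if np.std(y_pred) == 0 or np.std(y_true) == 0:
            return 0.0
        r = np.corrcoef(np.asarray(y_true, float), np.asarray(y_pred, float))[0, 1]
        return float(r * r) if np.isfinite(r) else 0.0
    if metric == "balanced_accuracy":
        return balanced_accuracy_score(y_true, y_pred)
    if metric == "roc_auc":
        return roc_auc_score(y_true, y_score)
    raise ValueError(f"unknown metric {metric!r}")


def repeated_cv(
    features: Union[FeatureMatrix, np.ndarray],
    targets: Sequence[float],
    config: BenchmarkConfig,
    model: str = "random_forest",
    representation: str = "features",
) -> CVReport:
    """Run the repeated k-fold protocol and collect per-fold metric values.

    Each repeat ``r`` draws a fresh fold partition seeded by
    ``random_seed + r`` (stratified for classification); each fold fits the
    model on the training rows (forest seed ``random_seed + 1000 r + fold``)
    and scores the held-out rows.  The report is bit-reproducible for a
    fixed configuration.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(targets)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and targets are misaligned")
    if X.shape[0] < config.n_folds:
        raise ValueError(f"need at least {config.n_folds} rows for {config.n_folds}-fold CV")
    if config.task == "classification" and np.unique(y).size != 2:
        raise ValueError("classification targets must be binary")

    results = {m: np.empty((config.n_repeats, config.n_folds)) for m in config.metrics}
    for r in range(config.n_repeats):
        if config.task == "classification":
            splitter = StratifiedKFold(
                n_splits=config.n_folds, shuffle=True, random_state=config.random_seed + r
            )
            splits = splitter.split(X, y)
        else:
            splitter = KFold(
                n_splits=config.n_folds, shuffle=True, random_state=config.random_seed + r
            )
            splits = splitter.split(X)
        for fold, (train, test) in enumerate(splits):
            estimator = _make_model(config, model, config.random_seed + 1000 * r + fold)
            estimator.fit(X[train], y[train])
            y_pred = estimator.predict(X[test])
            y_score = None
            if config.task == "classification":
                proba = estimator.predict_proba(X[test])
                y_score = proba[:, list(estimator.classes_).index(sorted(set(y))[1])]
            for metric in config.metrics:
                results[metric][r, fold] = _score(metric, y[test], y_pred, y_score)
    return CVReport(representation=representation, config=config, per_fold=results)


@dataclass
class ComparisonResult:
    """Outcome of comparing one metric between two representations."""

    metric: str
    per_fold_relative: Optional[np.ndarray] = None  # a/b - 1 per paired fold
    n_dropped: int = 0  # pairs dropped for a zero denominator
    u_statistic: Optional[float] = None
    p_value: Optional[float] = None
    alpha: float = 0.05
    significant: Optional[bool] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "metric": self.metric,
                "per_fold_relative": (
                    None if self.per_fold_relative is None else self.per_fold_relative.tolist()
                ),
                "n_dropped": self.n_dropped,
                "u_statistic": self.u_statistic,
                "p_value": self.p_value,
                "alpha": self.alpha,
                "significant": self.significant,
            },
            indent=1,
        )


def _check_paired(report_a: CVReport, report_b: CVReport) -> None:
    ca, cb = report_a.config, report_b.config
    if (ca.n_folds, ca.n_repeats, ca.random_seed) != (cb.n_folds, cb.n_repeats, cb.random_seed):
        raise ValueError("reports have mismatched fold structure and cannot be paired")


def relative_metric(report_a: CVReport, report_b: CVReport, metric: str) -> ComparisonResult:
    """Per-fold relative metric: value_a / value_b - 1, paired by (repeat, fold).

    Requires both reports to share the fold structure (same seed, folds and
    repeats).  A paired fold with a zero denominator is dropped and counted.
    """
    _check_paired(report_a, report_b)
    a = report_a.values(metric)
    b = report_b.values(metric)
    nonzero = b != 0
    return ComparisonResult(
        metric=metric,
        per_fold_relative=a[nonzero] / b[nonzero] - 1.0,
        n_dropped=int((~nonzero).sum()),
    )


def compare_mannwhitney(
    report_a: CVReport, report_b: CVReport, metric: str, alpha: float = 0.05
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test on the pooled per-fold metric values.

    Uses the exact null distribution for small tie-free samples, and the
    normal approximation with tie correction otherwise.  Two identical
    all-constant samples short-circuit to p = 1.
    """
    a = report_a.values(metric)
    b = report_b.values(metric)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per side")
    if np.unique(np.concatenate([a, b])).size == 1:
        u, p = a.size * b.size / 2.0, 1.0
    else:
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "asymptotic" if (has_ties or max(a.size, b.size) > 25) else "exact"
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        metric=metric,
        u_statistic=float(u),
        p_value=float(p),
        alpha=alpha,
        significant=bool(p < alpha),
    )


def plot_metric_bars(
    reports: Sequence[CVReport], metric: str, path: Union[str, Path]
) -> None:
    """Bar chart of mean metric per representation with 95% CI whiskers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [r.representation for r in reports]
    means, errs = [], []
    for report in reports:
        s = report.summary()[metric]
        means.append(s["mean"])
        errs.append(s["mean"] - s["ci95_low"])
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    ax.bar(labels, means, yerr=errs, capsize=4, color="#4878d0", ecolor="black")
    ax.set_ylabel(metric)
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
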