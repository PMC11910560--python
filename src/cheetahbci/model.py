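"""Hybrid FFNN + cheetah-optimizer classifier, statsmodels-style.

:class:`FFNNCOAClassifier` is the model object: it holds the feature table,
labels and subject identifiers, and ``fit()`` runs the cheetah optimization
algorithm over the network's flat weight vector (no backpropagation),
minimizing mean cross-entropy on the training split.  The returned
:class:`FFNNCOAResults` carries the fitted weights, the per-iteration
best-fitness history, prediction methods and session scoring.

Features are standardized (z-score per feature) with statistics estimated
on the training data only; the weight search box is +/-1 per dimension in
standardized units (a tight box that doubles as regularization).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ffnn
from .coa import COAConfig, optimize
from .evaluate import EvalReport, score_session
from .synthetic import TASKS

_LOG_CLIP = 1e-12
#: weight search half-width per dimension (standardized inputs); a tight box
#: doubles as regularization against overly sharp decision surfaces
DEFAULT_BOUND = 1.0


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Per-subject stratified holdout: every (subject, task) cell contributes
    trials to both the training and the test split."""

    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


def stratified_subject_split(
    table: pd.DataFrame, plan: SplitPlan = SplitPlan()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a feature table so each (subject_id, label) cell spans both splits."""
    rng = np.random.default_rng(plan.seed)
    test_idx: list[int] = []
    for _, group in table.groupby(["subject_id", "label"], sort=True):
        n = len(group)
        if n < 2:
            raise ValueError("every (subject, task) cell needs >= 2 trials to split")
        n_test = int(round(plan.test_fraction * n))
        n_test = min(max(n_test, 1), n - 1)
        chosen = rng.choice(group.index.to_numpy(), size=n_test, replace=False)
        test_idx.extend(chosen.tolist())
    test_mask = table.index.isin(test_idx)
    return table.loc[~test_mask], table.loc[test_mask]


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def cross_entropy_fitness(
    theta: np.ndarray, x: np.ndarray, y: np.ndarray, spec: ffnn.NetworkSpec
) -> float:
    """Mean cross-entropy of forward() scores against integer labels."""
    if len(x) == 0:
        raise ValueError("empty training set")
    probs = ffnn.forward(theta, x, spec)
    p_true = np.clip(probs[np.arange(len(y)), y], _LOG_CLIP, 1.0)
    return float(-np.mean(np.log(p_true)))


def misclassification_fitness(
    theta: np.ndarray, x: np.ndarray, y: np.ndarray, spec: ffnn.NetworkSpec
) -> float:
    """Fraction of training trials classified incorrectly."""
    if len(x) == 0:
        raise ValueError("empty training set")
    return float(np.mean(ffnn.predict(theta, x, spec) != y))


_OBJECTIVES = {
    "cross_entropy": cross_entropy_fitness,
    "misclassification": misclassification_fitness,
}


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class FFNNCOAClassifier:
    """Four-state motor-imagery classifier trained by a cheetah optimizer.

    Parameters
    ----------
    features : (n x 22) array of trial feature vectors.
    labels : length-n task labels (strings from the four-task vocabulary).
    subjects : optional subject id per trial (enables subject-wise scoring).
    spec : network architecture; input width must match the feature count.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        subjects: np.ndarray | None = None,
        modes: np.ndarray | None = None,
        spec: ffnn.NetworkSpec | None = None,
        classes: tuple[str, ...] = TASKS,
    ) -> None:
        self.exog = np.asarray(features, dtype=float)
        if self.exog.ndim != 2:
            raise ValueError("features must be a 2-D (trials x features) array")
        self.classes = tuple(classes)
        labels = np.asarray(labels)
        unknown = set(labels) - set(self.classes)
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}; classes are {self.classes}")
        self.endog = np.array([self.classes.index(l) for l in labels])
        counts = np.bincount(self.endog, minlength=len(self.classes))
        if (counts < 2).any():
            raise ValueError("need at least 2 examples of every class to train")
        self.subjects = (
            np.asarray(subjects) if subjects is not None else np.array(["S01"] * len(labels))
        )
        self.modes = np.asarray(modes) if modes is not None else np.array(["offline"] * len(labels))
        self.spec = spec or ffnn.NetworkSpec(n_in=self.exog.shape[1])
        if self.spec.n_in != self.exog.shape[1]:
            raise ValueError(
                f"network expects {self.spec.n_in} inputs, features have {self.exog.shape[1]}"
            )

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        feature_cols: list[str] | None = None,
        label_col: str = "label",
        subject_col: str = "subject_id",
        mode_col: str = "mode",
        spec: ffnn.NetworkSpec | None = None,
    ) -> "FFNNCOAClassifier":
        """Build the model from a feature table (columns f1..f22 by default)."""
        if feature_cols is None:
            feature_cols = [c for c in table.columns if c.startswith("f") and c[1:].isdigit()]
            feature_cols.sort(key=lambda c: int(c[1:]))
        return cls(
            features=table[feature_cols].to_numpy(),
            labels=table[label_col].to_numpy(),
            subjects=table[subject_col].to_numpy() if subject_col in table else None,
            modes=table[mode_col].to_numpy() if mode_col in table else None,
            spec=spec,
        )

    def fit(
        self,
        coa_config: COAConfig | None = None,
        seed: int | None = None,
        objective: str = "cross_entropy",
        bound: float = DEFAULT_BOUND,
        verbose: bool = False,
    ) -> "FFNNCOAResults":
        """Search the weight space with the cheetah optimizer.

        Returns a results object holding the best weight vector found, the
        optimizer's best-fitness history and the standardization statistics.
        """
        if objective not in _OBJECTIVES:
            raise ValueError(f"objective must be one of {sorted(_OBJECTIVES)}")
        mu = self.exog.mean(axis=0)
        sd = self.exog.std(axis=0)
        sd[sd == 0] = 1.0
        x = (self.exog - mu) / sd
        y = self.endog

        fitness = _OBJECTIVES[objective]
        obj = lambda theta: fitness(theta, x, y, self.spec)

        cfg = coa_config or COAConfig(
            n=30, D=self.spec.n_params, lower=-bound, upper=bound, T=1000, seed=seed
        )
        if cfg.D != self.spec.n_params:
            raise ValueError(f"COA dimension {cfg.D} != network parameter count {self.spec.n_params}")
        callback = None
        if verbose:
            callback = lambda s: print(f"  iter {s.t + 1:4d}  best fitness {s.best_fitness:.6f}")
        rng = np.random.default_rng(seed if seed is not None else cfg.seed)
        theta, best_f, history = optimize(obj, cfg, rng=rng, callback=callback)
        return FFNNCOAResults(
            model=self, params=theta, best_fitness=best_f, history=history,
            mean=mu, scale=sd, objective=objective, coa_config=cfg,
        )


class FFNNCOAResults:
    """Fitted FFNNCOA classifier: weights, training history, scoring."""

    def __init__(
        self,
        model: FFNNCOAClassifier,
        params: np.ndarray,
        best_fitness: float,
        history: np.ndarray,
        mean: np.ndarray,
        scale: np.ndarray,
        objective: str,
        coa_config: COAConfig | None = None,
    ) -> None:
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.best_fitness = float(best_fitness)
        self.history = np.asarray(history, dtype=float)
        self.mean = np.asarray(mean, dtype=float)
        self.scale = np.asarray(scale, dtype=float)
        self.objective = objective
        self.coa_config = coa_config

    # -- prediction ---------------------------------------------------------
    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(x, dtype=float)) - self.mean) / self.scale

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return ffnn.forward(self.params, self._standardize(features), self.model.spec)

    def predict(self, features: np.ndarray) -> np.ndarray:
        idx = ffnn.predict(self.params, self._standardize(features), self.model.spec)
        return np.asarray(self.model.classes)[idx]

    # -- scoring ------------------------------------------------------------
    def evaluate(
        self,
        features: np.ndarray | None = None,
        labels: np.ndarray | None = None,
        subjects: np.ndarray | None = None,
        mode: str = "offline",
    ) -> EvalReport:
        """Score a session (defaults to the training data)."""
        if features is None:
            features, labels = self.model.exog, self.model.endog
            labels = np.asarray(self.model.classes)[labels]
            subjects = self.model.subjects
        if labels is None:
            raise ValueError("labels required when features are given")
        preds = self.predict(features)
        manifest = pd.DataFrame(
            {
                "subject_id": subjects if subjects is not None else "S01",
                "label": np.asarray(labels),
                "prediction": preds,
            }
        )
        return score_session(manifest, mode=mode)

    def evaluate_table(self, table: pd.DataFrame, mode: str | None = None) -> EvalReport:
        feature_cols = sorted(
            (c for c in table.columns if c.startswith("f") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        if mode is None:
            mode = table["mode"].iloc[0] if "mode" in table else "offline"
        return self.evaluate(
            table[feature_cols].to_numpy(),
            table["label"].to_numpy(),
            table["subject_id"].to_numpy() if "subject_id" in table else None,
            mode=mode,
        )

    def training_accuracy(self) -> float:
        preds = self.predict(self.model.exog)
        truth = np.asarray(self.model.classes)[self.model.endog]
        return 100.0 * float(np.mean(preds == truth))

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "FFNN + cheetah-optimizer classification results",
            "=" * 52,
            f"Network                : {spec.n_in}-{spec.n_hidden}-{spec.n_out} "
            f"({spec.hidden_activation}/{spec.output_mapping})",
            f"Parameters searched    : {spec.n_params}",
            f"Objective              : {self.objective}",
            f"Final training fitness : {self.best_fitness:.6f}",
            f"Optimizer iterations   : {len(self.history)}",
            f"Training trials        : {len(self.model.endog)}",
            f"Training accuracy      : {self.training_accuracy():.2f} %",
        ]
        return "\n".join(lines)

    # -- persistence (plain-text JSON) --------------------------------------
    def save(self, path: str | Path) -> None:
        spec = self.model.spec
        payload = {
            "format": "cheetahbci-model/1",
            "network": {
                "n_in": spec.n_in, "n_hidden": spec.n_hidden, "n_out": spec.n_out,
                "hidden_activation": spec.hidden_activation,
                "output_mapping": spec.output_mapping,
            },
            "classes": list(self.model.classes),
            "objective": self.objective,
            "best_fitness": self.best_fitness,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "params": self.params.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FFNNCOAResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "cheetahbci-model/1":
            raise ValueError("unrecognized model file format")
        spec = ffnn.NetworkSpec(**payload["network"])
        classes = tuple(payload["classes"])
        # dummy model shell: prediction needs only spec/classes/scaling
        shell = FFNNCOAClassifier.__new__(FFNNCOAClassifier)
        shell.spec = spec
        shell.classes = classes
        shell.exog = np.zeros((0, spec.n_in))
        shell.endog = np.zeros(0, dtype=int)
        shell.subjects = np.array([])
        shell.modes = np.array([])
        return cls(
            model=shell,
            params=np.array(payload["params"]),
            best_fitness=payload["best_fitness"],
            history=np.array([]),
            mean=np.array(payload["mean"]),
            scale=np.array(payload["scale"]),
            objective=payload["objective"],
        )


def train_ffnncoa(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ffnn.NetworkSpec | None = None,
    coa_config: COAConfig | None = None,
    seed: int | None = None,
    objective: str = "cross_entropy",
) -> FFNNCOAResults:
    """Functional wrapper: build the model and fit it in one call."""
    model = FFNNCOAClassifier(features, labels, spec=spec)
    return model.fit(coa_config=coa_config, seed=seed, objective=objective)
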