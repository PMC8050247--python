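"""Class-balanced, sparsity-regularized phenotype classification.

Repository-scale metabolomics cohorts are heavily imbalanced (a disease
cohort is typically dwarfed by healthy controls), so the plain logistic
loss would be dominated by the majority class.  Every training sample is
therefore weighted by ``1 / b_t``, where ``b_t`` is the number of training
samples sharing its label: each phenotype then contributes exactly one unit
of loss mass, regardless of its prevalence.

With an L1 penalty the fitted coefficient vectors are sparse, which makes
the model interpretable: the few features with large coefficients are the
candidate biomarkers of each phenotype.  Interpretability is what lets a
user notice that a "biomarker" is actually an internal standard spiked in
under one acquisition protocol (a batch artifact); such features can be
blocklisted and the model retrained on the reduced feature set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .io import FeatureMatrix, PhenotypeTable, ValidationError, _expand_to

# the balanced loss has total mass <= 2 (one unit per class side), so useful
# penalty strengths sit well below 1
_DEFAULT_STRENGTH_GRID = tuple(float(s) for s in np.geomspace(1e-4, 1.0, 9))


@dataclass
class ClassBalanceWeights:
    """Per-sample weights w_t = 1 / b_t; each class's weights sum to 1."""

    weights: np.ndarray
    class_counts: dict[str, int]


def compute_class_weights(labels) -> ClassBalanceWeights:
    """Inverse-multiplicity weights from a label vector."""
    labels = np.asarray(labels, dtype=str)
    if labels.size == 0:
        raise ValueError("empty label vector")
    uniq, counts = np.unique(labels, return_counts=True)
    count_of = dict(zip(uniq.tolist(), counts.tolist()))
    w = np.array([1.0 / count_of[l] for l in labels])
    return ClassBalanceWeights(weights=w, class_counts=count_of)


def accuracy(predicted, truth) -> float:
    """Fraction of exactly matching labels."""
    predicted = np.asarray(predicted, dtype=str)
    truth = np.asarray(truth, dtype=str)
    if predicted.size != truth.size:
        raise ValueError(
            f"length mismatch: {predicted.size} predictions, {truth.size} truths"
        )
    if predicted.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(predicted == truth))


@dataclass
class BiomarkerReport:
    """Ranked per-class coefficients; the interpretability surface.

    ``table`` columns: feature_id, class_label, coefficient, rank (1-based,
    per class, by descending |coefficient| with ties broken by feature ID),
    uninformative (zero coefficient included only to pad to k), and
    suspected_artifact (feature is a known internal standard).
    """

    table: pd.DataFrame
    k: int

    def top_features(self, class_label: str | None = None) -> list[str]:
        t = self.table
        if class_label is not None:
            t = t[t["class_label"] == class_label]
        return list(dict.fromkeys(t["feature_id"]))

    def to_dict(self) -> dict:
        return {
            "table": [
                {
                    "feature_id": str(r.feature_id),
                    "class_label": str(r.class_label),
                    "coefficient": float(r.coefficient),
                    "rank": int(r.rank),
                    "uninformative": bool(r.uninformative),
                    "suspected_artifact": bool(r.suspected_artifact),
                }
                for r in self.table.itertuples()
            ],
            "k": int(self.k),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BiomarkerReport":
        rows = []
        for r in payload.get("table", []):
            rows.append(
                {
                    "feature_id": str(r["feature_id"]),
                    "class_label": str(r["class_label"]),
                    "coefficient": float(r["coefficient"]),
                    "rank": int(r["rank"]),
                    "uninformative": str(r["uninformative"]) in ("True", "true", "1"),
                    "suspected_artifact": str(r["suspected_artifact"])
                    in ("True", "true", "1"),
                }
            )
        cols = [
            "feature_id", "class_label", "coefficient", "rank",
            "uninformative", "suspected_artifact",
        ]
        return cls(table=pd.DataFrame(rows, columns=cols), k=int(payload["k"]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BiomarkerReport):
            return NotImplemented
        return self.k == other.k and self.table.equals(other.table)


class PhenotypeClassifier:
    """Model object: balanced penalized logistic regression on binary features.

    Parameters
    ----------
    features
        Binary features × samples matrix.
    phenotypes
        Sample metadata; its sample IDs must match the matrix columns (order
        is taken from the metadata).
    penalty
        ``"l1"`` (sparse, interpretable — the default) or ``"l2"``.
    strength
        Penalty weight in the objective
        ``sum_t w_t L_t + strength * P(beta)`` with ``P`` the L1 norm or
        half the squared L2 norm; ``"auto"`` selects it by stratified
        cross-validated balanced accuracy over a geometric grid.
    scheme
        ``"ovr"`` fits one balanced binary problem per class (keeps the
        one-coefficient-vector-per-class reading used for biomarker
        inspection); ``"multinomial"`` fits a softmax model instead.
    removed_features
        Feature IDs excluded before training (e.g. known internal standards).
    """

    def __init__(
        self,
        features: FeatureMatrix,
        phenotypes: PhenotypeTable,
        penalty: str = "l1",
        strength: float | str = "auto",
        scheme: str = "ovr",
        removed_features: tuple[str, ...] = (),
        tol: float = 1e-8,
        max_iter: int = 10000,
        seed: int = 0,
    ):
        if penalty not in ("l1", "l2"):
            raise ValueError(f"penalty must be 'l1' or 'l2', got {penalty!r}")
        if scheme not in ("ovr", "multinomial"):
            raise ValueError(f"unknown scheme {scheme!r}")
        if set(features.sample_ids) != set(phenotypes.sample_ids):
            raise ValidationError("feature matrix and phenotype table sample IDs differ")
        features = features.reorder_samples(phenotypes.sample_ids)
        removed = tuple(sorted(set(removed_features)))
        if removed:
            features = features.drop_features(removed)
        if features.n_features == 0:
            raise ValueError("no features left to train on")
        classes = phenotypes.classes
        if len(classes) < 2:
            raise ValueError(f"need >= 2 classes, got {classes}")

        self.features = features
        self.phenotypes = phenotypes
        self.penalty = penalty
        self.strength = strength
        self.scheme = scheme
        self.removed_features = removed
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed
        self.class_labels = classes

    @classmethod
    def from_files(
        cls, features_path, meta_path, dialect: str = "dense", **kwargs
    ) -> "PhenotypeClassifier":
        from .io import read_feature_table, read_phenotype_table

        return cls(
            read_feature_table(features_path, dialect=dialect),
            read_phenotype_table(meta_path),
            **kwargs,
        )

    # -- fitting ---------------------------------------------------------------

    def fit(self) -> "PhenotypeResults":
        strength = self.strength
        if strength == "auto":
            strength = self._select_strength()
        strength = float(strength)
        if strength <= 0:
            raise ValueError("penalty strength must be positive")

        Xd = self.features.values.T.astype(float)  # samples x features
        labels = self.phenotypes.labels
        w = compute_class_weights(labels).weights

        coefs = np.zeros((len(self.class_labels), Xd.shape[1]))
        intercepts = np.zeros(len(self.class_labels))
        if self.scheme == "ovr":
            for i, cls_label in enumerate(self.class_labels):
                est = self._binary_estimator(strength)
                est.fit(Xd, (labels == cls_label).astype(int), sample_weight=w)
                # liblinear orders classes [0, 1]; coef_ is for class 1
                coefs[i] = est.coef_[0]
                intercepts[i] = est.intercept_[0]
        else:
            est = LogisticRegression(
                l1_ratio=1.0 if self.penalty == "l1" else 0.0,
                C=1.0 / strength, solver="saga",
                tol=self.tol, max_iter=self.max_iter, random_state=self.seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Xd, labels, sample_weight=w)
            order = [list(est.classes_).index(c) for c in self.class_labels]
            coefs = est.coef_[order]
            intercepts = est.intercept_[order]

        return PhenotypeResults(
            model=self,
            coefficients=pd.DataFrame(
                coefs, index=self.class_labels, columns=self.features.feature_ids
            ),
            intercepts=pd.Series(intercepts, index=self.class_labels),
            strength_used=strength,
        )

    def _binary_estimator(self, strength: float) -> LogisticRegression:
        # liblinear solves min P(beta) + C * sum_t s_t * loss_t; C = 1/strength
        # maps it onto sum_t w_t loss_t + strength * P(beta).  intercept_scaling
        # damps liblinear's penalty on the (augmented) intercept.
        return LogisticRegression(
            l1_ratio=1.0 if self.penalty == "l1" else 0.0,
            C=1.0 / strength, solver="liblinear",
            tol=self.tol, max_iter=self.max_iter, intercept_scaling=10.0,
            random_state=self.seed,
        )

    def _select_strength(self, grid=_DEFAULT_STRENGTH_GRID, n_folds: int = 3) -> float:
        """Stratified CV over a geometric strength grid, scored by balanced accuracy.

        Balanced accuracy keeps the selection consistent with the balanced
        training loss.  Ties prefer the larger strength (the sparser, more
        interpretable model).
        """
        labels = self.phenotypes.labels
        min_class = min(compute_class_weights(labels).class_counts.values())
        n_folds = max(2, min(n_folds, min_class))
        sample_ids = np.asarray(self.phenotypes.sample_ids)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=self.seed)
        folds = [
            (tr, te)
            for tr, te in skf.split(sample_ids, labels)
            if len(set(labels[tr])) >= 2
        ]
        best_score, best_s = -np.inf, None
        for s in grid:
            scores = []
            for tr, te in folds:
                sub_meta = PhenotypeTable(
                    self.phenotypes.samples.iloc[tr], self.phenotypes.standards
                )
                sub_X = self.features.reorder_samples(list(sample_ids[tr]))
                res = PhenotypeClassifier(
                    sub_X, sub_meta, penalty=self.penalty, strength=s,
                    scheme=self.scheme, tol=self.tol, max_iter=self.max_iter,
                    seed=self.seed,
                ).fit()
                pred = res.predict(self.features.reorder_samples(list(sample_ids[te])))
                scores.append(balanced_accuracy_score(labels[te], pred))
            if scores and np.mean(scores) >= best_score:
                best_score, best_s = float(np.mean(scores)), float(s)
        return 1.0 if best_s is None else best_s


@dataclass
class PhenotypeResults:
    """Fitted balanced logistic model: coefficients, intercepts, diagnostics."""

    model: PhenotypeClassifier
    coefficients: pd.DataFrame  # classes x features
    intercepts: pd.Series
    strength_used: float
    _cached_report: BiomarkerReport | None = field(default=None, repr=False)

    @property
    def class_labels(self) -> list[str]:
        return list(self.coefficients.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.coefficients.columns)

    @property
    def removed_features(self) -> set[str]:
        return set(self.model.removed_features)

    def sparsity(self) -> float:
        """Fraction of coefficients that are exactly zero."""
        return float((self.coefficients.to_numpy() == 0).mean())

    # -- prediction ------------------------------------------------------------

    def decision_scores(self, features: FeatureMatrix) -> pd.DataFrame:
        """Per-class linear scores for each sample (samples × classes)."""
        aligned = _expand_to(features, self.feature_ids)
        Xd = aligned.values.T.astype(float)
        scores = Xd @ self.coefficients.to_numpy().T + self.intercepts.to_numpy()
        return pd.DataFrame(scores, index=features.sample_ids, columns=self.class_labels)

    def predict(self, features: FeatureMatrix) -> np.ndarray:
        """Label = argmax class score; ties go to the first label in vocabulary order."""
        scores = self.decision_scores(features).to_numpy()
        idx = np.argmax(scores, axis=1)  # first max wins; labels are sorted
        return np.asarray([self.class_labels[i] for i in idx], dtype=object)

    # -- interpretation --------------------------------------------------------

    def rank_biomarkers(
        self, k: int, suspected: set[str] | None = None
    ) -> BiomarkerReport:
        """Top-k features per class by |coefficient| (ties by feature ID).

        Zero-coefficient features are only used to pad up to ``k`` and are
        flagged ``uninformative``.  ``suspected`` defaults to the phenotype
        table's known internal-standard feature IDs.
        """
        if k <= 0:
            raise ValueError("k must be positive")
        if suspected is None:
            suspected = self.model.phenotypes.standard_feature_ids()
        rows = []
        for cls_label in self.class_labels:
            coef = self.coefficients.loc[cls_label]
            order = sorted(
                self.feature_ids, key=lambda f: (-abs(float(coef[f])), f)
            )
            for rank, f in enumerate(order[:k], start=1):
                c = float(coef[f])
                rows.append(
                    {
                        "feature_id": f,
                        "class_label": cls_label,
                        "coefficient": c,
                        "rank": rank,
                        "uninformative": c == 0.0,
                        "suspected_artifact": f in suspected,
                    }
                )
        cols = [
            "feature_id", "class_label", "coefficient", "rank",
            "uninformative", "suspected_artifact",
        ]
        return BiomarkerReport(table=pd.DataFrame(rows, columns=cols), k=k)

    def remove_and_retrain(self, blocklist: set[str]) -> "PhenotypeResults":
        """Drop blocklisted features (e.g. internal standards) and refit.

        Unknown IDs produce a warning, not an error; the retrained model uses
        the identical penalty, strength, tolerance and seed.
        """
        known = set(self.feature_ids) | self.removed_features
        unknown = set(blocklist) - known
        if unknown:
            warnings.warn(
                f"blocklist IDs not in the feature axis: {sorted(unknown)}",
                stacklevel=2,
            )
        removed = tuple(sorted(self.removed_features | set(blocklist)))
        m = self.model
        original = m.features  # already has m.removed_features dropped
        retrained = PhenotypeClassifier(
            original, m.phenotypes, penalty=m.penalty, strength=self.strength_used,
            scheme=m.scheme, removed_features=removed, tol=m.tol,
            max_iter=m.max_iter, seed=m.seed,
        )
        return retrained.fit()

    # -- reporting -------------------------------------------------------------

    def summary(self) -> str:
        n_nonzero = int((self.coefficients.to_numpy() != 0).sum())
        lines = [
            "Balanced penalized logistic classifier",
            f"  classes: {len(self.class_labels)}   features: {len(self.feature_ids)}"
            f"   removed: {len(self.removed_features)}",
            f"  penalty: {self.model.penalty}   strength: {self.strength_used:.6g}"
            f"   scheme: {self.model.scheme}",
            f"  non-zero coefficients: {n_nonzero}"
            f"   sparsity: {self.sparsity():.3f}",
            "  class                intercept  top feature (|coef|)",
        ]
        for cls_label in self.class_labels:
            coef = self.coefficients.loc[cls_label]
            top = sorted(self.feature_ids, key=lambda f: (-abs(float(coef[f])), f))[0]
            lines.append(
                f"  {cls_label:<20} {float(self.intercepts[cls_label]):+9.4f}"
                f"  {top} ({abs(float(coef[top])):.4f})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "class_labels": self.class_labels,
            "feature_ids": self.feature_ids,
            "coefficients": self.coefficients.to_numpy().tolist(),
            "intercepts": self.intercepts.to_numpy().tolist(),
            "penalty": self.model.penalty,
            "strength": self.strength_used,
            "scheme": self.model.scheme,
            "removed_features": sorted(self.removed_features),
        }


def balanced_objective(
    coefficients: np.ndarray,
    intercepts: np.ndarray,
    X: np.ndarray,
    labels: np.ndarray,
    class_labels: list[str],
    penalty: str = "l1",
    strength: float = 0.0,
) -> float:
    """Value of the class-balanced one-vs-rest logistic objective.

    ``sum_c sum_t w_t * logloss(y_t==c, score_c(x_t)) + strength * P(beta)``
    with ``w_t = 1 / b_t``.  Because the weights renormalize, duplicating all
    samples of any class leaves the value unchanged — the property that makes
    the balanced loss immune to cohort imbalance.
    """
    labels = np.asarray(labels, dtype=str)
    w = compute_class_weights(labels).weights
    total = 0.0
    for i, cls_label in enumerate(class_labels):
        y = (labels == cls_label).astype(float)
        z = X @ coefficients[i] + intercepts[i]
        # stable logloss: log(1 + exp(-s*z)), s = +-1
        s = 2.0 * y - 1.0
        total += float(w @ np.logaddexp(0.0, -s * z))
    beta = np.asarray(coefficients)
    if penalty == "l1":
        total += strength * float(np.abs(beta).sum())
    elif penalty == "l2":
        total += strength * 0.5 * float((beta**2).sum())
    else:
        raise ValueError(f"unknown penalty {penalty!r}")
    return total


def train(
    X: FeatureMatrix,
    y: PhenotypeTable,
    penalty: str = "l1",
    strength: float | str = "auto",
    **kwargs,
) -> PhenotypeResults:
    """Functional spelling of ``PhenotypeClassifier(...).fit()``."""
    return PhenotypeClassifier(X, y, penalty=penalty, strength=strength, **kwargs).fit()


def predict(results: PhenotypeResults, X: FeatureMatrix) -> np.ndarray:
    return results.predict(X)


def rank_biomarkers(results: PhenotypeResults, k: int) -> BiomarkerReport:
    return results.rank_biomarkers(k)


def remove_and_retrain(
    results: PhenotypeResults,
    X: FeatureMatrix,
    y: PhenotypeTable,
    blocklist: set[str],
) -> PhenotypeResults:
    """Retrain on ``X``/``y`` with ``blocklist`` excluded (plus prior removals)."""
    unknown = set(blocklist) - set(X.feature_ids)
    if unknown:
        warnings.warn(
            f"blocklist IDs not in the feature axis: {sorted(unknown)}", stacklevel=2
        )
    removed = tuple(sorted(results.removed_features | set(blocklist)))
    if len(removed) >= X.n_features:
        raise ValueError("blocklist would remove every feature")
    m = results.model
    return PhenotypeClassifier(
        X, y, penalty=m.penalty, strength=results.strength_used, scheme=m.scheme,
        removed_features=removed, tol=m.tol, max_iter=m.max_iter, seed=m.seed,
    ).fit()
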