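"""Fuzzy ARTMAP (FAM): an incremental, supervised adaptive-resonance
classifier.

A FAM network is a set of category weight vectors ``W_j`` in ``[0,1]^(2d)``
each mapped to one class label.  Inputs ``a`` in ``[0,1]^d`` are
complement-coded to ``AI = (a, 1-a)`` (constant L1 norm ``d``).  During
training a winner category is chosen by the choice function

    T_j = |AI ^ W_j| / (alpha + |W_j|),

where ``^`` is the componentwise minimum and ``|.|`` the L1 norm, and must
pass the vigilance test ``|AI ^ W_j| / |AI| >= rho``.  If the winner's label
disagrees with the supervised label, vigilance is temporarily raised just
above the winner's match ratio (match tracking) and the search resumes; if
no category resonates, a new one is created with ``W = AI``.  The resonating
winner learns by the convex update ``W <- beta (AI ^ W) + (1 - beta) W``.

Category structure depends on presentation order and on class overlap — the
category-proliferation problem that the differential-evolution pruning in
:mod:`avnlbp.defam` addresses.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted
from sklearn.utils.multiclass import unique_labels

__all__ = [
    "complement_code",
    "choice_values",
    "vigilance_pass",
    "FuzzyARTMAP",
]

# rho = 1.0 would demand exact containment up to float equality; cap just
# below 1 so resubstitution of a learned pattern still resonates.
_RHO_CAP = 1.0 - 1e-9


def complement_code(a) -> np.ndarray:
    """Complement coding ``a -> (a, 1-a)``; output has L1 norm exactly d."""
    arr = np.asarray(a, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D feature vector, got shape {arr.shape}")
    bad = np.flatnonzero((arr < 0) | (arr > 1) | ~np.isfinite(arr))
    if bad.size:
        raise ValueError(
            f"feature component {bad[0]} = {arr[bad[0]]} outside [0, 1]; "
            "scale features to the unit interval first"
        )
    return np.concatenate([arr, 1.0 - arr])


def choice_values(weights: np.ndarray, coded: np.ndarray, alpha: float) -> np.ndarray:
    """Choice function ``T_j = |AI ^ W_j| / (alpha + |W_j|)`` for all
    categories at once; ``weights`` has shape (n_categories, 2d)."""
    weights = np.atleast_2d(weights)
    if weights.shape[1] != coded.size:
        raise ValueError(
            f"dimension mismatch: weights have {weights.shape[1]} components, "
            f"coded input has {coded.size}"
        )
    overlap = np.minimum(weights, coded).sum(axis=1)
    return overlap / (alpha + weights.sum(axis=1))


def vigilance_pass(coded: np.ndarray, weight: np.ndarray, rho: float) -> bool:
    """Vigilance test: ``|AI ^ W| / |AI| >= rho``."""
    norm = coded.sum()
    if norm == 0:
        raise ValueError("coded input has zero L1 norm; vigilance undefined")
    return bool(np.minimum(coded, weight).sum() / norm >= rho)


class FuzzyARTMAP(ClassifierMixin, BaseEstimator):
    """Fuzzy ARTMAP classifier with match tracking.

    Parameters
    ----------
    rho : float, default=1.0
        Baseline vigilance in [0, 1].  Higher values force tighter (more
        numerous) categories; 1.0 is capped internally at ``1 - 1e-9``.
    alpha : float, default=0.001
        Choice parameter (> 0); small values reduce recoding.
    beta : float, default=0.8
        Learning rate in [0, 1]; 1.0 is fast learning (winner jumps to
        ``AI ^ W``).
    epsilon : float, default=0.001
        Match-tracking increment added to the mismatched winner's match
        ratio.
    epochs : int, default=5
        Passes over the training set.
    shuffle : bool, default=False
        Shuffle the presentation order each epoch (drawn from
        ``random_state``).  Category structure is order-sensitive, so two
        different orders may yield different networks.
    random_state : int or Generator, optional
        Presentation-order seed; only used when ``shuffle=True``.
    additive_update : bool, default=False
        Use the additive update ``W + beta (AI ^ W)`` instead of the
        standard convex update (audit flag; the additive form lets weights
        leave [0, 1]).

    Attributes
    ----------
    weights_ : ndarray of shape (n_categories, 2 * n_features_in_)
        Category weight vectors.
    category_classes_ : ndarray of shape (n_categories,)
        Index into ``classes_`` of each category's mapped class.
    classes_ : ndarray
        Sorted unique class labels seen in ``y``.
    n_categories_ : int

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[0.1, 0.1], [0.9, 0.9]])
    >>> clf = FuzzyARTMAP(rho=0.5).fit(X, [0, 1])
    >>> clf.predict([[0.12, 0.08]])
    array([0])
    """

    def __init__(self, rho: float = 1.0, alpha: float = 0.001, beta: float = 0.8,
                 epsilon: float = 0.001, epochs: int = 5, shuffle: bool = False,
                 random_state=None, additive_update: bool = False):
        self.rho = rho
        self.alpha = alpha
        self.beta = beta
        self.epsilon = epsilon
        self.epochs = epochs
        self.shuffle = shuffle
        self.random_state = random_state
        self.additive_update = additive_update

    # -- construction ------------------------------------------------------

    @classmethod
    def from_arrays(cls, weights: np.ndarray, category_classes: np.ndarray,
                    classes: np.ndarray, **params) -> "FuzzyARTMAP":
        """Build a fitted network directly from weight/label arrays (used by
        the evolutionary decoder and by JSON deserialization)."""
        net = cls(**params)
        weights = np.asarray(weights, dtype=np.float64)
        if weights.ndim == 1:
            weights = weights.reshape(1, -1)
        net.weights_ = weights
        net.category_classes_ = np.asarray(category_classes, dtype=np.intp)
        net.classes_ = np.asarray(classes)
        net.n_features_in_ = net.weights_.shape[1] // 2 if weights.size else 0
        return net

    # -- training ----------------------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError(f"expected 2-D feature matrix, got shape {X.shape}")
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature value")
        if X.min() < 0 or X.max() > 1:
            raise ValueError("features must be scaled to [0, 1]")
        return X

    def fit(self, X, y):
        """Train on features in [0, 1]^d with categorical labels."""
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = unique_labels(y)
        class_index = {c: k for k, c in enumerate(self.classes_)}
        y_idx = np.array([class_index[v] for v in y], dtype=np.intp)
        self.n_features_in_ = X.shape[1]

        rho_base = min(self.rho, _RHO_CAP)
        rng = (self.random_state
               if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))

        weights: list[np.ndarray] = []
        cat_class: list[int] = []
        seen: set[int] = set()

        for _ in range(int(self.epochs)):
            order = rng.permutation(len(X)) if self.shuffle else np.arange(len(X))
            for idx in order:
                coded = complement_code(X[idx])
                label = int(y_idx[idx])
                if label not in seen:
                    weights.append(coded.copy())
                    cat_class.append(label)
                    seen.add(label)
                    continue
                self._present(coded, label, weights, cat_class, rho_base)

        self.weights_ = np.vstack(weights)
        self.category_classes_ = np.array(cat_class, dtype=np.intp)
        return self

    def _present(self, coded: np.ndarray, label: int, weights: list[np.ndarray],
                 cat_class: list[int], rho_base: float) -> None:
        """One pattern presentation: ranked search, vigilance, match
        tracking, learn or create."""
        W = np.vstack(weights)
        T = choice_values(W, coded, self.alpha)
        norm = coded.sum()
        rho = rho_base
        # stable ranking: ties go to the lowest category index
        for j in np.argsort(-T, kind="stable"):
            match = np.minimum(coded, W[j]).sum() / norm
            if match < rho:
                continue
            if cat_class[j] == label:
                old = weights[j]
                if self.additive_update:
                    weights[j] = old + self.beta * np.minimum(coded, old)
                else:
                    weights[j] = (self.beta * np.minimum(coded, old)
                                  + (1.0 - self.beta) * old)
                return
            # predictive mismatch: raise vigilance just above this match
            rho = match + self.epsilon
        # search exhausted: commit a new category
        weights.append(coded.copy())
        cat_class.append(label)

    # -- inference ---------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Label of the category with maximal choice value (no vigilance at
        prediction; ties go to the lowest category index)."""
        check_is_fitted(self)
        if len(self.weights_) == 0:
            raise ValueError("network has no categories; cannot predict")
        X = self._validate_X(np.atleast_2d(np.asarray(X, dtype=np.float64)))
        out = np.empty(len(X), dtype=np.intp)
        for i, a in enumerate(X):
            T = choice_values(self.weights_, complement_code(a), self.alpha)
            out[i] = self.category_classes_[int(np.argmax(T))]
        return self.classes_[out]

    @property
    def n_categories_(self) -> int:
        check_is_fitted(self)
        return len(self.weights_)

    def pcc(self, X, y) -> float:
        """Percentage of correct classifications, in [0, 100]."""
        y = np.asarray(y)
        if len(y) == 0:
            raise ValueError("empty evaluation set")
        return 100.0 * float(np.mean(self.predict(X) == y))

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None) -> dict:
        """Serialize the fitted network (weights, labels, params)."""
        check_is_fitted(self)
        payload = {
            "n_features": int(self.n_features_in_),
            "classes": self.classes_.tolist(),
            "category_classes": self.category_classes_.tolist(),
            "weights": self.weights_.tolist(),
            "params": self.get_params(),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh)
        return payload

    @classmethod
    def from_json(cls, source) -> "FuzzyARTMAP":
        """Rebuild a fitted network from :meth:`to_json` output (dict or
        path)."""
        if not isinstance(source, dict):
            with open(source) as fh:
                source = json.load(fh)
        params = {k: v for k, v in source["params"].items()
                  if k != "random_state"}
        return cls.from_arrays(
            np.array(source["weights"], dtype=np.float64).reshape(
                len(source["weights"]), -1),
            source["category_classes"],
            np.array(source["classes"]),
            **params,
        )
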