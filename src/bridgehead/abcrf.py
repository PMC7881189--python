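"""Random-forest ABC: scenario choice and parameter estimation.

Scenario choice trains a classification forest on (summary statistics ->
scenario label); each tree casts one vote for the observed vector.  The
posterior probability of the selected scenario is estimated by a second,
regression forest trained on the out-of-bag correctness indicator of the
classifier, evaluated at the observed vector.  The prior error rate is
the out-of-bag misclassification fraction.

Parameter estimation trains a regression forest on (statistics ->
parameter) and reads the posterior off the forest's weighted empirical
distribution of training responses at the observed point: a training row
receives weight proportional to how often it co-occupies a leaf with the
observed vector (quantile-regression-forest weights).  Posterior median
and 2.5/97.5% quantiles come from that weighted distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .simulate import ReferenceTable
from .sumstats import SummaryVector

__all__ = [
    "ModelChoiceResult",
    "ParamEstimate",
    "choose_model",
    "QuantileRegressionForest",
    "estimate_parameter",
]

DEFAULT_N_TREES = 500


def _observed_row(observed, stat_names: list[str]) -> np.ndarray:
    if isinstance(observed, SummaryVector):
        if list(observed.names) != list(stat_names):
            raise ValueError(
                "observed summary vector is not conformable with the reference "
                "table statistics"
            )
        return observed.values.reshape(1, -1)
    arr = np.asarray(observed, dtype=float).reshape(1, -1)
    if arr.shape[1] != len(stat_names):
        raise ValueError(
            f"observed vector has {arr.shape[1]} statistics, reference table "
            f"has {len(stat_names)}"
        )
    return arr


@dataclass
class ModelChoiceResult:
    """Votes, selected scenario, posterior probability and prior error rate."""

    votes: dict[str, int]
    selected: str
    posterior_probability: float
    prior_error_rate: float
    n_trees: int

    def __post_init__(self) -> None:
        if sum(self.votes.values()) != self.n_trees:
            raise ValueError("votes must sum to the forest size")

    def summary(self) -> str:
        lines = ["scenario choice (random-forest ABC)", "-" * 38]
        for label in sorted(self.votes):
            mark = " <- selected" if label == self.selected else ""
            lines.append(f"  {label:<10} {self.votes[label]:>5} votes{mark}")
        lines.append(f"posterior probability of {self.selected}: "
                     f"{self.posterior_probability:.3f}")
        lines.append(f"prior (out-of-bag) error rate: {self.prior_error_rate:.3f}")
        return "\n".join(lines)


def choose_model(
    ref: ReferenceTable,
    observed,
    n_trees: int = DEFAULT_N_TREES,
    seed: int | None = 0,
    add_lda_axes: bool = False,
) -> ModelChoiceResult:
    """Random-forest scenario choice for one observed summary vector.

    Ties in the vote count are broken toward the lexicographically lowest
    scenario label.  Deterministic per seed.  ``add_lda_axes`` appends the
    linear-discriminant projections of the statistics as extra features
    (common ABC-RF practice; off by default).
    """
    forest = fit_choice_forest(ref, n_trees=n_trees, seed=seed,
                               add_lda_axes=add_lda_axes)
    return classify_observed(forest, ref, observed)


def fit_choice_forest(
    ref: ReferenceTable,
    n_trees: int = DEFAULT_N_TREES,
    seed: int | None = 0,
    add_lda_axes: bool = False,
):
    """Train the classification forest plus the OOB-correctness regressor.

    Returned object is reusable across many observed vectors (the forests
    are ephemeral; the reference table is the reproducibility artifact).
    """
    X = ref.stats_matrix()
    y = ref.scenario_column()
    lda = None
    if add_lda_axes:
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        lda = LinearDiscriminantAnalysis().fit(X, y)
        X = np.hstack([X, lda.transform(X)])
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2:
        raise ValueError("reference table must contain >= 2 scenario labels")
    if counts.min() < 2:
        small = labels[counts.argmin()]
        raise ValueError(f"scenario {small!r} has fewer than 2 reference rows")

    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=None if seed is None else int(seed),
        n_jobs=1,
    )
    clf.fit(X, y)

    oob = clf.oob_decision_function_
    seen = ~np.isnan(oob).any(axis=1)
    oob_pred = clf.classes_[np.nanargmax(np.where(seen[:, None], oob, -1), axis=1)]
    correct = (oob_pred == y).astype(float)
    prior_error = float(1.0 - correct[seen].mean())

    reg = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=1.0 / 3.0,
        min_samples_leaf=5,
        random_state=None if seed is None else int(seed) + 1,
        n_jobs=1,
    )
    reg.fit(X[seen], correct[seen])
    return {"clf": clf, "reg": reg, "prior_error": prior_error,
            "stat_names": ref.stat_names, "n_trees": n_trees, "lda": lda}


def classify_observed(forest, ref: ReferenceTable, observed) -> ModelChoiceResult:
    obs = _observed_row(observed, forest["stat_names"])
    if forest.get("lda") is not None:
        obs = np.hstack([obs, forest["lda"].transform(obs)])
    clf = forest["clf"]
    per_tree = np.array([t.predict(obs)[0] for t in clf.estimators_])
    tree_labels = clf.classes_[per_tree.astype(int)]
    votes = {str(lab): 0 for lab in clf.classes_}
    for lab in tree_labels:
        votes[str(lab)] += 1
    top = max(votes.values())
    selected = min(lab for lab, v in votes.items() if v == top)
    post = float(np.clip(forest["reg"].predict(obs)[0], 0.0, 1.0))
    return ModelChoiceResult(
        votes=votes,
        selected=selected,
        posterior_probability=post,
        prior_error_rate=forest["prior_error"],
        n_trees=forest["n_trees"],
    )


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

@dataclass
class ParamEstimate:
    """Posterior median and central 95% interval for one parameter."""

    name: str
    median: float
    q025: float
    q975: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (self.q025 <= self.median <= self.q975):
            raise ValueError("quantiles out of order")

    def summary(self) -> str:
        u = f" {self.units}" if self.units else ""
        return (f"{self.name}: median {self.median:.4g}{u} "
                f"(95% CI {self.q025:.4g} – {self.q975:.4g})")


def _weighted_quantiles(y: np.ndarray, w: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(y)
    y, w = y[order], w[order]
    cum = np.cumsum(w)
    cum /= cum[-1]
    return np.array([y[np.searchsorted(cum, q, side="left").clip(0, len(y) - 1)]
                     for q in qs])


class QuantileRegressionForest:
    """Regression forest exposing the weighted posterior distribution of
    its training responses at arbitrary query points."""

    def __init__(self, n_trees: int = DEFAULT_N_TREES, seed: int | None = 0,
                 min_samples_leaf: int = 5):
        self.forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=1.0 / 3.0,
            min_samples_leaf=min_samples_leaf,
            random_state=None if seed is None else int(seed),
            n_jobs=1,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "QuantileRegressionForest":
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y, dtype=float)
        self.forest.fit(self.X_, self.y_)
        self.train_leaves_ = self.forest.apply(self.X_)  # (n, n_trees)
        return self

    def weights(self, obs: np.ndarray) -> np.ndarray:
        """QRF weights of the training rows for one query row."""
        obs_leaves = self.forest.apply(obs.reshape(1, -1))[0]
        w = np.zeros(len(self.y_))
        for t in range(self.train_leaves_.shape[1]):
            same = self.train_leaves_[:, t] == obs_leaves[t]
            w[same] += 1.0 / same.sum()
        return w / self.train_leaves_.shape[1]

    def quantiles(self, obs: np.ndarray, qs=(0.025, 0.5, 0.975)) -> np.ndarray:
        return _weighted_quantiles(self.y_, self.weights(obs), qs)


def estimate_parameter(
    ref: ReferenceTable,
    observed,
    param: str,
    n_trees: int = DEFAULT_N_TREES,
    seed: int | None = 0,
    units: str = "",
) -> ParamEstimate:
    """Posterior median and 95% interval for one parameter of one scenario.

    ``ref`` must be restricted to a single scenario.  A constant response
    column yields a degenerate estimate equal to the constant.  Time
    parameters are stored in years throughout, so no unit conversion
    happens here.
    """
    if len(ref.labels) != 1:
        raise ValueError(
            "parameter estimation needs a reference table restricted to one "
            f"scenario; got labels {ref.labels}"
        )
    if param not in ref.param_names:
        raise KeyError(f"parameter {param!r} not in reference table")
    y = ref.parameter(param)
    obs = _observed_row(observed, ref.stat_names)[0]
    qrf = QuantileRegressionForest(n_trees=n_trees, seed=seed).fit(
        ref.stats_matrix(), y
    )
    q025, med, q975 = qrf.quantiles(obs)
    return ParamEstimate(name=param, median=float(med), q025=float(q025),
                         q975=float(q975), units=units)
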