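"""Random-forest approximate Bayesian computation.

Scenario choice and posterior parameter estimation follow the ABC-RF
methodology: a classification forest trained on the reference table yields
per-scenario votes and the out-of-bag "prior error rate"; the posterior
probability of the selected scenario is the prediction, at the observed
point, of a regression forest trained on the out-of-bag indicator
"OOB-classified scenario equals true scenario".  Parameter posteriors come
from one regression forest per parameter with leaf co-occurrence weights:
each training draw is weighted by how often it shares a terminal leaf with
the observed summary vector, and the weighted empirical distribution gives
posterior means, medians and credible quantiles.

Both analyses are exposed as Model classes whose ``fit()`` returns a Results
object with a ``summary()`` table, plus thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .abc_summaries import LdaProjector, fit_lda
from .scenario_engine import ReferenceTable

GENERATION_TIME_YEARS = 6.0
MUTATION_RATE_PER_SITE_PER_YEAR = 1.5e-9


def convert_units(value_generations: float, generation_time_years: float = GENERATION_TIME_YEARS) -> float:
    """Convert a time in generations to years before present."""
    if generation_time_years <= 0:
        raise ValueError("generation time must be positive")
    return value_generations * generation_time_years


def _mtry_regression(n_features: int) -> int:
    """Features tried per split in regression forests: n/3, floored at 5 so
    tiny summary vectors are not reduced to single-feature splits."""
    return min(n_features, max(5, n_features // 3))


def _as_series(observed) -> pd.Series:
    if isinstance(observed, pd.Series):
        return observed
    return pd.Series(dict(observed))


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q) -> np.ndarray:
    """Quantiles of a weighted empirical distribution (CDF inversion)."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cdf = np.cumsum(w)
    cdf = cdf / cdf[-1]
    return np.interp(np.atleast_1d(q), cdf, v)


# ------------------------------------------------------------- scenario choice


@dataclass
class ScenarioChoiceResults:
    """Votes, prior error rate and posterior probability for scenario choice."""

    votes: pd.Series  # vote fraction per scenario
    vote_counts: pd.Series
    selected: str
    prior_error_rate: float
    posterior_prob: float
    n_trees: int
    seed: int | None
    lda: LdaProjector | None = None

    def summary(self) -> str:
        lines = [
            "ABC-RF scenario choice",
            "=" * 46,
            f"{'scenario':<24}{'votes':>10}{'fraction':>10}",
            "-" * 46,
        ]
        for name, frac in self.votes.sort_values(ascending=False).items():
            mark = " *" if name == self.selected else ""
            lines.append(f"{name:<24}{int(self.vote_counts[name]):>10}{frac:>10.3f}{mark}")
        lines += [
            "-" * 46,
            f"selected scenario:       {self.selected}",
            f"posterior probability:   {self.posterior_prob:.3f}",
            f"prior error rate (OOB):  {self.prior_error_rate:.3f}",
            f"trees: {self.n_trees}",
        ]
        return "\n".join(lines)


class ScenarioChoiceModel:
    """Random-forest model choice over simulated scenarios.

    Parameters
    ----------
    reference : ReferenceTable
        Training set with >= 2 scenarios (equal row counts recommended).
    observed : pandas.Series or mapping
        Observed summary vector on the reference table's schema.
    add_lda : bool
        Append ``n_scenarios - 1`` discriminant axes (fitted on the reference
        table only) to both training rows and the observed vector.
    """

    def __init__(self, reference: ReferenceTable, observed, add_lda: bool = True):
        self.reference = reference
        self.observed = _as_series(observed)
        self.add_lda = add_lda
        labels = reference.scenario_labels
        if len(labels) < 2:
            raise ValueError("scenario choice needs at least two scenarios")
        missing = set(reference.summary_cols) - set(self.observed.index)
        if missing:
            raise ValueError(f"observed vector missing summaries: {sorted(missing)[:5]} ...")

    def fit(self, n_trees: int = 1000, seed: int | None = None) -> ScenarioChoiceResults:
        table = self.reference.table
        cols = list(self.reference.summary_cols)
        x = table[cols].to_numpy(dtype=float)
        obs = self.observed[cols].to_numpy(dtype=float)[None, :]
        projector = None
        if self.add_lda:
            projector = fit_lda(table, cols)
            x = np.hstack([x, projector.transform(table)])
            obs = np.hstack([obs, projector.transform(self.observed[cols])])
        y = table["scenario"].to_numpy()

        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(x, y)

        tree_votes = np.array(
            [clf.classes_[int(est.predict(obs)[0])] for est in clf.estimators_]
        )
        labels = list(self.reference.scenario_labels)
        counts = pd.Series({lab: int((tree_votes == lab).sum()) for lab in labels})
        fracs = counts / counts.sum()
        # argmax with ties resolved to the lowest scenario index
        selected = max(labels, key=lambda lab: (counts[lab], -labels.index(lab)))

        oob = clf.oob_decision_function_
        oob_pred = clf.classes_[np.nanargmax(np.nan_to_num(oob), axis=1)]
        prior_error = float((oob_pred != y).mean())

        # posterior probability of the selected scenario (OOB-indicator regression)
        indicator = (oob_pred == y).astype(float)
        reg = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=_mtry_regression(x.shape[1]),
            random_state=seed,
            n_jobs=1,
        )
        reg.fit(x, indicator)
        posterior = float(np.clip(reg.predict(obs)[0], 0.0, 1.0))

        return ScenarioChoiceResults(
            votes=fracs,
            vote_counts=counts,
            selected=selected,
            prior_error_rate=prior_error,
            posterior_prob=posterior,
            n_trees=n_trees,
            seed=seed,
            lda=projector,
        )


def model_choice(
    reference: ReferenceTable,
    observed,
    n_trees: int = 1000,
    seed: int | None = None,
    add_lda: bool = True,
) -> ScenarioChoiceResults:
    return ScenarioChoiceModel(reference, observed, add_lda).fit(n_trees, seed)


# -------------------------------------------------------- parameter estimation


@dataclass
class ParameterPosteriorResults:
    """Weighted posterior summaries per parameter of the selected scenario."""

    estimates: pd.DataFrame  # index: parameter; mean/median/q025/q975/oob_error
    weights: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    n_trees: int = 0
    seed: int | None = None
    generation_time_years: float = GENERATION_TIME_YEARS
    mutation_rate: float = MUTATION_RATE_PER_SITE_PER_YEAR

    def converted(self, time_params: list[str] | None = None) -> pd.DataFrame:
        """Estimates with time parameters converted from generations to years.

        By default every parameter whose name starts with ``t_`` is treated
        as a time in generations.
        """
        df = self.estimates.copy()
        if time_params is None:
            time_params = [p for p in df.index if p.startswith("t_")]
        for p in time_params:
            for col in ("mean", "median", "q025", "q975"):
                df.loc[p, col] = convert_units(df.loc[p, col], self.generation_time_years)
        return df

    def summary(self) -> str:
        lines = [
            "ABC-RF posterior parameter estimates",
            "=" * 72,
            f"{'parameter':<18}{'mean':>12}{'median':>12}{'q2.5%':>12}{'q97.5%':>12}",
            "-" * 72,
        ]
        for p, row in self.estimates.iterrows():
            lines.append(
                f"{p:<18}{row['mean']:>12.4g}{row['median']:>12.4g}"
                f"{row['q025']:>12.4g}{row['q975']:>12.4g}"
            )
        lines += [
            "-" * 72,
            f"trees per forest: {self.n_trees};  "
            f"time conversion: {self.generation_time_years} years/generation",
        ]
        return "\n".join(lines)


class ParameterRegressionModel:
    """Per-parameter RF regression posterior for a single scenario.

    ``reference`` must contain rows of one scenario only (use
    ``ReferenceTable.for_scenario``).
    """

    def __init__(self, reference: ReferenceTable, observed, params: list[str] | None = None):
        if len(reference.scenario_labels) != 1:
            raise ValueError("parameter estimation needs a single-scenario reference table")
        self.reference = reference
        self.observed = _as_series(observed)
        self.params = params or list(reference.param_cols)

    def fit(
        self,
        n_trees: int = 1000,
        seed: int | None = None,
        min_samples_leaf: int = 5,
    ) -> ParameterPosteriorResults:
        table = self.reference.table
        cols = list(self.reference.summary_cols)
        x = table[cols].to_numpy(dtype=float)
        obs = self.observed[cols].to_numpy(dtype=float)[None, :]
        records = {}
        weights_all = {}
        for k, param in enumerate(self.params):
            y = table[param].to_numpy(dtype=float)
            if np.ptp(y) == 0:  # degenerate prior: posterior is the constant
                records[param] = {
                    "mean": y[0],
                    "median": y[0],
                    "q025": y[0],
                    "q975": y[0],
                    "oob_error": 0.0,
                }
                weights_all[param] = np.full(len(y), 1.0 / len(y))
                continue
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=_mtry_regression(x.shape[1]),
                min_samples_leaf=min_samples_leaf,
                oob_score=True,
                random_state=None if seed is None else seed + k,
                n_jobs=1,
            )
            rf.fit(x, y)
            # leaf co-occurrence weights with the observed point
            train_leaves = rf.apply(x)  # (n, n_trees)
            obs_leaves = rf.apply(obs)[0]  # (n_trees,)
            w = np.zeros(len(y))
            for t in range(train_leaves.shape[1]):
                in_leaf = train_leaves[:, t] == obs_leaves[t]
                n_in = in_leaf.sum()
                if n_in:
                    w[in_leaf] += 1.0 / n_in
            w /= w.sum()
            mean = float(np.sum(w * y))
            median, q025, q975 = weighted_quantile(y, w, [0.5, 0.025, 0.975])
            oob_err = float(np.nanmean((rf.oob_prediction_ - y) ** 2))
            records[param] = {
                "mean": mean,
                "median": float(median),
                "q025": float(q025),
                "q975": float(q975),
                "oob_error": oob_err,
            }
            weights_all[param] = w
        est = pd.DataFrame.from_dict(records, orient="index")
        est.index.name = "parameter"
        # enforce q025 <= median <= q975 against interpolation jitter
        est["median"] = est[["q025", "median"]].max(axis=1)
        est["median"] = est[["median", "q975"]].min(axis=1)
        return ParameterPosteriorResults(
            estimates=est, weights=weights_all, n_trees=n_trees, seed=seed
        )


def estimate_parameters(
    reference: ReferenceTable,
    observed,
    params: list[str] | None = None,
    n_trees: int = 1000,
    seed: int | None = None,
) -> ParameterPosteriorResults:
    return ParameterRegressionModel(reference, observed, params).fit(n_trees, seed)
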