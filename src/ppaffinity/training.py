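"""Model training, AIC stepwise selection, and evaluation.

The regression target is |ΔG| (kcal/mol, positive scale — experimental
free energies are negative, published model weights positive). Fitting is
ordinary least squares via statsmodels. Stepwise selection minimises the
Gaussian-likelihood Akaike Information Criterion

    AIC = n · ln(RSS / n) + 2 · (k + 1),

with k the number of slope terms, accepting greedy add/drop moves while
the AIC decreases; among equally good moves, drops precede adds and
terms are considered in declared order, so the procedure is
deterministic.

Dataset container: a pandas DataFrame with one row per complex, columns
``id``, ``dg_exp`` (kcal/mol, negative), optional metadata ``method``,
``i_rmsd``, ``class``, plus the structural property columns (``ICs_*``,
``BSA_*``, ``%NIS_*``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .models import LinearAffinityModel

__all__ = [
    "AffinityRegressor", "StepwiseAICRegressor", "FitResult",
    "CrossValReport", "fit_linear", "aic_stepwise", "correlations",
    "cross_validate", "grouped_eval", "curate", "RELIABLE_METHODS",
]

#: Experimental-method labels retained by the reliable-subset filter.
RELIABLE_METHODS = frozenset({"stopped-flow", "spr", "spectroscopy", "itc"})


def _design(records: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    missing = [t for t in terms if t not in records.columns]
    if missing:
        raise KeyError(f"dataset lacks property column(s): {missing}")
    return records.loc[:, list(terms)].to_numpy(dtype=float)


def _check_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = []
        for j, term in enumerate(terms):
            others = np.delete(design, j + 1, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(
                others, X[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
                collinear.append(term)
        raise ValueError(
            f"rank-deficient design; collinear term(s): {collinear or terms}")


def gaussian_aic(rss: float, n: int, k: int) -> float:
    """AIC = n·ln(RSS/n) + 2·(k+1) for an OLS model with k slope terms."""
    return n * math.log(max(rss, 1e-300) / n) + 2.0 * (k + 1)


class AffinityRegressor(RegressorMixin, BaseEstimator):
    """OLS fit of |ΔG| on named structural properties.

    Parameters
    ----------
    terms
        Property columns to use; ``None`` means every ``ICs_*`` / ``BSA_*``
        / ``%NIS_*`` column present in ``X``.

    Fitted attributes include ``coef_``, ``intercept_``, ``model_`` (a
    :class:`LinearAffinityModel` with the fitted weights), ``aic_`` and
    the underlying statsmodels ``results_``.
    """

    def __init__(self, terms: Sequence[str] | None = None):
        self.terms = terms

    def _resolve_terms(self, X: pd.DataFrame) -> list[str]:  # noqa: N803
        if self.terms is not None:
            return list(self.terms)
        return [c for c in X.columns
                if c.startswith(("ICs_", "BSA_", "%NIS_"))]

    def fit(self, X: pd.DataFrame, y):  # noqa: N803
        terms = self._resolve_terms(X)
        y = np.abs(np.asarray(y, dtype=float))
        if len(X) <= len(terms) + 1:
            raise ValueError(
                f"need more than {len(terms) + 1} records to fit "
                f"{len(terms)} terms; got {len(X)}")
        M = _design(X, terms)
        _check_rank(M, terms)
        res = sm.OLS(y, sm.add_constant(M, has_constant="add")).fit()
        self.terms_ = terms
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.bse_ = np.asarray(res.bse[1:], dtype=float)
        self.results_ = res
        self.rss_ = float(res.ssr)
        self.aic_ = gaussian_aic(self.rss_, len(y), len(terms))
        self.n_features_in_ = len(terms)
        self.model_ = LinearAffinityModel(
            terms={t: float(c) for t, c in zip(terms, self.coef_)},
            intercept=self.intercept_, name="fitted").fit()
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:  # noqa: N803
        M = _design(X, self.terms_)
        return M @ self.coef_ + self.intercept_


class StepwiseAICRegressor(RegressorMixin, BaseEstimator):
    """Bidirectional greedy AIC term selection around OLS fits.

    Starts from the full candidate set and repeatedly applies the
    single-term drop or add that most decreases the AIC, until no move
    improves it. ``aic_trace_`` records (move, term, AIC) per step.
    """

    def __init__(self, candidate_terms: Sequence[str] | None = None,
                 direction: str = "both"):
        self.candidate_terms = candidate_terms
        self.direction = direction

    def _aic_for(self, X, y, terms) -> float:  # noqa: N803
        y = np.abs(np.asarray(y, dtype=float))
        if terms:
            M = sm.add_constant(_design(X, terms), has_constant="add")
        else:
            M = np.ones((len(X), 1))
        rss = float(sm.OLS(y, M).fit().ssr)
        return gaussian_aic(rss, len(y), len(terms))

    def fit(self, X: pd.DataFrame, y):  # noqa: N803
        if self.direction not in ("both", "backward", "forward"):
            raise ValueError(f"unknown direction {self.direction!r}")
        candidates = (list(self.candidate_terms)
                      if self.candidate_terms is not None
                      else AffinityRegressor()._resolve_terms(X))
        current = [] if self.direction == "forward" else list(candidates)
        aic = self._aic_for(X, y, current)
        trace: list[tuple[str, str | None, float]] = [("start", None, aic)]
        while True:
            best: tuple[float, str, str] | None = None  # (aic, move, term)
            moves: list[tuple[str, str]] = []
            if self.direction in ("both", "backward"):
                moves += [("drop", t) for t in current]
            if self.direction in ("both", "forward"):
                moves += [("add", t) for t in candidates if t not in current]
            for move, term in moves:
                trial = ([t for t in current if t != term] if move == "drop"
                         else current + [term])
                trial_aic = self._aic_for(X, y, trial)
                if trial_aic < aic - 1e-10 and (
                        best is None or trial_aic < best[0] - 1e-10):
                    best = (trial_aic, move, term)
            if best is None:
                break
            aic, move, term = best
            current = ([t for t in current if t != term] if move == "drop"
                       else current + [term])
            trace.append((move, term, aic))
        # preserve candidate declaration order in the selected set
        selected = [t for t in candidates if t in current]
        self.selected_terms_ = selected
        self.aic_ = aic
        self.aic_trace_ = trace
        if selected:
            self._fitted = AffinityRegressor(terms=selected).fit(X, y)
            self.coef_ = self._fitted.coef_
            self.intercept_ = self._fitted.intercept_
            self.model_ = self._fitted.model_
        else:
            yabs = np.abs(np.asarray(y, dtype=float))
            self.coef_ = np.empty(0)
            self.intercept_ = float(yabs.mean())
            self.model_ = LinearAffinityModel(
                terms={}, intercept=self.intercept_, name="fitted").fit()
        self.terms_ = selected
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:  # noqa: N803
        if self.selected_terms_:
            return self._fitted.predict(X)
        return np.full(len(X), self.intercept_)


@dataclass
class FitResult:
    """A fitted model plus its in-sample evaluation."""

    model: LinearAffinityModel
    r_pearson: float
    s_spearman: float
    rmse: float
    p_value: float
    selected_terms: list[str]
    n: int
    aic: float | None = None
    aic_trace: list[tuple[str, str | None, float]] | None = None
    standard_errors: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "model": self.model.to_dict(),
            "r_pearson": self.r_pearson,
            "s_spearman": self.s_spearman,
            "rmse_kcal_mol": self.rmse,
            "p_value": self.p_value,
            "selected_terms": list(self.selected_terms),
            "n": self.n,
        }
        if self.aic is not None:
            out["aic"] = self.aic
            out["aic_trace"] = [list(t) for t in (self.aic_trace or [])]
        return out


def correlations(x: Sequence[float], y: Sequence[float]
                 ) -> tuple[float, float, float]:
    """Pearson R, Spearman S (average ranks for ties) and the two-sided
    p-value of the Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length sequences of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    r, p = stats.pearsonr(x, y)
    s = stats.spearmanr(x, y).statistic
    return float(r), float(s), float(p)


def _evaluate(pred: np.ndarray, y_abs: np.ndarray) -> tuple[float, float, float, float]:
    rmse = float(np.sqrt(np.mean((pred - y_abs) ** 2)))
    if len(y_abs) >= 3 and np.ptp(pred) > 0 and np.ptp(y_abs) > 0:
        r, s, p = correlations(pred, y_abs)
    else:
        r = s = p = float("nan")
    return r, s, rmse, p


def fit_linear(records: pd.DataFrame, terms: Sequence[str]) -> FitResult:
    """OLS fit of |ΔG| on the given property columns."""
    est = AffinityRegressor(terms=terms).fit(records, records["dg_exp"])
    y_abs = np.abs(records["dg_exp"].to_numpy(dtype=float))
    r, s, rmse, p = _evaluate(est.predict(records), y_abs)
    return FitResult(
        model=est.model_, r_pearson=r, s_spearman=s, rmse=rmse, p_value=p,
        selected_terms=list(est.terms_), n=len(records), aic=est.aic_,
        standard_errors=dict(zip(est.terms_, est.bse_)))


def aic_stepwise(records: pd.DataFrame, candidate_terms: Sequence[str],
                 direction: str = "both") -> FitResult:
    """Greedy bidirectional AIC selection over the candidate terms."""
    est = StepwiseAICRegressor(candidate_terms=candidate_terms,
                               direction=direction)
    est.fit(records, records["dg_exp"])
    y_abs = np.abs(records["dg_exp"].to_numpy(dtype=float))
    pred = est.predict(records)
    if est.selected_terms_:
        r, s, rmse, p = _evaluate(pred, y_abs)
        ses = dict(zip(est.selected_terms_, est._fitted.bse_))
    else:
        rmse = float(np.sqrt(np.mean((pred - y_abs) ** 2)))  # = std of |ΔG|
        r = s = p = float("nan")
        ses = {}
    return FitResult(
        model=est.model_, r_pearson=r, s_spearman=s, rmse=rmse, p_value=p,
        selected_terms=list(est.selected_terms_), n=len(records),
        aic=est.aic_, aic_trace=est.aic_trace_, standard_errors=ses)


@dataclass
class CrossValReport:
    """Repeated k-fold cross-validation results."""

    k: int
    repeats: int
    seed: int
    folds: list[dict]  # one entry per (repeat, fold)

    @property
    def mean_rmse(self) -> float:
        return float(np.mean([f["rmse"] for f in self.folds]))

    @property
    def mean_r(self) -> float:
        rs = [f["r_pearson"] for f in self.folds
              if not math.isnan(f["r_pearson"])]
        return float(np.mean(rs)) if rs else float("nan")

    def to_dict(self) -> dict:
        return {"k": self.k, "repeats": self.repeats, "seed": self.seed,
                "mean_rmse": self.mean_rmse, "mean_r": self.mean_r,
                "folds": self.folds}


def cross_validate(
    records: pd.DataFrame,
    terms: Sequence[str],
    k: int = 4,
    repeats: int = 10,
    seed: int = 0,
    stepwise: bool = False,
) -> CrossValReport:
    """Repeated k-fold CV (default 4-fold, 10 repeats, seeded shuffling).

    Each repeat partitions the records into k complementary subsets;
    every record is held out exactly once per repeat. Folds are simple
    random partitions (no stratification).
    """
    n = len(records)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} records for {k}-fold CV")
    n_terms = len(terms)
    if n - math.ceil(n / k) <= n_terms + 1:
        raise ValueError("training folds too small for the number of terms")
    rng = np.random.default_rng(seed)
    y_abs = np.abs(records["dg_exp"].to_numpy(dtype=float))
    folds: list[dict] = []
    for rep in range(repeats):
        order = rng.permutation(n)
        for fold_i, test_idx in enumerate(np.array_split(order, k)):
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            train = records.iloc[train_mask]
            test = records.iloc[test_idx]
            est = (StepwiseAICRegressor(candidate_terms=terms) if stepwise
                   else AffinityRegressor(terms=terms))
            est.fit(train, train["dg_exp"])
            pred = est.predict(test)
            yt = y_abs[test_idx]
            rmse = float(np.sqrt(np.mean((pred - yt) ** 2)))
            if len(yt) >= 3 and np.ptp(pred) > 0 and np.ptp(yt) > 0:
                r = float(stats.pearsonr(pred, yt)[0])
            else:
                r = float("nan")
            folds.append({
                "repeat": rep, "fold": fold_i,
                "terms": list(est.terms_),
                "coef": [float(c) for c in est.coef_],
                "intercept": float(est.intercept_),
                "r_pearson": r, "rmse": rmse, "n_test": int(len(yt)),
            })
    return CrossValReport(k=k, repeats=repeats, seed=seed, folds=folds)


def grouped_eval(
    records: pd.DataFrame,
    group_key: str = "method",
    value_col: str = "ICs_total",
    min_group: int = 3,
) -> pd.DataFrame:
    """Per-group correlation of a property with experimental ΔG.

    ``group_key`` is either a metadata column (e.g. ``method``) or
    ``"rigidity"``, which bins on interface RMSD: rigid when
    ``i_rmsd`` ≤ 1.0 Å, flexible above. Groups smaller than
    ``min_group`` are flagged insufficient and get no correlation.
    """
    if group_key == "rigidity":
        if "i_rmsd" not in records.columns:
            raise KeyError("rigidity grouping requires an 'i_rmsd' column")
        labels = np.where(records["i_rmsd"].to_numpy(dtype=float) <= 1.0,
                          "rigid", "flexible")
    elif group_key in records.columns:
        labels = records[group_key].to_numpy()
    else:
        raise KeyError(f"unknown group key {group_key!r}")
    rows = []
    for group in pd.unique(labels):
        sub = records.iloc[np.flatnonzero(labels == group)]
        row = {"group": group, "n": len(sub), "sufficient": len(sub) >= min_group,
               "r_pearson": float("nan"), "s_spearman": float("nan"),
               "p_value": float("nan")}
        if row["sufficient"]:
            try:
                r, s, p = correlations(sub[value_col], sub["dg_exp"])
                row.update(r_pearson=r, s_spearman=s, p_value=p)
            except ValueError:
                pass  # degenerate variance stays NaN
        rows.append(row)
    return pd.DataFrame(rows)


def curate(
    records: pd.DataFrame,
    reliable_only: bool = False,
) -> pd.DataFrame:
    """Benchmark curation filters.

    Drops records whose ``dg_exp`` is not a unique number (inequality
    strings such as ``"> -14"``) and records flagged with an interface
    gap longer than two residues (boolean column
    ``interface_gap_excluded``). With ``reliable_only`` the experimental
    method must be one of stopped-flow, SPR, spectroscopy or ITC.
    """
    df = records.copy()

    def _numeric(v) -> float:
        try:
            return float(v)
        except (TypeError, ValueError):
            return float("nan")

    dg = df["dg_exp"].map(_numeric)
    keep = dg.notna()
    df = df.loc[keep].assign(dg_exp=dg[keep])
    if "interface_gap_excluded" in df.columns:
        df = df.loc[~df["interface_gap_excluded"].astype(bool)]
    if reliable_only:
        if "method" not in df.columns:
            raise KeyError("reliable-subset filter requires a 'method' column")
        norm = (df["method"].astype(str).str.strip().str.lower()
                .str.replace(" ", "-"))
        df = df.loc[norm.isin(RELIABLE_METHODS)]
    return df.reset_index(drop=True)
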