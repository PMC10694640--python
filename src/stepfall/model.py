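"""Negative-binomial fall-risk model with stability-based backward elimination.

Twelve-month fall counts are modelled with an NB2 regression (log link,
variance mu + alpha*mu^2) on z-transformed gait parameters, always
adjusting for intervention-group membership. Candidate parameters are
screened for mutual correlation, then reduced by a stability criterion:
the model is refit on 10 random 70% subsets of the cohort and a term is
kept only while the mean and SD of its Wald P values across subsets stay
below 0.20; the least stable term is dropped and the procedure repeats.
Discrimination of fallers (>= 1 fall) from nonfallers is summarized by the
AUC of the predicted expected count, both in-sample and under repeated
80/20 shuffle-split cross-validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats
from scipy.special import gammaln

from .cohort import Standardizer

__all__ = [
    "ModelSpec",
    "NBFit",
    "StabilityReport",
    "EvalResult",
    "SingularDesignError",
    "DegenerateOutcomeError",
    "EmptyModelError",
    "UndefinedAUCError",
    "PRESETS",
    "fit_nb",
    "fit_cohort",
    "design_matrix",
    "predict_risk",
    "auc",
    "evaluate",
    "stability_elimination",
    "select_candidates",
    "add_group_interactions",
    "nb2_loglikelihood",
]


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient (separation or collinearity)."""


class DegenerateOutcomeError(ValueError):
    """Outcome admits no NB fit (e.g. all counts zero)."""


class EmptyModelError(RuntimeError):
    """Backward elimination removed every gait term."""


class UndefinedAUCError(ValueError):
    """AUC is undefined (single-class labels)."""


@dataclass(frozen=True)
class ModelSpec:
    """Terms of a fall-count model on standardized gait parameters.

    The intercept and the group covariate are always included and never
    eliminated. ``quantity_interactions`` are products of two standardized
    main effects (a quantity parameter with another parameter);
    ``group_interactions`` are group x parameter products added after
    elimination and not themselves eliminable.
    """

    main_effects: tuple[str, ...]
    quantity_interactions: tuple[tuple[str, str], ...] = ()
    group_interactions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for a, b in self.quantity_interactions:
            if a not in self.main_effects or b not in self.main_effects:
                raise ValueError(f"interaction {a}:{b} references absent main effect")
        for p in self.group_interactions:
            if p not in self.main_effects:
                raise ValueError(f"group interaction references absent main effect {p}")

    @property
    def eliminable_terms(self) -> tuple[str, ...]:
        """Gait terms subject to backward elimination (not group/intercept)."""
        return self.main_effects + tuple(f"{a}:{b}" for a, b in self.quantity_interactions)

    @property
    def required_params(self) -> tuple[str, ...]:
        return self.main_effects

    def drop(self, term: str) -> "ModelSpec":
        """Remove a term; dropping a main effect drops interactions using it."""
        if ":" in term:
            a, b = term.split(":", 1)
            qi = tuple(p for p in self.quantity_interactions if p != (a, b))
            if qi == self.quantity_interactions:
                raise KeyError(term)
            return replace(self, quantity_interactions=qi)
        if term not in self.main_effects:
            raise KeyError(term)
        return ModelSpec(
            main_effects=tuple(t for t in self.main_effects if t != term),
            quantity_interactions=tuple(
                p for p in self.quantity_interactions if term not in p
            ),
            group_interactions=tuple(p for p in self.group_interactions if p != term),
        )


#: The six-parameter model reported for the original week-long cohort.
PRESETS: dict[str, ModelSpec] = {
    "paper2023": ModelSpec(
        main_effects=(
            "total_steps",
            "cadence",
            "cov_stride_time",
            "dfa_step",
            "sampen_step",
            "sampen_stride",
        )
    )
}


@dataclass(frozen=True)
class NBFit:
    """Fitted NB2 regression on standardized predictors."""

    terms: tuple[str, ...]
    coefficients: np.ndarray
    dispersion: float
    std_errors: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    converged: bool

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def pvalue(self, term: str) -> float:
        return float(self.p_values[self.terms.index(term)])

    def as_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coefficients": [float(c) for c in self.coefficients],
            "std_errors": [float(s) for s in self.std_errors],
            "p_values": [float(p) for p in self.p_values],
            "dispersion": self.dispersion,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class StabilityReport:
    """Mean/SD of per-term P values over the random 70% subset fits."""

    iteration: int
    mean_p: dict[str, float]
    sd_p: dict[str, float]
    stable: dict[str, bool]
    removed: str | None
    n_nonconverged: int
    subset_seed: int


@dataclass(frozen=True)
class EvalResult:
    """In-sample and shuffle-split AUC of a fixed model specification."""

    auc_insample: float
    auc_cv_mean: float
    auc_cv_sd: float
    auc_per_split: tuple[float, ...]
    n_splits: int
    train_fraction: float
    n_redraws: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "auc_insample": self.auc_insample,
            "auc_cv_mean": self.auc_cv_mean,
            "auc_cv_sd": self.auc_cv_sd,
            "auc_per_split": list(self.auc_per_split),
            "n_splits": self.n_splits,
            "train_fraction": self.train_fraction,
            "n_redraws": self.n_redraws,
            "seed": self.seed,
        }


def design_matrix(z_cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design with intercept, group, main effects and interaction products.

    ``z_cohort`` must already carry standardized parameter columns and a
    binary ``group`` column; interaction columns are products of the
    standardized columns (group interactions use the raw 0/1 indicator).
    """
    X = pd.DataFrame(index=z_cohort.index)
    X["const"] = 1.0
    X["group"] = z_cohort["group"].astype(float)
    for name in spec.main_effects:
        X[name] = z_cohort[name].astype(float)
    for a, b in spec.quantity_interactions:
        X[f"{a}:{b}"] = z_cohort[a].astype(float) * z_cohort[b].astype(float)
    for p in spec.group_interactions:
        X[f"group:{p}"] = z_cohort["group"].astype(float) * z_cohort[p].astype(float)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # pivoted QR exposes which columns fall outside the independent set
        _, _, piv = linalg.qr(arr, mode="economic", pivoting=True)
        offending = [X.columns[i] for i in sorted(piv[rank:])]
        raise SingularDesignError(
            f"rank-deficient design; collinear column(s): {', '.join(offending)}"
        )


def fit_nb(X: pd.DataFrame, y: np.ndarray) -> NBFit:
    """Maximum-likelihood NB2 fit (log link) with Wald P values.

    Raises on rank-deficient designs and all-zero outcomes; a
    non-converged optimizer is reported through ``converged`` rather than
    silently accepted.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != len(X):
        raise ValueError("X and y length mismatch")
    if y.shape[0] < X.shape[1] + 10:
        raise ValueError("need at least 10 more observations than model terms")
    if np.all(y == 0):
        raise DegenerateOutcomeError("all fall counts are zero; NB fit undefined")
    _check_rank(X)
    model = sm.NegativeBinomial(y, X.to_numpy(dtype=float), loglike_method="nb2")
    k = X.shape[1]
    res, converged = None, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # optimizers differ in robustness near the alpha -> 0 boundary; accept
        # the first converged fit with a usable covariance
        for method, maxiter in (("lbfgs", 1000), ("bfgs", 500), ("nm", 5000)):
            try:
                cand = model.fit(method=method, maxiter=maxiter, disp=0)
            except (np.linalg.LinAlgError, ValueError):
                continue
            ok = bool(cand.mle_retvals.get("converged", False))
            with np.errstate(invalid="ignore"):
                usable = ok and bool(np.all(np.isfinite(np.asarray(cand.bse[:k]))))
            if res is None or (usable and not converged):
                res, converged = cand, usable
            if usable:
                break
    if res is None:
        raise DegenerateOutcomeError("NB optimization failed for every optimizer")
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        bse = np.asarray(res.bse[:k], dtype=float)
        pvals = np.asarray(res.pvalues[:k], dtype=float)
        llf = float(res.llf)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    return NBFit(
        terms=tuple(X.columns),
        coefficients=np.asarray(res.params[:k], dtype=float),
        dispersion=float(max(res.params[-1], 1e-12)),
        std_errors=bse,
        p_values=pvals,
        log_likelihood=llf,
        converged=converged,
    )


def fit_cohort(
    cohort: pd.DataFrame, spec: ModelSpec
) -> tuple[NBFit, Standardizer, pd.DataFrame]:
    """Standardize the spec's parameters on this cohort, build design, fit.

    Returns the fit, the fitted standardizer (reusable on held-out data)
    and the design matrix. Rows with missing values in required columns
    must be removed by the caller beforehand.
    """
    std = Standardizer().fit(cohort, spec.required_params)
    X = design_matrix(std.transform(cohort), spec)
    fit = fit_nb(X, cohort["fall_count"].to_numpy())
    return fit, std, X


def complete_cases(cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = list(spec.required_params)
    return cohort.dropna(subset=cols).reset_index(drop=True)


def predict_risk(fit: NBFit, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Expected fall count exp(X beta); rows must match the fit's term order."""
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.atleast_2d(X)
    if arr.shape[1] != fit.coefficients.size:
        raise ValueError(
            f"design has {arr.shape[1]} columns, fit expects {fit.coefficients.size}"
        )
    return np.exp(arr @ fit.coefficients)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random faller outscores a random nonfaller (ties 0.5).

    Mann-Whitney formulation via average ranks; exact, no trapezoid
    approximation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def nb2_loglikelihood(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood; reduces to the Poisson log-likelihood as alpha -> 0."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if alpha <= 1e-12:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    inv = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + inv)
            - gammaln(inv)
            - gammaln(y + 1)
            + y * np.log(alpha * mu / (1 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def evaluate(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    n_splits: int = 10,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> EvalResult:
    """Train=test AUC plus repeated shuffle-split AUC for a fixed spec.

    Each split re-estimates standardization on its training fraction only,
    fits the NB model on the training rows and scores the held-out rows; a
    split whose test part lacks one of the classes is redrawn (at most 100
    attempts per split).
    """
    df = complete_cases(cohort, spec)
    fit, std, X = fit_cohort(df, spec)
    labels = df["faller"].to_numpy().astype(bool)
    insample = auc(predict_risk(fit, X), labels)

    rng = np.random.default_rng(seed)
    n = len(df)
    n_train = int(round(train_fraction * n))
    if not 0 < n_train < n:
        raise ValueError("train fraction leaves an empty train or test set")
    per_split, n_redraws = [], 0
    for _ in range(n_splits):
        for _attempt in range(100):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            te_labels = labels[te]
            if te_labels.any() and not te_labels.all() and df["fall_count"].iloc[tr].sum() > 0:
                break
            n_redraws += 1
        else:
            raise UndefinedAUCError("could not draw a two-class test split in 100 tries")
        train, test = df.iloc[tr], df.iloc[te]
        fit_tr, std_tr, X_tr = fit_cohort(train.reset_index(drop=True), spec)
        X_te = design_matrix(std_tr.transform(test.reset_index(drop=True)), spec)
        per_split.append(auc(predict_risk(fit_tr, X_te), te_labels))
    arr = np.array(per_split)
    return EvalResult(
        auc_insample=insample,
        auc_cv_mean=float(arr.mean()),
        auc_cv_sd=float(arr.std(ddof=1)),
        auc_per_split=tuple(float(a) for a in arr),
        n_splits=n_splits,
        train_fraction=train_fraction,
        n_redraws=n_redraws,
        seed=seed,
    )


def _subset_pvalues(
    df: pd.DataFrame, spec: ModelSpec, idx: np.ndarray
) -> tuple[dict[str, float], bool]:
    sub = df.iloc[idx].reset_index(drop=True)
    fit, _, _ = fit_cohort(sub, spec)
    if not fit.converged:
        return {t: 1.0 for t in spec.eliminable_terms}, False
    return {t: fit.pvalue(t) for t in spec.eliminable_terms}, True


def stability_elimination(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    n_subsets: int = 10,
    subset_fraction: float = 0.7,
    threshold: float = 0.20,
    seed: int = 0,
    one_at_a_time: bool = True,
) -> tuple[ModelSpec, list[StabilityReport]]:
    """Backward elimination by P-value stability across random 70% subsets.

    Each round fits the current specification on ``n_subsets`` independent
    random subsets (each ``subset_fraction`` of the cohort, drawn without
    replacement) and computes the mean and SD of every gait term's Wald P
    value. A term is stable when both are below ``threshold``. If every
    gait term is stable the procedure stops; otherwise the least stable
    term (largest mean P; ties broken by larger SD, then name) is removed
    and the round repeats. With ``one_at_a_time`` False, all unstable
    terms are removed simultaneously each round. The group covariate and
    intercept are never eliminated. Subsets that draw a singular design
    are redrawn; a non-converged subset fit contributes P = 1 for every
    term (conservative) and is counted in the report.
    """
    df = complete_cases(cohort, spec)
    fit_cohort(df, spec)  # full-data fit must be non-singular before starting
    rng = np.random.default_rng(seed)
    n = len(df)
    size = int(round(subset_fraction * n))
    history: list[StabilityReport] = []
    current = spec
    iteration = 0
    while True:
        if not current.eliminable_terms:
            raise EmptyModelError("elimination removed every gait term")
        pvals: dict[str, list[float]] = {t: [] for t in current.eliminable_terms}
        n_nonconv = 0
        for _ in range(n_subsets):
            for _attempt in range(100):
                idx = rng.choice(n, size=size, replace=False)
                try:
                    row, ok = _subset_pvalues(df, current, idx)
                    break
                except (SingularDesignError, DegenerateOutcomeError, ValueError, np.linalg.LinAlgError):
                    continue
            else:
                raise SingularDesignError("no fittable 70% subset in 100 draws")
            if not ok:
                n_nonconv += 1
            for t, p in row.items():
                pvals[t].append(p)
        mean_p = {t: float(np.mean(v)) for t, v in pvals.items()}
        sd_p = {t: float(np.std(v, ddof=1)) for t, v in pvals.items()}
        stable = {t: mean_p[t] < threshold and sd_p[t] < threshold for t in pvals}
        if all(stable.values()):
            history.append(
                StabilityReport(iteration, mean_p, sd_p, stable, None, n_nonconv, seed)
            )
            return current, history
        unstable = [t for t, s in stable.items() if not s]
        unstable.sort(key=lambda t: (-mean_p[t], -sd_p[t], t))
        to_remove = unstable[:1] if one_at_a_time else unstable
        for t in to_remove:
            history.append(
                StabilityReport(iteration, mean_p, sd_p, stable, t, n_nonconv, seed)
            )
            current = current.drop(t)
        iteration += 1


def add_group_interactions(spec: ModelSpec) -> ModelSpec:
    """Add group x parameter terms for every surviving main effect."""
    return replace(spec, group_interactions=spec.main_effects)


def select_candidates(
    cohort: pd.DataFrame,
    correlation,
    candidates: tuple[str, ...],
    rho_threshold: float = 0.7,
    max_terms: int | None = None,
    quantity_params: tuple[str, ...] = ("total_steps",),
    include_quantity_interactions: bool = False,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Best uncorrelated candidate subset by in-sample AUC.

    Enumerates every non-empty subset of ``candidates`` containing at most
    one parameter from any pair whose |Spearman rho| >= ``rho_threshold``,
    optionally augments each subset with quantity x parameter interaction
    terms, fits each and ranks by in-sample AUC (ties: fewer terms, then
    name order). Returns the winning spec and the scored leaderboard.
    """
    conflicts = {
        frozenset(p) for p in correlation.correlated_pairs(rho_threshold)
        if p[0] in candidates and p[1] in candidates
    }

    def admissible(subset: tuple[str, ...]) -> bool:
        return not any(
            frozenset((a, b)) in conflicts
            for i, a in enumerate(subset)
            for b in subset[i + 1 :]
        )

    subsets: list[tuple[str, ...]] = []

    def grow(prefix: tuple[str, ...], rest: tuple[str, ...]) -> None:
        if prefix:
            subsets.append(prefix)
        if max_terms is not None and len(prefix) >= max_terms:
            return
        for i, c in enumerate(rest):
            cand = prefix + (c,)
            if admissible(cand):
                grow(cand, rest[i + 1 :])

    grow((), tuple(candidates))
    rows = []
    for subset in subsets:
        qi: tuple[tuple[str, str], ...] = ()
        if include_quantity_interactions:
            qi = tuple(
                (q, p) for q in quantity_params if q in subset for p in subset if p != q
            )
        spec = ModelSpec(main_effects=subset, quantity_interactions=qi)
        df = complete_cases(cohort, spec)
        try:
            fit, _, X = fit_cohort(df, spec)
            score = auc(predict_risk(fit, X), df["faller"].to_numpy().astype(bool))
        except (SingularDesignError, DegenerateOutcomeError, ValueError):
            continue
        rows.append({"terms": subset, "n_terms": len(subset), "auc_insample": score})
    if not rows:
        raise EmptyModelError("no admissible candidate subset could be fitted")
    board = pd.DataFrame(rows).sort_values(
        by=["auc_insample", "n_terms", "terms"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    best = tuple(board.loc[0, "terms"])
    qi = ()
    if include_quantity_interactions:
        qi = tuple(
            (q, p) for q in quantity_params if q in best for p in best if p != q
        )
    return ModelSpec(main_effects=best, quantity_interactions=qi), board
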