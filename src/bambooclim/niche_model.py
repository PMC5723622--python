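"""Binomial-logit niche models: fitting, AICc all-subsets selection, LOOCV,
Youden-threshold classification, and imbalanced-classification metrics.

The occupancy model is an ordinary GLM with binomial family and logit link,
P(presence) = logit⁻¹(β·x). Model selection ranks every subset of a global
model's terms by the small-sample-corrected Akaike criterion

    AICc = -2ℓ + 2k + 2k(k+1)/(n - k - 1).

Validation scores each record out-of-fold (leave-one-out), picks the
probability cutoff that maximises Youden's J = sensitivity + specificity - 1
(robust to the presence-heavy class balance typical of roadside occupancy
surveys), and reports AUC, MCC, informedness, accuracy, sensitivity,
specificity, PPV and NPV. The classification rule is inclusive:
presence iff score >= τ.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

INTERCEPT = "intercept"

# the five temperature-related and two precipitation candidate predictors of
# the two-stage global-model protocol
TEMPERATURE_VARS = (
    "mean_annual_temp",
    "annual_min_temp",
    "annual_max_temp",
    "warmth_index",
    "coldness_index",
)
PRECIP_VARS = ("annual_precip", "growing_precip")
COMMON_VARS = ("nongrowing_precip", "radiation", "forest_ratio", "farmland_ratio")


class ModelStructureError(ValueError):
    """Invalid design matrix or response (rank deficiency, bad labels...)."""


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation prevented convergence."""

    def __init__(self, predictor: str):
        self.predictor = predictor
        super().__init__(
            f"logistic fit did not converge; predictor {predictor!r} appears "
            "to separate the classes"
        )


@dataclass(frozen=True)
class FittedNicheModel:
    """A fitted binomial-logit model with its information-criterion bookkeeping."""

    predictor_names: tuple[str, ...]  # excludes the intercept
    coefficients: dict[str, float]  # includes 'intercept'
    coefficient_covariance: np.ndarray
    log_likelihood: float
    n_obs: int
    k_params: int
    aicc: float

    def linear_predictor(self, predictors: dict[str, np.ndarray]) -> np.ndarray:
        eta = np.full_like(
            np.asarray(predictors[self.predictor_names[0]], dtype=float)
            if self.predictor_names
            else np.zeros(1),
            self.coefficients[INTERCEPT],
        )
        for name in self.predictor_names:
            eta = eta + self.coefficients[name] * np.asarray(
                predictors[name], dtype=float
            )
        return eta

    def predict_proba(self, predictors: dict[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        if isinstance(predictors, pd.DataFrame):
            predictors = {c: predictors[c].to_numpy() for c in predictors.columns}
        from scipy.special import expit

        return expit(self.linear_predictor(predictors))

    def standard_errors(self) -> dict[str, float]:
        se = np.sqrt(np.diag(self.coefficient_covariance))
        names = (INTERCEPT,) + self.predictor_names
        return dict(zip(names, se))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.fn, self.tn):
            if v < 0:
                raise ModelStructureError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Threshold-dependent metrics plus AUC; undefined ratios are NaN."""

    auc: float
    mcc: float
    informedness: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float


SEPARATION_COEF_LIMIT = 30.0  # |standardised slope| beyond which we call separation


def fit_logistic(
    X: pd.DataFrame, y: np.ndarray | pd.Series, tol: float = 1e-8, maxiter: int = 100
) -> FittedNicheModel:
    """Maximum-likelihood binomial-logit fit of presence on the given predictors.

    ``X`` holds predictor columns only; an intercept is always added. Raises
    :class:`SeparationError` (naming the most implicated predictor) when the
    likelihood has no finite maximiser, and :class:`ModelStructureError` for
    rank-deficient designs or non-binary responses.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ModelStructureError("response must be binary 0/1")
    names = tuple(X.columns)
    Xv = X.to_numpy(dtype=float)
    n = len(y)
    for j, name in enumerate(names):
        if np.std(Xv[:, j]) == 0.0:
            raise ModelStructureError(f"predictor {name!r} has zero variance")
    design = sm.add_constant(Xv, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ModelStructureError("rank-deficient design matrix")

    model = sm.GLM(y, design, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=maxiter, tol=tol)
        except Exception:
            raise SeparationError(_most_separating(Xv, y, names)) from None

    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)):
        raise SeparationError(_most_separating(Xv, y, names))
    # drifting to huge standardised slopes means the MLE is at infinity
    scales = np.concatenate([[1.0], Xv.std(axis=0)]) if names else np.array([1.0])
    if np.any(np.abs(params[1:] * scales[1:]) > SEPARATION_COEF_LIMIT):
        raise SeparationError(_most_separating(Xv, y, names))

    k = len(params)
    coeffs = {INTERCEPT: float(params[0])}
    coeffs.update({name: float(b) for name, b in zip(names, params[1:])})
    return FittedNicheModel(
        predictor_names=names,
        coefficients=coeffs,
        coefficient_covariance=np.asarray(res.cov_params()),
        log_likelihood=float(res.llf),
        n_obs=n,
        k_params=k,
        aicc=aicc(float(res.llf), k, n),
    )


def _most_separating(Xv: np.ndarray, y: np.ndarray, names: tuple[str, ...]) -> str:
    """Heuristic: the predictor whose class means differ most in SD units."""
    if not names:
        return INTERCEPT
    best, best_d = names[0], -1.0
    for j, name in enumerate(names):
        sd = Xv[:, j].std()
        if sd == 0:
            continue
        d = abs(Xv[y == 1, j].mean() - Xv[y == 0, j].mean()) / sd
        if d > best_d:
            best, best_d = name, d
    return best


def aicc(log_likelihood: float, k_params: int, n_obs: int) -> float:
    """Small-sample corrected AIC; undefined when n_obs <= k_params + 1."""
    if n_obs <= k_params + 1:
        raise ModelStructureError(
            f"AICc undefined for n={n_obs}, k={k_params} (correction term blows up)"
        )
    return (
        -2.0 * log_likelihood
        + 2.0 * k_params
        + 2.0 * k_params * (k_params + 1) / (n_obs - k_params - 1)
    )


def dredge_subsets(
    terms: tuple[str, ...] | list[str],
    data: pd.DataFrame,
    response: str = "presence",
) -> pd.DataFrame:
    """Fit every subset of ``terms`` (2^m models incl. intercept-only) and rank by AICc.

    Returns a DataFrame with columns (terms, k, logLik, AICc, deltaAICc,
    status), sorted ascending by AICc with ties broken by fewer parameters
    then lexicographic term order. Subsets that fail to converge get status
    'separated' and are pushed out of the ranking (NaN AICc, sorted last).
    """
    terms = tuple(terms)
    if len(terms) > 20:
        raise ModelStructureError("more than 20 candidate terms (2^20 cap)")
    y = data[response]
    rows = []
    for r in range(len(terms) + 1):
        for subset in itertools.combinations(terms, r):
            try:
                m = fit_logistic(data[list(subset)], y)
                rows.append(
                    {
                        "terms": " + ".join(subset) if subset else "(intercept)",
                        "k": m.k_params,
                        "logLik": m.log_likelihood,
                        "AICc": m.aicc,
                        "status": "ok",
                        "_terms": subset,
                    }
                )
            except (SeparationError, ModelStructureError) as exc:
                rows.append(
                    {
                        "terms": " + ".join(subset) if subset else "(intercept)",
                        "k": r + 1,
                        "logLik": np.nan,
                        "AICc": np.nan,
                        "status": f"separated: {exc}",
                        "_terms": subset,
                    }
                )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=["AICc", "k", "_terms"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    best = out["AICc"].min()
    out["deltaAICc"] = out["AICc"] - best
    return out.drop(columns="_terms")[
        ["terms", "k", "logLik", "AICc", "deltaAICc", "status"]
    ]


def two_stage_selection(
    data: pd.DataFrame, response: str = "presence"
) -> pd.DataFrame:
    """All-subsets search over ten global models and pooled AICc ranking.

    Each global model pairs one of the five temperature-related variables
    with one of the two precipitation variables, plus non-growing-season
    precipitation, sun radiation, and forest/farmland ratios. Every global
    model is dredged; the union of all subsets (deduplicated by term set) is
    ranked by AICc.
    """
    seen: dict[str, dict] = {}
    for temp_var in TEMPERATURE_VARS:
        for precip_var in PRECIP_VARS:
            terms = (temp_var, precip_var) + COMMON_VARS
            table = dredge_subsets(terms, data, response)
            for _, row in table.iterrows():
                key = " + ".join(sorted(row["terms"].split(" + ")))
                if key not in seen or (
                    not math.isnan(row["AICc"])
                    and (
                        math.isnan(seen[key]["AICc"]) or row["AICc"] < seen[key]["AICc"]
                    )
                ):
                    seen[key] = row.to_dict()
    pooled = pd.DataFrame(seen.values()).sort_values(
        by=["AICc", "k", "terms"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    pooled["deltaAICc"] = pooled["AICc"] - pooled["AICc"].min()
    return pooled[["terms", "k", "logLik", "AICc", "deltaAICc", "status"]]


def loocv_scores(
    terms: tuple[str, ...] | list[str],
    data: pd.DataFrame,
    response: str = "presence",
) -> np.ndarray:
    """Leave-one-out out-of-fold probabilities, in input row order.

    Record i is scored by a model fitted on every record except i.
    Non-convergent folds are scored NaN with a warning rather than failing
    the whole validation (small presence-heavy datasets can separate once a
    pivotal absence is held out).
    """
    terms = list(terms)
    n = len(data)
    if n < 3:
        raise ModelStructureError("LOOCV needs at least 3 records")
    X = data[terms].reset_index(drop=True)
    y = np.asarray(data[response], dtype=float)
    scores = np.full(n, np.nan)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            m = fit_logistic(X.loc[keep], y[keep])
        except (SeparationError, ModelStructureError) as exc:
            warnings.warn(f"LOOCV fold {i} failed ({exc}); scored as missing")
            continue
        scores[i] = m.predict_proba({t: X.loc[[i], t].to_numpy() for t in terms})[0]
    return scores


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ModelStructureError("both classes must be present")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the tie-corrected rank statistic P(s₊ > s₋) + ½P(s₊ = s₋)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def youden_candidates(scores: np.ndarray) -> np.ndarray:
    """Candidate cutoffs: midpoints between consecutive sorted unique scores,
    with -inf/+inf sentinels."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Cutoff maximising J = sensitivity + specificity - 1 under the >= rule.

    Ties in J are broken toward the smallest cutoff (favouring sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    best_tau, best_j = None, -np.inf
    for tau in youden_candidates(scores):
        c = confusion(scores, labels, tau)
        sens = c.tp / (c.tp + c.fn)
        spec = c.tn / (c.tn + c.fp)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_tau, best_j = tau, j
    return float(best_tau)


def confusion(
    scores: np.ndarray, labels: np.ndarray, tau: float
) -> ConfusionCounts:
    """2x2 counts under the inclusive rule: predict presence iff score >= tau."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= tau
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
        return float("nan")
    return num / den


def metrics(
    counts: ConfusionCounts, auc: float = float("nan"), threshold: float = float("nan")
) -> MetricsReport:
    """Full metric panel from a confusion matrix (plus externally supplied AUC).

    Any ratio with an empty margin is NaN with a warning — silent zeros
    would corrupt model ranking.
    """
    if counts.total == 0:
        raise ModelStructureError("empty confusion matrix")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if mcc_den == 0:
        warnings.warn("MCC undefined (empty margin); reported as NaN")
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricsReport(
        auc=auc,
        mcc=mcc,
        informedness=sens + spec - 1.0,
        accuracy=(tp + tn) / counts.total,
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(tp, tp + fp, "PPV"),
        npv=_ratio(tn, tn + fn, "NPV"),
        threshold=threshold,
    )


def solve_confusion(
    n_pos: int, n_neg: int, accuracy: float, informedness: float, decimals: int = 3
) -> ConfusionCounts:
    """Recover the integer confusion matrix from printed accuracy and informedness.

    Exhaustively scans TP <= n_pos, TN <= n_neg for matrices whose accuracy
    and J both round to the printed values at ``decimals`` places. Raises
    with the full candidate list if no matrix or more than one matches.
    """
    matches = []
    for tp in range(n_pos + 1):
        for tn in range(n_neg + 1):
            acc = (tp + tn) / (n_pos + n_neg)
            j = tp / n_pos + tn / n_neg - 1.0
            if round(acc, decimals) == round(accuracy, decimals) and round(
                j, decimals
            ) == round(informedness, decimals):
                matches.append(
                    ConfusionCounts(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)
                )
    if len(matches) != 1:
        raise ModelStructureError(
            f"expected exactly one confusion matrix matching accuracy="
            f"{accuracy}, informedness={informedness}; found {matches}"
        )
    return matches[0]


@dataclass(frozen=True)
class CollinearityReport:
    pairs: pd.DataFrame  # columns: var_a, var_b, r
    zero_variance: tuple[str, ...]


def collinearity_screen(
    predictors: pd.DataFrame, threshold: float = 0.7
) -> CollinearityReport:
    """Flag predictor pairs with |Pearson r| >= threshold; zero-variance
    columns are reported, not crashed on."""
    if predictors.shape[1] < 2:
        raise ModelStructureError("need at least 2 predictors to screen")
    zero_var = tuple(c for c in predictors.columns if predictors[c].std() == 0)
    live = [c for c in predictors.columns if c not in zero_var]
    corr = predictors[live].corr(method="pearson")
    rows = []
    for a, b in itertools.combinations(live, 2):
        r = corr.loc[a, b]
        if abs(r) >= threshold:
            rows.append({"var_a": a, "var_b": b, "r": float(r)})
    return CollinearityReport(
        pairs=pd.DataFrame(rows, columns=["var_a", "var_b", "r"]),
        zero_variance=zero_var,
    )
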