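"""Prediction of complete PEEP-absorber behaviour from bedside variables.

Reproduces the study's statistical pipeline: a univariate logistic screen at
alpha = 0.05 over the a-priori candidate covariates, a multiple logistic
regression with iterative VIF pruning (threshold 5, highest first), a
multinomial secondary analysis with the low-absorber class as reference, the
respiratory-rate threshold chosen by Youden's J on the RR-only ROC curve,
tenfold stratified cross-validation for an overoptimism-corrected AUROC with
bootstrap CI and a calibration mean absolute error, diagnostic 2x2 metrics
with Clopper-Pearson intervals, and the fixed published bedside score
``logit = -5 + 3.5 * [RR < 20] + 2.9 * [flow limitation]``.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2, chi2_contingency, f_oneway, fisher_exact, norm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.proportion import proportion_confint

from .config import AnalysisConfig
from .errors import DegenerateModelError

__all__ = [
    "CANDIDATE_COVARIATES",
    "LogisticFit",
    "DiagnosticMetrics",
    "ThresholdResult",
    "CVResult",
    "univariate_screen",
    "fit_multivariable",
    "choose_rr_threshold",
    "bedside_score",
    "diagnostic_metrics",
    "cross_validate",
    "fit_multinomial",
    "group_comparisons",
    "analyze_cohort",
]

# the a-priori candidate set (the published per-class characteristics table)
CANDIDATE_COVARIATES = [
    "age", "female", "bmi", "respiratory_rate", "expiratory_time",
    "minute_ventilation", "tidal_volume_per_ibw", "resistance", "elastance",
    "flow_limited", "chronic_pulmonary_disease", "acute_pulmonary_disease",
    "smoking_history", "pao2_fio2", "supine",
]

BEDSIDE_INTERCEPT = -5.0
BEDSIDE_COEF_RR_BELOW_20 = 3.5
BEDSIDE_COEF_FL = 2.9
RR_THRESHOLD = 20.0


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    table: pd.DataFrame               # coef, or, ci, p per covariate
    llf: float
    auc: float                        # apparent AUROC
    auc_corrected: float | None = None
    auc_corrected_ci: tuple | None = None
    calibration_mae: float | None = None
    dropped_for_vif: list = field(default_factory=list)
    separation_flags: list = field(default_factory=list)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        cols = [c for c in self.table.index if c != "const"]
        x = df[cols].astype(float).to_numpy()
        eta = self.table.loc["const", "coef"] + x @ self.table.loc[cols, "coef"].to_numpy()
        return expit(eta)


@dataclass
class DiagnosticMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple
    specificity_ci: tuple
    ppv_ci: tuple
    npv_ci: tuple
    counts: tuple                     # (tp, fn, fp, tn)

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
        }


@dataclass
class ThresholdResult:
    threshold: float
    youden_j: float
    informative: bool


@dataclass
class CVResult:
    auc_corrected: float
    auc_ci: tuple
    calibration_mae: float
    apparent_auc: float
    per_fold_aucs: list


# ---------------------------------------------------------------------------
# low-level logistic fitting robust to (quasi-)separation
# ---------------------------------------------------------------------------

def _null_llf(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n = len(y)
    return n * (p * np.log(p) + (1 - p) * np.log(1 - p))


def _sklearn_llf(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float]:
    clf = LogisticRegression(penalty=None, max_iter=5000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(x, y)
    probs = np.clip(clf.predict_proba(x)[:, 1], 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(probs) + (1 - y) * np.log(1 - probs)))
    params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    return params, llf


def _logit_fit(y: np.ndarray, x: pd.DataFrame):
    """ML logistic fit; falls back to an unpenalized sklearn solve when the
    IRLS path fails.  Returns (params, bse, llf, separation_flag)."""
    xc = sm.add_constant(x.astype(float), has_constant="add")
    flag = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, xc).fit(disp=0, maxiter=500, method="bfgs")
        params = res.params.to_numpy()
        bse = res.bse.to_numpy()
        llf = float(res.llf)
        if not res.mle_retvals.get("converged", True):
            flag = True
    except Exception:
        params, llf = _sklearn_llf(y, xc.to_numpy()[:, 1:])
        bse = np.full(len(params), np.nan)
        flag = True
    if np.any(np.abs(params[1:]) > 8) or np.any(~np.isfinite(bse)) \
            or np.any(bse[1:] > 10):
        flag = True
    # a binary covariate with an empty outcome cell separates quasi-completely
    for col in x.columns:
        vals = np.asarray(x[col], dtype=float)
        if set(np.unique(vals)) <= {0.0, 1.0}:
            for v in (0.0, 1.0):
                if (vals == v).any() and len(np.unique(y[vals == v])) == 1:
                    flag = True
    return params, bse, llf, flag


def _wald_p(params, bse):
    z = params / bse
    return 2 * norm.sf(np.abs(z))


# ---------------------------------------------------------------------------
# pipeline operations
# ---------------------------------------------------------------------------

def univariate_screen(cohort: pd.DataFrame, outcome: str = "label",
                      positive: str = "complete",
                      candidates: list[str] | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Single-covariate logistic fits; Wald p-values with a likelihood-ratio
    fallback on (quasi-)separation.  Adds a ``selected`` column (p < alpha).
    """
    candidates = candidates or [c for c in CANDIDATE_COVARIATES
                                if c in cohort.columns]
    y = (cohort[outcome] == positive).to_numpy(dtype=float)
    if y.min() == y.max():
        raise DegenerateModelError("outcome has a single class")
    rows = []
    for cov in candidates:
        x = cohort[[cov]].astype(float)
        if float(x[cov].std()) == 0.0:
            rows.append({"covariate": cov, "p": 1.0, "odds_ratio": np.nan,
                         "separation": False, "selected": False})
            continue
        params, bse, llf, flag = _logit_fit(y, x)
        if flag:
            p = float(chi2.sf(2.0 * (llf - _null_llf(y)), 1))
        else:
            p = float(_wald_p(params, bse)[1])
        rows.append({"covariate": cov, "p": p,
                     "odds_ratio": float(np.exp(np.clip(params[1], -500, 500))),
                     "separation": bool(flag), "selected": bool(p < alpha)})
    return pd.DataFrame(rows).set_index("covariate")


def _vif_prune(x: pd.DataFrame, threshold: float) -> tuple[pd.DataFrame, list]:
    dropped = []
    cols = list(x.columns)
    while len(cols) > 1:
        design = sm.add_constant(x[cols].astype(float), has_constant="add")
        with np.errstate(divide="ignore"):
            vifs = np.array([
                variance_inflation_factor(design.to_numpy(), i)
                for i in range(1, design.shape[1])
            ])
        vifs = np.where(np.isfinite(vifs), vifs, np.inf)
        max_v = vifs.max()
        if max_v <= threshold:
            break
        # exact collinearity gives several infinite/equal VIFs; ties resolve
        # toward dropping the covariate listed later in the candidate order
        tied = np.where((vifs >= max_v * (1 - 1e-9)) | np.isinf(vifs))[0] \
            if np.isinf(max_v) else np.where(vifs >= max_v * (1 - 1e-9))[0]
        worst = int(tied[-1])
        dropped.append((cols[worst], float(vifs[worst])))
        cols.pop(worst)
    return x[cols], dropped


def fit_multivariable(cohort: pd.DataFrame, selected: list[str],
                      outcome: str = "label", positive: str = "complete",
                      vif_threshold: float = 5.0) -> LogisticFit:
    """VIF-pruned maximum-likelihood multiple logistic regression."""
    if not selected:
        raise DegenerateModelError("no covariates selected")
    y = (cohort[outcome] == positive).to_numpy(dtype=float)
    x, dropped = _vif_prune(cohort[selected].astype(float), vif_threshold)
    params, bse, llf, flag = _logit_fit(y, x)
    names = ["const"] + list(x.columns)
    with np.errstate(over="ignore"):
        or_ = np.exp(np.clip(params, -500, 500))
        lo = np.exp(np.clip(params - 1.96 * bse, -500, 500))
        hi = np.exp(np.clip(params + 1.96 * bse, -500, 500))
    table = pd.DataFrame({
        "coef": params, "or": or_, "or_lo": lo, "or_hi": hi,
        "p": _wald_p(params, bse),
    }, index=names)
    probs = expit(sm.add_constant(x.astype(float), has_constant="add")
                  .to_numpy() @ params)
    auc = float(roc_auc_score(y, probs)) if 0 < y.mean() < 1 else float("nan")
    return LogisticFit(table=table, llf=llf, auc=auc,
                       dropped_for_vif=[d[0] for d in dropped],
                       separation_flags=[list(x.columns)] if flag else [])


def choose_rr_threshold(cohort: pd.DataFrame, outcome: str = "label",
                        positive: str = "complete",
                        rr_col: str = "respiratory_rate") -> ThresholdResult:
    """Best compromise between sensitivity and specificity (Youden's J) on
    the ROC of respiratory rate alone; positive prediction is RR below the
    threshold, ties resolved toward the lower threshold."""
    rr = cohort[rr_col].to_numpy(dtype=float)
    y = (cohort[outcome] == positive).to_numpy(dtype=bool)
    uniq = np.unique(rr)
    if len(uniq) < 2:
        raise DegenerateModelError("respiratory rate does not vary")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos, n_neg = y.sum(), (~y).sum()
    if n_pos == 0 or n_neg == 0:
        raise DegenerateModelError("outcome has a single class")
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = rr < t
        sens = (pred & y).sum() / n_pos
        spec = (~pred & ~y).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return ThresholdResult(threshold=float(best_t), youden_j=float(best_j),
                           informative=bool(best_j > 0.05))


def bedside_score(rr_below_20: bool, flow_limited: bool) -> float:
    """Published bedside probability of complete PEEP-absorber behaviour."""
    eta = (BEDSIDE_INTERCEPT
           + BEDSIDE_COEF_RR_BELOW_20 * float(bool(rr_below_20))
           + BEDSIDE_COEF_FL * float(bool(flow_limited)))
    return float(expit(eta))


def _proportion_ci(count: int, nobs: int, alpha: float = 0.05) -> tuple:
    if nobs == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="beta")
    return (float(lo), float(hi))


def diagnostic_metrics(tp: int, fn: int, fp: int, tn: int,
                       alpha: float = 0.05) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV with exact (Clopper-Pearson) CIs.

    A zero margin leaves the corresponding metric NaN rather than raising.
    """
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("counts must be non-negative")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return DiagnosticMetrics(
        sensitivity=ratio(tp, tp + fn), specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp), npv=ratio(tn, tn + fn),
        sensitivity_ci=_proportion_ci(tp, tp + fn, alpha),
        specificity_ci=_proportion_ci(tn, tn + fp, alpha),
        ppv_ci=_proportion_ci(tp, tp + fp, alpha),
        npv_ci=_proportion_ci(tn, tn + fn, alpha),
        counts=(tp, fn, fp, tn),
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fast_auc(y: np.ndarray, score: np.ndarray) -> float:
    order = np.argsort(score, kind="mergesort")
    ranks = np.empty(len(score))
    sorted_scores = score[order]
    # average ranks for ties
    ranks[order] = np.arange(1, len(score) + 1)
    i = 0
    while i < len(sorted_scores):
        j = i
        while j + 1 < len(sorted_scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        if j > i:
            ranks[order[i:j + 1]] = (i + j + 2) / 2.0
        i = j + 1
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


class BedsideModelSpec:
    """Fold-wise refit of the parsimonious bedside model: the RR threshold is
    re-chosen on the training fold (Youden's J) and a logistic model on
    [RR below threshold, flow limitation] is refitted."""

    def __init__(self, refit_threshold: bool = True,
                 threshold: float = RR_THRESHOLD):
        self.refit_threshold = refit_threshold
        self.threshold = threshold

    def features(self, df: pd.DataFrame, threshold: float) -> pd.DataFrame:
        return pd.DataFrame({
            "rr_below": (df["respiratory_rate"] < threshold).astype(float),
            "fl": df["flow_limited"].astype(float),
        }, index=df.index)

    def fit(self, train: pd.DataFrame, outcome: str = "label",
            positive: str = "complete"):
        thr = self.threshold
        if self.refit_threshold:
            try:
                thr = choose_rr_threshold(train, outcome, positive).threshold
            except DegenerateModelError:
                thr = self.threshold
        y = (train[outcome] == positive).to_numpy(dtype=float)
        x = self.features(train, thr)
        params, _, _, _ = _logit_fit(y, x)

        def predictor(test: pd.DataFrame) -> np.ndarray:
            xt = self.features(test, thr).to_numpy()
            return expit(params[0] + xt @ params[1:])

        return predictor


class ColumnsModelSpec:
    """Plain logistic model on a fixed covariate list."""

    def __init__(self, columns: list[str]):
        self.columns = list(columns)

    def fit(self, train: pd.DataFrame, outcome: str = "label",
            positive: str = "complete"):
        y = (train[outcome] == positive).to_numpy(dtype=float)
        x = train[self.columns].astype(float)
        params, _, _, _ = _logit_fit(y, x)

        def predictor(test: pd.DataFrame) -> np.ndarray:
            xt = test[self.columns].astype(float).to_numpy()
            return expit(params[0] + xt @ params[1:])

        return predictor


def _calibration_mae(y: np.ndarray, probs: np.ndarray, method: str = "lowess",
                     bins: int = 10) -> float:
    if method == "bins":
        order = np.argsort(probs)
        splits = np.array_split(order, bins)
        err = [abs(probs[idx].mean() - y[idx].mean())
               for idx in splits if len(idx)]
        return float(np.mean(err))
    uniq = np.unique(probs)
    if len(uniq) <= 16:
        # discrete score: the smoothed calibration curve degenerates to the
        # observed frequency at each distinct predicted value
        err = 0.0
        for u in uniq:
            m = probs == u
            err += m.sum() * abs(u - y[m].mean())
        return float(err / len(y))
    frac = float(np.clip(40.0 / len(y), 0.15, 2.0 / 3.0))
    # it=0: robustness iterations would treat one binary outcome class as
    # outliers and bias the smoothed event frequency
    smooth = lowess(y, probs, frac=frac, it=0, return_sorted=False)
    return float(np.mean(np.abs(probs - np.clip(smooth, 0.0, 1.0))))


def cross_validate(cohort: pd.DataFrame, model_spec=None, k: int = 10,
                   seed: int = 0, outcome: str = "label",
                   positive: str = "complete", bootstrap_reps: int = 2000,
                   pooling: str = "pooled",
                   calibration_smoother: str = "lowess",
                   alpha: float = 0.05) -> CVResult:
    """Stratified k-fold CV; the corrected AUROC is computed from pooled
    out-of-fold predictions (or the per-fold mean), its CI by stratified
    bootstrap over patients, and the calibration MAE against a smoothed
    observed-frequency curve on the out-of-fold predictions."""
    model_spec = model_spec or BedsideModelSpec()
    y = (cohort[outcome] == positive).to_numpy(dtype=int)
    if y.sum() < k or (len(y) - y.sum()) < k:
        raise DegenerateModelError(
            "too few patients in one class for stratified folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    fold_aucs = []
    for train_idx, test_idx in skf.split(cohort, y):
        predictor = model_spec.fit(cohort.iloc[train_idx], outcome, positive)
        oof[test_idx] = predictor(cohort.iloc[test_idx])
        if 0 < y[test_idx].mean() < 1:
            fold_aucs.append(_fast_auc(y[test_idx], oof[test_idx]))
    if pooling == "per_fold":
        corrected = float(np.nanmean(fold_aucs))
    else:
        corrected = _fast_auc(y, oof)
    # apparent performance: refit on the full cohort
    predictor = model_spec.fit(cohort, outcome, positive)
    apparent = _fast_auc(y, predictor(cohort))
    # stratified bootstrap CI on the pooled out-of-fold AUROC
    rng = np.random.default_rng(seed)
    pos_idx = np.where(y == 1)[0]
    neg_idx = np.where(y == 0)[0]
    boot = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        take = np.concatenate([rng.choice(pos_idx, len(pos_idx)),
                               rng.choice(neg_idx, len(neg_idx))])
        boot[b] = _fast_auc(y[take], oof[take])
    ci = (float(np.nanquantile(boot, alpha / 2)),
          float(np.nanquantile(boot, 1 - alpha / 2)))
    mae = _calibration_mae(y.astype(float), oof, calibration_smoother)
    return CVResult(auc_corrected=float(corrected), auc_ci=ci,
                    calibration_mae=mae, apparent_auc=float(apparent),
                    per_fold_aucs=[float(a) for a in fold_aucs])


# ---------------------------------------------------------------------------
# secondary analyses
# ---------------------------------------------------------------------------

def fit_multinomial(cohort: pd.DataFrame, selected: list[str],
                    outcome: str = "label") -> pd.DataFrame:
    """Multinomial logistic regression with the low-absorber class as the
    reference level; odds ratios per class versus low."""
    labels = cohort[outcome].astype(str)
    present = set(labels.unique())
    if not {"complete", "high", "low"} <= present:
        raise DegenerateModelError(
            f"all three classes required, got {sorted(present)}")
    if not selected:
        raise DegenerateModelError("no covariates selected")
    cat = pd.Categorical(labels, categories=["low", "high", "complete"])
    y = cat.codes
    x = sm.add_constant(cohort[selected].astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MNLogit(y, x).fit(disp=0, maxiter=1000, method="bfgs")
    try:
        bse_all = res.bse
    except Exception:
        # singular Hessian under (quasi-)separation: report estimates only
        bse_all = pd.DataFrame(np.nan, index=res.params.index,
                               columns=res.params.columns)
    frames = []
    for j, cls in enumerate(["high", "complete"]):
        params = res.params.iloc[:, j]
        bse = bse_all.iloc[:, j]
        with np.errstate(over="ignore"):
            frames.append(pd.DataFrame({
                "class": cls,
                "coef": params,
                "or": np.exp(np.clip(params, -500, 500)),
                "or_lo": np.exp(np.clip(params - 1.96 * bse, -500, 500)),
                "or_hi": np.exp(np.clip(params + 1.96 * bse, -500, 500)),
                "p": _wald_p(params.to_numpy(), bse.to_numpy()),
            }))
    return pd.concat(frames)


def group_comparisons(cohort: pd.DataFrame,
                      covariates: list[str] | None = None,
                      outcome: str = "label") -> pd.DataFrame:
    """Three-class comparisons: one-way ANOVA for continuous covariates and a
    chi-squared test for binary ones, with Tukey / pairwise-Fisher flags."""
    covariates = covariates or [c for c in CANDIDATE_COVARIATES
                                if c in cohort.columns]
    groups = {lab: cohort[cohort[outcome] == lab] for lab in
              ("complete", "high", "low")}
    rows = []
    for cov in covariates:
        values = cohort[cov]
        is_binary = values.dropna().isin([0, 1, True, False]).all()
        if float(values.astype(float).std()) == 0.0:
            rows.append({"covariate": cov, "p": np.nan, "test": "skipped",
                         "pairwise": ""})
            continue
        if is_binary:
            table = pd.crosstab(cohort[outcome], values.astype(bool))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(chi2_contingency(table)[1])
            flags = []
            for a, b in (("complete", "high"), ("complete", "low"),
                         ("high", "low")):
                t2 = np.array([
                    [int(groups[a][cov].astype(bool).sum()),
                     int((~groups[a][cov].astype(bool)).sum())],
                    [int(groups[b][cov].astype(bool).sum()),
                     int((~groups[b][cov].astype(bool)).sum())],
                ])
                if t2.sum(axis=1).min() > 0:
                    pf = fisher_exact(t2)[1]
                    if pf < 0.05:
                        flags.append(f"{a} vs {b}")
            rows.append({"covariate": cov, "p": p, "test": "chi2",
                         "pairwise": "; ".join(flags)})
        else:
            samples = [g[cov].astype(float).to_numpy() for g in groups.values()
                       if len(g) >= 2]
            if len(samples) < 2:
                rows.append({"covariate": cov, "p": np.nan, "test": "skipped",
                             "pairwise": ""})
                continue
            p = float(f_oneway(*samples)[1])
            flags = []
            if all(len(s) >= 2 for s in samples) and len(samples) == 3:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    tk = pairwise_tukeyhsd(cohort[cov].astype(float),
                                           cohort[outcome].astype(str))
                pairs = list(itertools.combinations(
                    range(len(tk.groupsunique)), 2))
                for (i1, i2), rej in zip(pairs, tk.reject):
                    if rej:
                        flags.append(f"{tk.groupsunique[i1]} vs "
                                     f"{tk.groupsunique[i2]}")
            rows.append({"covariate": cov, "p": p, "test": "anova",
                         "pairwise": "; ".join(flags)})
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def analyze_cohort(cohort: pd.DataFrame, config: AnalysisConfig | None = None,
                   seed: int = 0) -> dict:
    """Full statistical analysis of an analyzed cohort table.

    Rows with missing labels or failed validation are excluded first,
    mirroring the study's data-validation step.
    """
    cfg = config or AnalysisConfig()
    df = cohort.copy()
    for col, value in (("eligible", True), ("valid", True)):
        if col in df.columns:
            df = df[df[col] == value]
    df = df[df["label"].notna()].reset_index(drop=True)
    if df.empty:
        raise DegenerateModelError("no analyzable patients")

    screen = univariate_screen(df, alpha=cfg.alpha)
    selected = list(screen.index[screen["selected"]])
    results: dict = {"n": len(df), "screen": screen, "selected": selected}

    results["class_fractions"] = {
        lab: float((df["label"] == lab).mean())
        for lab in ("complete", "high", "low")
    }
    results["fl_prevalence"] = float(df["flow_limited"].mean())

    if selected:
        fit = fit_multivariable(df, selected, vif_threshold=cfg.vif_threshold)
        results["multivariable"] = fit
    thr = choose_rr_threshold(df)
    results["rr_threshold"] = thr

    cv = cross_validate(
        df, BedsideModelSpec(refit_threshold=cfg.refit_threshold_in_cv),
        k=cfg.folds, seed=seed, bootstrap_reps=cfg.bootstrap_reps,
        pooling=cfg.auroc_pooling,
        calibration_smoother=cfg.calibration_smoother, alpha=cfg.alpha)
    results["cv"] = cv

    # diagnostic 2x2 tables of the three bedside rules
    y = (df["label"] == "complete").to_numpy(dtype=bool)
    fl = df["flow_limited"].astype(bool).to_numpy()
    rr_low = (df["respiratory_rate"] < thr.threshold).to_numpy()
    results["diagnostics"] = {}
    for name, pred in (("fl", fl), ("rr_low", rr_low),
                       ("rr_low_and_fl", rr_low & fl)):
        tp = int((pred & y).sum())
        fn = int((~pred & y).sum())
        fp = int((pred & ~y).sum())
        tn = int((~pred & ~y).sum())
        results["diagnostics"][name] = diagnostic_metrics(
            tp, fn, fp, tn, alpha=cfg.alpha)

    results["group_comparisons"] = group_comparisons(df)
    multi_sel = list(results["group_comparisons"]
                     .query("p < @cfg.alpha").index)
    try:
        results["multinomial"] = fit_multinomial(df, multi_sel or selected)
    except DegenerateModelError as exc:
        results["multinomial"] = None
        results["multinomial_error"] = str(exc)
    return results
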