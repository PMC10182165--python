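"""LOOCV orchestration, the delta-radiomics baseline, and discrimination
statistics.

The evaluation protocol mirrors the motivating study: leave-one-out
cross-validation (one fold per patient), fold-safe standardization (fitted on
the N-1 training patients only, audited), the sequence model retrained M
times per fold with distinct derived seeds, and the held-out probability
summarised by its mean and variance over repeats. Discrimination is reported
as the empirical (Mann-Whitney) AUC with a DeLong 95% CI, paired model
comparison by the two-sided DeLong test, and threshold metrics
(sensitivity/specificity/PPV/NPV) with Wilson CIs.

The delta-radiomics baseline summarises each series by its last-minus-first
feature vector and classifies it with an L2-regularised logistic regression
(a substituted head standing in for the network-based classifier of the
delta-radiomics literature, which is out of scope here); the regularisation
strength is chosen by inner LOOCV over a small grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort
from .errors import DegenerateFeatureError, TrainingError, ValidationError
from .lstm import TSRHyperparams, forward, train, train_ensemble
from .preprocessing import apply_standardizer, delta_features, fit_standardizer, \
    pad_and_mask


# ---------------------------------------------------------------------------
# ROC / AUC statistics (empirical AUC + DeLong variance)
# ---------------------------------------------------------------------------

class AucCI(NamedTuple):
    auc: float
    ci_low: float
    ci_high: float


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    """Per-observation structural components V10 (cases) and V01 (controls)
    of the empirical AUC, via midranks (ties counted 1/2)."""
    labels = np.asarray(labels, dtype=int)
    pos = np.asarray(scores, dtype=float)[labels == 1]
    neg = np.asarray(scores, dtype=float)[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValidationError("AUC undefined: both classes must be present")
    combined = np.concatenate([pos, neg])
    r_all = rankdata(combined)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01


def _delong_cov(score_rows: np.ndarray, labels: np.ndarray):
    """AUCs and DeLong covariance matrix for k correlated score vectors
    (rows of score_rows) over the same observations."""
    k = score_rows.shape[0]
    m = int(np.sum(labels == 1))
    n = int(np.sum(labels == 0))
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    for r in range(k):
        v10[r], v01[r] = _delong_placements(score_rows[r], labels)
    aucs = v10.mean(axis=1)
    s10 = np.cov(v10, ddof=1) if m > 1 else np.zeros((k, k))
    s01 = np.cov(v01, ddof=1) if n > 1 else np.zeros((k, k))
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return aucs, cov


def roc_auc(probabilities, labels, alpha: float = 0.05) -> AucCI:
    """Empirical AUC (concordance with ties at 1/2) with a DeLong asymptotic
    CI truncated to [0, 1]. Degenerate variance (perfect separation) gives a
    point CI at the estimate."""
    scores = np.asarray(probabilities, dtype=float).reshape(1, -1)
    aucs, cov = _delong_cov(scores, np.asarray(labels, dtype=int))
    auc = float(aucs[0])
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    z = norm.ppf(1 - alpha / 2)
    return AucCI(auc, max(0.0, auc - z * se), min(1.0, auc + z * se))


@dataclass(frozen=True)
class PairedRocComparison:
    """Two-sided DeLong test for the difference of two correlated AUCs
    measured on the same patients."""

    auc_a: float
    auc_b: float
    diff: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float


def compare_rocs_paired(probs_a, probs_b, labels, alpha: float = 0.05) -> PairedRocComparison:
    """Paired DeLong comparison of two score vectors on identical patients.

    Identical curves have a zero-variance difference; that degenerate case is
    reported as z = 0, p = 1.
    """
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (a.shape == b.shape == y.shape):
        raise ValidationError(
            f"length mismatch: probs_a {a.shape}, probs_b {b.shape}, labels {y.shape}"
        )
    aucs, cov = _delong_cov(np.vstack([a, b]), y)
    diff = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    zcrit = norm.ppf(1 - alpha / 2)
    if var <= 1e-15:
        z = 0.0
        p = 1.0 if abs(diff) <= 1e-15 else 0.0
        half = 0.0
    else:
        se = np.sqrt(var)
        z = diff / se
        p = float(2 * norm.sf(abs(z)))
        half = zcrit * se
    return PairedRocComparison(
        auc_a=float(aucs[0]), auc_b=float(aucs[1]), diff=diff,
        ci_low=diff - half, ci_high=diff + half, z=float(z), p_value=p,
    )


# ---------------------------------------------------------------------------
# Threshold metrics
# ---------------------------------------------------------------------------

class ProportionCI(NamedTuple):
    value: float
    ci_low: float
    ci_high: float


def _wilson(count: int, nobs: int, alpha: float = 0.05) -> ProportionCI:
    if nobs == 0:
        return ProportionCI(float("nan"), float("nan"), float("nan"))
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    return ProportionCI(count / nobs, float(lo), float(hi))


def youden_threshold(probabilities, labels) -> float:
    """Threshold (among observed score values) maximising Youden's J =
    sensitivity + specificity - 1 under the rule "predict positive when
    score >= threshold"; ties broken toward the lower threshold (higher
    sensitivity)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    best_t, best_j = None, -np.inf
    for t in np.unique(p):
        pred = p >= t
        j = np.sum(pred & (y == 1)) / n1 + np.sum(~pred & (y == 0)) / n0 - 1.0
        if j > best_j or (j == best_j and best_t is not None and t < best_t):
            best_j, best_t = j, float(t)
    return best_t


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and discrimination metrics at a threshold.

    CI methods are stamped so reports are self-describing: DeLong for the
    AUC, Wilson for the proportions. Undefined proportions (empty
    denominator, e.g. NPV of an all-positive predictor) are NaN.
    """

    threshold: float
    threshold_rule: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: ProportionCI
    specificity: ProportionCI
    ppv: ProportionCI
    npv: ProportionCI
    auc: AucCI
    ci_methods: dict = field(default_factory=lambda: {"auc": "DeLong", "proportions": "Wilson"})

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.tn, self.fn)

    def summary(self) -> str:
        f = lambda m: f"{m.value:.3f} [{m.ci_low:.3f}-{m.ci_high:.3f}]"
        return "\n".join([
            f"threshold {self.threshold:.4f} ({self.threshold_rule}); "
            f"TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn}",
            f"sensitivity {f(self.sensitivity)}  specificity {f(self.specificity)}",
            f"PPV {f(self.ppv)}  NPV {f(self.npv)}",
            f"AUC {self.auc.auc:.3f} [{self.auc.ci_low:.3f}-{self.auc.ci_high:.3f}] "
            f"(CI: {self.ci_methods['auc']}/{self.ci_methods['proportions']})",
        ])

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "threshold_rule": self.threshold_rule,
            "counts": {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn},
            "sensitivity": list(self.sensitivity),
            "specificity": list(self.specificity),
            "ppv": list(self.ppv),
            "npv": list(self.npv),
            "auc": list(self.auc),
            "ci_methods": dict(self.ci_methods),
        }


def classification_metrics(probabilities, labels, threshold="youden") -> MetricsReport:
    """Dichotomise scores and report the standard discrimination measures.

    A true positive is a predicted progression in a patient with confirmed
    progression; a false positive is predicted progression in a patient with
    stable disease, and so on. ``threshold`` is either a number in [0, 1]
    (rule: positive iff score >= threshold) or ``"youden"`` (default) for the
    J-maximising point of the empirical ROC. Binary external scores (e.g. a
    dichotomised expert rating) can be passed directly as probabilities in
    {0, 1} with threshold 0.5.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValidationError("labels must contain both classes")
    if threshold == "youden":
        t = youden_threshold(p, y)
        rule = "youden"
    else:
        t = float(threshold)
        if not 0 <= t <= 1:
            raise ValidationError(f"threshold must be in [0,1], got {t}")
        rule = "fixed"
    pred = p >= t
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return MetricsReport(
        threshold=t, threshold_rule=rule, tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_wilson(tp, tp + fn),
        specificity=_wilson(tn, tn + fp),
        ppv=_wilson(tp, tp + fp),
        npv=_wilson(tn, tn + fn),
        auc=roc_auc(p, y),
    )


# ---------------------------------------------------------------------------
# LOOCV with repeat-averaged probabilities
# ---------------------------------------------------------------------------

def _derived_seed(base_seed: int, fold: int, repeat: int) -> int:
    """Deterministic per-(fold, repeat) seed, so any single repeat can be
    re-run in isolation."""
    return int(np.random.SeedSequence((base_seed, fold, repeat)).generate_state(1)[0])


@dataclass
class LOOCVResult:
    """Held-out probabilities from a leave-one-out run: per patient the mean
    and variance over M training repeats, plus a per-fold leakage audit."""

    patient_ids: list[str]
    labels: np.ndarray
    prob_mean: np.ndarray
    prob_var: np.ndarray
    per_repeat: np.ndarray            # N x M held-out probabilities
    m_repeats: int
    base_seed: int
    model_name: str
    hyper: object | None
    audit: list[dict]

    def auc(self) -> AucCI:
        return roc_auc(self.prob_mean, self.labels)

    def metrics(self, threshold="youden") -> MetricsReport:
        return classification_metrics(self.prob_mean, self.labels, threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": self.patient_ids,
            "label": self.labels,
            "prob_mean": self.prob_mean,
            "prob_var": self.prob_var,
        })

    def summary(self) -> str:
        a = self.auc()
        return (
            f"{self.model_name}: LOOCV over {len(self.patient_ids)} patients, "
            f"{self.m_repeats} repeat(s)/fold\n"
            f"AUC {a.auc:.3f} [95% CI {a.ci_low:.3f}-{a.ci_high:.3f}]"
        )


def run_loocv(cohort: Cohort, hyper: TSRHyperparams | None = None,
              m_repeats: int = 100, base_seed: int = 0) -> LOOCVResult:
    """Leave-one-out evaluation of the multistream LSTM.

    Per fold: a standardizer is fitted on the N-1 training patients and
    applied to both sides; the network is trained ``m_repeats`` times with
    distinct derived seeds; the held-out patient's probability distribution
    over repeats is summarised by mean and (population) variance. The audit
    list records, for every fold, the held-out id and the ids the
    standardizer saw — the held-out id must never appear there.
    """
    hyper = hyper or TSRHyperparams()
    n = len(cohort)
    if n < 2:
        raise ValidationError("LOOCV needs at least 2 patients")
    if m_repeats < 1:
        raise ValidationError("m_repeats must be >= 1")
    if set(cohort.labels.tolist()) != {0, 1}:
        raise ValidationError("cohort must contain both classes")

    ids = cohort.patient_ids
    per_repeat = np.empty((n, m_repeats))
    audit = []
    for i, held_out in enumerate(ids):
        train_patients = [p for p in cohort.patients if p.patient_id != held_out]
        train_labels = {p.label for p in train_patients}
        if train_labels != {0, 1}:
            raise TrainingError(
                f"fold {i} (held out {held_out}): training set is single-class"
            )
        train_ids = [p.patient_id for p in train_patients]
        scaler = fit_standardizer(cohort, train_ids)
        assert held_out not in scaler.fitted_on  # leakage guard, never disabled
        std_train = [apply_standardizer(scaler, p) for p in train_patients]
        held = next(p for p in cohort.patients if p.patient_id == held_out)
        std_held = apply_standardizer(scaler, held)
        train_batch = pad_and_mask(std_train, cohort.schema)
        held_batch = pad_and_mask([std_held], cohort.schema)
        seeds = [_derived_seed(base_seed, i, r) for r in range(m_repeats)]
        models = train_ensemble(train_batch, cohort.schema, hyper, seeds)
        for r, params in enumerate(models):
            per_repeat[i, r] = forward(held_batch, params, hyper, training=False)[0]
        audit.append({
            "fold": i,
            "held_out": held_out,
            "fitted_on": sorted(scaler.fitted_on),
            "train_ids": sorted(train_ids),
        })
    return LOOCVResult(
        patient_ids=list(ids),
        labels=cohort.labels.copy(),
        prob_mean=per_repeat.mean(axis=1),
        prob_var=per_repeat.var(axis=1, ddof=0),
        per_repeat=per_repeat,
        m_repeats=m_repeats,
        base_seed=base_seed,
        model_name="TSR (multistream LSTM)",
        hyper=hyper,
        audit=audit,
    )


# ---------------------------------------------------------------------------
# Delta-radiomics baseline (substituted L2-logistic head)
# ---------------------------------------------------------------------------

DR_C_GRID = (0.01, 0.1, 1.0, 10.0)


def _delta_matrix(patients) -> np.ndarray:
    return np.vstack([delta_features(p) for p in patients])


def _fit_dr_head(x: np.ndarray, y: np.ndarray, c_grid=DR_C_GRID) -> LogisticRegression:
    """L2 logistic regression on delta features; C chosen by inner LOOCV on
    mean held-out BCE. Refuses an all-zero (degenerate) design matrix."""
    if not np.any(np.ptp(x, axis=0) > 0):
        raise DegenerateFeatureError(
            "delta design matrix is degenerate (all delta features constant); "
            "the DR baseline cannot be fitted"
        )
    if set(np.unique(y)) != {0, 1}:
        raise TrainingError("DR training set must contain both classes")
    best_c, best_bce = None, np.inf
    n = x.shape[0]
    for c in c_grid:
        probs = np.empty(n)
        ok = True
        for i in range(n):
            idx = np.arange(n) != i
            if len(set(y[idx])) < 2:
                ok = False
                break
            clf = LogisticRegression(C=c, solver="liblinear", max_iter=500)
            clf.fit(x[idx], y[idx])
            probs[i] = clf.predict_proba(x[i:i + 1])[0, 1]
        if not ok:
            continue
        p = np.clip(probs, 1e-12, 1 - 1e-12)
        bce = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        if bce < best_bce:
            best_bce, best_c = bce, c
    if best_c is None:  # inner folds all degenerate: fall back to mid-grid C
        best_c = c_grid[len(c_grid) // 2]
    clf = LogisticRegression(C=best_c, solver="liblinear", max_iter=500)
    clf.fit(x, y)
    return clf


class DeltaRadiomicsModel:
    """Delta-radiomics classifier bound to a cohort: last-minus-first
    standardized features + L2 logistic head (substituted head)."""

    def __init__(self, cohort: Cohort, c_grid=DR_C_GRID):
        self.cohort = cohort
        self.c_grid = tuple(c_grid)

    def fit(self) -> "DRResults":
        scaler = fit_standardizer(self.cohort, self.cohort.patient_ids)
        std = apply_standardizer(scaler, self.cohort)
        x = _delta_matrix(std.patients)
        clf = _fit_dr_head(x, self.cohort.labels, self.c_grid)
        return DRResults(model=self, scaler=scaler, clf=clf)


@dataclass
class DRResults:
    model: DeltaRadiomicsModel
    scaler: object
    clf: LogisticRegression

    def predict(self, data) -> np.ndarray:
        patients = data.patients if isinstance(data, Cohort) else list(data)
        std = [apply_standardizer(self.scaler, p) for p in patients]
        return self.clf.predict_proba(_delta_matrix(std))[:, 1]

    def summary(self) -> str:
        probs = self.predict(self.model.cohort)
        a = roc_auc(probs, self.model.cohort.labels)
        return (
            "Delta-radiomics baseline (substituted L2-logistic head)\n"
            f"C = {self.clf.C}; in-sample AUC {a.auc:.3f} "
            f"[{a.ci_low:.3f}-{a.ci_high:.3f}]"
        )


def dr_baseline_loocv(cohort: Cohort, m_repeats: int = 1,
                      base_seed: int = 0, c_grid=DR_C_GRID) -> LOOCVResult:
    """LOOCV of the delta-radiomics baseline. The head is deterministic, so
    repeats collapse to one fit per fold regardless of ``m_repeats`` (the
    collapse is recorded in the result)."""
    n = len(cohort)
    if n < 2:
        raise ValidationError("LOOCV needs at least 2 patients")
    if any(p.n_visits < 2 for p in cohort.patients):
        raise ValidationError("DR baseline needs T_i >= 2 for every patient")
    ids = cohort.patient_ids
    probs = np.empty(n)
    audit = []
    for i, held_out in enumerate(ids):
        train_patients = [p for p in cohort.patients if p.patient_id != held_out]
        if {p.label for p in train_patients} != {0, 1}:
            raise TrainingError(
                f"fold {i} (held out {held_out}): training set is single-class"
            )
        train_ids = [p.patient_id for p in train_patients]
        scaler = fit_standardizer(cohort, train_ids)
        assert held_out not in scaler.fitted_on
        std_train = [apply_standardizer(scaler, p) for p in train_patients]
        held = next(p for p in cohort.patients if p.patient_id == held_out)
        std_held = apply_standardizer(scaler, held)
        x = _delta_matrix(std_train)
        y = np.array([p.label for p in train_patients])
        clf = _fit_dr_head(x, y, c_grid)
        probs[i] = clf.predict_proba(_delta_matrix([std_held]))[0, 1]
        audit.append({
            "fold": i,
            "held_out": held_out,
            "fitted_on": sorted(scaler.fitted_on),
            "train_ids": sorted(train_ids),
        })
    return LOOCVResult(
        patient_ids=list(ids),
        labels=cohort.labels.copy(),
        prob_mean=probs,
        prob_var=np.zeros(n),
        per_repeat=probs[:, None],
        m_repeats=1,  # deterministic head: repeats collapse
        base_seed=base_seed,
        model_name="DR-baseline (substituted head)",
        hyper=None,
        audit=audit,
    )


# ---------------------------------------------------------------------------
# Hyperparameter random search under LOOCV
# ---------------------------------------------------------------------------

def tune_random_search(cohort: Cohort, search_space: dict, n_draws: int,
                       seed: int = 0, m_repeats: int = 1):
    """Random-sampling hyperparameter search scored by mean held-out BCE
    under LOOCV.

    ``search_space`` maps TSRHyperparams field names (e.g. ``hidden_units``,
    ``dropout_rate``, ``learning_rate``, ``epochs``) to finite candidate
    lists; each draw samples one value per dimension. Returns ``(best_hyper,
    trace)`` with the full per-draw trace as a DataFrame.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    if not search_space:
        raise ValidationError("search_space must be non-empty")
    rng = np.random.default_rng(seed)
    keys = sorted(search_space)
    rows = []
    best_hyper, best_bce = None, np.inf
    for draw in range(n_draws):
        choice = {k: search_space[k][int(rng.integers(len(search_space[k])))]
                  for k in keys}
        hyper = TSRHyperparams(**choice)
        res = run_loocv(cohort, hyper, m_repeats=m_repeats,
                        base_seed=_derived_seed(seed, draw, 0))
        p = np.clip(res.prob_mean, 1e-12, 1 - 1e-12)
        y = res.labels
        bce = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        rows.append({**choice, "mean_bce": bce, "auc": res.auc().auc, "draw": draw})
        if bce < best_bce:
            best_bce, best_hyper = bce, hyper
    return best_hyper, pd.DataFrame(rows)
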