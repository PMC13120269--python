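"""ROC decision analysis: DeLong inference, operating points, logistic models,
and resampling-based internal validation.

Rule direction is explicit.  A marker where *low* values predict the positive
class (e.g. the intratumoral/peritumoral ADC ratio, where restricted tumor
diffusion signals nodal metastasis) classifies ``score <= cutoff`` as
positive; a ``high_predicts_positive`` marker classifies ``score >= cutoff``
as positive.  Internally scores are oriented so that higher always means more
likely positive, and cutoffs are mapped back to the original scale for
reporting.

The empirical AUC uses the Mann-Whitney estimator with tie weight 1/2; its
variance and the covariance between paired markers follow the DeLong
placement-value decomposition.  Fixed-sensitivity / fixed-specificity
operating points are *achieved* empirical points, never interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    ParameterError,
    SeparationError,
    ValidationError,
)

LOW = "low_predicts_positive"
HIGH = "high_predicts_positive"


# ---------------------------------------------------------------------------
# ROC construction
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    metric: str
    rule_direction: str
    scores: np.ndarray        # original scale
    labels: np.ndarray        # 0/1
    cutoffs: np.ndarray       # original scale; one per operating point
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int

    @property
    def _internal(self) -> np.ndarray:
        return -self.scores if self.rule_direction == LOW else self.scores


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(scores) & pd.notna(labels)
    scores, labels = scores[keep], labels[keep].astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InsufficientDataError(
            f"both classes required, got {n_pos} positives / {n_neg} negatives"
        )
    return scores, labels, n_pos, n_neg


def roc(scores, labels, rule_direction: str = HIGH,
        metric: str = "") -> ROCCurve:
    """Empirical ROC over every unique score threshold (plus the trivial
    classify-none point), honoring the declared rule direction."""
    if rule_direction not in (LOW, HIGH):
        raise ParameterError(f"unknown rule direction {rule_direction!r}")
    scores, labels, n_pos, n_neg = _check_scores_labels(scores, labels)
    s = -scores if rule_direction == LOW else scores
    thresholds = np.unique(s)[::-1]                     # descending
    # positive iff s >= t; prepend a sentinel above the max -> (sens 0, spec 1)
    sens = np.empty(len(thresholds) + 1)
    spec = np.empty(len(thresholds) + 1)
    cuts = np.empty(len(thresholds) + 1)
    sens[0], spec[0], cuts[0] = 0.0, 1.0, np.inf
    pos = s[labels == 1]
    neg = s[labels == 0]
    for i, t in enumerate(thresholds, start=1):
        sens[i] = np.mean(pos >= t)
        spec[i] = np.mean(neg < t)
        cuts[i] = t
    cutoffs = -cuts if rule_direction == LOW else cuts
    return ROCCurve(metric=metric, rule_direction=rule_direction,
                    scores=scores, labels=labels, cutoffs=cutoffs,
                    sensitivity=sens, specificity=spec,
                    n_pos=n_pos, n_neg=n_neg)


def auc_empirical(scores, labels, rule_direction: str = HIGH) -> float:
    """Mann-Whitney AUC with tie weight 1/2 (equivalent to the ROC sweep)."""
    scores, labels, n_pos, n_neg = _check_scores_labels(scores, labels)
    s = -scores if rule_direction == LOW else scores
    ranks = stats.rankdata(s)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# DeLong inference
# ---------------------------------------------------------------------------

@dataclass
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_vs_half: float
    variance: float
    degenerate: bool = False


def _placements(curve: ROCCurve) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    s = curve._internal
    pos = s[curve.labels == 1]
    neg = s[curve.labels == 0]
    # psi(x, y) = 1 if x > y, 1/2 if x == y, 0 otherwise
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def delong_auc_inference(curve: ROCCurve, level: float = 0.95) -> AUCResult:
    """AUC with DeLong variance, Wald CI (truncated to [0,1]) and two-sided
    p against the chance value 0.5."""
    if curve.n_pos < 2 or curve.n_neg < 2:
        raise InsufficientDataError("need >= 2 subjects in each class")
    v10, v01, auc = _placements(curve)
    var = float(np.var(v10, ddof=1) / curve.n_pos +
                np.var(v01, ddof=1) / curve.n_neg)
    z_crit = stats.norm.ppf(0.5 + level / 2)
    if var <= 0:
        p = 1.0 if auc == 0.5 else float(np.nextafter(0, 1))
        return AUCResult(auc=auc, ci_low=auc, ci_high=auc, p_vs_half=p,
                         variance=0.0, degenerate=True)
    se = np.sqrt(var)
    z = (auc - 0.5) / se
    p = float(2 * stats.norm.sf(abs(z)))
    return AUCResult(
        auc=auc,
        ci_low=float(max(0.0, auc - z_crit * se)),
        ci_high=float(min(1.0, auc + z_crit * se)),
        p_vs_half=p,
        variance=var,
    )


def delong_compare(curve_a: ROCCurve, curve_b: ROCCurve) -> float:
    """Two-sided DeLong p-value for the paired AUC difference of two markers
    measured on the same subjects."""
    if (len(curve_a.labels) != len(curve_b.labels)
            or not np.array_equal(curve_a.labels, curve_b.labels)):
        raise ValidationError("curves must share the same subjects and labels")
    v10a, v01a, auc_a = _placements(curve_a)
    v10b, v01b, auc_b = _placements(curve_b)
    m, n = curve_a.n_pos, curve_a.n_neg
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 1.0 if auc_a == auc_b else float(np.nextafter(0, 1))
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Operating points and confusion reconstruction
# ---------------------------------------------------------------------------

@dataclass
class OperatingPoint:
    strategy: str
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    degenerate: bool = False


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


def _rates_from_counts(tp, fp, fn, tn):
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    acc = (tp + tn) / (tp + fp + fn + tn)
    return float(ppv), float(npv), float(acc)


def _point_at_index(curve: ROCCurve, i: int, strategy: str) -> OperatingPoint:
    sens, spec = float(curve.sensitivity[i]), float(curve.specificity[i])
    tp = int(round(sens * curve.n_pos))
    tn = int(round(spec * curve.n_neg))
    fn, fp = curve.n_pos - tp, curve.n_neg - tn
    ppv, npv, acc = _rates_from_counts(tp, fp, fn, tn)
    return OperatingPoint(strategy=strategy, cutoff=float(curve.cutoffs[i]),
                          sensitivity=sens, specificity=spec,
                          ppv=ppv, npv=npv, accuracy=acc)


def youden_cutoff(curve: ROCCurve) -> OperatingPoint:
    """Cutoff maximizing J = sensitivity + specificity - 1; ties go to higher
    specificity, then to the lower cutoff; a flat J = 0 curve is flagged."""
    j = curve.sensitivity + curve.specificity - 1.0
    # lexicographic argmax: J, then specificity, then -cutoff
    order = sorted(
        range(len(j)),
        key=lambda i: (j[i], curve.specificity[i], -curve.cutoffs[i]),
        reverse=True,
    )
    best = order[0]
    point = _point_at_index(curve, best, "youden")
    if np.max(j) <= 0:
        point.degenerate = True
    return point


def operating_point_at(curve: ROCCurve, strategy: str,
                       target: float | None = None) -> OperatingPoint:
    """Operating point by strategy.

    ``fixed_specificity``: the achieved point with the smallest specificity
    >= target (the closest attainable from above), breaking ties toward
    higher sensitivity; ``fixed_sensitivity`` is symmetric.  No interpolation
    between empirical points is performed.
    """
    if strategy == "youden":
        return youden_cutoff(curve)
    if strategy not in ("fixed_specificity", "fixed_sensitivity"):
        raise ParameterError(f"unknown strategy {strategy!r}")
    if target is None or not (0 < target <= 1):
        raise ParameterError(f"target must lie in (0, 1], got {target}")
    if strategy == "fixed_specificity":
        primary, secondary = curve.specificity, curve.sensitivity
    else:
        primary, secondary = curve.sensitivity, curve.specificity
    ok = np.where(primary >= target)[0]
    # spec=1 (or sens=1) is always achievable at an extreme threshold
    best_primary = primary[ok].min()
    cands = ok[primary[ok] == best_primary]
    best = cands[np.argmax(secondary[cands])]
    label = f"{strategy}({target:g})"
    return _point_at_index(curve, int(best), label)


def confusion_from_rates(sensitivity: float, specificity: float,
                         n_pos: int, n_neg: int):
    """Reconstruct integer confusion counts from printed sensitivity and
    specificity via half-up rounding, and derive PPV/NPV/accuracy.

    Returns ``(ConfusionCounts, ppv, npv, accuracy)``.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ParameterError("rates must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ParameterError("need at least one subject per class")
    tp = int(np.floor(sensitivity * n_pos + 0.5))
    tn = int(np.floor(specificity * n_neg + 0.5))
    fn, fp = n_pos - tp, n_neg - tn
    ppv, npv, acc = _rates_from_counts(tp, fp, fn, tn)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn), ppv, npv, acc


def apply_frozen_threshold(scores, labels, cutoff: float,
                           rule_direction: str = LOW) -> OperatingPoint:
    """Evaluate a previously frozen cutoff on a new cohort without refitting."""
    if not np.isfinite(cutoff):
        raise ParameterError("cutoff must be finite")
    scores, labels, n_pos, n_neg = _check_scores_labels(scores, labels)
    if rule_direction == LOW:
        pred = scores <= cutoff
    elif rule_direction == HIGH:
        pred = scores >= cutoff
    else:
        raise ParameterError(f"unknown rule direction {rule_direction!r}")
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn, tn = n_pos - tp, n_neg - fp
    ppv, npv, acc = _rates_from_counts(tp, fp, fn, tn)
    return OperatingPoint(strategy="frozen", cutoff=float(cutoff),
                          sensitivity=tp / n_pos, specificity=tn / n_neg,
                          ppv=ppv, npv=npv, accuracy=acc)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

@dataclass
class PredictorEffect:
    name: str
    scaling: str          # "per_0.1" | "per_doubling" | "identity"
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LogisticModelResult:
    effects: list[PredictorEffect]
    model_auc: float
    n: int


def fit_logistic(outcome, predictors: pd.DataFrame,
                 scaling: dict[str, str] | None = None) -> LogisticModelResult:
    """Maximum-likelihood logistic regression with interpretable scalings.

    ``scaling`` maps predictor name to "per_0.1" (coefficient reported per
    +0.1 unit, the convention for ADC/rADC/ratio metrics), "per_doubling"
    (predictor entered as log2, e.g. tumor volume), or "identity".
    Perfect separation aborts with a :class:`SeparationError`.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    scaling = scaling or {}
    y = np.asarray(outcome, dtype=float)
    X = predictors.copy().astype(float)
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[keep], X.loc[keep]
    if len(y) < 10:
        raise InsufficientDataError(f"need n >= 10, got {len(y)}")
    if len(np.unique(y)) != 2:
        raise InsufficientDataError("outcome must contain both classes")
    for col in X.columns:
        how = scaling.get(col, "identity")
        if how == "per_0.1":
            X[col] = X[col] / 0.1
        elif how == "per_doubling":
            X[col] = np.log2(X[col])
        elif how != "identity":
            raise ParameterError(f"unknown scaling {how!r} for {col}")
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            fit = sm.Logit(y, design).fit(disp=0, method="newton", maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError, RuntimeWarning) as e:
            raise SeparationError(f"logistic fit failed to converge: {e}") from e
    if not fit.mle_retvals.get("converged", True) or \
            np.any(np.abs(fit.params.drop("const")) > 50):
        raise SeparationError("perfect separation detected (diverging coefficients)")
    ci = fit.conf_int()
    effects = []
    for col in X.columns:
        effects.append(PredictorEffect(
            name=col,
            scaling=scaling.get(col, "identity"),
            odds_ratio=float(np.exp(fit.params[col])),
            ci_low=float(np.exp(ci.loc[col, 0])),
            ci_high=float(np.exp(ci.loc[col, 1])),
            p_value=float(fit.pvalues[col]),
        ))
    model_auc = auc_empirical(fit.predict(design), y, HIGH)
    return LogisticModelResult(effects=effects, model_auc=model_auc, n=int(len(y)))


# ---------------------------------------------------------------------------
# Internal validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    apparent_auc: float
    cv_mean_auc: float
    cv_sd: float
    cv_fold_sd: float
    bootstrap_corrected_auc: float
    bootstrap_ci: tuple[float, float]
    optimism: float
    cutoff_bootstrap_median: float
    cutoff_bootstrap_iqr: tuple[float, float]
    seed: int


def _stratified_folds(labels: np.ndarray, folds: int, rng: np.random.Generator):
    """Index lists for one repeat of stratified k-fold assignment."""
    assign = np.empty(len(labels), dtype=int)
    for cls in (0, 1):
        idx = np.where(labels == cls)[0]
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return [np.where(assign == f)[0] for f in range(folds)]


def validate_internal(scores, labels, rule_direction: str = LOW,
                      folds: int = 5, repeats: int = 200,
                      n_boot: int = 2000, seed: int = 0) -> ValidationResult:
    """Repeated stratified k-fold CV plus bootstrap optimism correction for a
    single-marker rule (no refitting: the marker itself is the score).

    Per repeat, the AUC is the mean of the test-fold AUCs; ``cv_mean_auc`` /
    ``cv_sd`` summarize the repeat-level values (``cv_fold_sd`` keeps the
    fold-level dispersion).  Bootstrap optimism is the mean over resamples of
    (AUC on the resample) - (AUC of the resample-derived rule on the original
    data); for a fixed marker the resample-derived rule is the marker itself.
    The Youden cutoff is recomputed on every resample for cutoff stability.
    Fully reproducible from ``seed``.
    """
    scores, labels, n_pos, n_neg = _check_scores_labels(scores, labels)
    if min(n_pos, n_neg) < folds:
        raise ParameterError(
            f"each class needs >= {folds} members for {folds}-fold CV"
        )
    apparent = auc_empirical(scores, labels, rule_direction)

    cv_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    repeat_aucs = np.empty(repeats)
    fold_aucs = []
    for r in range(repeats):
        per_fold = []
        for test_idx in _stratified_folds(labels, folds, cv_rng):
            per_fold.append(
                auc_empirical(scores[test_idx], labels[test_idx], rule_direction)
            )
        fold_aucs.extend(per_fold)
        repeat_aucs[r] = np.mean(per_fold)

    boot_rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n = len(scores)
    boot_aucs = np.empty(n_boot)
    optimisms = np.empty(n_boot)
    cutoffs = np.empty(n_boot)
    b = 0
    while b < n_boot:
        idx = boot_rng.integers(0, n, size=n)
        lab_b = labels[idx]
        if lab_b.min() == lab_b.max():
            continue  # resample lost a class; redraw
        sc_b = scores[idx]
        auc_b = auc_empirical(sc_b, lab_b, rule_direction)
        boot_aucs[b] = auc_b
        optimisms[b] = auc_b - apparent   # fixed rule: original AUC unchanged
        curve_b = roc(sc_b, lab_b, rule_direction)
        cutoffs[b] = youden_cutoff(curve_b).cutoff
        b += 1

    optimism = float(np.mean(optimisms))
    ci = (float(np.percentile(boot_aucs, 2.5)),
          float(np.percentile(boot_aucs, 97.5)))
    return ValidationResult(
        apparent_auc=apparent,
        cv_mean_auc=float(np.mean(repeat_aucs)),
        cv_sd=float(np.std(repeat_aucs, ddof=1)),
        cv_fold_sd=float(np.std(fold_aucs, ddof=1)),
        bootstrap_corrected_auc=apparent - optimism,
        bootstrap_ci=ci,
        optimism=optimism,
        cutoff_bootstrap_median=float(np.median(cutoffs)),
        cutoff_bootstrap_iqr=(float(np.percentile(cutoffs, 25)),
                              float(np.percentile(cutoffs, 75))),
        seed=seed,
    )
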