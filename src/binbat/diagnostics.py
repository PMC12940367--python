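"""Cohort-level diagnostic statistics.

Implements the evaluation layer of the assay: exclusion of IgE
non-responders (clinically allergic patients whose basophils do not
respond to anti-IgE in vitro), one-sided unpaired Wilcoxon rank-sum
comparisons of allergic versus tolerant groups, ROC curves with AUC as
the Mann-Whitney probability, Youden-optimal operating cutoffs,
confusion-matrix metrics (sensitivity, specificity, PPV, NPV) with
Wilson score intervals, the serum sIgE clamping rule, and a three-way
reactivity categorization.

Orientation is fixed throughout to "higher marker value => allergic";
markers that anti-discriminate trigger a warning rather than a silent
reversal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.proportion import proportion_confint

from .exceptions import BinbatError, DataIntegrityError

EXACT_MAX_N = 12  # combined-size bound for the exact rank-sum p-value

#: Default three-way reactivity class boundaries (low, high) per marker kind.
REACTIVITY_BOUNDARIES = {"bat": (5.0, 35.0), "sige": (0.35, 17.5)}
REACTIVITY_SYMBOLS = {"negative": "↓", "intermediate": "→", "high": "↑"}


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 contingency of predicted vs OFC status (positives = allergic)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0 or int(v) != v:
                raise ValueError("confusion-matrix counts must be non-negative integers")

    @property
    def n_allergic(self) -> int:
        return self.tp + self.fn

    @property
    def n_tolerant(self) -> int:
        return self.tn + self.fp


@dataclass
class RocCurve:
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff": self.cutoffs, "sensitivity": self.sensitivity,
                             "specificity": self.specificity})


@dataclass
class DiagnosticSummary:
    """Per-marker diagnostic accuracy (Table-1-style row)."""

    marker: str
    unit: str
    auc: float
    cutoff: float
    wilcoxon_p: float
    sensitivity: tuple  # (value, ci_low, ci_high); value NaN if undefined
    specificity: tuple
    ppv: tuple
    npv: tuple
    matrix: ConfusionMatrix
    wilcoxon_method: str = ""


@dataclass
class ReactivityClass:
    marker: str
    patient_id: str
    value: float
    label: str  # {negative, intermediate, high}
    symbol: str
    boundaries: tuple


# ---------------------------------------------------------------------------
# non-responder exclusion
# ---------------------------------------------------------------------------

def exclude_nonresponders(
    patients: list,
    activation: pd.DataFrame,
    threshold: float = 5.0,
) -> tuple[list, list]:
    """Flag and remove allergic patients without an anti-IgE response.

    ``activation`` needs columns ``patient_id``, ``condition`` and
    ``pct_cd63_pos``; replicate anti-IgE rows are averaged.  An allergic
    patient whose mean anti-IgE %CD63+ is below ``threshold`` is a
    non-responder: confirmed clinical reactivity without in-vitro
    CD63 response, hence uninterpretable by this assay and excluded
    from diagnostic evaluation.  Tolerant patients are never removed.
    Returns the evaluable patients and an exclusion log.
    """
    anti = activation[activation["condition"] == "anti_IgE"]
    mean_anti = anti.groupby("patient_id")["pct_cd63_pos"].mean()
    evaluable, log = [], []
    for p in patients:
        if p.status == "allergic":
            if p.patient_id not in mean_anti.index:
                raise DataIntegrityError(
                    f"allergic patient {p.patient_id} lacks an anti-IgE sample")
            value = float(mean_anti.loc[p.patient_id])
            if value < threshold:
                p.non_responder = True
                log.append({"patient_id": p.patient_id, "anti_ige_pct": value,
                            "reason": f"anti-IgE %CD63+ {value:.2f} < {threshold}"})
                continue
            p.non_responder = False
        evaluable.append(p)
    return evaluable, log


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    p: float
    statistic: float  # Mann-Whitney U of the first sample
    method: str  # {exact, asymptotic}


def wilcoxon_rank_sum(x, y, alternative: str = "greater") -> WilcoxonResult:
    """Unpaired one-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p-value over all C(m+n, m) rank assignments when the combined
    sample size is at most 12 and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.  The
    method used is recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise BinbatError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    combined = np.concatenate([x, y])
    ties = np.unique(combined).size < combined.size
    if combined.size <= EXACT_MAX_N and not ties:
        res = mannwhitneyu(x, y, alternative=alternative, method="exact")
        return WilcoxonResult(p=float(res.pvalue), statistic=float(res.statistic),
                              method="exact")
    res = mannwhitneyu(x, y, alternative=alternative, method="asymptotic",
                       use_continuity=True)
    return WilcoxonResult(p=float(res.pvalue), statistic=float(res.statistic),
                          method="asymptotic")


def mann_whitney_auc(scores_pos, scores_neg) -> float:
    """AUC as the Mann-Whitney probability.

    AUC = [#(pos > neg) + 0.5 * #(pos = neg)] / (n_pos * n_neg),
    computed via midranks so ties contribute half.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise BinbatError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# ROC / Youden / predictive values
# ---------------------------------------------------------------------------

def roc_and_youden(
    scores,
    labels,
    *,
    tie_break: str = "specificity",
) -> tuple[RocCurve, float, ConfusionMatrix]:
    """ROC over candidate cutoffs and the Youden-optimal operating point.

    Candidate cutoffs are the midpoints between consecutive sorted
    unique scores plus -inf/+inf sentinels; prediction is "score >=
    cutoff => allergic".  Youden's J = sensitivity + specificity - 1 is
    maximized; ties are broken toward higher specificity (fewer false
    positives) by default, toward higher sensitivity with
    ``tie_break='sensitivity'``.  A maximal J <= 0 triggers an
    anti-discrimination warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise BinbatError("both classes must be present for ROC analysis")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cutoffs = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.empty(cutoffs.size)
    spec = np.empty(cutoffs.size)
    for i, c in enumerate(cutoffs):
        pred = scores >= c
        sens[i] = (pred & labels).sum() / n_pos
        spec[i] = (~pred & ~labels).sum() / n_neg
    j = sens + spec - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    if tie_break == "specificity":
        eq = candidates[spec[candidates] >= spec[candidates].max() - 1e-12]
        best = int(eq.max())  # equal specificity: prefer the higher cutoff
    elif tie_break == "sensitivity":
        eq = candidates[sens[candidates] >= sens[candidates].max() - 1e-12]
        best = int(eq.min())
    else:
        raise ValueError("tie_break must be 'specificity' or 'sensitivity'")
    if best_j <= 0:
        warnings.warn(
            "marker does not discriminate in the expected orientation "
            "(higher value => allergic); maximal Youden J <= 0", stacklevel=2)
    cut = float(cutoffs[best])
    pred = scores >= cut
    matrix = ConfusionMatrix(
        tp=int((pred & labels).sum()), fp=int((pred & ~labels).sum()),
        tn=int((~pred & ~labels).sum()), fn=int((~pred & labels).sum()))
    auc = mann_whitney_auc(scores[labels], scores[~labels])
    return RocCurve(cutoffs=cutoffs, sensitivity=sens, specificity=spec, auc=auc), cut, matrix


def _proportion_with_ci(count: int, nobs: int, alpha: float = 0.05) -> tuple:
    if nobs == 0:
        return (float("nan"), float("nan"), float("nan"))
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    return (count / nobs, float(lo), float(hi))


def predictive_values(matrix: ConfusionMatrix, alpha: float = 0.05) -> dict:
    """Sensitivity, specificity, PPV and NPV with 95% Wilson score CIs.

    Metrics with a zero denominator are reported as NaN triples rather
    than raising.
    """
    return {
        "sensitivity": _proportion_with_ci(matrix.tp, matrix.tp + matrix.fn, alpha),
        "specificity": _proportion_with_ci(matrix.tn, matrix.tn + matrix.fp, alpha),
        "ppv": _proportion_with_ci(matrix.tp, matrix.tp + matrix.fp, alpha),
        "npv": _proportion_with_ci(matrix.tn, matrix.tn + matrix.fn, alpha),
    }


def matrix_from_rates(
    sensitivity: float,
    specificity: float,
    n_allergic: int,
    n_tolerant: int,
    decimals: int = 2,
) -> ConfusionMatrix:
    """Reconstruct the unique integer confusion matrix behind printed rates.

    Finds the TP in [0, n_allergic] whose sensitivity rounds to the
    printed value at the given precision (and likewise TN for
    specificity); raises if no count or more than one matches, so a
    reconstruction is only returned when it is unambiguous.
    """
    tol = 0.5 * 10.0 ** (-decimals) + 1e-12

    def _unique_count(rate: float, n: int, what: str) -> int:
        hits = [k for k in range(n + 1) if abs(k / n - rate) < tol]
        if len(hits) != 1:
            raise BinbatError(
                f"{what} {rate} with n={n} has {len(hits)} integer solutions; "
                "cannot reconstruct an unambiguous matrix")
        return hits[0]

    tp = _unique_count(sensitivity, n_allergic, "sensitivity")
    tn = _unique_count(specificity, n_tolerant, "specificity")
    return ConfusionMatrix(tp=tp, fp=n_tolerant - tn, tn=tn, fn=n_allergic - tp)


# ---------------------------------------------------------------------------
# sIgE handling and reactivity classes
# ---------------------------------------------------------------------------

def clamp_sige(value):
    """Clamp serum sIgE (kU/L) to the assay's reportable range.

    Values < 0.1 are set to 0.05 and values > 100 to 101; negatives are
    rejected.  Accepts scalars or arrays.
    """
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValueError("sIgE values must be >= 0")
    out = np.where(v < 0.1, 0.05, np.where(v > 100.0, 101.0, v))
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def classify_reactivity(
    marker: str,
    value: float,
    *,
    patient_id: str = "",
    kind: str = "bat",
    boundaries: tuple | None = None,
) -> ReactivityClass:
    """Three-way reactivity class: negative (<low), intermediate, high (>high).

    Default boundaries: BAT %CD63+ 5/35; sIgE 0.35/17.5 kU/L.  The
    boundaries used are echoed in the result since they are
    configuration, not a published rule.
    """
    if boundaries is None:
        if kind not in REACTIVITY_BOUNDARIES:
            raise ValueError(f"unknown marker kind {kind!r}")
        boundaries = REACTIVITY_BOUNDARIES[kind]
    lo, hi = boundaries
    if not lo < hi:
        raise ValueError("class boundaries must be strictly increasing")
    if value < lo:
        label = "negative"
    elif value > hi:
        label = "high"
    else:
        label = "intermediate"
    return ReactivityClass(marker=marker, patient_id=patient_id, value=float(value),
                           label=label, symbol=REACTIVITY_SYMBOLS[label],
                           boundaries=(float(lo), float(hi)))


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

#: marker name -> (kind, unit) for the default Table-1-style panel
DEFAULT_MARKERS = {
    "bat_gluten": ("bat", "%CD63+"),
    "bat_wheat": ("bat", "%CD63+"),
    "bat_gliadin": ("bat", "%CD63+"),
    "sige_tri_a_19": ("sige", "kU/L"),
    "sige_wheat_f4": ("sige", "kU/L"),
    "sige_gluten_f79": ("sige", "kU/L"),
}


def cohort_report(
    data: pd.DataFrame,
    markers: dict | None = None,
    *,
    tie_break: str = "specificity",
) -> tuple[list, pd.DataFrame]:
    """Per-marker diagnostic summaries and per-patient reactivity classes.

    ``data`` holds one row per evaluable patient with columns
    ``patient_id``, ``status`` and one column per marker; sIgE markers
    are clamped before analysis.  Markers with missing values are
    dropped with a warning.  Returns a list of
    :class:`DiagnosticSummary` and the classification table.
    """
    markers = markers if markers is not None else {
        m: kv for m, kv in DEFAULT_MARKERS.items() if m in data.columns}
    if "status" not in data.columns:
        raise DataIntegrityError("cohort table needs a 'status' column")
    is_allergic = (data["status"] == "allergic").to_numpy()
    if is_allergic.sum() < 2 or (~is_allergic).sum() < 2:
        raise BinbatError("need at least 2 patients per class")

    summaries, class_rows = [], []
    for marker, (kind, unit) in markers.items():
        if marker not in data.columns or data[marker].isna().any():
            warnings.warn(f"marker {marker} missing values; excluded from report",
                          stacklevel=2)
            continue
        values = data[marker].to_numpy(dtype=float)
        if kind == "sige":
            values = clamp_sige(values)
        test = wilcoxon_rank_sum(values[is_allergic], values[~is_allergic],
                                 alternative="greater")
        roc, cutoff, matrix = roc_and_youden(values, is_allergic, tie_break=tie_break)
        pv = predictive_values(matrix)
        summaries.append(DiagnosticSummary(
            marker=marker, unit=unit, auc=roc.auc, cutoff=cutoff,
            wilcoxon_p=test.p, wilcoxon_method=test.method,
            sensitivity=pv["sensitivity"], specificity=pv["specificity"],
            ppv=pv["ppv"], npv=pv["npv"], matrix=matrix))
        for pid, v in zip(data["patient_id"], values):
            rc = classify_reactivity(marker, v, patient_id=pid, kind=kind)
            class_rows.append({"patient_id": pid, "marker": marker, "value": v,
                               "class": rc.label, "symbol": rc.symbol,
                               "boundary_low": rc.boundaries[0],
                               "boundary_high": rc.boundaries[1]})
    return summaries, pd.DataFrame(class_rows)


def summaries_to_frame(summaries: list) -> pd.DataFrame:
    """Flatten diagnostic summaries to a Table-1-style frame."""
    rows = []
    for s in summaries:
        rows.append({
            "marker": s.marker, "unit": s.unit,
            "npv": s.npv[0], "npv_ci_low": s.npv[1], "npv_ci_high": s.npv[2],
            "ppv": s.ppv[0], "ppv_ci_low": s.ppv[1], "ppv_ci_high": s.ppv[2],
            "cutoff": s.cutoff, "p_wilcoxon": s.wilcoxon_p,
            "sensitivity": s.sensitivity[0], "sensitivity_ci_low": s.sensitivity[1],
            "sensitivity_ci_high": s.sensitivity[2],
            "specificity": s.specificity[0], "specificity_ci_low": s.specificity[1],
            "specificity_ci_high": s.specificity[2],
            "auc": s.auc,
            "tp": s.matrix.tp, "fp": s.matrix.fp, "tn": s.matrix.tn, "fn": s.matrix.fn,
        })
    return pd.DataFrame(rows)
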