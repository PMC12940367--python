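"""Per-sample activation quantification.

The central convention: each patient's CD63 positivity cutoff is
anchored on their own unstimulated negative control so that the control
itself reads (at most) 1% CD63+ basophils.  Stimulated samples are then
quantified as the percentage of gated basophils at or above that
cutoff, and a response is called positive at >= 5% (inclusive).  The
same anchoring idea, with a valley-derived cutoff fixed at baseline, is
used for the CD32 time course around oral food challenges, whose values
are normalized so the baseline reads exactly 70%.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .events import StimulationCondition
from .exceptions import BinbatError, UnimodalDensityError
from .gating import valley_threshold

ANCHOR_PCT = 1.0
POSITIVITY_THRESHOLD = 5.0
CD32_ANCHOR = 70.0


@dataclass
class ActivationResult:
    """Anchored CD63 quantification of one sample."""

    patient_id: str
    condition: StimulationCondition
    cutoff: float
    pct_cd63_pos: float
    positive: bool
    n_basophils: int
    replicate: int = 1

    def __post_init__(self):
        if not 0.0 <= self.pct_cd63_pos <= 100.0:
            raise ValueError("%CD63+ must be in [0, 100]")


@dataclass
class DoseResponseCurve:
    """Ordered dose/%CD63+ points for one patient and allergen."""

    patient_id: str
    allergen: str
    concentrations: list
    pct_cd63_pos: list
    replicate_sd: list | None = None

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if len(c) != len(self.pct_cd63_pos):
            raise ValueError("length mismatch")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class ReplicateStats:
    condition: str
    values: list
    mean: float
    sd: float  # sample SD (n-1 denominator)


@dataclass
class CD32Timecourse:
    """Raw and baseline-normalized %CD32+ over an OFC series."""

    patient_id: str
    outcome: str  # {allergic_reaction, tolerant_uneventful}
    timepoints: list
    raw_pct: list
    normalized_pct: list | None = None
    anchor: float = CD32_ANCHOR


# ---------------------------------------------------------------------------
# CD63 anchoring
# ---------------------------------------------------------------------------

def anchor_cd63_cutoff(neg_control_cd63, anchor_pct: float = ANCHOR_PCT) -> float:
    """Anchored CD63 cutoff from a negative-control basophil sample.

    Nearest-rank-above convention: with n values and anchor a%, the
    cutoff is the k-th largest value where k = floor(n*a/100), so that
    at most a% of the control's own events are >= cutoff.  Ties at the
    cutoff are resolved by moving it strictly above the tied value (the
    control then reads below a% rather than above).  With k = 0 the
    cutoff is placed just above the maximum.
    """
    v = np.asarray(neg_control_cd63, dtype=float)
    if v.size == 0:
        raise BinbatError("cannot anchor a cutoff on an empty negative control")
    if not 0.0 < anchor_pct < 50.0:
        raise ValueError("anchor percentage must be in (0, 50)")
    if v.size < 100:
        warnings.warn(
            f"anchoring on only {v.size} basophil events; cutoff will be coarse",
            stacklevel=2)
    k = int(np.floor(v.size * anchor_pct / 100.0))
    s = np.sort(v)[::-1]
    if k == 0:
        return float(np.nextafter(s[0], np.inf))
    cand = s[k - 1]
    if np.count_nonzero(v >= cand) > k:
        warnings.warn(
            "ties at the anchored cutoff; placing cutoff strictly above the tied value",
            stacklevel=2)
        return float(np.nextafter(cand, np.inf))
    return float(cand)


def percent_activated(cd63_values, cutoff: float) -> float:
    """Percentage of basophils with CD63 >= cutoff."""
    v = np.asarray(cd63_values, dtype=float)
    if v.size == 0:
        raise BinbatError("cannot compute %CD63+ of an empty sample")
    return 100.0 * np.count_nonzero(v >= cutoff) / v.size


def positivity(pct: float, threshold: float = POSITIVITY_THRESHOLD) -> bool:
    """Positive BAT response call at >= threshold percent (inclusive)."""
    if not 0.0 <= pct <= 100.0:
        raise ValueError("percentage must be in [0, 100]")
    return pct >= threshold


def evaluate_sample(
    patient_id: str,
    condition: StimulationCondition,
    basophil_cd63,
    cutoff: float,
    *,
    threshold: float = POSITIVITY_THRESHOLD,
    replicate: int = 1,
) -> ActivationResult:
    """Quantify one stimulated sample against a pre-anchored cutoff."""
    v = np.asarray(basophil_cd63, dtype=float)
    pct = percent_activated(v, cutoff)
    return ActivationResult(
        patient_id=patient_id, condition=condition, cutoff=float(cutoff),
        pct_cd63_pos=pct, positive=positivity(pct, threshold),
        n_basophils=int(v.size), replicate=replicate)


def replicate_stats(values, condition: str = "") -> ReplicateStats:
    """Mean and sample SD (n-1 denominator) of replicate %CD63+ values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise BinbatError("replicate statistics require at least 2 values")
    return ReplicateStats(condition=condition, values=v.tolist(),
                          mean=float(v.mean()), sd=float(v.std(ddof=1)))


# ---------------------------------------------------------------------------
# CD32 quantification and time-course normalization
# ---------------------------------------------------------------------------

def cd32_cutoff(baseline_cd32, *, quantile_fallback: float = 0.5) -> float:
    """CD32 positivity cutoff from the baseline sample (valley strategy).

    The cutoff is fixed at baseline and reused across a patient's
    timepoints, so time-course changes reflect biology rather than gate
    drift.  If the baseline density is unimodal, a quantile fallback is
    used with a warning.
    """
    v = np.asarray(baseline_cd32, dtype=float)
    if v.size == 0:
        raise BinbatError("empty baseline CD32 sample")
    try:
        return valley_threshold(v, "above")
    except UnimodalDensityError:
        warnings.warn("unimodal CD32 density; falling back to quantile cutoff",
                      stacklevel=2)
        return float(np.quantile(v, quantile_fallback))


def percent_cd32(basophil_cd32, cutoff: float) -> float:
    """Percentage of basophils with CD32 >= cutoff."""
    v = np.asarray(basophil_cd32, dtype=float)
    if v.size == 0:
        raise BinbatError("cannot compute %CD32+ of an empty sample")
    return 100.0 * np.count_nonzero(v >= cutoff) / v.size


def normalize_timecourse(series: CD32Timecourse, anchor: float = CD32_ANCHOR) -> CD32Timecourse:
    """Scale a CD32 time course so the baseline reads exactly ``anchor``.

    Every raw value is multiplied by anchor / baseline; normalizing an
    already-normalized series is the identity (the baseline is already
    at the anchor).
    """
    raw = np.asarray(series.raw_pct, dtype=float)
    if len(series.timepoints) != raw.size:
        raise BinbatError("timepoint/value length mismatch")
    if "baseline" not in series.timepoints:
        raise BinbatError("series lacks a baseline timepoint")
    base = raw[series.timepoints.index("baseline")]
    if base <= 0:
        raise BinbatError("baseline %CD32+ must be > 0 for normalization")
    source = (np.asarray(series.normalized_pct, dtype=float)
              if series.normalized_pct is not None else raw)
    base_src = source[series.timepoints.index("baseline")]
    norm = source * (anchor / base_src)
    return replace(series, normalized_pct=norm.tolist(), anchor=float(anchor))


def dose_response(
    patient_id: str,
    allergen: str,
    results: list,
) -> DoseResponseCurve:
    """Assemble a dose-response curve from per-sample activation results.

    ``results`` holds :class:`ActivationResult` objects for allergen
    conditions of one patient/allergen; replicates at the same dose are
    averaged and their sample SD reported (NaN for singletons).
    """
    by_dose: dict = {}
    for r in results:
        c = r.condition
        if c.kind != "allergen" or c.allergen != allergen:
            raise BinbatError(f"result for {c.label} does not belong to allergen {allergen}")
        by_dose.setdefault(float(c.concentration), []).append(r.pct_cd63_pos)
    doses = sorted(by_dose)
    means = [float(np.mean(by_dose[d])) for d in doses]
    sds = [float(np.std(by_dose[d], ddof=1)) if len(by_dose[d]) > 1 else float("nan")
           for d in doses]
    return DoseResponseCurve(patient_id=patient_id, allergen=allergen,
                             concentrations=doses, pct_cd63_pos=means,
                             replicate_sd=sds)
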