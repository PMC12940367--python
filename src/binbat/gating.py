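"""Automated basophil identification within whole-blood event tables.

Basophils are gated as SSC-low AND FceRIa-high (optionally refined by
CD32-high).  Two strategies are provided:

``valley``
    Places each threshold at the minimum of a smoothed 1-D histogram
    between the relevant pair of density modes (Silverman-rule
    bandwidth).  This is the default because the assay's analysis is
    automated, but no published gating rule exists for it; the method
    is a replacement, not a reconstruction, and all thresholds are
    reported for reproducibility.

``quantile``
    Deterministic fallback using configured quantiles of each channel.

Thresholds are inclusive on the basophil side: an event is gated if
SSC <= ssc_threshold and FceRIa >= fceri_threshold.  Gating operates on
the floored-log10 display scale; raw tables are transformed internally,
so masks are invariant to whether the caller pre-transformed the data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .events import CD32, FCERI, LOG10_FLOOR, RAW, SSC, EventTable, default_display_transform
from .exceptions import DataIntegrityError, GatingError, UnimodalDensityError

DEFAULT_MIN_EVENTS = 10_000
DEFAULT_MIN_BASOPHILS = 300


@dataclass
class BasophilGate:
    """Result of automated basophil gating on one event table."""

    ssc_threshold: float
    fceri_threshold: float
    cd32_threshold: float | None
    mask: np.ndarray
    strategy: str
    scale: str = LOG10_FLOOR  # scale the thresholds are expressed on
    qc: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        for thr in (self.ssc_threshold, self.fceri_threshold):
            if not np.isfinite(thr):
                raise ValueError("gate thresholds must be finite")

    @property
    def n_basophils(self) -> int:
        return int(self.mask.sum())

    @property
    def basophil_fraction(self) -> float:
        return self.n_basophils / self.mask.size if self.mask.size else 0.0

    def report(self) -> dict:
        return {
            "strategy": self.strategy,
            "scale": self.scale,
            "ssc_threshold": float(self.ssc_threshold),
            "fceri_threshold": float(self.fceri_threshold),
            "cd32_threshold": None if self.cd32_threshold is None else float(self.cd32_threshold),
            "n_events": int(self.mask.size),
            "n_basophils": self.n_basophils,
            "basophil_fraction": self.basophil_fraction,
            **self.qc,
        }


def valley_threshold(
    values: np.ndarray,
    side: str,
    *,
    bins: int = 256,
    bandwidth: float | None = None,
    prominence: float = 0.5,
    depth_ratio: float = 0.5,
    rel_height: float = 0.05,
) -> float:
    """Place a threshold at the density valley between two modes.

    ``side='above'`` separates a (possibly rare) high mode from the bulk:
    the rightmost detected peak is the target and the highest peak the
    reference.  ``side='below'`` separates the bulk high mode (to be
    excluded, e.g. granulocytes on SSC) from everything below it.

    The histogram is smoothed with a Gaussian kernel whose bandwidth
    follows Silverman's rule unless given; peaks are detected on
    log1p(counts) so rare modes are not drowned out, with a prominence
    filter.  A candidate valley must dip below ``depth_ratio`` times the
    smaller flanking peak; if no adequately separated mode pair exists,
    :class:`UnimodalDensityError` is raised (the quantile strategy is
    the deterministic fallback).  The returned threshold is the midpoint
    of the minimal plateau between the chosen peaks.
    """
    if side not in ("above", "below"):
        raise ValueError("side must be 'above' or 'below'")
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise GatingError("too few events for density estimation")
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise UnimodalDensityError(
            "degenerate (constant) channel; consider strategy='quantile'")
    counts, edges = np.histogram(v, bins=bins, range=(lo, hi))
    bin_w = edges[1] - edges[0]
    if bandwidth is None:
        sd = np.std(v)
        iqr = np.subtract(*np.percentile(v, [75, 25]))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bandwidth = 0.9 * spread * v.size ** (-0.2)
    sigma = max(bandwidth / bin_w, 1.0)
    smooth = gaussian_filter1d(counts.astype(float), sigma)
    centers = (edges[:-1] + edges[1:]) / 2.0

    peaks, _ = find_peaks(np.log1p(smooth), prominence=prominence)
    if peaks.size < 2:
        raise UnimodalDensityError(
            "fewer than two density modes detected; consider strategy='quantile'")

    def _valley_between(a: int, b: int) -> tuple[float, float] | None:
        left, right = sorted((a, b))
        seg = smooth[left:right + 1]
        vmin = seg.min()
        if vmin >= depth_ratio * min(smooth[a], smooth[b]):
            return None
        flat = np.flatnonzero(seg <= vmin + 1e-12 * max(vmin, 1.0))
        mid = left + int(flat[len(flat) // 2])
        return centers[mid], vmin

    if side == "above":
        for target in peaks[:0:-1]:  # rightmost first; needs a peak to its left
            left = peaks[peaks < target]
            ref = int(left[np.argmax(smooth[left])])
            got = _valley_between(ref, int(target))
            if got is not None:
                return float(got[0])
        raise UnimodalDensityError(
            "no adequately separated high mode found; consider strategy='quantile'")

    # side == 'below': exclude the rightmost dominant mode
    dominant = peaks[smooth[peaks] >= rel_height * smooth[peaks].max()]
    if dominant.size < 1:
        raise UnimodalDensityError("no dominant mode found")
    ref = int(dominant[-1])
    left_peaks = peaks[peaks < ref]
    if left_peaks.size == 0:
        raise UnimodalDensityError(
            "no mode below the dominant high mode; consider strategy='quantile'")
    target = int(left_peaks[np.argmax(smooth[left_peaks])])
    got = _valley_between(target, ref)
    if got is None:
        raise UnimodalDensityError(
            "modes insufficiently separated; consider strategy='quantile'")
    return float(got[0])


def threshold_gate(
    table: EventTable,
    ssc_threshold: float,
    fceri_threshold: float,
    cd32_threshold: float | None = None,
) -> np.ndarray:
    """Boolean basophil mask for explicit thresholds (inclusive on the
    basophil side: SSC <= thr, FceRIa >= thr, optionally CD32 >= thr)."""
    mask = (table.values(SSC) <= ssc_threshold) & (table.values(FCERI) >= fceri_threshold)
    if cd32_threshold is not None:
        mask &= table.values(CD32) >= cd32_threshold
    return mask


def auto_gate(
    table: EventTable,
    strategy: str = "valley",
    *,
    min_events: int = DEFAULT_MIN_EVENTS,
    min_basophils: int = DEFAULT_MIN_BASOPHILS,
    refine_cd32: bool = False,
    ssc_quantile: float = 0.85,
    fceri_quantile: float = 0.995,
    cd32_quantile: float = 0.5,
    on_unimodal: str = "error",
    valley_params: dict | None = None,
) -> BasophilGate:
    """Identify basophils as SSC-low / FceRIa-high events.

    ``on_unimodal`` controls behaviour when the valley strategy cannot
    find a separated FceRIa-high mode: ``"error"`` (default) raises
    :class:`UnimodalDensityError` suggesting the quantile fallback;
    ``"empty"`` returns an all-false gate flagged by QC, which lets
    batch pipelines continue past samples without a basophil mode.
    CD32 refinement (off by default) intersects a CD32-high mask from
    the same strategy.
    """
    if strategy not in ("valley", "quantile"):
        raise ValueError(f"unknown gating strategy {strategy!r}")
    if on_unimodal not in ("error", "empty"):
        raise ValueError("on_unimodal must be 'error' or 'empty'")
    if table.n_events < min_events:
        warnings.warn(
            f"only {table.n_events} events (< {min_events}); gate thresholds may be unstable",
            stacklevel=2)

    work = default_display_transform(table)
    ssc, fceri = work.values(SSC), work.values(FCERI)
    vp = valley_params or {}

    empty_reason = None
    if strategy == "quantile":
        ssc_thr = float(np.quantile(ssc, ssc_quantile))
        fceri_thr = float(np.quantile(fceri, fceri_quantile))
    else:
        try:
            ssc_thr = valley_threshold(ssc, "below", **vp)
        except UnimodalDensityError:
            # SSC without a separated high mode: keep everything on SSC.
            ssc_thr = float(ssc.max())
        try:
            fceri_thr = valley_threshold(fceri, "above", **vp)
        except UnimodalDensityError as exc:
            if on_unimodal == "error":
                raise
            fceri_thr = float(fceri.max())
            empty_reason = str(exc)

    cd32_thr = None
    if refine_cd32 and empty_reason is None:
        cd32 = work.values(CD32)
        if strategy == "quantile":
            cd32_thr = float(np.quantile(cd32, cd32_quantile))
        else:
            try:
                cd32_thr = valley_threshold(cd32, "above", **vp)
            except UnimodalDensityError:
                warnings.warn("CD32 density unimodal; refinement skipped", stacklevel=2)

    if empty_reason is not None:
        mask = np.zeros(table.n_events, dtype=bool)
    else:
        mask = threshold_gate(work, ssc_thr, fceri_thr, cd32_thr)

    gate = BasophilGate(
        ssc_threshold=ssc_thr, fceri_threshold=fceri_thr, cd32_threshold=cd32_thr,
        mask=mask, strategy=strategy,
        qc={"unimodal_fceri": empty_reason} if empty_reason else {},
    )
    gate.qc.update(gate_qc(gate, min_basophils))
    return gate


def apply_gate(table: EventTable, gate: BasophilGate) -> EventTable:
    """Return the basophil subset of ``table`` selected by ``gate``."""
    if gate.mask.shape != (table.n_events,):
        raise DataIntegrityError(
            f"gate built for {gate.mask.size} events, table has {table.n_events}")
    return table.subset(
        gate.mask,
        provenance=f"basophil gate ({gate.strategy}): "
                   f"SSC<={gate.ssc_threshold:.4g}, FceRIa>={gate.fceri_threshold:.4g}")


def gate_qc(gate: BasophilGate, min_basophils: int = DEFAULT_MIN_BASOPHILS) -> dict:
    """Pass/fail QC on the gated basophil count (inclusive minimum)."""
    ok = gate.n_basophils >= min_basophils
    report = {"qc_pass": bool(ok), "min_basophils": int(min_basophils)}
    if not ok:
        report["qc_reason"] = (
            f"only {gate.n_basophils} basophil events gated (minimum {min_basophils})")
    return report
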