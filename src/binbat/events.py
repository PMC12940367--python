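"""Event-level cytometry data model, readers/writers, and axis transforms.

The in-memory container is :class:`EventTable`, a thin wrapper around a
pandas DataFrame of per-cell intensities with an explicit per-channel
transform state, so that threshold-based downstream steps (gating,
anchoring, binning) always know which scale they operate on and
double-transforming is rejected.

Canonical semantic marker names used throughout the package are ``SSC``
(side scatter), ``FceRIa`` (high-affinity IgE receptor alpha chain, the
basophil identification marker), ``CD63`` (degranulation/activation
marker) and ``CD32`` (FcgRIIB, inhibitory IgG receptor).  A
:class:`ChannelMap` translates instrument/file channel identifiers into
these names; mapping is always explicit configuration, never guessed
from fluorophore labels.

CSV is the canonical interchange format (header row of channel names,
one row per event).  FCS 3.0/3.1 support is read-only and deliberately
strict: linear list-mode only, unsupported features raise rather than
being silently ignored.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    ChannelMissingError,
    DataIntegrityError,
    TransformStateError,
    UnsupportedFCSError,
)

# Canonical semantic marker names.
SSC = "SSC"
FCERI = "FceRIa"
CD63 = "CD63"
CD32 = "CD32"
MARKERS = (SSC, FCERI, CD63, CD32)

RAW = "raw"
LOG10_FLOOR = "log10_floor"
ARCSINH = "arcsinh"
TRANSFORMS = (RAW, LOG10_FLOOR, ARCSINH)


@dataclass(frozen=True)
class ChannelMap:
    """Mapping from semantic marker name to file channel identifier."""

    mapping: dict

    def __post_init__(self):
        missing = [m for m in MARKERS if m not in self.mapping]
        if missing:
            raise ChannelMissingError(
                f"channel map must cover all semantic markers; missing {missing}"
            )
        values = list(self.mapping.values())
        if len(set(values)) != len(values):
            raise DataIntegrityError("channel map values must be unique")

    @classmethod
    def identity(cls) -> "ChannelMap":
        return cls({m: m for m in MARKERS})

    def __getitem__(self, marker: str) -> str:
        return self.mapping[marker]


@dataclass
class EventTable:
    """Per-cell marker intensities for one sample.

    Parameters
    ----------
    data
        ``n_events x n_channels`` frame of finite, non-missing
        intensities (arbitrary units).
    transforms
        Per-channel transform state, one of ``raw``, ``log10_floor``,
        ``arcsinh``.  Channels not listed default to ``raw``.
    metadata
        Free-form sample metadata (sample record, gate provenance, ...).
    truth
        Optional ground-truth sidecar (same row order as ``data``) with
        planted population / activation labels; only present for
        synthetic data.
    """

    data: pd.DataFrame
    transforms: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    truth: pd.DataFrame | None = None

    def __post_init__(self):
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.isna().to_numpy().any():
            raise DataIntegrityError("event table contains missing values")
        for c in self.data.columns:
            if not np.issubdtype(self.data[c].dtype, np.number):
                raise DataIntegrityError(f"channel {c!r} is not numeric")
        full = {c: RAW for c in self.data.columns}
        for c, state in self.transforms.items():
            if state not in TRANSFORMS:
                raise ValueError(f"unknown transform state {state!r}")
            full[c] = state
        self.transforms = full
        if self.truth is not None and len(self.truth) != len(self.data):
            raise DataIntegrityError("truth sidecar length mismatch")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list:
        return list(self.data.columns)

    def values(self, channel: str) -> np.ndarray:
        if channel not in self.data.columns:
            raise ChannelMissingError(f"channel {channel!r} not in table")
        return self.data[channel].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray, provenance: str | None = None) -> "EventTable":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_events,):
            raise DataIntegrityError(
                f"mask length {mask.shape} does not match table with {self.n_events} events"
            )
        meta = dict(self.metadata)
        if provenance:
            prov = list(meta.get("provenance", []))
            prov.append(provenance)
            meta["provenance"] = prov
        truth = self.truth.loc[mask].reset_index(drop=True) if self.truth is not None else None
        return EventTable(
            data=self.data.loc[mask].reset_index(drop=True),
            transforms=dict(self.transforms),
            metadata=meta,
            truth=truth,
        )


@dataclass(frozen=True)
class StimulationCondition:
    """One stimulation condition of the BAT panel.

    ``kind`` is one of ``negative_control``, ``allergen``, ``anti_IgE``,
    ``fMLP``.  A concentration (ug/mL) is carried if and only if the
    condition is an allergen stimulation.
    """

    kind: str
    allergen: str | None = None
    concentration: float | None = None

    KINDS = ("negative_control", "allergen", "anti_IgE", "fMLP")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown condition kind {self.kind!r}")
        if self.kind == "allergen":
            if self.allergen is None or self.concentration is None:
                raise ValueError("allergen condition requires allergen name and concentration")
            if self.concentration <= 0:
                raise ValueError("allergen concentration must be > 0")
        else:
            if self.concentration is not None:
                raise ValueError(f"{self.kind} condition must not carry a concentration")

    @property
    def label(self) -> str:
        if self.kind == "allergen":
            conc = f"{self.concentration:g}".replace(".", "p")
            return f"{self.allergen}_{conc}"
        return self.kind


@dataclass
class SampleRecord:
    """One stimulated (or control) sample of one patient."""

    patient_id: str
    condition: StimulationCondition
    replicate: int = 1
    timepoint: str | None = None  # OFC series tag
    path: str | None = None


@dataclass
class PatientRecord:
    """One study participant."""

    patient_id: str
    cohort: str  # {child, adult}
    status: str  # OFC outcome: {allergic, tolerant}
    sige: dict = field(default_factory=dict)  # marker -> kU/L
    non_responder: bool | None = None  # derived (or planted, for synthetic data)

    def __post_init__(self):
        if self.cohort not in ("child", "adult"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.status not in ("allergic", "tolerant"):
            raise ValueError(f"unknown OFC status {self.status!r}")
        for marker, v in self.sige.items():
            if v < 0:
                raise ValueError(f"negative sIgE for {marker}")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def transform(
    table: EventTable,
    channel: str,
    method: str,
    *,
    floor: float = 1.0,
    cofactor: float = 150.0,
) -> EventTable:
    """Return a new table with ``channel`` moved from raw to a display scale.

    ``log10_floor`` maps v -> log10(max(v, floor)); ``arcsinh`` maps
    v -> asinh(v / cofactor).  Both are strictly monotone on the floored
    domain, so thresholds convert consistently between scales.
    Re-transforming an already transformed channel raises
    :class:`TransformStateError`.
    """
    if channel not in table.channels:
        raise ChannelMissingError(f"channel {channel!r} not in table")
    if table.transforms[channel] != RAW:
        raise TransformStateError(
            f"channel {channel!r} already on {table.transforms[channel]} scale"
        )
    v = table.values(channel)
    if method == LOG10_FLOOR:
        if floor <= 0:
            raise ValueError("floor must be > 0")
        out = np.log10(np.maximum(v, floor))
    elif method == ARCSINH:
        if cofactor <= 0:
            raise ValueError("cofactor must be > 0")
        out = np.arcsinh(v / cofactor)
    else:
        raise ValueError(f"unknown transform method {method!r}")
    data = table.data.copy()
    data[channel] = out
    transforms = dict(table.transforms)
    transforms[channel] = method
    return EventTable(data=data, transforms=transforms,
                      metadata=dict(table.metadata), truth=table.truth)


def default_display_transform(table: EventTable, *, floor: float = 1.0) -> EventTable:
    """Apply the default display/gating scale: log10 (floored) everywhere.

    Fluorescence channels are conventionally viewed on a log-like scale;
    SSC is included because the log map is strictly monotone and keeps
    all four axes comparable for valley finding and square binning.
    Channels already transformed are left untouched.
    """
    out = table
    for c in out.channels:
        if out.transforms[c] == RAW:
            out = transform(out, c, LOG10_FLOOR, floor=floor)
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_events_csv(path, channel_map: ChannelMap | None = None) -> EventTable:
    """Read an event CSV (header = channel names, one row per event).

    If ``channel_map`` is given, the four mapped channels are selected
    and renamed to the canonical semantic names; a missing channel
    raises :class:`ChannelMissingError` naming it.  Non-numeric cells
    raise :class:`DataIntegrityError` with the offending row index.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if channel_map is not None:
        for marker in MARKERS:
            col = channel_map[marker]
            if col not in df.columns:
                raise ChannelMissingError(
                    f"{path.name}: required channel {col!r} (marker {marker}) missing from header"
                )
        df = df[[channel_map[m] for m in MARKERS]]
        df.columns = list(MARKERS)
    for c in df.columns:
        if not np.issubdtype(df[c].dtype, np.number):
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = coerced.isna() & df[c].notna()
            if bad.any():
                row = int(np.argmax(bad.to_numpy()))
                raise DataIntegrityError(
                    f"{path.name}: non-numeric value in channel {c!r} at row {row}"
                )
            df[c] = coerced
    return EventTable(data=df.astype(float), metadata={"source": str(path)})


def write_events_csv(table: EventTable, path, float_format: str | None = "%.7g") -> None:
    """Write the event table as CSV.

    The default format keeps 7 significant digits, the stated precision
    of the interchange format; pass ``float_format=None`` for full
    (bit-exact) round trips.
    """
    table.data.to_csv(path, index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 read-only support (linear list-mode subset)
# ---------------------------------------------------------------------------

_DTYPES = {"F": ("f", 32), "D": ("d", 64)}


def _parse_text_segment(raw: bytes) -> dict:
    if not raw:
        raise DataIntegrityError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise DataIntegrityError("TEXT segment has an odd number of fields")
    kw = {}
    for k, v in zip(parts[::2], parts[1::2]):
        key = k.decode("ascii", "replace").strip().upper()
        kw[key] = v.decode("ascii", "replace").strip()
    return kw


def read_fcs(path, channel_map: ChannelMap | None = None) -> EventTable:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventTable`.

    Supported subset: ``$MODE=L``, ``$DATATYPE`` F/D/I, linear
    amplification (``$PnE = 0,0``) on every parameter, a single data
    segment.  Anything else raises :class:`UnsupportedFCSError`; an
    event count inconsistent with the DATA segment length raises
    :class:`DataIntegrityError`.  CSV is the canonical fallback format
    (see :func:`read_events_csv`).
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 58:
        raise DataIntegrityError(f"{path.name}: file too short for an FCS header")
    version = raw[0:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise UnsupportedFCSError(f"{path.name}: unsupported FCS version {version!r}")

    def _offset(a, b):
        s = raw[a:b].decode("ascii", "replace").strip()
        return int(s) if s else 0

    text_beg, text_end = _offset(10, 18), _offset(18, 26)
    data_beg, data_end = _offset(26, 34), _offset(34, 42)
    kw = _parse_text_segment(raw[text_beg:text_end + 1])

    if kw.get("$MODE", "L") != "L":
        raise UnsupportedFCSError(f"{path.name}: only list mode ($MODE=L) is supported")
    dtype_code = kw.get("$DATATYPE")
    if dtype_code not in ("F", "D", "I"):
        raise UnsupportedFCSError(f"{path.name}: unsupported $DATATYPE {dtype_code!r}")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise UnsupportedFCSError(f"{path.name}: unsupported $BYTEORD {byteord!r}")

    names, bits = [], []
    for i in range(1, n_par + 1):
        pne = kw.get(f"$P{i}E", "0,0")
        decades = pne.split(",")[0]
        if float(decades) != 0.0:
            raise UnsupportedFCSError(
                f"{path.name}: parameter {i} declares log amplification ($P{i}E={pne}); "
                "only linear amplification is supported"
            )
        names.append(kw.get(f"$P{i}N", f"P{i}"))
        bits.append(int(kw.get(f"$P{i}B", "32")))

    if dtype_code in _DTYPES:
        code, need_bits = _DTYPES[dtype_code]
        if any(b != need_bits for b in bits):
            raise UnsupportedFCSError(f"{path.name}: $PnB must be {need_bits} for type {dtype_code}")
        np_dtype = np.dtype(f"{endian}{code}{need_bits // 8}")
    else:  # integer
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise UnsupportedFCSError(f"{path.name}: integer data requires uniform $PnB of 16 or 32")
        np_dtype = np.dtype(f"{endian}u{bits[0] // 8}")

    if data_beg == 0 and data_end == 0:
        data_beg = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    seg = raw[data_beg:data_end + 1]
    need = n_par * n_tot * np_dtype.itemsize
    if len(seg) < need:
        raise DataIntegrityError(
            f"{path.name}: DATA segment holds {len(seg)} bytes but $TOT={n_tot} x $PAR={n_par} "
            f"requires {need}"
        )
    if len(seg) > need and len(seg) - need >= np_dtype.itemsize:
        raise DataIntegrityError(
            f"{path.name}: DATA segment length {len(seg)} inconsistent with $TOT={n_tot}"
        )
    mat = np.frombuffer(seg[:need], dtype=np_dtype).reshape(n_tot, n_par).astype(float)
    df = pd.DataFrame(mat, columns=names)
    if channel_map is not None:
        for marker in MARKERS:
            col = channel_map[marker]
            if col not in df.columns:
                raise ChannelMissingError(
                    f"{path.name}: required channel {col!r} (marker {marker}) not among {names}"
                )
        df = df[[channel_map[m] for m in MARKERS]]
        df.columns = list(MARKERS)
    return EventTable(data=df, metadata={"source": str(path), "fcs_version": version})
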