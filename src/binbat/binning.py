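"""PRI square-bin statistics for a 2-D marker plane.

The pattern-recognition-of-immune-cells (PRI) representation partitions
a 2-D marker plane (here typically FceRIa x CD63, on display scale)
into square bins and colours each bin by a statistic of a target
marker:

* ``n_b`` — event count of bin b;
* ``MSI_b`` — mean signal intensity of the target marker over all
  events in b;
* ``MSI+_b`` — mean over target-positive events only (undefined, not
  zero, when the bin holds none: low intensities must not be
  fabricated);
* ``freq+_b`` — target-positive fraction of the bin.

Bins are half-open squares ``[origin + k*w, origin + (k+1)*w)`` with a
common width on both axes; the origin defaults to the data minimum
floored to a bin-width multiple, so grids are deterministic for fixed
data.  Quadrant statistics use the same inclusive-side convention as
gating (x <= x_thr is "low", y >= y_thr is "high"): black percentages
are fractions of all events per quadrant, red percentages the
target-positive fractions within each quadrant.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventTable
from .exceptions import BinbatError

DEFAULT_BIN_WIDTH = 0.2  # log10 decades
DEFAULT_MIN_CELLS = 5

QUADRANTS = ("x_low_y_low", "x_low_y_high", "x_high_y_low", "x_high_y_high")


@dataclass
class BinGrid:
    """Square-bin partition of a 2-D marker plane with per-bin statistics."""

    x: str
    y: str
    target: str
    cutoff: float
    bin_width: float
    origin: tuple
    bins: pd.DataFrame  # columns: ix, iy, n, msi, n_pos, msi_pos, freq_pos, below_min_cells
    min_cells: int
    n_events: int
    x_thr: float | None = None
    y_thr: float | None = None
    quadrants: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)


def build_grid(
    events: EventTable,
    x: str,
    y: str,
    target: str,
    cutoff: float,
    *,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_cells: int = DEFAULT_MIN_CELLS,
    origin: tuple | None = None,
    x_thr: float | None = None,
    y_thr: float | None = None,
) -> BinGrid:
    """Bin events on the ``x`` x ``y`` plane and compute per-bin statistics.

    An empty event table yields an empty (zero-bin) grid.  If quadrant
    thresholds are supplied, quadrant statistics are attached (x_thr
    conventionally the gate threshold, y_thr the target positivity
    cutoff).
    """
    if bin_width <= 0:
        raise BinbatError("bin width must be > 0")
    if not np.isfinite(cutoff):
        raise BinbatError("positivity cutoff must be finite")
    xv, yv, tv = (events.values(c) for c in (x, y, target))

    if events.n_events == 0:
        bins = pd.DataFrame(columns=["ix", "iy", "n", "msi", "n_pos", "msi_pos",
                                     "freq_pos", "below_min_cells"])
        grid_origin = origin if origin is not None else (0.0, 0.0)
    else:
        if origin is None:
            grid_origin = (np.floor(xv.min() / bin_width) * bin_width,
                           np.floor(yv.min() / bin_width) * bin_width)
        else:
            grid_origin = (float(origin[0]), float(origin[1]))
        ix = np.floor((xv - grid_origin[0]) / bin_width).astype(int)
        iy = np.floor((yv - grid_origin[1]) / bin_width).astype(int)
        pos = tv >= cutoff
        df = pd.DataFrame({"ix": ix, "iy": iy, "t": tv, "pos": pos})
        g = df.groupby(["ix", "iy"], sort=True)
        bins = g.agg(n=("t", "size"), msi=("t", "mean"), n_pos=("pos", "sum")).reset_index()
        pos_means = (df[df["pos"]].groupby(["ix", "iy"])["t"].mean()
                     .rename("msi_pos").reset_index())
        bins = bins.merge(pos_means, on=["ix", "iy"], how="left")
        bins["freq_pos"] = bins["n_pos"] / bins["n"]
        bins["below_min_cells"] = bins["n"] < min_cells

    quadrants = None
    if x_thr is not None and y_thr is not None and events.n_events > 0:
        quadrants = quadrant_stats(events, x_thr, y_thr, target, cutoff, x=x, y=y)

    return BinGrid(x=x, y=y, target=target, cutoff=float(cutoff),
                   bin_width=float(bin_width), origin=tuple(grid_origin),
                   bins=bins, min_cells=int(min_cells), n_events=events.n_events,
                   x_thr=x_thr, y_thr=y_thr, quadrants=quadrants)


def quadrant_stats(
    events: EventTable,
    x_thr: float,
    y_thr: float,
    target: str,
    cutoff: float,
    *,
    x: str | None = None,
    y: str | None = None,
) -> pd.DataFrame:
    """Per-quadrant event percentages and target-positive percentages.

    Quadrant membership uses the gate convention: ``x <= x_thr`` is the
    low side, ``y >= y_thr`` the high side.  ``pct_all`` sums to 100
    over the four quadrants; ``pct_pos`` is positives / quadrant events
    x 100, NaN for empty quadrants.
    """
    if not (np.isfinite(x_thr) and np.isfinite(y_thr)):
        raise BinbatError("quadrant thresholds must be finite")
    channels = events.channels
    x = x if x is not None else channels[0]
    y = y if y is not None else channels[1]
    xv, yv, tv = events.values(x), events.values(y), events.values(target)
    x_low = xv <= x_thr
    y_high = yv >= y_thr
    pos = tv >= cutoff
    n = len(xv)
    rows = []
    for name, mx, my in (("x_low_y_low", x_low, ~y_high),
                         ("x_low_y_high", x_low, y_high),
                         ("x_high_y_low", ~x_low, ~y_high),
                         ("x_high_y_high", ~x_low, y_high)):
        m = mx & my
        nq = int(m.sum())
        rows.append({
            "quadrant": name,
            "n": nq,
            "pct_all": 100.0 * nq / n if n else np.nan,
            "n_pos": int((m & pos).sum()),
            "pct_pos": 100.0 * (m & pos).sum() / nq if nq else np.nan,
        })
    return pd.DataFrame(rows)


def render_grid(
    grid: BinGrid,
    mode: str,
    path,
    *,
    cmap: str = "coolwarm",
    annotate: bool = True,
    dpi: int = 120,
) -> None:
    """Render the grid as a colour-coded bin plot (blue = low, red = high).

    ``mode`` selects the statistic: ``MSI``, ``MSI_plus`` or ``freq``.
    Bins below the ``min_cells`` display threshold (or with an undefined
    statistic) are rendered neutral grey.  Quadrant percentages are
    annotated when thresholds are attached: black = percent of all
    events, red = percent of target-positive events within the quadrant.
    Output is deterministic for fixed inputs and renderer settings.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    stat_col = {"MSI": "msi", "MSI_plus": "msi_pos", "freq": "freq_pos"}.get(mode)
    if stat_col is None:
        raise ValueError(f"unknown render mode {mode!r}")
    bins = grid.bins
    fig, ax = plt.subplots(figsize=(5, 4.2))
    if len(bins) == 0:
        warnings.warn("rendering an empty grid", stacklevel=2)
    else:
        ix0, ix1 = int(bins["ix"].min()), int(bins["ix"].max())
        iy0, iy1 = int(bins["iy"].min()), int(bins["iy"].max())
        arr = np.full((iy1 - iy0 + 1, ix1 - ix0 + 1), np.nan)
        shown = bins.loc[~bins["below_min_cells"]]
        vals = shown[stat_col].to_numpy(dtype=float)
        arr[shown["iy"].to_numpy() - iy0, shown["ix"].to_numpy() - ix0] = vals
        if np.all(np.isnan(arr)):
            warnings.warn(f"no displayable bins for mode {mode}", stacklevel=2)
        w, (ox, oy) = grid.bin_width, grid.origin
        extent = (ox + ix0 * w, ox + (ix1 + 1) * w, oy + iy0 * w, oy + (iy1 + 1) * w)
        cm = matplotlib.colormaps[cmap].copy()
        cm.set_bad("0.85")
        im = ax.imshow(arr, origin="lower", extent=extent, cmap=cm,
                       aspect="auto", interpolation="nearest")
        fig.colorbar(im, ax=ax, label=f"{mode} ({grid.target})")
    ax.set_xlabel(grid.x)
    ax.set_ylabel(grid.y)
    if annotate and grid.quadrants is not None:
        ax.axvline(grid.x_thr, color="k", lw=0.8)
        ax.axhline(grid.y_thr, color="k", lw=0.8)
        corners = {"x_low_y_low": (0.02, 0.04), "x_low_y_high": (0.02, 0.92),
                   "x_high_y_low": (0.78, 0.04), "x_high_y_high": (0.78, 0.92)}
        for _, row in grid.quadrants.iterrows():
            cx, cy = corners[row["quadrant"]]
            ax.text(cx, cy, f"{row['pct_all']:.1f}%", color="black",
                    transform=ax.transAxes, fontsize=8)
            if np.isfinite(row["pct_pos"]):
                ax.text(cx, cy + 0.045, f"{row['pct_pos']:.1f}%", color="red",
                        transform=ax.transAxes, fontsize=8)
    fig.savefig(path, dpi=dpi, metadata=_deterministic_metadata(str(path)))
    plt.close(fig)


def _deterministic_metadata(path: str) -> dict | None:
    # strip creation timestamps so identical inputs give identical bytes
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": "binbat"}
    return None
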