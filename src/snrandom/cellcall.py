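"""Barcode ranking, knee detection and nucleus calling.

Barcodes are ordered by a per-barcode signal (genes detected by default,
matching the barcode-gene rank plot; UMIs optional).  True nuclei separate
from the ambient background at the steep drop of that curve; the knee is
located on the running-median-smoothed log10(value) vs log10(rank) curve as
the point of maximum perpendicular distance to the chord joining the curve's
endpoints — a scale-invariant concretisation of "the significant steep
slope".  When the distance profile has no unique, sufficiently prominent
maximum the caller falls back to an expected-cell-count quantile rule
(threshold = 99th percentile of the top N barcodes' signal, divided by 10),
and a flat curve raises :class:`NoKneeError`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .quantify import CountMatrix

__all__ = ["RankCurve", "CallResult", "NoKneeError", "rank_barcodes",
           "call_knee", "capture_metrics", "plot_rank_curve"]


class NoKneeError(RuntimeError):
    """The rank curve has no detectable knee; pass expected_cells instead."""


@dataclass
class RankCurve:
    """Barcodes in non-increasing metric order with log-log coordinates."""

    barcodes: np.ndarray
    values: np.ndarray
    metric: str = "genes"

    def __post_init__(self):
        if np.any(np.diff(self.values) > 0):
            raise ValueError("rank-curve values must be non-increasing")

    @property
    def log_rank(self) -> np.ndarray:
        return np.log10(np.arange(1, len(self.values) + 1))

    @property
    def log_value(self) -> np.ndarray:
        return np.log10(np.maximum(self.values, 0.5))  # guard zeros


@dataclass
class CallResult:
    called_cells: set
    threshold_value: float
    method: str                     # knee | expected_cells
    diagnostics: dict = field(default_factory=dict)

    def write_json(self, path) -> None:
        d = {"n_called": len(self.called_cells),
             "threshold_value": self.threshold_value,
             "method": self.method,
             "diagnostics": {k: v for k, v in self.diagnostics.items()
                             if np.isscalar(v)}}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def rank_barcodes(
    source: Union[CountMatrix, Mapping[str, float], pd.Series],
    metric: str = "genes",
) -> RankCurve:
    """Order barcodes by descending metric; ties broken lexicographically by
    barcode for determinism."""
    if isinstance(source, CountMatrix):
        values = (source.genes_detected_per_cell() if metric == "genes"
                  else source.cell_totals())
        barcodes = np.asarray(source.cells)
    else:
        series = pd.Series(source)
        barcodes, values = series.index.to_numpy(), series.to_numpy()
    if len(barcodes) == 0:
        raise ValueError("no barcodes to rank")
    order = np.lexsort((barcodes, -np.asarray(values, dtype=float)))
    return RankCurve(barcodes=np.asarray(barcodes)[order],
                     values=np.asarray(values, dtype=float)[order],
                     metric=metric)


def _running_median(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(y) < 3:
        return y
    window = min(window if window % 2 == 1 else window + 1, len(y))
    if window % 2 == 0:
        window -= 1
    return pd.Series(y).rolling(window, center=True, min_periods=1).median().to_numpy()


def call_knee(
    curve: RankCurve,
    window: int = 15,
    min_prominence: float = 0.05,
    min_dynamic_range: float = 10.0,
    expected_cells: Optional[int] = None,
) -> CallResult:
    """Call nuclei from the barcode rank curve (see module docstring).

    Raises :class:`NoKneeError` when the curve spans less than a decade, or
    when no prominent unique knee exists and ``expected_cells`` was not given.
    """
    if len(curve.values) < 10:
        raise NoKneeError("need at least 10 barcodes")
    vmax, vmin = curve.values[0], curve.values[-1]
    if vmax <= 0 or vmax / max(vmin, 0.5) < min_dynamic_range:
        raise NoKneeError(
            "flat rank curve (max/min < 10): rerun with --expected-cells")

    # Resample onto a uniform log10(rank) grid: the raw curve is piecewise
    # constant (integer metrics, dense high ranks), so smoothing and slopes
    # are only well behaved on an even grid.
    x_raw = curve.log_rank
    y_raw = curve.log_value
    n_grid = 512
    xs = np.linspace(x_raw[0], x_raw[-1], n_grid)
    ys = _running_median(np.interp(xs, x_raw, y_raw), window)
    p0 = np.array([xs[0], ys[0]])
    p1 = np.array([xs[-1], ys[-1]])
    chord = p1 - p0
    chord_len = float(np.hypot(*chord))
    # perpendicular distance of every grid point to the chord
    d = np.abs(chord[0] * (ys - p0[1]) - chord[1] * (xs - p0[0])) / chord_len
    dmax = float(d.max())
    at_max = np.flatnonzero(d >= dmax - 1e-9)
    prominent = dmax / chord_len >= min_prominence
    unique = len(at_max) == 1

    if prominent and unique:
        knee_idx = int(at_max[0])
        # The distance maximum locates the shoulder, but thresholding at that
        # very rank would cut into the upper population's tail.  From the
        # knee, find the first clearly-steep grid point (twice the chord
        # slope) and walk down until the curve flattens back above the chord
        # slope — the foot of the cliff, i.e. the top of the ambient plateau
        # — so the whole upper population sits above the cut.
        grad = np.gradient(ys, xs)
        # the cliff is the steepest grid point at/after the knee (the last 5%
        # of the grid is excluded: rank compression makes the integer-valued
        # deep tail artificially steep there)
        hi = max(knee_idx + 1, int(0.95 * n_grid))
        j = knee_idx + int(np.argmin(grad[knee_idx:hi]))
        # running medians preserve the edge, so take the threshold midway
        # (geometric mean) between the curve values half a smoothing window
        # above and below the cliff — inside the gap separating nuclei from
        # ambient barcodes
        w = window // 2 + 1
        v_hi = 10.0 ** ys[max(0, j - w)]
        v_lo = 10.0 ** ys[min(n_grid - 1, j + w)]
        threshold = float(np.sqrt(v_hi * v_lo))
        method = "knee"
        diagnostics = {"knee_rank": float(10.0 ** xs[knee_idx]),
                       "threshold_rank": float(10.0 ** xs[j]),
                       "distance": dmax,
                       "relative_prominence": dmax / chord_len,
                       "distance_profile": d}
    else:
        if expected_cells is None:
            raise NoKneeError(
                "no unique prominent knee; rerun with expected_cells")
        n = min(int(expected_cells), len(curve.values))
        threshold = float(np.quantile(curve.values[:n], 0.99) / 10.0)
        method = "expected_cells"
        diagnostics = {"expected_cells": expected_cells,
                       "quantile_value": threshold * 10.0}

    called = set(curve.barcodes[curve.values >= threshold])  # ties included
    return CallResult(called_cells=called, threshold_value=threshold,
                      method=method, diagnostics=diagnostics)


def capture_metrics(
    call: CallResult,
    truth_nuclei: Optional[Sequence[str]] = None,
    reads_valid_barcode: Optional[int] = None,
    reads_in_called: Optional[int] = None,
) -> dict:
    """Capture rate against simulator truth and/or reads-in-cells from totals.

    capture_rate = |called ∩ truth| / |truth|; reads_in_cells = reads whose
    cell id was called / reads with a valid barcode.  Fields without inputs
    are explicit None.
    """
    out = {"n_called": len(call.called_cells), "capture_rate": None,
           "reads_in_cells": None}
    if truth_nuclei is not None:
        truth = set(truth_nuclei)
        out["capture_rate"] = len(call.called_cells & truth) / len(truth) if truth else None
        out["n_truth"] = len(truth)
        out["ambient_in_called"] = len(call.called_cells - truth)
    if reads_valid_barcode:
        out["reads_in_cells"] = (reads_in_called or 0) / reads_valid_barcode
    return out


def plot_rank_curve(curve: RankCurve, call: Optional[CallResult] = None,
                    path=None):
    """Log-log rank plot with the called threshold marked (optional PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(np.arange(1, len(curve.values) + 1), np.maximum(curve.values, 0.5))
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("barcode rank")
    ax.set_ylabel(curve.metric)
    if call is not None:
        ax.axhline(call.threshold_value, ls="--", color="red",
                   label=f"{call.method}: {len(call.called_cells)} called")
        ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
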