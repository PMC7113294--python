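"""Replicate-level statistics: Grubbs outlier screening and per-day summaries.

A cultivation experiment runs N parallel flow cells for several days and
yields one value per flow cell × day for each structural parameter.  Small
replicate numbers make both the estimated mean and the detectability of
outliers unreliable; these routines operationalise the replicate workflow:
iterative two-sided Grubbs tests per day, outlier removal, and mean /
median / sample-SD summaries of the survivors, exported as annotated
heat-map tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReplicateTable",
    "grubbs_critical_value",
    "grubbs_test",
    "grubbs_outliers",
    "replicate_summary",
    "heatmap_table",
    "read_heatmap_csv",
]


@dataclass
class ReplicateTable:
    """One parameter's values over flow cells (rows) × days (columns).

    ``values`` is a DataFrame indexed by flow-cell id with day numbers as
    columns; NaN marks missing cells.  ``outliers`` is a same-shaped
    boolean mask (True only on non-missing cells).
    """

    values: pd.DataFrame
    parameter: str
    units: str = ""
    outliers: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.outliers is None:
            self.outliers = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if self.outliers.shape != self.values.shape:
            raise ValueError("outlier mask shape differs from value matrix")
        if bool((self.outliers & self.values.isna()).any().any()):
            raise ValueError("outlier mask marks missing cells")


@lru_cache(maxsize=None)
def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha).

    Closed form from the Student-t quantile t = t_{α/(2n), n−2}:

        G_crit = (n−1)/√n · √( t² / (n−2+t²) )
    """
    if n < 3:
        raise ValueError(f"Grubbs test needs n >= 3, got {n}")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values, alpha: float = 0.05) -> int | None:
    """One round of the two-sided Grubbs test; index of the outlier or None.

    G = max|x_i − x̄| / s is compared against :func:`grubbs_critical_value`.
    A zero-spread sample has no outlier by definition.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    n = x.size
    if n < 3:
        raise ValueError(f"Grubbs test needs n >= 3, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = dev[i] / sd
    return i if g > grubbs_critical_value(n, alpha) else None


def grubbs_outliers(
    values, alpha: float = 0.05, *, max_removals: int | None = None
) -> list[int]:
    """Iteratively applied Grubbs test; indices (into the input) of all outliers.

    Each detected outlier is removed and the test repeated on the
    remainder, until none is found, fewer than 3 values remain, or the
    removal cap ⌈n/4⌉ is reached (guards against stripping a genuine
    heavy-tailed sample).
    """
    x = np.asarray(values, dtype=np.float64)
    if max_removals is None:
        max_removals = math.ceil(x.size / 4)
    alive = list(range(x.size))
    removed: list[int] = []
    while len(alive) >= 3 and len(removed) < max_removals:
        hit = grubbs_test(x[alive], alpha)
        if hit is None:
            break
        removed.append(alive.pop(hit))
    return removed


def replicate_summary(table: ReplicateTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-day mean/median/SD after Grubbs outlier removal.

    Returns a DataFrame indexed by day with columns mean, median, sd,
    n_used, n_outliers, reliable.  Days with fewer than 3 non-missing
    values skip the outlier test and are flagged ``reliable=False``, but
    their statistics are still reported.  The table's outlier mask is
    updated in place.
    """
    rows = []
    for day in table.values.columns:
        col = table.values[day]
        present = col.dropna()
        out_idx: list = []
        if present.size >= 3:
            removed = grubbs_outliers(present.to_numpy(), alpha)
            out_idx = [present.index[i] for i in removed]
        table.outliers[day] = False
        for fc in out_idx:
            table.outliers.loc[fc, day] = True
        kept = present.drop(index=out_idx)
        rows.append(
            {
                "day": day,
                "mean": kept.mean() if kept.size else np.nan,
                "median": kept.median() if kept.size else np.nan,
                "sd": kept.std(ddof=1) if kept.size > 1 else np.nan,
                "n_used": int(kept.size),
                "n_outliers": len(out_idx),
                "reliable": present.size >= 3,
            }
        )
    return pd.DataFrame(rows).set_index("day")


def _format_cell(value: float, outlier: bool) -> str:
    if pd.isna(value):
        return ""
    text = repr(float(value))
    return f"{text} o" if outlier else text


def heatmap_table(
    tables: list[ReplicateTable],
    out_dir,
    *,
    alpha: float = 0.05,
    render: bool = True,
    cmap: str = "viridis",
) -> list[str]:
    """Export annotated heat-map tables, one CSV (and PNG) per parameter.

    All tables must share the same flow-cell and day axes.  CSV cells hold
    the value (``repr`` precision, so re-reading is exact), with outliers
    annotated by a trailing ``o`` and missing values left blank — the
    layout of a heat-map figure with per-cell annotations.  With
    ``render=True`` a colour-mapped PNG with a calibration bar is written
    alongside each CSV.
    """
    from pathlib import Path

    if not tables:
        raise ValueError("no tables given")
    ref = tables[0]
    for t in tables[1:]:
        if not t.values.index.equals(ref.values.index) or not t.values.columns.equals(
            ref.values.columns
        ):
            raise ValueError(
                f"table {t.parameter!r} axes differ from {ref.parameter!r}"
            )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for t in tables:
        replicate_summary(t, alpha)  # refresh outlier mask
        cells = pd.DataFrame(
            [
                [
                    _format_cell(t.values.iat[i, j], bool(t.outliers.iat[i, j]))
                    for j in range(t.values.shape[1])
                ]
                for i in range(t.values.shape[0])
            ],
            index=t.values.index,
            columns=t.values.columns,
        )
        slug = t.parameter.lower().replace(" ", "_")
        csv_path = out_dir / f"heatmap_{slug}.csv"
        cells.to_csv(csv_path, index_label="flow_cell")
        written.append(str(csv_path))
        if render:
            written.append(_render_heatmap(t, out_dir / f"heatmap_{slug}.png", cmap))
    return written


def _render_heatmap(t: ReplicateTable, path, cmap: str) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 0.5 * t.values.shape[1], 1.0 + 0.3 * t.values.shape[0]))
    data = np.ma.masked_invalid(t.values.to_numpy(dtype=np.float64))
    im = ax.imshow(data, aspect="auto", cmap=cmap)
    ax.set_xticks(range(t.values.shape[1]), [str(c) for c in t.values.columns])
    ax.set_yticks(range(t.values.shape[0]), [str(i) for i in t.values.index])
    ax.set_xlabel("day")
    ax.set_ylabel("flow cell")
    label = f"{t.parameter} [{t.units}]" if t.units else t.parameter
    ax.set_title(label)
    for (i, j), flagged in np.ndenumerate(t.outliers.to_numpy()):
        if flagged:
            ax.text(j, i, "o", ha="center", va="center", color="red")
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def read_heatmap_csv(path, parameter: str = "", units: str = "") -> ReplicateTable:
    """Read back a CSV written by :func:`heatmap_table`, exactly.

    Recovers the value matrix (float-exact, thanks to ``repr`` cells), the
    outlier mask (trailing ``o``), and the missing mask (blank cells).
    """
    raw = pd.read_csv(path, index_col="flow_cell", dtype=str)
    raw.columns = [int(c) if str(c).isdigit() else c for c in raw.columns]
    values = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns, dtype=np.float64)
    outliers = pd.DataFrame(False, index=raw.index, columns=raw.columns)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw.iat[i, j]
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            text = str(cell).strip()
            if text.endswith(" o"):
                outliers.iat[i, j] = True
                text = text[:-2]
            values.iat[i, j] = float(text)
    return ReplicateTable(values, parameter=parameter, units=units, outliers=outliers)
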