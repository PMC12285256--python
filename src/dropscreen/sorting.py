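"""Fluorescence-activated droplet sorting (FADS) gate arithmetic.

Operations on per-droplet fluorescence records: top-quantile gates (sort
the brightest q of the population), fixed-threshold exceedance ratios,
log-scale intensity histograms as displayed by the sorter, and
strain-composition summaries of the gated subpopulation.

Gate convention: the top-fraction threshold is the empirical (1-q) quantile
with linear interpolation, and droplets strictly above it are selected;
ties at the threshold are excluded, so the gate never sorts more than
requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SortGate",
    "top_fraction_gate",
    "fraction_exceeding",
    "intensity_histogram",
    "gate_composition",
]


@dataclass(frozen=True)
class SortGate:
    """A realized sorting gate and what it selected."""

    mode: str  # "top_fraction" | "fixed_threshold"
    q: float | None
    threshold_used: float
    selected_count: int
    n_total: int
    degenerate: bool = False  # all intensities tied: nothing selectable

    @property
    def selected_fraction(self) -> float:
        return self.selected_count / self.n_total if self.n_total else 0.0


def top_fraction_gate(intensities, q: float) -> tuple[SortGate, np.ndarray]:
    """Select the brightest fraction ``q`` of droplets.

    Returns the gate and the integer indices of selected droplets. With all
    intensities tied the threshold equals every value, nothing exceeds it,
    and the gate is flagged degenerate.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("cannot gate an empty population")
    if not 0 < q < 1:
        raise ValueError(f"top fraction must be in (0, 1), got {q}")
    threshold = float(np.quantile(x, 1.0 - q))
    selected = np.flatnonzero(x > threshold)
    gate = SortGate(
        mode="top_fraction", q=q, threshold_used=threshold,
        selected_count=int(selected.size), n_total=int(x.size),
        degenerate=bool(selected.size == 0 and np.ptp(x) == 0),
    )
    return gate, selected


def fixed_threshold_gate(intensities, threshold: float) -> tuple[SortGate, np.ndarray]:
    """Select droplets strictly above a fixed intensity threshold."""
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("cannot gate an empty population")
    selected = np.flatnonzero(x > threshold)
    gate = SortGate(
        mode="fixed_threshold", q=None, threshold_used=float(threshold),
        selected_count=int(selected.size), n_total=int(x.size),
    )
    return gate, selected


def fraction_exceeding(intensities, thresholds) -> np.ndarray:
    """Proportion of droplets strictly exceeding each threshold.

    Thresholds must be sorted ascending; the output is non-increasing.
    """
    x = np.asarray(intensities, dtype=float)
    th = np.asarray(list(thresholds), dtype=float)
    if np.any(np.diff(th) < 0):
        raise ValueError("thresholds must be sorted ascending")
    if x.size == 0:
        return np.zeros_like(th)
    return np.array([(x > t).mean() for t in th])


def intensity_histogram(
    intensities, n_bins: int = 50, log_axis: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of droplet fluorescence, log-spaced bins by default.

    Returns ``(counts, bin_edges)``; counts sum to the population size.
    An empty population yields an empty histogram.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    if log_axis:
        if np.any(x <= 0):
            raise ValueError("log-axis histogram requires positive intensities")
        lo, hi = np.log10(x.min()), np.log10(x.max())
        if lo == hi:  # all mass in one bin
            edges = np.logspace(lo - 0.05, hi + 0.05, 2)
        else:
            edges = np.logspace(lo, hi, n_bins + 1)
            # guard against round-off pushing extremes outside the edges
            edges[0] = min(edges[0], x.min())
            edges[-1] = max(edges[-1], x.max())
    else:
        edges = np.histogram_bin_edges(x, bins=n_bins)
    counts, edges = np.histogram(x, bins=edges)
    return counts, edges


def _strain_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith("n_")]
    if not cols:
        raise ValueError("table has no per-strain count columns (n_<strain>)")
    return cols


def droplet_content_class(table: pd.DataFrame) -> pd.Series:
    """Label each droplet by its strain content.

    ``empty``, ``only_<strain>`` for single-strain droplets, ``mixed`` for
    co-encapsulation.
    """
    cols = _strain_columns(table)
    present = table[cols].to_numpy() > 0
    n_strains = present.sum(axis=1)
    labels = np.full(len(table), "mixed", dtype=object)
    labels[n_strains == 0] = "empty"
    for j, col in enumerate(cols):
        only_this = (n_strains == 1) & present[:, j]
        labels[only_this] = f"only_{col[2:]}"
    return pd.Series(labels, index=table.index, name="content")


def gate_composition(table: pd.DataFrame, selected_idx) -> pd.DataFrame:
    """Strain-content composition of a droplet table before and after a gate.

    ``selected_idx`` are positional indices into ``table`` (as returned by
    the gate functions). Returns per-content-class droplet counts in the
    whole population (``n_total``) and in the gated subset (``n_selected``).
    """
    content = droplet_content_class(table)
    selected_mask = np.zeros(len(table), dtype=bool)
    selected_mask[np.asarray(selected_idx, dtype=int)] = True
    out = (
        pd.DataFrame({"content": content.to_numpy(), "selected": selected_mask})
        .groupby("content", sort=True)
        .agg(n_total=("selected", "size"), n_selected=("selected", "sum"))
        .reset_index()
    )
    return out
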