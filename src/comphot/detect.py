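"""Candidate comparative hotspots from pairs of variability bands.

A *candidate comparative hotspot* is a maximal segment of the analysis
unit where the two vectors' variability bands have empty intersection:
the lower edge of one band lies strictly above the upper edge of the
other at every grid point of the segment.  The vector whose band is on
top is the *winner*.  Candidates are found on the collapsed axis and
expanded back to genomic coordinates, re-inserting any blind stretches
interior to them.

Robustness to the smoothing level is probed by re-running detection with
both bandwidths multiplied by a common sensitivity factor ``s`` in
``[0.05, 20]`` (``h = h_opt * s``, same ``s`` for both vectors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .blindmap import AnalysisUnit, BlindMap
from .density import (DEFAULT_GRID_SIZE, DEFAULT_LEVEL, IntegrationSiteSet,
                      VariabilityBand, estimate_density, select_bandwidth,
                      variability_band)

logger = logging.getLogger("comphot.detect")

#: admissible range of the sensitivity factor
S_RANGE = (0.05, 20.0)
#: default sensitivity grid (log-spaced, always containing 1.0)
DEFAULT_S_GRID = (0.05, 0.1, 0.2, 0.5, 0.8, 1.0, 1.25, 2.0, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class CandidateHotspot:
    """Maximal band-disjoint segment, on collapsed and genomic scales."""

    unit: AnalysisUnit | None
    a: float  # collapsed start
    b: float  # collapsed end (half-open)
    winner: str
    start: int | None = None  # genomic, filled by to_genomic
    end: int | None = None
    id: str = ""

    @property
    def collapsed_length(self) -> float:
        return self.b - self.a

    @property
    def genomic_length(self) -> int | None:
        if self.start is None or self.end is None:
            return None
        return self.end - self.start


@dataclass
class SensitivityScan:
    """Candidates re-detected at ``h_opt * s`` for each sensitivity factor."""

    s_values: list[float]
    per_s_candidates: dict[float, list[CandidateHotspot]]
    h_opt: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.s_values:
            for c in self.per_s_candidates[s]:
                rows.append({"s": s,
                             "unit": c.unit.id if c.unit else "",
                             "start": c.start if c.start is not None else c.a,
                             "end": c.end if c.end is not None else c.b,
                             "winner": c.winner})
        return pd.DataFrame(rows, columns=["s", "unit", "start", "end", "winner"])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    d = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def find_candidates(band_a: VariabilityBand, band_b: VariabilityBand,
                    labels: tuple[str, str] | None = None,
                    unit: AnalysisUnit | None = None) -> list[CandidateHotspot]:
    """Maximal grid-point runs where one band lies strictly above the other.

    Segment boundaries are reported at grid resolution: a run over grid
    cells ``i..j`` becomes the collapsed interval
    ``[grid[i], grid[j] + step)``.  Single-point runs are retained; no
    length filter is applied (the exact test stage prunes weak
    candidates).
    """
    ga, gb = band_a.grid, band_b.grid
    if ga.shape != gb.shape or not np.allclose(ga, gb):
        raise ValueError("bands must share the same grid")
    if labels is None:
        labels = (band_a.estimate.label or "A", band_b.estimate.label or "B")
    step = band_a.estimate.step
    out: list[CandidateHotspot] = []
    for mask, winner in ((band_a.lower > band_b.upper, labels[0]),
                         (band_b.lower > band_a.upper, labels[1])):
        for i, j in _runs(mask):
            out.append(CandidateHotspot(unit=unit, a=float(ga[i]),
                                        b=float(ga[j] + step), winner=winner))
    out.sort(key=lambda c: c.a)
    return out


def to_genomic(candidates: list[CandidateHotspot],
               bmap: BlindMap) -> list[CandidateHotspot]:
    """Expand collapsed candidate intervals back to genomic coordinates.

    Interior blind stretches are re-inserted, so the genomic length is at
    least the collapsed length.
    """
    out = []
    L = bmap.collapsed_length
    for c in candidates:
        a = int(np.clip(np.floor(c.a), 0, L - 1))
        b = int(np.clip(np.ceil(c.b), a + 1, L))
        gs, ge = bmap.expand_interval(a, b)
        out.append(replace(c, unit=bmap.unit, start=gs, end=ge))
    return out


def bands_for_unit(sites_a: IntegrationSiteSet, sites_b: IntegrationSiteSet,
                   level: float = DEFAULT_LEVEL,
                   grid_size: int = DEFAULT_GRID_SIZE,
                   h: tuple[float, float] | None = None,
                   ucv_grid: int = 200) -> tuple[VariabilityBand, VariabilityBand, dict[str, float]]:
    """Estimate both densities at their own UCV-optimal bandwidths and band them."""
    if h is None:
        h = (select_bandwidth(sites_a, grid=ucv_grid).h_opt,
             select_bandwidth(sites_b, grid=ucv_grid).h_opt)
    ea = estimate_density(sites_a, h[0], grid_size=grid_size)
    eb = estimate_density(sites_b, h[1], grid_size=grid_size)
    return (variability_band(ea, level), variability_band(eb, level),
            {sites_a.vector or "A": h[0], sites_b.vector or "B": h[1]})


def sensitivity_scan(sites_a: IntegrationSiteSet, sites_b: IntegrationSiteSet,
                     s_grid=DEFAULT_S_GRID, level: float = DEFAULT_LEVEL,
                     grid_size: int = DEFAULT_GRID_SIZE,
                     bmap: BlindMap | None = None,
                     ucv_grid: int = 200) -> SensitivityScan:
    """Re-run estimate -> band -> candidates at ``h_opt * s`` for each ``s``.

    Both vectors' cross-validated bandwidths are scaled by the same
    factor.  The ``s = 1`` entry is the main detection output.
    """
    s_vals = sorted(float(s) for s in s_grid)
    if any(s < S_RANGE[0] or s > S_RANGE[1] for s in s_vals):
        raise ValueError(f"sensitivity factors must lie in {S_RANGE}")
    if 1.0 not in s_vals:
        raise ValueError("s grid must contain 1.0")
    ha = select_bandwidth(sites_a, grid=ucv_grid).h_opt
    hb = select_bandwidth(sites_b, grid=ucv_grid).h_opt
    labels = (sites_a.vector or "A", sites_b.vector or "B")
    per_s: dict[float, list[CandidateHotspot]] = {}
    unit = sites_a.unit or (bmap.unit if bmap is not None else None)
    for s in s_vals:
        band_a, band_b, _ = bands_for_unit(sites_a, sites_b, level=level,
                                           grid_size=grid_size,
                                           h=(ha * s, hb * s))
        cands = find_candidates(band_a, band_b, labels=labels, unit=unit)
        if bmap is not None:
            cands = to_genomic(cands, bmap)
        per_s[s] = cands
    return SensitivityScan(s_values=s_vals, per_s_candidates=per_s,
                           h_opt={labels[0]: ha, labels[1]: hb})


def plot_unit(band_a: VariabilityBand, band_b: VariabilityBand,
              candidates: list[CandidateHotspot] | None = None,
              labels: tuple[str, str] = ("A", "B"), ax=None):
    """Band-and-candidate track plot for one unit (matplotlib Axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    for band, color, lab in ((band_a, "tab:blue", labels[0]),
                             (band_b, "tab:red", labels[1])):
        ax.fill_between(band.grid, band.lower, band.upper, alpha=0.35,
                        color=color, label=lab)
        ax.plot(band.grid, band.estimate.values, color=color, lw=0.8)
    ymax = max(band_a.upper.max(), band_b.upper.max())
    for c in candidates or []:
        color = "tab:blue" if c.winner == labels[0] else "tab:red"
        ax.hlines(-0.05 * ymax, c.a, c.b, color=color, lw=4)
    ax.set_xlabel("collapsed position (bp)")
    ax.set_ylabel("density")
    ax.legend(loc="upper right", fontsize=8)
    return ax
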