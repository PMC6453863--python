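"""ESS sectorization: 5-degree sectors x 200 µm axial intervals.

Cells hold the area-weighted mean wall shear stress of the elements whose
centroid falls in the cell (half-open bins); uncovered cells are masked, never
imputed as zero.  Low ESS is < 1.0 Pa and very-low ESS is < 0.5 Pa, both
strict, so very-low cells are a subset of low cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SEGMENT_DISTAL, SEGMENT_PROXIMAL, SEGMENT_SCAFFOLDED

N_SECTORS = 72
SECTOR_DEG = 5.0
INTERVAL_UM = 200.0

LOW_ESS_PA = 1.0
VERY_LOW_ESS_PA = 0.5


@dataclass
class ESSMap:
    """Sector x interval grid of ESS values (Pa), masked where uncovered."""

    ess: np.ma.MaskedArray          # (n_intervals, 72)
    segment: np.ndarray             # (n_intervals,) segment label per interval
    start_um: float = 0.0
    interval_um: float = INTERVAL_UM

    def __post_init__(self) -> None:
        if self.ess.shape[1] != N_SECTORS:
            raise ValueError(f"ESS map must have {N_SECTORS} sectors")

    @property
    def n_intervals(self) -> int:
        return self.ess.shape[0]

    def cells(self, segment: str | None = None) -> np.ma.MaskedArray:
        if segment is None:
            return self.ess
        rows = self.segment == segment
        return self.ess[rows]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (interval, sector, ess, segment) table of covered cells."""
        ii, jj = np.nonzero(~self.ess.mask)
        return pd.DataFrame({
            "interval": ii,
            "axial_start_um": self.start_um + ii * self.interval_um,
            "sector": jj,
            "ess_pa": self.ess.data[ii, jj],
            "segment": self.segment[ii],
        })


def sectorize(
    elements: pd.DataFrame,
    interval_um: float = INTERVAL_UM,
    start_um: float = 0.0,
    segment_bounds_um: tuple | None = None,
) -> ESSMap:
    """Bin wall elements into the 5-degree x ``interval_um`` grid.

    ``elements`` needs columns ``axial_um``, ``angle_deg``, ``wss_pa`` and
    (optionally) ``area_m2`` for area weighting; missing areas weight equally.
    ``segment_bounds_um`` = (scaffold_start, scaffold_end) labels intervals;
    without it every interval is labelled scaffolded.
    """
    ang = elements["angle_deg"].to_numpy(dtype=float)
    if np.any((ang < 0) | (ang >= 360.0)):
        raise ValueError("element angles must lie in [0, 360)")
    z = elements["axial_um"].to_numpy(dtype=float) - start_um
    if np.any(z < 0):
        raise ValueError("element axial positions precede the map start")
    wss = elements["wss_pa"].to_numpy(dtype=float)
    area = (elements["area_m2"].to_numpy(dtype=float)
            if "area_m2" in elements.columns else np.ones_like(wss))

    ki = np.floor(z / interval_um).astype(int)
    kj = np.floor(ang / SECTOR_DEG).astype(int)
    n_int = int(ki.max()) + 1
    flat = ki * N_SECTORS + kj
    size = n_int * N_SECTORS
    wsum = np.bincount(flat, weights=area * wss, minlength=size)
    asum = np.bincount(flat, weights=area, minlength=size)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (wsum / asum).reshape(n_int, N_SECTORS)
    mask = asum.reshape(n_int, N_SECTORS) <= 0
    ess = np.ma.MaskedArray(np.where(mask, 0.0, vals), mask=mask)

    centers = start_um + (np.arange(n_int) + 0.5) * interval_um
    if segment_bounds_um is None:
        segment = np.full(n_int, SEGMENT_SCAFFOLDED, dtype=object)
    else:
        s0, s1 = segment_bounds_um
        segment = np.where(centers < s0, SEGMENT_PROXIMAL,
                           np.where(centers < s1, SEGMENT_SCAFFOLDED,
                                    SEGMENT_DISTAL)).astype(object)
    return ESSMap(ess=ess, segment=segment, start_um=start_um,
                  interval_um=interval_um)


def replicate_axisymmetric(wall_elements: pd.DataFrame) -> pd.DataFrame:
    """Expand axisymmetric wall elements (no angle) around the circumference:
    each element appears once per 5-degree sector at the sector centre with
    1/72 of its area."""
    reps = []
    centers = SECTOR_DEG * (np.arange(N_SECTORS) + 0.5)
    for c in centers:
        part = wall_elements.copy()
        part["angle_deg"] = c
        if "area_m2" in part.columns:
            part["area_m2"] = part["area_m2"] / N_SECTORS
        reps.append(part)
    return pd.concat(reps, ignore_index=True)


def classify_ess(ess_map: ESSMap):
    """Per-cell labels and low / very-low fractions over covered cells."""
    data = ess_map.ess
    labels = np.full(data.shape, "normal", dtype=object)
    labels[(~data.mask) & (data.data < LOW_ESS_PA)] = "low"
    labels[(~data.mask) & (data.data < VERY_LOW_ESS_PA)] = "very_low"
    labels[data.mask] = "missing"
    n = float((~data.mask).sum())
    frac_low = float(((~data.mask) & (data.data < LOW_ESS_PA)).sum()) / n
    frac_very_low = float(((~data.mask) & (data.data < VERY_LOW_ESS_PA)).sum()) / n
    return labels, frac_low, frac_very_low


@dataclass
class ESSSummary:
    level: str
    n_cells: int
    mean_pa: float
    sd_pa: float
    median_pa: float
    frac_low: float
    frac_very_low: float


def _stats(cells: np.ma.MaskedArray, level: str) -> ESSSummary:
    vals = cells.compressed()
    if vals.size == 0:
        raise ValueError(f"no covered cells at level {level!r}")
    return ESSSummary(
        level=level,
        n_cells=int(vals.size),
        mean_pa=float(np.mean(vals)),
        sd_pa=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
        median_pa=float(np.median(vals)),
        frac_low=float(np.mean(vals < LOW_ESS_PA)),
        frac_very_low=float(np.mean(vals < VERY_LOW_ESS_PA)),
    )


def summarize(ess_map: ESSMap, level: str = "device"):
    """ESS statistics at the requested level.

    ``device``: one summary over scaffolded cells.  ``segment``: dict of
    summaries for the scaffolded / proximal / distal segments (present ones).
    ``cross_section``: DataFrame of per-interval statistics including the
    per-cross-section median used for distribution-style summaries.
    """
    if level == "device":
        return _stats(ess_map.cells(SEGMENT_SCAFFOLDED), "device")
    if level == "segment":
        out = {}
        for seg in (SEGMENT_SCAFFOLDED, SEGMENT_PROXIMAL, SEGMENT_DISTAL):
            cells = ess_map.cells(seg)
            if cells.size and (~cells.mask).sum() > 0:
                out[seg] = _stats(cells, seg)
        return out
    if level == "cross_section":
        rows = []
        for i in range(ess_map.n_intervals):
            cells = ess_map.ess[i]
            vals = cells.compressed()
            if vals.size == 0:
                continue
            rows.append(dict(
                interval=i,
                segment=ess_map.segment[i],
                n_cells=int(vals.size),
                mean_pa=float(np.mean(vals)),
                sd_pa=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                median_pa=float(np.median(vals)),
                frac_low=float(np.mean(vals < LOW_ESS_PA)),
                frac_very_low=float(np.mean(vals < VERY_LOW_ESS_PA)),
            ))
        if not rows:
            raise ValueError("no covered cells in the map")
        return pd.DataFrame(rows)
    raise ValueError(f"unknown level {level!r}")
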