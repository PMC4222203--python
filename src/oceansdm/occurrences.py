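"""Presence-only occurrence handling.

Parsing of occurrence CSVs, grid-cell deduplication in yearly or monthly
mode, covariate extraction against annual/monthly layer stacks, and
(bias-weighted) background sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import AlignmentError, InputError
from .grids import EnvGrid, EnvStack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OccurrenceRecord:
    lon: float
    lat: float
    month: int | None = None  # 1..12, None = unknown
    source: str = ""


@dataclass
class OccurrenceSet:
    """Deduplicated presence records plus bookkeeping counts."""

    records: list[OccurrenceRecord]
    mode: str  # "yearly" | "monthly"
    n_input: int = 0
    n_dropped_no_month: int = 0

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SampleMatrix:
    """Covariate rows for presences or background points."""

    X: np.ndarray  # (n, p)
    variables: tuple[str, ...]
    role: str  # "presence" | "background"
    cell_ids: list[tuple[int, int]]
    months: np.ndarray  # per-row month, 0 = annual

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.months = np.asarray(self.months, dtype=int)

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx: np.ndarray) -> "SampleMatrix":
        idx = np.asarray(idx)
        return SampleMatrix(
            X=self.X[idx],
            variables=self.variables,
            role=self.role,
            cell_ids=[self.cell_ids[i] for i in np.atleast_1d(idx)],
            months=self.months[idx],
        )

    def select_variables(self, variables: Sequence[str]) -> "SampleMatrix":
        cols = [self.variables.index(v) for v in variables]
        return SampleMatrix(
            X=self.X[:, cols],
            variables=tuple(variables),
            role=self.role,
            cell_ids=list(self.cell_ids),
            months=self.months,
        )


# ---------------------------------------------------------------------------
# parsing

def _parse_month(value) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in ("nan", "none", "na"):
        return None
    try:
        m = int(float(s))
        if 1 <= m <= 12:
            return m
        return None
    except ValueError:
        pass
    try:
        return int(pd.Timestamp(s).month)
    except (ValueError, TypeError):
        return None


def read_occurrences(path: str) -> list[OccurrenceRecord]:
    """Read an occurrence CSV with header lon,lat[,month|date][,source].

    Rows with unparseable or out-of-range coordinates are rejected and the
    count is logged. ``longitude``/``latitude`` column aliases are accepted;
    dates are reduced to their month.
    """
    df = pd.read_csv(path, dtype=str)
    cols = {c.strip().lower(): c for c in df.columns}
    lon_col = cols.get("lon") or cols.get("longitude")
    lat_col = cols.get("lat") or cols.get("latitude")
    if lon_col is None or lat_col is None:
        raise InputError(f"{path}: occurrence CSV must have lon and lat columns")
    month_col = cols.get("month") or cols.get("date")
    source_col = cols.get("source")
    records: list[OccurrenceRecord] = []
    rejected = 0
    for _, row in df.iterrows():
        try:
            lon = float(row[lon_col])
            lat = float(row[lat_col])
        except (TypeError, ValueError):
            rejected += 1
            continue
        if not (np.isfinite(lon) and np.isfinite(lat)) or not (-90.0 <= lat <= 90.0):
            rejected += 1
            continue
        lon = ((lon + 180.0) % 360.0) - 180.0
        month = _parse_month(row[month_col]) if month_col else None
        source = str(row[source_col]) if source_col and pd.notna(row[source_col]) else ""
        records.append(OccurrenceRecord(lon=lon, lat=lat, month=month, source=source))
    if rejected:
        log.warning("%s: rejected %d rows with invalid coordinates", path, rejected)
    return records


# ---------------------------------------------------------------------------
# deduplication

def dedupe(
    records: Sequence[OccurrenceRecord],
    geometry: EnvGrid,
    mode: str = "yearly",
) -> OccurrenceSet:
    """One record per occupied cell (yearly) or per (cell, month) (monthly).

    Monthly mode drops records without a month (counted); yearly mode keeps
    them. The first record in input order wins per key, so the operation is
    deterministic and idempotent.
    """
    if mode not in ("yearly", "monthly"):
        raise InputError(f"unknown dedupe mode {mode!r}")
    if not records:
        raise InputError("no occurrence records to deduplicate")
    seen: dict[tuple, OccurrenceRecord] = {}
    dropped_no_month = 0
    off_grid = 0
    for rec in records:
        cell = geometry.cell_index(rec.lon, rec.lat)
        if cell is None:
            off_grid += 1
            continue
        if mode == "monthly":
            if rec.month is None:
                dropped_no_month += 1
                continue
            key = (cell, rec.month)
        else:
            key = cell
        seen.setdefault(key, rec)
    if off_grid:
        log.warning("dedupe: %d records fell outside the grid", off_grid)
    if dropped_no_month:
        log.info("dedupe(monthly): dropped %d records without month", dropped_no_month)
    if not seen:
        log.warning("dedupe: empty result")
    return OccurrenceSet(
        records=list(seen.values()),
        mode=mode,
        n_input=len(records),
        n_dropped_no_month=dropped_no_month,
    )


# ---------------------------------------------------------------------------
# covariate extraction

def extract_covariates(
    occset: OccurrenceSet,
    annual: EnvStack,
    monthly: Sequence[EnvStack] | None = None,
    mode: str | None = None,
    variables: Sequence[str] | None = None,
) -> SampleMatrix:
    """Per-record covariate rows from the annual or per-month stacks.

    Yearly mode reads every record from the annual stack; monthly mode reads
    each record from the stack of its sampling month. Records on masked
    cells are dropped (logged).
    """
    mode = mode or occset.mode
    variables = tuple(variables) if variables else annual.variables
    if mode == "monthly":
        if monthly is None or len(monthly) != 12:
            raise InputError("monthly mode needs all 12 monthly stacks")
        by_month = {s.month: s for s in monthly}
        if set(by_month) != set(range(1, 13)):
            raise InputError("monthly stacks must cover months 1..12")
    rows, cells, months = [], [], []
    dropped = 0
    geom = annual.reference()
    for rec in occset.records:
        cell = geom.cell_index(rec.lon, rec.lat)
        if cell is None or not annual.mask[cell]:
            dropped += 1
            continue
        if mode == "monthly":
            if rec.month is None:
                dropped += 1
                continue
            stack = by_month[rec.month]
            months.append(rec.month)
        else:
            stack = annual
            months.append(0)
        row = stack.values_at([cell], variables)[0]
        if not np.all(np.isfinite(row)):
            dropped += 1
            months.pop()
            continue
        rows.append(row)
        cells.append(cell)
    if dropped:
        log.warning("extract_covariates: dropped %d records (masked/off-grid/no month)", dropped)
    if not rows:
        raise InputError("no records with valid covariates")
    return SampleMatrix(
        X=np.vstack(rows), variables=variables, role="presence",
        cell_ids=cells, months=np.asarray(months, dtype=int),
    )


# ---------------------------------------------------------------------------
# background sampling

def sample_background(
    stack: EnvStack,
    n: int = 10000,
    bias: EnvGrid | None = None,
    seed: int = 0,
    variables: Sequence[str] | None = None,
) -> SampleMatrix:
    """Draw n ocean cells without replacement, uniformly or bias-weighted."""
    variables = tuple(variables) if variables else stack.variables
    geom = stack.reference()
    ii, jj = np.nonzero(stack.mask)
    n_ocean = ii.size
    if bias is not None:
        if not bias.same_geometry(geom):
            raise AlignmentError("bias grid geometry does not match the stack")
        w = np.where(np.isfinite(bias.values), bias.values, 0.0)[ii, jj]
        if w.min() < 0:
            raise InputError("bias grid has negative weights")
        total = w.sum()
        if total <= 0:
            raise InputError("bias grid is all zero over the ocean")
        p = w / total
        available = int((w > 0).sum())
    else:
        p = None
        available = n_ocean
    if n > available:
        raise InputError(f"cannot draw {n} cells from {available} available without replacement")
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_ocean, size=n, replace=False, p=p)
    cells = [(int(ii[k]), int(jj[k])) for k in pick]
    X = stack.values_at(cells, variables)
    month = stack.month or 0
    return SampleMatrix(
        X=X, variables=variables, role="background",
        cell_ids=cells, months=np.full(n, month, dtype=int),
    )


def sample_background_monthly(
    monthly: Sequence[EnvStack],
    n: int = 10000,
    bias: EnvGrid | None = None,
    seed: int = 0,
    variables: Sequence[str] | None = None,
) -> SampleMatrix:
    """Background for monthly models: cells drawn per month, n split evenly."""
    if len(monthly) != 12:
        raise InputError("need 12 monthly stacks")
    parts = []
    for m, stack in enumerate(monthly, start=1):
        n_m = n // 12 + (1 if m <= n % 12 else 0)
        if n_m == 0:
            continue
        parts.append(sample_background(stack, n=n_m, bias=bias, seed=seed + m, variables=variables))
    X = np.vstack([p.X for p in parts])
    cells = [c for p in parts for c in p.cell_ids]
    months = np.concatenate([p.months for p in parts])
    return SampleMatrix(
        X=X, variables=parts[0].variables, role="background",
        cell_ids=cells, months=months,
    )


def build_bias_grid(
    records: Sequence[OccurrenceRecord],
    geometry: EnvGrid,
    smooth_radius: int = 0,
    floor_frac: float = 1e-6,
) -> EnvGrid:
    """Sampling-effort grid: per-cell record counts, smoothed and floored.

    Smoothing is a moving-window mean of half-width ``smooth_radius`` cells
    (wrapping in longitude). Ocean cells are floored at ``floor_frac`` of
    the maximum so the whole ocean stays admissible as background.
    """
    if not records:
        raise InputError("no records for bias grid")
    counts = np.zeros(geometry.shape)
    for rec in records:
        cell = geometry.cell_index(rec.lon, rec.lat)
        if cell is not None:
            counts[cell] += 1.0
    if smooth_radius > 0:
        size = 2 * int(smooth_radius) + 1
        counts = ndimage.uniform_filter(counts, size=size, mode=("nearest", "wrap"))
    peak = counts.max()
    if peak > 0:
        counts = np.maximum(counts, floor_frac * peak)
    values = np.where(geometry.mask, counts, np.nan)
    return EnvGrid(
        variable="bias", units="1",
        lat=geometry.lat.copy(), lon=geometry.lon.copy(),
        values=values, mask=geometry.mask.copy(),
    )
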