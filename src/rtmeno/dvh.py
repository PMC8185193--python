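"""Dose-volume histogram containers and tabular I/O.

A dose-volume histogram (DVH) summarises how the absorbed dose is distributed
over an organ's volume.  Planning systems export either *differential* DVHs
(fraction of organ volume per dose bin) or *cumulative* DVHs (fraction of
volume receiving at least a given dose), with volumes in either relative
(fraction / percent) or absolute (cm³) units.

The canonical in-memory form here is :class:`DifferentialDVH` with relative
volumes: bins are half-open ``[lower, upper)`` intervals in Gy and the bin
volumes are dimensionless fractions.  Absolute volume, when known, is carried
along as ``total_volume_cc`` and used only as a weight when organs are merged
(e.g. left + right ovary into a single "both ovaries" histogram).

Doses are total physical dose in Gy throughout; no fractionation correction
(EQD2 or similar) is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

TECHNIQUES = ("IFRT", "ISRT")
OVARY_LABEL = "ovaries"

#: Organs-at-risk vocabulary used by the paired plan comparison (free labels
#: are accepted everywhere; this fixes the default row order of reports).
DEFAULT_OAR_ORDER = (
    "small_bowel",
    "bladder",
    "femoral_head_left",
    "femoral_head_right",
    "rectum",
    "spinal_cord",
    "uterus",
    OVARY_LABEL,
)

DEFAULT_BIN_WIDTH = 0.1  # Gy

_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class DifferentialDVH:
    """Binned dose-vs-volume record.

    Parameters
    ----------
    organ
        Organ label (e.g. ``"ovaries"``).
    bin_edges
        Strictly increasing dose values in Gy, length ``B + 1``;
        ``bin_edges[0] >= 0``.  Bin ``i`` is ``[bin_edges[i], bin_edges[i+1])``.
    bin_volume
        Non-negative fractional volume per bin, length ``B``.
    total_volume_cc
        Absolute organ volume in cm³, if known.  Used only as a weight by
        :func:`combine_organs`.
    """

    organ: str
    bin_edges: np.ndarray
    bin_volume: np.ndarray
    total_volume_cc: float | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        vols = np.asarray(self.bin_volume, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "bin_volume", vols)
        if edges.ndim != 1 or vols.ndim != 1 or edges.size != vols.size + 1:
            raise ValidationError(
                f"{self.organ}: need B+1 bin edges for B bin volumes, got "
                f"{edges.size} edges / {vols.size} volumes"
            )
        if vols.size == 0:
            raise ValidationError(f"{self.organ}: empty DVH (no bins)")
        if not np.all(np.isfinite(edges)) or not np.all(np.isfinite(vols)):
            raise ValidationError(f"{self.organ}: non-finite dose or volume")
        if edges[0] < 0:
            raise ValidationError(f"{self.organ}: negative dose edge {edges[0]}")
        if not np.all(np.diff(edges) > 0):
            raise ValidationError(f"{self.organ}: bin edges not strictly increasing")
        if np.any(vols < -1e-12):
            idx = int(np.argmin(vols))
            raise ValidationError(
                f"{self.organ}: negative bin volume {vols[idx]} at bin {idx}"
            )
        if self.total_volume_cc is not None and self.total_volume_cc <= 0:
            raise ValidationError(f"{self.organ}: non-positive total volume")

    @property
    def midpoints(self) -> np.ndarray:
        """Bin midpoints ½(dᵢ + dᵢ₊₁) in Gy."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_fraction(self) -> float:
        return float(self.bin_volume.sum())

    def normalized(self) -> "DifferentialDVH":
        """Return a copy whose bin volumes sum to exactly 1."""
        s = self.total_fraction
        if s <= 0:
            raise ValidationError(f"{self.organ}: cannot normalize all-zero DVH")
        return DifferentialDVH(
            self.organ, self.bin_edges, self.bin_volume / s, self.total_volume_cc
        )


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative DVH: fraction of volume receiving at least each grid dose."""

    organ: str
    dose_grid: np.ndarray
    volume_at_or_above: np.ndarray
    total_volume_cc: float | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.dose_grid, dtype=float)
        voa = np.asarray(self.volume_at_or_above, dtype=float)
        object.__setattr__(self, "dose_grid", grid)
        object.__setattr__(self, "volume_at_or_above", voa)
        if grid.size != voa.size or grid.size < 2:
            raise ValidationError(f"{self.organ}: cumulative DVH needs >= 2 grid points")
        if not np.all(np.diff(grid) > 0) or grid[0] < 0:
            raise ValidationError(f"{self.organ}: dose grid not strictly increasing from >= 0")
        if np.any(np.diff(voa) > 1e-12):
            raise ValidationError(f"{self.organ}: cumulative volume must be non-increasing")
        if abs(voa[0] - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.organ}: cumulative DVH must start at 1 (got {voa[0]})"
            )
        if voa[-1] < -1e-12:
            raise ValidationError(f"{self.organ}: negative tail volume")


@dataclass(frozen=True)
class PlanRecord:
    """One treatment plan for one patient: organ label -> DifferentialDVH."""

    patient_id: str
    technique: str
    organs: Mapping[str, DifferentialDVH] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValidationError(
                f"unknown technique {self.technique!r}; expected one of {TECHNIQUES}"
            )


@dataclass(frozen=True)
class PatientPair:
    """Both plans (IFRT and ISRT) of one patient — the unit of paired analysis."""

    patient_id: str
    ifrt: PlanRecord
    isrt: PlanRecord

    def __post_init__(self) -> None:
        if self.ifrt.patient_id != self.patient_id or self.isrt.patient_id != self.patient_id:
            raise ValidationError(f"{self.patient_id}: plan patient ids disagree")
        if self.ifrt.technique != "IFRT" or self.isrt.technique != "ISRT":
            raise ValidationError(f"{self.patient_id}: plans must be (IFRT, ISRT)")
        for plan in (self.ifrt, self.isrt):
            if not _has_ovaries(plan):
                raise ValidationError(
                    f"{self.patient_id}/{plan.technique}: no ovary DVH "
                    f"('{OVARY_LABEL}' or 'ovary_left'+'ovary_right')"
                )


def _has_ovaries(plan: PlanRecord) -> bool:
    return OVARY_LABEL in plan.organs or (
        "ovary_left" in plan.organs and "ovary_right" in plan.organs
    )


# ---------------------------------------------------------------------------
# conversions


def to_cumulative(d: DifferentialDVH) -> CumulativeDVH:
    """Convert a differential DVH to cumulative form (normalized to start at 1)."""
    s = d.total_fraction
    if s <= 0:
        raise ValidationError(f"{d.organ}: cannot convert all-zero DVH")
    tail = np.concatenate([np.cumsum(d.bin_volume[::-1])[::-1], [0.0]]) / s
    return CumulativeDVH(d.organ, d.bin_edges, tail, d.total_volume_cc)


def to_differential(c: CumulativeDVH) -> DifferentialDVH:
    """Convert cumulative to differential by successive differences.

    Volume still present at the top of the dose grid (``volume_at_or_above[-1]
    > 0``) is carried into one extra bin above the grid so total volume is
    conserved.
    """
    vols = -np.diff(c.volume_at_or_above)
    edges = c.dose_grid.copy()
    residual = float(c.volume_at_or_above[-1])
    if residual > 1e-12:
        step = edges[-1] - edges[-2]
        edges = np.append(edges, edges[-1] + step)
        vols = np.append(vols, residual)
    return DifferentialDVH(c.organ, edges, np.clip(vols, 0.0, None), c.total_volume_cc)


def rebin(d: DifferentialDVH, width: float = DEFAULT_BIN_WIDTH) -> DifferentialDVH:
    """Rebin onto the regular grid 0, width, 2·width, … covering the max dose.

    The volume mass of each input bin is apportioned to output bins in
    proportion to overlap length (i.e. dose is taken as uniform within each
    input bin).  Total volume is conserved exactly.
    """
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    top = d.bin_edges[-1]
    n_out = max(int(np.ceil(top / width - _EDGE_TOL)), 1)
    out_edges = np.arange(n_out + 1) * width
    out = np.zeros(n_out)
    lo_all, hi_all = d.bin_edges[:-1], d.bin_edges[1:]
    for lo, hi, v in zip(lo_all, hi_all, d.bin_volume):
        if v == 0.0:
            continue
        k0 = min(max(int(np.floor(lo / width + _EDGE_TOL)), 0), n_out - 1)
        k1 = min(max(int(np.ceil(hi / width - _EDGE_TOL)), k0 + 1), n_out)
        ks = np.arange(k0, k1)
        overlap = np.minimum(hi, (ks + 1) * width) - np.maximum(lo, ks * width)
        overlap = np.clip(overlap, 0.0, None)
        total = overlap.sum()
        if total <= 0:  # degenerate; dump into containing bin
            out[k0] += v
        else:
            out[k0:k1] += v * overlap / total
    return DifferentialDVH(d.organ, out_edges, out, d.total_volume_cc)


def combine_organs(
    a: DifferentialDVH, b: DifferentialDVH, organ: str | None = None
) -> DifferentialDVH:
    """Volume-weighted merge of two DVHs on a common grid.

    Weights are absolute volumes (``total_volume_cc``) when both are known;
    otherwise the two organs are weighted equally and a warning is logged.
    """
    if a.bin_edges.size != b.bin_edges.size or not np.allclose(
        a.bin_edges, b.bin_edges, atol=_EDGE_TOL, rtol=0.0
    ):
        raise ValueError(
            f"cannot combine {a.organ} and {b.organ}: dose grids differ; "
            "rebin both to a common grid first"
        )
    if a.total_volume_cc is not None and b.total_volume_cc is not None:
        wa, wb = a.total_volume_cc, b.total_volume_cc
        total_cc: float | None = wa + wb
    else:
        logger.warning(
            "combine_organs(%s, %s): absolute volumes unknown, weighting equally",
            a.organ,
            b.organ,
        )
        wa = wb = 1.0
        total_cc = None
    va = a.bin_volume / a.total_fraction
    vb = b.bin_volume / b.total_fraction
    merged = (wa * va + wb * vb) / (wa + wb)
    label = organ if organ is not None else (a.organ if a.organ == b.organ else f"{a.organ}+{b.organ}")
    return DifferentialDVH(label, a.bin_edges, merged, total_cc)


def mean_dose(d: DifferentialDVH) -> float:
    """Mean dose in Gy: Σ midpointᵢ·vᵢ / Σ vᵢ."""
    s = d.total_fraction
    if s <= 0:
        raise ValidationError(f"{d.organ}: mean dose of all-zero DVH is undefined")
    return float(d.midpoints @ d.bin_volume / s)


def max_dose(d: DifferentialDVH, tol: float = 1e-9) -> float:
    """Maximum dose in Gy: upper edge of the highest bin with volume > tol."""
    nonzero = np.flatnonzero(d.bin_volume > tol)
    if nonzero.size == 0:
        raise ValidationError(f"{d.organ}: max dose of all-zero DVH is undefined")
    return float(d.bin_edges[nonzero[-1] + 1])


def ovaries_dvh(plan: PlanRecord, width: float = DEFAULT_BIN_WIDTH) -> DifferentialDVH:
    """Combined both-ovaries DVH of a plan, rebinned to ``width``.

    Uses the pre-combined ``"ovaries"`` entry when present; otherwise merges
    ``ovary_left`` and ``ovary_right`` (volume-weighted when absolute volumes
    are available).
    """
    if OVARY_LABEL in plan.organs:
        return rebin(plan.organs[OVARY_LABEL], width)
    try:
        left = rebin(plan.organs["ovary_left"], width)
        right = rebin(plan.organs["ovary_right"], width)
    except KeyError as exc:
        raise ValidationError(
            f"{plan.patient_id}/{plan.technique}: no ovary DVH present"
        ) from exc
    n = max(left.bin_volume.size, right.bin_volume.size)
    left, right = (_pad_bins(x, n, width) for x in (left, right))
    return combine_organs(left, right, organ=OVARY_LABEL)


def _pad_bins(d: DifferentialDVH, n_bins: int, width: float) -> DifferentialDVH:
    if d.bin_volume.size >= n_bins:
        return d
    edges = np.arange(n_bins + 1) * width
    vols = np.zeros(n_bins)
    vols[: d.bin_volume.size] = d.bin_volume
    return DifferentialDVH(d.organ, edges, vols, d.total_volume_cc)


# ---------------------------------------------------------------------------
# tabular I/O

REQUIRED_COLUMNS = ("patient_id", "technique", "organ", "dose_gy", "volume")


def read_dvh_table(
    path,
    dvh_type: str | None = None,
    volume_kind: str | None = None,
) -> list[PlanRecord]:
    """Read plan DVHs from the package's CSV schema.

    Expected columns: ``patient_id, technique, organ, dvh_type, dose_gy,
    volume, volume_kind[, organ_volume_cc]`` — one bin (differential) or grid
    point (cumulative) per row, doses in Gy, UTF-8, decimal point.  The
    ``dvh_type`` / ``volume_kind`` columns may be omitted if the corresponding
    argument supplies a file-wide value.

    Differential rows give the bin *lower* edge; bins are taken as contiguous
    and the final upper edge extends by the last spacing (0.1 Gy when an organ
    has a single row).  Absolute volumes (cm³) are normalized to fractions
    with the total retained as ``total_volume_cc``.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"DVH table is missing required column: {col!r}")
    for col, arg in (("dvh_type", dvh_type), ("volume_kind", volume_kind)):
        if col not in df.columns:
            if arg is None:
                raise SchemaError(
                    f"DVH table has no {col!r} column and no file-wide value was given"
                )
            df[col] = arg

    bad_dose = df.index[df["dose_gy"] < 0]
    if len(bad_dose):
        raise ValidationError(f"negative dose_gy at row {bad_dose[0]}")
    bad_vol = df.index[df["volume"] < 0]
    if len(bad_vol):
        raise ValidationError(f"negative volume at row {bad_vol[0]}")
    bad_tech = df.index[~df["technique"].isin(TECHNIQUES)]
    if len(bad_tech):
        raise ValidationError(
            f"unknown technique {df.loc[bad_tech[0], 'technique']!r} at row {bad_tech[0]}"
        )
    bad_type = df.index[~df["dvh_type"].isin(("differential", "cumulative"))]
    if len(bad_type):
        raise ValidationError(
            f"unknown dvh_type {df.loc[bad_type[0], 'dvh_type']!r} at row {bad_type[0]}"
        )
    bad_kind = df.index[~df["volume_kind"].isin(("relative", "absolute"))]
    if len(bad_kind):
        raise ValidationError(
            f"unknown volume_kind {df.loc[bad_kind[0], 'volume_kind']!r} at row {bad_kind[0]}"
        )

    plans: dict[tuple[str, str], dict[str, DifferentialDVH]] = {}
    for (pid, tech, organ), grp in df.groupby(
        ["patient_id", "technique", "organ"], sort=True
    ):
        grp = grp.sort_values("dose_gy")
        kinds = grp["dvh_type"].unique()
        if len(kinds) != 1:
            raise ValidationError(f"{pid}/{tech}/{organ}: mixed dvh_type values")
        vkinds = grp["volume_kind"].unique()
        if len(vkinds) != 1:
            raise ValidationError(f"{pid}/{tech}/{organ}: mixed volume_kind values")
        organ_cc = None
        if "organ_volume_cc" in grp.columns:
            cc = grp["organ_volume_cc"].dropna()
            if len(cc):
                organ_cc = float(cc.iloc[0])
        dvh = _build_dvh(
            str(organ),
            grp["dose_gy"].to_numpy(float),
            grp["volume"].to_numpy(float),
            str(kinds[0]),
            str(vkinds[0]),
            organ_cc,
        )
        plans.setdefault((str(pid), str(tech)), {})[str(organ)] = dvh

    return [
        PlanRecord(pid, tech, organs)
        for (pid, tech), organs in sorted(plans.items())
    ]


def _build_dvh(
    organ: str,
    doses: np.ndarray,
    vols: np.ndarray,
    kind: str,
    volume_kind: str,
    organ_cc: float | None,
) -> DifferentialDVH:
    if kind == "cumulative":
        total_cc = organ_cc
        if volume_kind == "absolute":
            if vols[0] <= 0:
                raise ValidationError(f"{organ}: cumulative DVH starts at zero volume")
            total_cc = organ_cc if organ_cc is not None else float(vols[0])
            vols = vols / vols[0]
        elif vols[0] > 0 and abs(vols[0] - 1.0) > 1e-9:
            vols = vols / vols[0]  # e.g. percent exports starting at 100
        return to_differential(CumulativeDVH(organ, doses, vols, total_cc))

    # differential: doses are contiguous bin lower edges
    if doses.size >= 2:
        step = doses[-1] - doses[-2]
    else:
        step = DEFAULT_BIN_WIDTH
    edges = np.append(doses, doses[-1] + step)
    total = float(vols.sum())
    if total <= 0:
        raise ValidationError(f"{organ}: all-zero DVH volumes")
    total_cc = organ_cc
    if volume_kind == "absolute" and total_cc is None:
        total_cc = total
    return DifferentialDVH(organ, edges, vols / total, total_cc)


def write_dvh_table(records: Iterable[PlanRecord], path) -> None:
    """Write plan records to the package CSV schema (differential, relative)."""
    rows = []
    for rec in records:
        for organ, d in rec.organs.items():
            for lo, v in zip(d.bin_edges[:-1], d.bin_volume):
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "technique": rec.technique,
                        "organ": organ,
                        "dvh_type": "differential",
                        "dose_gy": lo,
                        "volume": v,
                        "volume_kind": "relative",
                        "organ_volume_cc": d.total_volume_cc,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def pair_plans(records: Iterable[PlanRecord]) -> list[PatientPair]:
    """Group plan records into per-patient IFRT/ISRT pairs.

    Patients missing either technique are dropped with a logged warning.
    """
    by_patient: dict[str, dict[str, PlanRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, {})[rec.technique] = rec
    pairs = []
    for pid in sorted(by_patient):
        plans = by_patient[pid]
        if set(plans) != set(TECHNIQUES):
            logger.warning("patient %s lacks one technique; dropped from pairing", pid)
            continue
        pairs.append(PatientPair(pid, plans["IFRT"], plans["ISRT"]))
    return pairs
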