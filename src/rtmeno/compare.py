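"""Paired IFRT-vs-ISRT cohort comparison with the exact sign test.

Each patient contributes one plan per technique, so every endpoint (organ
mean/max dose, surviving NGF percentage, predicted time to menopause at each
theoretical treatment age) yields one within-patient difference.  The
endpoints are bounded, skewed and floored at zero, so significance is
assessed with the exact paired sign test: ties (differences within a
tolerance of zero) are excluded and the two-sided p-value is the doubled
binomial(n, ½) tail of the larger sign count, capped at 1.

Sign conventions: dose differences are IFRT − ISRT; surviving-NGF and
time-to-menopause differences are ISRT − IFRT (the *gain* from the smaller
target volume).  The two-sided p-value is unaffected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dvh import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_OAR_ORDER,
    DifferentialDVH,
    PatientPair,
    max_dose,
    mean_dose,
    ovaries_dvh,
)
from .follicle import dvh_survival_fraction
from .menopause import AgeGrid, time_to_menopause

logger = logging.getLogger(__name__)

#: Differences at or below this are treated as ties for dose endpoints.
DOSE_ZERO_TOL = 1e-9
#: Tie tolerance for time-to-menopause rows: half the 0.01-year rounding unit,
#: so two times equal after rounding count as a tie.
TIME_ZERO_TOL = 0.005

#: Organs whose comparison metric is the maximum rather than the mean dose.
MAX_DOSE_ORGANS = frozenset({"spinal_cord"})


@dataclass(frozen=True)
class SignTestResult:
    """Exact paired sign test summary."""

    n_total: int
    n_nonzero: int
    n_positive: int
    p_two_sided: float


@dataclass(frozen=True)
class ComparisonRow:
    """One endpoint's per-arm summary plus the paired test."""

    metric: str
    n: int
    mean_ifrt: float
    sd_ifrt: float
    mean_isrt: float
    sd_isrt: float
    mean_diff: float
    sd_diff: float
    test: SignTestResult


def exact_sign_test(
    differences: Sequence[float], zero_tolerance: float = DOSE_ZERO_TOL
) -> SignTestResult:
    """Exact two-sided sign test on paired differences.

    Differences with ``|d| <= zero_tolerance`` are excluded as ties; on the
    ``m`` remaining, ``p = min(1, 2·P[Bin(m, ½) >= max(k, m−k)])`` where ``k``
    is the number of positive differences.  ``m = 0`` gives ``p = 1``.
    """
    d = np.asarray(list(differences), dtype=float)
    if d.size == 0:
        raise ValueError("sign test needs at least one paired observation")
    nonzero = np.abs(d) > zero_tolerance
    m = int(nonzero.sum())
    k = int((d[nonzero] > 0).sum())
    if m == 0:
        p = 1.0
    else:
        k_major = max(k, m - k)
        p = min(1.0, 2.0 * float(stats.binom.sf(k_major - 1, m, 0.5)))
    return SignTestResult(n_total=int(d.size), n_nonzero=m, n_positive=k, p_two_sided=p)


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def _row(
    metric: str,
    ifrt: np.ndarray,
    isrt: np.ndarray,
    diffs: np.ndarray,
    zero_tolerance: float,
) -> ComparisonRow:
    return ComparisonRow(
        metric=metric,
        n=int(ifrt.size),
        mean_ifrt=float(ifrt.mean()),
        sd_ifrt=_sd(ifrt),
        mean_isrt=float(isrt.mean()),
        sd_isrt=_sd(isrt),
        mean_diff=float(diffs.mean()),
        sd_diff=_sd(diffs),
        test=exact_sign_test(diffs, zero_tolerance),
    )


def compare_oar_doses(
    cohort: Sequence[PatientPair],
    organs: Sequence[str] | None = None,
    zero_tolerance: float = DOSE_ZERO_TOL,
) -> list[ComparisonRow]:
    """Per-organ dose summary (mean dose; max dose for the spinal cord).

    Differences are IFRT − ISRT.  A patient missing an organ in either plan is
    excluded from that organ's row with a logged warning.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if organs is None:
        present: set[str] = set()
        for pair in cohort:
            present |= set(pair.ifrt.organs) | set(pair.isrt.organs)
        organs = [o for o in DEFAULT_OAR_ORDER if o in present]
        organs += sorted(present - set(DEFAULT_OAR_ORDER) - {"ovary_left", "ovary_right"})
    rows = []
    for organ in organs:
        metric_fn = max_dose if organ in MAX_DOSE_ORGANS else mean_dose
        ifrt_vals, isrt_vals = [], []
        excluded = 0
        for pair in cohort:
            if organ not in pair.ifrt.organs or organ not in pair.isrt.organs:
                excluded += 1
                continue
            ifrt_vals.append(metric_fn(pair.ifrt.organs[organ]))
            isrt_vals.append(metric_fn(pair.isrt.organs[organ]))
        if excluded:
            logger.warning("%s: %d patient(s) excluded (organ missing)", organ, excluded)
        if not ifrt_vals:
            continue
        ifrt_arr, isrt_arr = np.asarray(ifrt_vals), np.asarray(isrt_vals)
        suffix = "dmax_gy" if organ in MAX_DOSE_ORGANS else "dmean_gy"
        rows.append(
            _row(f"{organ}_{suffix}", ifrt_arr, isrt_arr, ifrt_arr - isrt_arr, zero_tolerance)
        )
    return rows


def _cohort_survival(
    cohort: Sequence[PatientPair], bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    g_ifrt = np.array(
        [float(dvh_survival_fraction(ovaries_dvh(p.ifrt, bin_width), None)) for p in cohort]
    )
    g_isrt = np.array(
        [float(dvh_survival_fraction(ovaries_dvh(p.isrt, bin_width), None)) for p in cohort]
    )
    return g_ifrt, g_isrt


def surviving_ngf_summary(
    cohort: Sequence[PatientPair],
    bin_width: float = DEFAULT_BIN_WIDTH,
    zero_tolerance: float = DOSE_ZERO_TOL,
) -> ComparisonRow:
    """Per-arm surviving-NGF percentage summary; differences are ISRT − IFRT."""
    if not cohort:
        raise ValueError("empty cohort")
    g_ifrt, g_isrt = _cohort_survival(cohort, bin_width)
    return _row("surviving_ngf_percent", g_ifrt, g_isrt, g_isrt - g_ifrt, zero_tolerance)


def compare_menopause(
    cohort: Sequence[PatientPair],
    grid: AgeGrid | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    zero_tolerance: float = TIME_ZERO_TOL,
) -> list[ComparisonRow]:
    """Per-age time-to-menopause comparison over the theoretical age grid.

    For each patient and arm, the combined both-ovaries DVH is converted to a
    surviving-NGF percentage, then to a predicted time to menopause at every
    grid age.  Differences are the ISRT − IFRT time gain; ties within
    ``zero_tolerance`` years (default: half the reporting rounding unit) are
    excluded from the sign test.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if grid is None:
        grid = AgeGrid()
    g_ifrt, g_isrt = _cohort_survival(cohort, bin_width)
    rows = []
    for age in grid:
        t_ifrt = np.array([time_to_menopause(age, g).time_to_menopause for g in g_ifrt])
        t_isrt = np.array([time_to_menopause(age, g).time_to_menopause for g in g_isrt])
        rows.append(
            _row(f"age_{age:g}", t_ifrt, t_isrt, t_isrt - t_ifrt, zero_tolerance)
        )
    return rows


def rows_to_frame(rows: Iterable[ComparisonRow]) -> pd.DataFrame:
    """Tabulate comparison rows (one endpoint per row)."""
    return pd.DataFrame(
        {
            "metric": r.metric,
            "n": r.n,
            "mean_ifrt": r.mean_ifrt,
            "sd_ifrt": r.sd_ifrt,
            "mean_isrt": r.mean_isrt,
            "sd_isrt": r.sd_isrt,
            "mean_diff": r.mean_diff,
            "sd_diff": r.sd_diff,
            "n_nonzero": r.test.n_nonzero,
            "p_value": r.test.p_two_sided,
        }
        for r in rows
    )
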