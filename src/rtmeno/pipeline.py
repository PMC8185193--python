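"""End-to-end report assembly: doses → survival → menopause + hormone fits."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .compare import (
    DOSE_ZERO_TOL,
    TIME_ZERO_TOL,
    compare_menopause,
    compare_oar_doses,
    rows_to_frame,
    surviving_ngf_summary,
)
from .dvh import DEFAULT_BIN_WIDTH, pair_plans, read_dvh_table
from .hormones import fit_cohort, group_summary, read_hormone_table
from .menopause import AgeGrid
from .simulate import DvhSimConfig, HormoneSimConfig, simulate_hormone_cohort, simulate_paired_dvh_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full analysis run.

    When ``dvh_csv`` / ``hormone_csv`` are ``None`` the corresponding cohort
    is simulated from ``seed`` with the default generator calibration.
    """

    out_dir: str = "rtmeno_report"
    dvh_csv: str | None = None
    hormone_csv: str | None = None
    seed: int = 0
    n_patients: int = 13
    n_hormone: int = 499
    bin_width: float = DEFAULT_BIN_WIDTH
    age_start: float = 18.0
    age_stop: float = 48.0
    age_step: float = 2.0
    dose_zero_tol: float = DOSE_ZERO_TOL
    time_zero_tol: float = TIME_ZERO_TOL
    sex_coding: str = "halves"
    report_format: str = "csv"

    def age_grid(self) -> AgeGrid:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        ages, a = [], self.age_start
        while a <= self.age_stop + 1e-9:
            ages.append(round(a, 6))
            a += self.age_step
        return AgeGrid(tuple(ages))


def _round(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(decimals)
    return out


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every pipeline stage and write the report bundle.

    Produces organ-dose, time-to-menopause, regression and group-summary
    tables plus a JSON manifest (versions, seed, config echo).  Partial
    outputs are removed if any stage fails.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        df = _round(df)
        if cfg.report_format == "markdown":
            path = out_dir / f"{name}.md"
            header = "| " + " | ".join(df.columns) + " |"
            sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
            body = [
                "| " + " | ".join(str(v) for v in row) + " |"
                for row in df.itertuples(index=False)
            ]
            path.write_text("\n".join([header, sep, *body]) + "\n")
        else:
            path = out_dir / f"{name}.csv"
            df.to_csv(path, index=False, float_format="%.2f")
        written.append(path)

    try:
        if cfg.dvh_csv is not None:
            plans = read_dvh_table(cfg.dvh_csv)
            cohort = pair_plans(plans)
        else:
            cohort = simulate_paired_dvh_cohort(
                DvhSimConfig(n_patients=cfg.n_patients, seed=cfg.seed)
            )
        if not cohort:
            raise ValueError("empty DVH cohort: nothing to compare")
        oar_rows = compare_oar_doses(cohort, zero_tolerance=cfg.dose_zero_tol)
        oar_rows.append(
            surviving_ngf_summary(cohort, cfg.bin_width, cfg.dose_zero_tol)
        )
        emit("oar_doses", rows_to_frame(oar_rows))

        meno_rows = compare_menopause(
            cohort, cfg.age_grid(), cfg.bin_width, cfg.time_zero_tol
        )
        meno = rows_to_frame(meno_rows)
        meno.insert(0, "age_years", [float(a) for a in cfg.age_grid()])
        emit("time_to_menopause", meno)

        if cfg.hormone_csv is not None:
            hormones = read_hormone_table(cfg.hormone_csv)
        else:
            hormones = simulate_hormone_cohort(
                HormoneSimConfig(n=cfg.n_hormone, seed=cfg.seed)
            )
        fits = fit_cohort(hormones, sex_coding=cfg.sex_coding)
        reg = pd.DataFrame(
            {
                "term": fits["log_fsh"].terms,
                "coef_fsh": fits["log_fsh"].coefficients,
                "p_fsh": fits["log_fsh"].p_values,
                "coef_lh": fits["log_lh"].coefficients,
                "p_lh": fits["log_lh"].p_values,
            }
        )
        emit("hormone_regression", reg)
        emit("hormone_groups", group_summary(hormones))

        manifest = {
            "rtmeno_version": __version__,
            "versions": _library_versions(),
            "seed": cfg.seed,
            "config": dataclasses.asdict(cfg),
            "n_patient_pairs": len(cohort),
            "n_hormone_records": len(hormones),
            "coding_note": fits["log_fsh"].coding_note,
            "outputs": [p.name for p in written],
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(manifest_path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return {"out_dir": str(out_dir), "outputs": [str(p) for p in written]}


def _library_versions() -> dict[str, str]:
    import numpy, pandas, scipy, statsmodels  # noqa: PLC0415

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "statsmodels": statsmodels.__version__,
    }
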