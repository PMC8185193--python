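"""Seeded synthetic cohorts: paired-plan DVHs and hormone records.

No per-patient planning data is distributed with the package, so these
generators produce cohorts with the statistical structure the analysis
assumes, calibrated to published summary statistics.

*Paired DVH cohorts.*  Each patient's ovarian (and other organ-at-risk) DVH
is a two-component mixture: a fraction ``f`` of the organ near the
prescription dose (the in-field component) and the remainder in a low-dose
bath — the minimal shape capturing how arc-therapy plans trade conformal
high dose for a widespread low-dose wash.  Per-patient target mean doses are
drawn from truncated normals whose location and scale are solved so the
*truncated* mean and SD equal the configured cohort targets, and the two
techniques are coupled comonotonically (one shared uniform per patient and
organ), which preserves both marginals while enforcing the hard constraint
that the smaller target volume never increases the dose: ISRT mean dose ≤
IFRT mean dose in every patient.

*Hormone cohorts.*  Covariates are drawn from configured group frequencies;
log-scale outcomes are the linear predictor of the regression design (same
coding as :func:`rtmeno.hormones.build_design`) plus normal residuals, then
exponentiated back to U/L.

A single integer seed drives a named substream per patient, so enlarging a
cohort never reshuffles already-generated patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .dvh import DifferentialDVH, PatientPair, PlanRecord, mean_dose
from .errors import ConfigurationError
from .hormones import (
    OUTCOMES,
    TERMS,
    HormoneRecord,
    build_design,
)

#: Cohort (mean, SD) calibration targets for organ dose summaries, in Gy,
#: per technique.  Spinal-cord values are maximum dose; all others mean dose.
DEFAULT_DOSE_TARGETS: dict[str, dict[str, tuple[float, float]]] = {
    "small_bowel": {"IFRT": (13.29, 1.52), "ISRT": (7.88, 2.65)},
    "bladder": {"IFRT": (11.67, 3.56), "ISRT": (8.74, 3.36)},
    "femoral_head_left": {"IFRT": (17.51, 4.10), "ISRT": (14.47, 4.89)},
    "femoral_head_right": {"IFRT": (9.40, 7.23), "ISRT": (5.02, 5.13)},
    "rectum": {"IFRT": (10.03, 4.01), "ISRT": (6.44, 3.48)},
    "spinal_cord": {"IFRT": (18.88, 1.43), "ISRT": (15.06, 2.85)},
    "uterus": {"IFRT": (14.51, 5.41), "ISRT": (8.94, 4.43)},
}

#: Ovarian mean-dose (mean, SD) targets per technique, in Gy.
DEFAULT_OVARY_TARGETS: dict[str, tuple[float, float]] = {
    "IFRT": (15.13, 6.34),
    "ISRT": (7.44, 5.64),
}

#: Generating coefficients for the hormone simulator, by outcome and term
#: (same coding as the regression design: age z-scored, sex ±½ female
#: positive, ABVD = 1 vs 2+2 = 0, IDRT = 1 vs SDRT = 0).
DEFAULT_HORMONE_COEFFICIENTS: dict[str, dict[str, float]] = {
    "log_fsh": {
        "intercept": 2.069,
        "age_z": 0.039,
        "sex": 0.101,
        "age_sex": -0.040,
        "chemo_abvd": -0.634,
        "rt_idrt": 0.598,
    },
    "log_lh": {
        "intercept": 1.624,
        "age_z": 0.033,
        "sex": -0.036,
        "age_sex": -0.056,
        "chemo_abvd": -0.243,
        "rt_idrt": 0.349,
    },
}


@dataclass(frozen=True)
class DvhSimConfig:
    """Configuration for the paired-plan DVH generator."""

    n_patients: int = 13
    seed: int = 0
    prescription_dose: float = 30.0
    mean_dose_targets: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OVARY_TARGETS)
    )
    oar_dose_targets: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DOSE_TARGETS.items()}
    )
    in_field_fraction_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"IFRT": (0.0, 1.0), "ISRT": (0.0, 1.0)}
    )
    bath_dose_range: tuple[float, float] = (0.2, 3.0)
    oar_list: tuple[str, ...] = (
        "ovaries",
        "uterus",
        "small_bowel",
        "rectum",
        "bladder",
        "spinal_cord",
        "femoral_head_left",
        "femoral_head_right",
    )
    bin_width: float = 0.1

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.prescription_dose <= 0:
            raise ConfigurationError("prescription dose must be positive")
        lo, hi = self.bath_dose_range
        if not (0 <= lo <= hi):
            raise ConfigurationError(f"invalid bath dose range {self.bath_dose_range}")
        for tech, (m, s) in self.mean_dose_targets.items():
            if s < 0:
                raise ConfigurationError(f"{tech}: negative target SD")
            if not (0 < m < self.prescription_dose):
                raise ConfigurationError(
                    f"{tech}: target mean {m} Gy not attainable below the "
                    f"{self.prescription_dose} Gy prescription"
                )
        for tech, (f_lo, f_hi) in self.in_field_fraction_range.items():
            if not (0 <= f_lo <= f_hi <= 1):
                raise ConfigurationError(f"{tech}: invalid in-field fraction range")

    def targets_for(self, organ: str) -> Mapping[str, tuple[float, float]]:
        if organ == "ovaries":
            return self.mean_dose_targets
        try:
            return self.oar_dose_targets[organ]
        except KeyError as exc:
            raise ConfigurationError(f"no dose targets configured for {organ!r}") from exc


@dataclass(frozen=True)
class HormoneSimConfig:
    """Configuration for the hormone-cohort generator."""

    n: int = 499
    seed: int = 0
    coefficients: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_HORMONE_COEFFICIENTS.items()}
    )
    residual_sd: float = 0.8
    idrt_fraction: float = 0.042
    female_fraction: float = 258 / 499
    abvd_fraction: float = 0.5
    sex_coding: str = "halves"
    months_since_rt_mean: float = 41.4
    months_since_rt_sd: float = 19.2

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if self.residual_sd <= 0:
            raise ConfigurationError("residual_sd must be positive")
        for name in ("idrt_fraction", "female_fraction", "abvd_fraction"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ConfigurationError(f"{name} must be a proportion in [0, 1]")
        for outcome, coefs in self.coefficients.items():
            if outcome not in OUTCOMES:
                raise ConfigurationError(f"unknown outcome {outcome!r}")
            unknown = set(coefs) - set(TERMS)
            if unknown:
                raise ConfigurationError(f"unknown coefficient terms {sorted(unknown)}")


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


_DIST_CACHE: dict[tuple[float, float, float, float], object] = {}


class _UpperTruncatedGamma:
    """Gamma conditioned on [0, upper], sampled through its quantile function."""

    def __init__(self, shape: float, scale: float, upper: float) -> None:
        self.shape, self.scale = shape, scale
        self.cap = float(stats.gamma.cdf(upper, shape, scale=scale))

    def ppf(self, u):
        return stats.gamma.ppf(np.asarray(u) * self.cap, self.shape, scale=self.scale)


def _solve_moments(gap, x0, mean, sd, lower, upper, family: str):
    sol, _info, ier, msg = optimize.fsolve(gap, x0, full_output=True)
    if ier != 1 or not np.allclose(gap(sol), 0.0, atol=1e-6):
        raise ConfigurationError(
            f"cannot calibrate {family} to mean={mean}, sd={sd} "
            f"on [{lower}, {upper}]: {msg}"
        )
    return sol


def calibrated_truncnorm(mean: float, sd: float, lower: float, upper: float):
    """Truncated normal on [lower, upper] whose truncated mean/SD hit targets.

    The location and scale of the parent normal are solved numerically so the
    distribution after truncation has exactly the requested moments — naive
    truncation of N(mean, sd) would bias the mean away from the boundary.
    """

    def gap(params):
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (lower - loc) / scale, (upper - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = _solve_moments(gap, [mean, np.log(sd)], mean, sd, lower, upper, "truncated normal")
    loc, scale = float(sol[0]), float(np.exp(sol[1]))
    return stats.truncnorm((lower - loc) / scale, (upper - loc) / scale, loc=loc, scale=scale)


def _calibrated_truncgamma(mean: float, sd: float, upper: float):
    """Gamma conditioned on [0, upper] with the conditioned mean/SD matched."""

    def gap(params):
        k, theta = np.exp(params)
        f0 = stats.gamma.cdf(upper, k, scale=theta)
        f1 = stats.gamma.cdf(upper, k + 1, scale=theta)
        f2 = stats.gamma.cdf(upper, k + 2, scale=theta)
        m1 = k * theta * f1 / f0
        m2 = k * (k + 1) * theta**2 * f2 / f0
        return [m1 - mean, np.sqrt(max(m2 - m1**2, 1e-12)) - sd]

    x0 = [np.log((mean / sd) ** 2), np.log(sd**2 / mean)]
    sol = _solve_moments(gap, x0, mean, sd, 0.0, upper, "truncated gamma")
    k, theta = (float(np.exp(v)) for v in sol)
    return _UpperTruncatedGamma(k, theta, upper)


def calibrated_dose_distribution(mean: float, sd: float, lower: float, upper: float):
    """Per-patient target-dose distribution with exact cohort moments.

    Uses a moment-calibrated truncated normal; when the requested coefficient
    of variation exceeds what that family can reach near a boundary (e.g.
    femoral-head doses with SD ≈ mean), falls back to a gamma conditioned on
    the same support, calibrated the same way.
    """
    key = (round(mean, 9), round(sd, 9), round(lower, 9), round(upper, 9))
    if key in _DIST_CACHE:
        return _DIST_CACHE[key]
    if sd == 0:
        dist = stats.norm(loc=mean, scale=1e-12)  # effectively a point mass
    else:
        try:
            dist = calibrated_truncnorm(mean, sd, lower, upper)
        except ConfigurationError:
            dist = _calibrated_truncgamma(mean, sd, upper)
    _DIST_CACHE[key] = dist
    return dist


def _two_component_dvh(
    organ: str, f: float, spike_dose: float, bath_dose: float, width: float
) -> DifferentialDVH:
    top = max(spike_dose, bath_dose)
    n_bins = int(np.floor(top / width)) + 1
    edges = np.arange(n_bins + 1) * width
    vols = np.zeros(n_bins)
    vols[min(int(bath_dose // width), n_bins - 1)] += 1.0 - f
    vols[min(int(spike_dose // width), n_bins - 1)] += f
    return DifferentialDVH(organ, edges, vols)


def _organ_dvh(
    cfg: DvhSimConfig,
    organ: str,
    technique: str,
    target_mean: float,
    bath_dose: float,
    spike_dose: float,
    u_extra: float,
) -> DifferentialDVH:
    f_lo, f_hi = cfg.in_field_fraction_range.get(technique, (0.0, 1.0))
    if organ == "spinal_cord":
        # summarised by D_max: put the spike at the drawn value itself
        f = f_lo + (f_hi - f_lo) * (0.3 + 0.4 * u_extra)
        bath = min(bath_dose, 0.5 * target_mean)
        return _two_component_dvh(organ, f, target_mean, bath, cfg.bin_width)
    m, b, s = target_mean, bath_dose, spike_dose
    f_raw = (m - b) / (s - b)
    s_eff, b_eff = s, b
    if f_raw > 1.0 and f_hi >= 1.0:
        f, s_eff = 1.0, m  # target above the spike: move the spike (m <= 1.05·Rx)
    elif f_raw < 0.0 and f_lo <= 0.0:
        f, b_eff = 0.0, min(b, max(m, 0.0))  # target below the bath
    else:
        f = float(np.clip(f_raw, f_lo, f_hi))
    return _two_component_dvh(organ, f, s_eff, b_eff, cfg.bin_width)


def simulate_paired_dvh_cohort(cfg: DvhSimConfig | None = None) -> list[PatientPair]:
    """Generate a cohort of paired IFRT/ISRT plan records.

    Fully reproducible per seed; per-patient ISRT ovarian mean dose never
    exceeds the IFRT mean dose.
    """
    cfg = cfg or DvhSimConfig()
    cfg.validate()
    upper = 1.05 * cfg.prescription_dose
    dists = {
        organ: {
            tech: calibrated_dose_distribution(m, s, 0.0, upper)
            for tech, (m, s) in cfg.targets_for(organ).items()
        }
        for organ in cfg.oar_list
    }
    spike_dist = stats.truncnorm(
        (0.9 * cfg.prescription_dose - cfg.prescription_dose) / (0.02 * cfg.prescription_dose),
        (upper - cfg.prescription_dose) / (0.02 * cfg.prescription_dose),
        loc=cfg.prescription_dose,
        scale=0.02 * cfg.prescription_dose,
    )
    pairs = []
    for i in range(cfg.n_patients):
        rng = _patient_rng(cfg.seed, i)
        pid = f"P{i + 1:03d}"
        organs: dict[str, dict[str, DifferentialDVH]] = {"IFRT": {}, "ISRT": {}}
        for organ in cfg.oar_list:
            u = rng.uniform()
            bath = rng.uniform(*cfg.bath_dose_range)
            spike = float(spike_dist.ppf(rng.uniform()))
            u_extra = rng.uniform()
            m_ifrt = float(dists[organ]["IFRT"].ppf(u))
            m_isrt = min(float(dists[organ]["ISRT"].ppf(u)), m_ifrt)
            organs["IFRT"][organ] = _organ_dvh(
                cfg, organ, "IFRT", m_ifrt, bath, spike, u_extra
            )
            organs["ISRT"][organ] = _organ_dvh(
                cfg, organ, "ISRT", m_isrt, bath, spike, u_extra
            )
        if mean_dose(organs["ISRT"]["ovaries"]) > mean_dose(organs["IFRT"]["ovaries"]):
            organs["ISRT"]["ovaries"] = organs["IFRT"]["ovaries"]  # hard constraint
        pairs.append(
            PatientPair(
                pid,
                PlanRecord(pid, "IFRT", organs["IFRT"]),
                PlanRecord(pid, "ISRT", organs["ISRT"]),
            )
        )
    return pairs


def simulate_hormone_cohort(cfg: HormoneSimConfig | None = None) -> list[HormoneRecord]:
    """Generate a hormone cohort from the configured linear model.

    Covariates are drawn per the configured group frequencies (ages uniform
    within the cohort's eligibility windows); log-scale outcomes are the
    design's linear predictor under the generating coefficients plus
    Normal(0, residual_sd) noise, exponentiated back to U/L.
    """
    cfg = cfg or HormoneSimConfig()
    cfg.validate()
    draws = []
    for i in range(cfg.n):
        rng = _patient_rng(cfg.seed, i)
        sex = "female" if rng.uniform() < cfg.female_fraction else "male"
        age_hi = 39.9 if sex == "female" else 49.9
        age = float(rng.uniform(18.0, age_hi))
        chemo = "ABVD" if rng.uniform() < cfg.abvd_fraction else "2+2"
        rt = "IDRT" if rng.uniform() < cfg.idrt_fraction else "SDRT"
        eps = rng.normal(0.0, cfg.residual_sd, size=2)
        months = float(
            max(1.0, rng.normal(cfg.months_since_rt_mean, cfg.months_since_rt_sd))
        )
        draws.append((sex, age, chemo, rt, eps, months))

    # placeholder hormones to build the design with the cohort's own coding
    proto = [
        HormoneRecord(f"H{i + 1:04d}", sex, age, chemo, rt, 1.0, 1.0, months)
        for i, (sex, age, chemo, rt, _, months) in enumerate(draws)
    ]
    design = build_design(proto, sex_coding=cfg.sex_coding)
    betas = {
        outcome: np.array(
            [cfg.coefficients.get(outcome, {}).get(term, 0.0) for term in TERMS]
        )
        for outcome in OUTCOMES
    }
    eta_fsh = design.X @ betas["log_fsh"]
    eta_lh = design.X @ betas["log_lh"]
    records = []
    for i, (sex, age, chemo, rt, eps, months) in enumerate(draws):
        records.append(
            HormoneRecord(
                patient_id=f"H{i + 1:04d}",
                sex=sex,
                age=age,
                chemo=chemo,
                rt_field=rt,
                fsh=float(np.exp(eta_fsh[i] + eps[0])),
                lh=float(np.exp(eta_lh[i] + eps[1])),
                months_since_rt=months,
            )
        )
    return records
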