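"""Predicting time to premature menopause from surviving ovarian reserve.

The normal decline of the non-growing follicle (NGF) pool with age is
described by Hansen's model

    log10 n(age) = −0.00019 · age^2.452 + 5.717,

an NGF count of ≈ 5.2·10⁵ at birth falling monotonically thereafter.  After
irradiation a woman of age ``a`` retains ``n(a) · g/100`` follicles, where
``g`` is the surviving percentage from the Wallace survival function.  Her
*effective reproductive age* ``r`` is the age whose normal reserve equals that
depleted count — the closed-form inverse of the Hansen curve:

    r = ((5.717 − log10 n) / 0.00019)^(1/2.452).

Menopause is predicted when reproductive age reaches 50.4 years (the average
age at natural menopause), so the remaining time is

    t = max(0, 50.4 − r),

floored at zero: a reproductive age already beyond 50.4 means immediate
menopause, not a negative time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .follicle import SurvivalFraction

#: Hansen NGF-decline model constants: log10 n = −A·age^P + C
HANSEN_A = 0.00019
HANSEN_P = 2.452
HANSEN_C = 5.717

#: Average age at natural menopause (years) used as the model's endpoint.
MENOPAUSE_AGE = 50.4


@dataclass(frozen=True)
class MenopausePrediction:
    """Full model chain for one (age at treatment, surviving fraction) cell."""

    age_at_treatment: float
    g_percent: float
    ngf_initial: float
    ngf_post: float
    reproductive_age: float
    time_to_menopause: float


@dataclass(frozen=True)
class AgeGrid:
    """Theoretical ages at start of therapy; default 18–48 years in 2-year steps."""

    ages: tuple[float, ...] = field(
        default_factory=lambda: tuple(range(18, 49, 2))
    )

    def __iter__(self):
        return iter(self.ages)

    def __len__(self) -> int:
        return len(self.ages)


def hansen_ngf(age):
    """NGF count at a given age in years (scalar or array)."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    n = 10.0 ** (-HANSEN_A * age**HANSEN_P + HANSEN_C)
    return float(n) if n.ndim == 0 else n


def effective_reproductive_age(n):
    """Age whose normal NGF count equals ``n`` (inverse of :func:`hansen_ngf`)."""
    n = np.asarray(n, dtype=float)
    n_max = 10.0**HANSEN_C
    if np.any(n <= 0) or np.any(n > n_max * (1 + 1e-12)):
        raise ValueError(f"NGF count must be in (0, {n_max:.4g}]")
    r = np.clip((HANSEN_C - np.log10(n)) / HANSEN_A, 0.0, None) ** (1.0 / HANSEN_P)
    return float(r) if r.ndim == 0 else r


def time_to_menopause(
    age_at_treatment: float, g: SurvivalFraction | float
) -> MenopausePrediction:
    """Predicted time from treatment to premature menopause.

    Chains the Hansen baseline at ``age_at_treatment``, depletion by the
    surviving percentage ``g``, the closed-form inversion back to an effective
    reproductive age, and subtraction from the 50.4-year menopause anchor
    (floored at zero).
    """
    g_percent = float(g)
    if not (0.0 < g_percent <= 100.0):
        raise ValueError(
            f"surviving percentage must be in (0, 100], got {g_percent}"
        )
    if not (0.0 <= age_at_treatment < MENOPAUSE_AGE):
        raise ValueError(
            f"age at treatment must be in [0, {MENOPAUSE_AGE}), got {age_at_treatment}"
        )
    n0 = hansen_ngf(age_at_treatment)
    n_post = n0 * g_percent / 100.0
    r = effective_reproductive_age(n_post)
    t = max(0.0, MENOPAUSE_AGE - r)
    return MenopausePrediction(
        age_at_treatment=float(age_at_treatment),
        g_percent=g_percent,
        ngf_initial=n0,
        ngf_post=n_post,
        reproductive_age=r,
        time_to_menopause=t,
    )


def menopause_grid(
    g: SurvivalFraction | float, grid: AgeGrid | None = None
) -> list[MenopausePrediction]:
    """One :func:`time_to_menopause` prediction per age of ``grid``."""
    if grid is None:
        grid = AgeGrid()
    return [time_to_menopause(age, g) for age in grid]
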