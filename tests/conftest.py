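import numpy as np
import pytest

from rtmeno.dvh import DifferentialDVH, PatientPair, PlanRecord


def grid_dvh(volumes, width=0.1, organ="ovaries", total_cc=None):
    """DVH on the regular grid 0, width, 2·width, … with the given bin volumes."""
    v = np.asarray(volumes, dtype=float)
    edges = np.arange(v.size + 1) * width
    return DifferentialDVH(organ, edges, v, total_cc)


def uniform_dvh(lo, hi, organ="ovaries", total_cc=None):
    """All volume spread uniformly over [lo, hi)."""
    return DifferentialDVH(organ, np.array([lo, hi]), np.array([1.0]), total_cc)


def random_grid_dvh(rng, max_bins=300, width=0.1, organ="ovaries"):
    """Random normalized DVH on the 0.1 Gy grid (sparse nonzero bins)."""
    n = int(rng.integers(2, max_bins))
    v = rng.random(n) * (rng.random(n) < 0.3)
    if v.sum() == 0:
        v[int(rng.integers(0, n))] = 1.0
    return grid_dvh(v / v.sum(), width, organ)


def pair_from_dvhs(pid, ifrt_ovaries, isrt_ovaries, extra=None):
    """Build a PatientPair from two ovary DVHs (plus optional extra organs)."""
    extra = extra or {}
    ifrt_organs = {"ovaries": ifrt_ovaries, **{k: v[0] for k, v in extra.items()}}
    isrt_organs = {"ovaries": isrt_ovaries, **{k: v[1] for k, v in extra.items()}}
    return PatientPair(
        pid,
        PlanRecord(pid, "IFRT", ifrt_organs),
        PlanRecord(pid, "ISRT", isrt_organs),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_pair():
    """One patient: ovaries uniform 10 Gy (IFRT) vs uniform 2 Gy (ISRT)."""
    return pair_from_dvhs(
        "P001",
        uniform_dvh(9.95, 10.05),
        uniform_dvh(1.95, 2.05),
    )
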