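"""Stage-shift interception model of screening survival benefit.

A cohort enters a precancerous stage and progresses through ordered
disease stages (default IEN → I → II → III) in annual steps; progressing
past the last stage means clinical presentation, at which point the stage
at diagnosis is drawn from an observed baseline distribution.  At each
scheduled screening round an undiagnosed individual in stage ``s`` is
intercepted with probability ``sensitivity[s]`` and assigned the 5-year
overall survival of that stage.  The screening benefit is the difference
in expected 5-year survival between the screened and unscreened arms.

The shipped :func:`illustrative_params` are plausible round numbers for a
high-incidence esophageal-cancer setting, intended for demonstrations and
property tests; they are NOT estimates from any specific cohort — users
supply their own rates for real projections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

CLINICAL = "clinical"


@dataclass(frozen=True)
class InterceptionParams:
    """All rates driving the interception model.

    ``progression[i]`` is the annual probability of moving from stage i to
    stage i+1; the last entry is the annual probability of clinical
    presentation from the last stage.  ``baseline_stage_dist`` is the
    stage distribution at clinical diagnosis.  ``test_interval_years`` of
    ``math.inf`` means no screening; 0 means testing at every annual step.
    """

    stages: tuple[str, ...] = ("IEN", "I", "II", "III")
    progression: tuple[float, ...] = (0.1, 0.4, 0.5, 0.6)
    baseline_stage_dist: tuple[float, ...] = (0.0, 0.15, 0.35, 0.5)
    survival_5yr: tuple[float, ...] = (0.95, 0.75, 0.45, 0.2)
    sensitivity: tuple[float, ...] = (0.6, 0.8, 0.85, 0.9)
    test_interval_years: float = 1.0
    horizon_years: int = 30

    def __post_init__(self) -> None:
        n = len(self.stages)
        for name in ("progression", "baseline_stage_dist", "survival_5yr",
                     "sensitivity"):
            v = getattr(self, name)
            if len(v) != n:
                raise ValueError(f"{name} must have one entry per stage")
            if any(not 0.0 <= x <= 1.0 for x in v):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if abs(sum(self.baseline_stage_dist) - 1.0) > 1e-9:
            raise ValueError("baseline_stage_dist must sum to 1")
        if self.test_interval_years < 0:
            raise ValueError("test_interval_years must be >= 0 (inf = none)")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")

    def test_years(self) -> set[int]:
        if math.isinf(self.test_interval_years):
            return set()
        if self.test_interval_years == 0:
            return set(range(self.horizon_years))
        years = set()
        m = 0
        while True:
            t = int(round(m * self.test_interval_years))
            if t >= self.horizon_years:
                break
            years.add(t)
            m += 1
        return years


@dataclass
class InterceptionResult:
    survival_with: float
    survival_without: float
    benefit: float
    detection_distribution: dict[str, float]


def _expected_survival(params: InterceptionParams, screened: bool,
                       ) -> tuple[float, dict[str, float]]:
    n = len(params.stages)
    sens = np.asarray(params.sensitivity if screened else (0.0,) * n)
    prog = np.asarray(params.progression)
    occ = np.zeros(n)
    occ[0] = 1.0
    detected = np.zeros(n)
    clinical = 0.0
    tests = params.test_years()
    for t in range(params.horizon_years):
        if t in tests:
            caught = occ * sens
            detected += caught
            occ -= caught
        moved = occ * prog
        occ -= moved
        clinical += moved[-1]
        occ[1:] += moved[:-1]
    clinical += occ.sum()  # remaining mass presents clinically at horizon

    surv = np.asarray(params.survival_5yr)
    base = np.asarray(params.baseline_stage_dist)
    expected = float(detected @ surv + clinical * (base @ surv))
    dist = {s: float(detected[i]) for i, s in enumerate(params.stages)}
    dist[CLINICAL] = float(clinical)
    return expected, dist


def run_interception(params: InterceptionParams) -> InterceptionResult:
    """Closed-form cohort expectation of screening benefit.

    Exact propagation of the occupancy distribution (no sampling); the
    without-screening arm is the same chain with all sensitivities 0.
    """
    with_screen, dist = _expected_survival(params, screened=True)
    without, _ = _expected_survival(params, screened=False)
    return InterceptionResult(with_screen, without, with_screen - without, dist)


def benefit_curve(params: InterceptionParams,
                  intervals: list[float]) -> list[InterceptionResult]:
    """Run the model at each test interval, all other parameters fixed."""
    if sorted(intervals) != list(intervals):
        raise ValueError("intervals must be sorted")
    return [run_interception(replace(params, test_interval_years=iv))
            for iv in intervals]


def illustrative_params(**overrides) -> InterceptionParams:
    """Default parameter set for demonstrations (synthetic, not cohort-derived)."""
    return replace(InterceptionParams(), **overrides) if overrides else InterceptionParams()
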