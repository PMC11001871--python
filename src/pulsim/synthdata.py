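"""Synthetic murine-cohort simulator.

Generates tumor-volume trajectories for treatment groups combining pulsed
radiotherapy with anti-PD-L1 (or isotype-control) antibody, mirroring the
statistical structure of a 26-group preclinical study: exponential baseline
growth, linear-quadratic (LQ) radiation cell kill applied at pulse days, and a
delayed, time-windowed immune-mediated kill whose strength depends on whether
anti-PD-L1 is pharmacologically active.

The update rule, per animal and per day ``t`` (1-based steps)::

    V <- V * SF(d)                 if a pulse of dose d is delivered at t
    V <- V * exp(rho - K_imm(t))   daily growth / immune kill

with ``SF(d) = exp(-(alpha*d + beta*d**2))`` and ``K_imm(t)`` equal to
``kappa`` when t falls inside the immune window of some earlier pulse
(``[pulse + immune_delay, pulse + immune_delay + immune_duration]``) while
anti-PD-L1 is active, ``kappa_bare`` when the window is open but the drug is
not, and 0 outside any window.  An administration at step ``s`` keeps the
antibody active over ``[s, s + drug_persistence]``.

All randomness flows through :class:`numpy.random.Generator`; identical seeds
give bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGENTS",
    "DynamicsParams",
    "TreatmentSchedule",
    "GroupSummary",
    "GroupDesign",
    "Study",
    "simulate_animal",
    "summarize_group",
    "generate_study",
    "default_study_config",
    "offset_recovery_config",
    "summaries_to_frame",
    "summaries_from_frame",
    "schedules_to_json",
    "schedules_from_json",
]

AGENTS = ("isotype", "anti_pdl1")

#: modelling window in days; the study's measurement horizon
DEFAULT_N_STEPS = 18
#: first radiation pulse lands on step 3 (day 14 post-implantation; the drug
#: schedule starts two days earlier, which defines step 1)
DEFAULT_FIRST_PULSE_STEP = 3
DEFAULT_MEASUREMENT_STEPS = (1, 4, 7, 10, 14, 18)


def _check_finite(name: str, value: float) -> float:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class DynamicsParams:
    """Mechanistic parameters of the tumor/radiation/immune dynamics.

    Parameters
    ----------
    rho
        Baseline exponential growth rate, per day.
    alpha, beta
        LQ cell-kill coefficients, per Gy and per Gy^2.  The defaults give
        alpha/beta = 10 Gy, the conventional tumor value.
    immune_delay
        Days between a radiation pulse and the onset of immune-mediated kill
        (adaptive response needs about a week to develop in a "cold" tumor).
    immune_duration
        Days the immune window stays open after onset.
    kappa
        Maximal immune kill rate (per day) while anti-PD-L1 is active.
    kappa_bare
        Immune kill rate without checkpoint blockade (0 <= kappa_bare <= kappa).
    drug_persistence
        Days an antibody administration remains pharmacologically active;
        2 days reproduces continuous coverage under every-other-day dosing.
    noise_cv
        Inter-animal coefficient of variation applied as log-normal
        multiplicative noise to the initial volume and to rho.
    """

    rho: float = 0.25
    alpha: float = 0.3
    beta: float = 0.03
    immune_delay: float = 7.0
    immune_duration: float = 10.0
    kappa: float = 0.35
    kappa_bare: float = 0.10
    drug_persistence: float = 2.0
    noise_cv: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "rho", "alpha", "beta", "immune_delay", "immune_duration",
            "kappa", "kappa_bare", "drug_persistence", "noise_cv",
        ):
            _check_finite(name, getattr(self, name))
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if not (0 <= self.kappa_bare <= self.kappa):
            raise ValueError("need 0 <= kappa_bare <= kappa")
        if self.immune_delay < 0:
            raise ValueError("immune_delay must be >= 0")
        if self.immune_duration <= 0:
            raise ValueError("immune_duration must be > 0")
        if self.drug_persistence < 0:
            raise ValueError("drug_persistence must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass(frozen=True)
class TreatmentSchedule:
    """Per-day radiation doses and antibody administrations.

    Steps are 1-based; step 1 is the day of the first drug administration.
    """

    n_steps: int = DEFAULT_N_STEPS
    radiation: tuple[tuple[int, float], ...] = ()
    drug: tuple[tuple[int, str], ...] = ()
    measurement_steps: tuple[int, ...] = DEFAULT_MEASUREMENT_STEPS

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "radiation",
            tuple((int(s), float(d)) for s, d in self.radiation),
        )
        object.__setattr__(
            self, "drug", tuple((int(s), str(a)) for s, a in self.drug)
        )
        object.__setattr__(
            self, "measurement_steps",
            tuple(int(s) for s in self.measurement_steps),
        )
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        for s, d in self.radiation:
            if not 1 <= s <= self.n_steps:
                raise ValueError(f"radiation step {s} outside 1..{self.n_steps}")
            if d <= 0:
                raise ValueError(f"radiation dose must be > 0, got {d}")
        for s, a in self.drug:
            if not 1 <= s <= self.n_steps:
                raise ValueError(f"drug step {s} outside 1..{self.n_steps}")
            if a not in AGENTS:
                raise ValueError(f"unknown agent {a!r}; expected one of {AGENTS}")
        ms = self.measurement_steps
        if any(b <= a for a, b in zip(ms, ms[1:])):
            raise ValueError("measurement_steps must be strictly increasing")
        if any(not 1 <= s <= self.n_steps for s in ms):
            raise ValueError("measurement steps outside the window")
        if len(ms) > 6:
            raise ValueError("at most 6 measurement steps are supported")

    @property
    def pulse_steps(self) -> tuple[int, ...]:
        return tuple(s for s, _ in self.radiation)

    def to_dict(self) -> dict:
        return {
            "n_steps": self.n_steps,
            "radiation": [{"step": s, "dose_gy": d} for s, d in self.radiation],
            "drug": [{"step": s, "agent": a} for s, a in self.drug],
            "measurement_steps": list(self.measurement_steps),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TreatmentSchedule":
        return cls(
            n_steps=int(d.get("n_steps", DEFAULT_N_STEPS)),
            radiation=tuple(
                (r["step"], r["dose_gy"]) for r in d.get("radiation", ())
            ),
            drug=tuple((r["step"], r["agent"]) for r in d.get("drug", ())),
            measurement_steps=tuple(
                d.get("measurement_steps", DEFAULT_MEASUREMENT_STEPS)
            ),
        )


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean/SD tumor volume at each measurement step."""

    group_id: str
    n_animals: int
    records: tuple[tuple[int, float, float], ...]  # (step, mean_mm3, sd_mm3)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "records",
            tuple((int(s), float(m), float(sd)) for s, m, sd in self.records),
        )
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        steps = [s for s, _, _ in self.records]
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError("record steps must be strictly increasing")
        if any(sd < 0 for _, _, sd in self.records):
            raise ValueError("sd_mm3 must be >= 0")

    @property
    def steps(self) -> tuple[int, ...]:
        return tuple(s for s, _, _ in self.records)

    @property
    def means(self) -> np.ndarray:
        return np.array([m for _, m, _ in self.records], dtype=float)

    @property
    def sds(self) -> np.ndarray:
        return np.array([sd for _, _, sd in self.records], dtype=float)


@dataclass(frozen=True)
class GroupDesign:
    """One arm of the study: schedule blueprint plus cohort size."""

    group_id: str
    radiation: tuple[tuple[int, float], ...] = ()
    drug_agent: str = "isotype"
    drug_steps: tuple[int, ...] = tuple(range(1, DEFAULT_N_STEPS + 1, 2))
    n_animals: int = 8
    measurement_steps: tuple[int, ...] = DEFAULT_MEASUREMENT_STEPS
    n_steps: int = DEFAULT_N_STEPS

    def schedule(self) -> TreatmentSchedule:
        return TreatmentSchedule(
            n_steps=self.n_steps,
            radiation=self.radiation,
            drug=tuple((s, self.drug_agent) for s in self.drug_steps),
            measurement_steps=self.measurement_steps,
        )


@dataclass
class Study:
    """A set of treatment groups: schedules plus summary statistics."""

    params: DynamicsParams
    schedules: dict[str, TreatmentSchedule] = field(default_factory=dict)
    summaries: dict[str, GroupSummary] = field(default_factory=dict)

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(self.schedules)

    def __len__(self) -> int:
        return len(self.schedules)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 log-normal multiplier with coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma2 = math.log1p(cv * cv)
    return float(np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2))))


def survival_fraction(dose: float, alpha: float, beta: float) -> float:
    """LQ surviving fraction SF(d) = exp(-(alpha*d + beta*d^2))."""
    return math.exp(-(alpha * dose + beta * dose * dose))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _immune_kill_rate(
    t: int, params: DynamicsParams, schedule: TreatmentSchedule
) -> float:
    window_open = any(
        p + params.immune_delay <= t <= p + params.immune_delay + params.immune_duration
        for p in schedule.pulse_steps
    )
    if not window_open:
        return 0.0
    drug_active = any(
        a == "anti_pdl1" and s <= t <= s + params.drug_persistence
        for s, a in schedule.drug
    )
    return params.kappa if drug_active else params.kappa_bare


def simulate_animal(
    params: DynamicsParams,
    schedule: TreatmentSchedule,
    seed,
) -> np.ndarray:
    """Simulate one animal's daily tumor volume (mm^3) over the window.

    Returns an array of length ``schedule.n_steps``; entry ``t-1`` is the
    volume at the end of day ``t``.  Animals enter the study at 150-200 mm^3
    (the randomization criterion), with optional log-normal inter-animal
    noise on initial volume and growth rate.
    """
    rng = _as_rng(seed)
    v0 = rng.uniform(150.0, 200.0) * _lognormal_factor(rng, params.noise_cv)
    rho = params.rho * _lognormal_factor(rng, params.noise_cv)

    doses = dict(schedule.radiation)
    series = np.empty(schedule.n_steps, dtype=float)
    v = v0
    for t in range(1, schedule.n_steps + 1):
        if t in doses:
            v *= survival_fraction(doses[t], params.alpha, params.beta)
        v *= math.exp(rho - _immune_kill_rate(t, params, schedule))
        series[t - 1] = v
    return series


def summarize_group(
    trajectories: Sequence[np.ndarray],
    measurement_steps: Sequence[int],
    group_id: str = "group",
) -> GroupSummary:
    """Mean and sample SD (ddof=1) of animal volumes at the measured steps."""
    if len(trajectories) == 0:
        raise ValueError("summarize_group needs at least one trajectory")
    if len(trajectories) < 2:
        raise ValueError("summarize_group needs >= 2 trajectories for an SD")
    mat = np.asarray(trajectories, dtype=float)
    if mat.ndim != 2:
        raise ValueError("trajectories must share a common length")
    idx = np.asarray(measurement_steps, dtype=int) - 1
    sub = mat[:, idx]
    means = sub.mean(axis=0)
    # identical animals must give SD exactly 0, not mean-subtraction roundoff
    sds = np.where(
        np.ptp(sub, axis=0) == 0, 0.0, sub.std(axis=0, ddof=1)
    )
    return GroupSummary(
        group_id=group_id,
        n_animals=mat.shape[0],
        records=tuple(
            (int(s), float(m), float(sd))
            for s, m, sd in zip(measurement_steps, means, sds)
        ),
    )


def default_study_config(
    *,
    first_pulse_step: int = DEFAULT_FIRST_PULSE_STEP,
    measurement_steps: Sequence[int] = DEFAULT_MEASUREMENT_STEPS,
    n_steps: int = DEFAULT_N_STEPS,
) -> list[GroupDesign]:
    """The default 26-group design.

    Two no-radiation controls, four single-pulse dose levels (10/15/20/40 Gy)
    and seven two-pulse dose/spacing combinations, each crossed with the two
    antibody arms (isotype control vs anti-PD-L1, every other day from step 1).
    Group ids 1-8 match the arms the study's figures name explicitly
    (e.g. group 3 = single 20 Gy + isotype, group 8 = two 20 Gy pulses 10 days
    apart + anti-PD-L1); the remaining arms fill ids 9-26.
    """
    eod = tuple(range(1, n_steps + 1, 2))
    ms = tuple(measurement_steps)

    def design(gid, radiation, agent):
        # alternate 8/7 animals per group, as in the experimental cohorts
        return GroupDesign(
            group_id=str(gid),
            radiation=radiation,
            drug_agent=agent,
            drug_steps=eod,
            n_animals=8 if gid % 2 == 1 else 7,
            measurement_steps=ms,
            n_steps=n_steps,
        )

    p1 = first_pulse_step
    single = lambda d: ((p1, float(d)),)
    double = lambda d, gap: ((p1, float(d)), (p1 + gap, float(d)))

    designs = [
        design(1, (), "isotype"),
        design(2, (), "anti_pdl1"),
        design(3, single(20), "isotype"),
        design(4, single(20), "anti_pdl1"),
        design(5, single(40), "isotype"),
        design(6, single(40), "anti_pdl1"),
        design(7, double(20, 10), "isotype"),
        design(8, double(20, 10), "anti_pdl1"),
        design(9, single(10), "isotype"),
        design(10, single(10), "anti_pdl1"),
        design(11, single(15), "isotype"),
        design(12, single(15), "anti_pdl1"),
    ]
    gid = 13
    for dose, gap in [(10, 1), (10, 4), (10, 10), (15, 1), (15, 10), (20, 1), (20, 4)]:
        for agent in AGENTS:
            designs.append(design(gid, double(dose, gap), agent))
            gid += 1
    return designs


def offset_recovery_config(
    *,
    dose: float = 6.0,
    offsets: Sequence[int] = tuple(range(1, 15)),
    n_drug_days: int = 4,
    first_pulse_step: int = DEFAULT_FIRST_PULSE_STEP,
    n_steps: int = DEFAULT_N_STEPS,
    measurement_steps: Sequence[int] = DEFAULT_MEASUREMENT_STEPS,
) -> list[GroupDesign]:
    """A study design for timing-recovery experiments.

    The default study doses the antibody every other day from step 1 in every
    drug arm, so it carries no information about drug *timing*.  This design
    adds single-pulse groups whose anti-PD-L1 course (``n_drug_days``
    consecutive days) starts at varying offsets after the pulse, alongside
    control, drug-only and radiation-only arms, so a surrogate trained on it
    can be probed for the immune-response delay with an offset sweep.

    The default pulse dose is 6 Gy: with the default LQ coefficients, single
    doses of 10 Gy and above leave a surviving fraction below e^-6 and
    sterilize the simulated tumor outright, erasing the post-pulse dynamics
    the recovery experiment is meant to expose; 6 Gy (SF ~ 0.056) is a deep
    but survivable kill.  Offsets default to daily coverage of the full sweep
    range (1..14): the offset sweep interrogates the learned timing response
    at every day, and offsets absent from training leave the curve
    under-constrained there.
    """
    ms = tuple(measurement_steps)
    eod = tuple(range(1, n_steps + 1, 2))
    p1 = first_pulse_step
    designs = [
        GroupDesign("control", (), "isotype", eod, 8, ms, n_steps),
        GroupDesign("drug_only", (), "anti_pdl1", eod, 8, ms, n_steps),
        GroupDesign("rt_only", ((p1, dose),), "isotype", eod, 8, ms, n_steps),
        GroupDesign("rt_drug_eod", ((p1, dose),), "anti_pdl1", eod, 8, ms, n_steps),
    ]
    for off in offsets:
        start = p1 + int(off)
        days = tuple(s for s in range(start, start + n_drug_days) if s <= n_steps)
        if not days:
            continue
        designs.append(
            GroupDesign(
                f"rt_offset_{off:02d}", ((p1, dose),), "anti_pdl1",
                days, 8, ms, n_steps,
            )
        )
    return designs


def generate_study(
    config: Iterable[GroupDesign] | None = None,
    seed: int = 0,
    params: DynamicsParams | None = None,
) -> Study:
    """Simulate every group of a study design and summarize it.

    Each group gets an independent child seed derived from ``seed``, so the
    study is reproducible as a whole and group-by-group.
    """
    designs = list(default_study_config() if config is None else config)
    ids = [d.group_id for d in designs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate group ids in study config")
    params = params or DynamicsParams()
    root = np.random.default_rng(seed)
    study = Study(params=params)
    for design in designs:
        schedule = design.schedule()
        group_rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        trajectories = [
            simulate_animal(params, schedule, group_rng)
            for _ in range(design.n_animals)
        ]
        study.schedules[design.group_id] = schedule
        study.summaries[design.group_id] = summarize_group(
            trajectories, schedule.measurement_steps, design.group_id
        )
    return study


# ---------------------------------------------------------------------------
# serialization

def summaries_to_frame(study: Study) -> pd.DataFrame:
    rows = [
        {
            "group_id": gid,
            "n_animals": summ.n_animals,
            "step": s,
            "mean_mm3": m,
            "sd_mm3": sd,
        }
        for gid, summ in study.summaries.items()
        for s, m, sd in summ.records
    ]
    return pd.DataFrame(rows, columns=["group_id", "n_animals", "step", "mean_mm3", "sd_mm3"])


def summaries_from_frame(frame: pd.DataFrame) -> dict[str, GroupSummary]:
    out: dict[str, GroupSummary] = {}
    for gid, grp in frame.groupby("group_id", sort=False):
        grp = grp.sort_values("step")
        out[str(gid)] = GroupSummary(
            group_id=str(gid),
            n_animals=int(grp["n_animals"].iloc[0]),
            records=tuple(
                (int(r.step), float(r.mean_mm3), float(r.sd_mm3))
                for r in grp.itertuples()
            ),
        )
    return out


def schedules_to_json(schedules: Mapping[str, TreatmentSchedule]) -> str:
    return json.dumps(
        {gid: sch.to_dict() for gid, sch in schedules.items()},
        indent=2,
        sort_keys=True,
    )


def schedules_from_json(text: str) -> dict[str, TreatmentSchedule]:
    raw = json.loads(text)
    return {gid: TreatmentSchedule.from_dict(d) for gid, d in raw.items()}
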