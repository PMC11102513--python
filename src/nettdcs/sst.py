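"""Stop-signal task engine and SSRT estimation.

The stop-signal task measures response inhibition: on most trials the
participant responds to an arrow as fast as possible ("go"); on a random
25% an auditory stop signal follows the arrow after a stop-signal delay
(SSD) and the response must be withheld.  An adaptive staircase raises
the SSD by one step after every successful stop and lowers it after
every failure, converging to the delay at which inhibition succeeds half
the time.

Behavior is modeled as an independent horse race between a go process
(ex-Gaussian finishing time) and a stop process (Gaussian latency
triggered at the SSD): the stop wins — the response is withheld — iff
SSD + stop latency < go RT.  The stop-signal reaction time (SSRT), the
latent duration of the inhibition process, is estimated either by the
mean method (mean go RT minus mean SSD) or by the integration method
(the p-th go-RT quantile minus mean SSD, where p is the observed
probability of responding on stop trials).  The integration method is
robust to go-RT skew; the mean method inherits an upward bias equal to
the go distribution's mean-median gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SstSchedule",
    "SstSession",
    "RaceAgentParams",
    "make_schedule",
    "simulate_session",
    "ssrt_mean",
    "ssrt_integration",
]

DEFAULT_BURN_IN_STOP_TRIALS = 8


@dataclass(frozen=True)
class SstSchedule:
    """Trial-by-trial plan: practice flags, arrow directions, stop flags."""

    is_practice: np.ndarray  # bool per trial
    direction: np.ndarray    # 0 = left, 1 = right
    is_stop: np.ndarray      # bool per trial (False on practice trials)
    seed: int

    def __post_init__(self):
        n = self.is_practice.size
        if not (self.direction.size == n and self.is_stop.size == n):
            raise ValueError("schedule arrays must have equal length")

    @property
    def n_trials(self) -> int:
        return self.is_practice.size

    @property
    def n_test_trials(self) -> int:
        return int(np.sum(~self.is_practice))

    @property
    def n_stop_trials(self) -> int:
        return int(np.sum(self.is_stop))


@dataclass(frozen=True)
class RaceAgentParams:
    """Independent-race simulation agent.

    Go finishing times are ex-Gaussian (Normal(mu, sigma) + Exp(tau));
    stop latencies are Normal(stop_mu, stop_sigma).  ``omission_rate`` is
    the probability the go process never finishes on a trial.
    Defaults produce SSRTs in the low-200 ms range typical of healthy
    adults.
    """

    go_mu_ms: float = 440.0
    go_sigma_ms: float = 60.0
    go_tau_ms: float = 80.0
    stop_mu_ms: float = 200.0
    stop_sigma_ms: float = 30.0
    omission_rate: float = 0.01

    def __post_init__(self):
        if min(self.go_sigma_ms, self.go_tau_ms, self.stop_sigma_ms) < 0:
            raise ValueError("scale parameters must be nonnegative")
        if not (0.0 <= self.omission_rate < 1.0):
            raise ValueError("omission rate must be in [0, 1)")


@dataclass(frozen=True)
class SstSession:
    """Per-trial records of one simulated (or logged) session.

    ``trials`` columns: trial, block, practice, type ('go'|'stop'),
    ssd_ms (NaN on go trials), rt_ms (NaN when no response), outcome
    ('correct_go', 'omission', 'successful_stop', 'failed_stop').
    """

    trials: pd.DataFrame
    staircase: np.ndarray = field(default_factory=lambda: np.array([]))
    agent: RaceAgentParams | None = None

    def stop_trials(self, include_practice: bool = False) -> pd.DataFrame:
        df = self.trials
        sel = df["type"] == "stop"
        if not include_practice:
            sel &= ~df["practice"]
        return df[sel]

    def go_rts(self) -> np.ndarray:
        df = self.trials
        sel = (df["type"] == "go") & ~df["practice"] & (df["outcome"] == "correct_go")
        return df.loc[sel, "rt_ms"].to_numpy()

    def stop_success_rate(self) -> float:
        stops = self.stop_trials()
        if len(stops) == 0:
            raise ValueError("session contains no stop trials")
        return float((stops["outcome"] == "successful_stop").mean())


def make_schedule(
    n_blocks: int = 5,
    trials_per_block: int = 64,
    stop_fraction: float = 0.25,
    practice_trials: int = 16,
    seed: int = 0,
) -> SstSchedule:
    """Seeded trial schedule: practice block then test blocks.

    Each test block contains exactly ``round(stop_fraction *
    trials_per_block)`` stop trials at random positions, and left/right
    arrow directions balanced within one trial per block.  Practice
    trials are go-only.
    """
    if n_blocks < 0 or trials_per_block < 0 or practice_trials < 0:
        raise ValueError("counts must be nonnegative")
    if not (0.0 <= stop_fraction <= 1.0):
        raise ValueError("stop fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    exact = stop_fraction * trials_per_block
    n_stop_per_block = int(round(exact))
    if trials_per_block and abs(exact - n_stop_per_block) > 1e-9:
        warnings.warn(
            f"stop fraction {stop_fraction} x {trials_per_block} trials is not an "
            f"integer; rounding to {n_stop_per_block} stop trials per block",
            stacklevel=2,
        )

    def balanced_directions(n):
        d = np.zeros(n, dtype=int)
        d[: n // 2] = 1
        if n % 2:
            d[n // 2] = rng.integers(0, 2)
        return rng.permutation(d)

    practice = np.ones(practice_trials, dtype=bool)
    dir_parts = [balanced_directions(practice_trials)]
    stop_parts = [np.zeros(practice_trials, dtype=bool)]
    for _ in range(n_blocks):
        stops = np.zeros(trials_per_block, dtype=bool)
        pos = rng.choice(trials_per_block, size=n_stop_per_block, replace=False)
        stops[pos] = True
        stop_parts.append(stops)
        dir_parts.append(balanced_directions(trials_per_block))
    is_practice = np.concatenate([practice, np.zeros(n_blocks * trials_per_block, dtype=bool)])
    return SstSchedule(
        is_practice=is_practice,
        direction=np.concatenate(dir_parts),
        is_stop=np.concatenate(stop_parts),
        seed=int(seed),
    )


def simulate_session(
    schedule: SstSchedule,
    agent: RaceAgentParams = RaceAgentParams(),
    staircase_step_ms: float = 50.0,
    initial_ssd_ms: float = 250.0,
    ssd_floor_ms: float = 50.0,
    ssd_ceiling_ms: float = 1150.0,
    seed: int = 0,
) -> SstSession:
    """Run the race-model agent through a schedule with the SSD staircase.

    On each stop trial the stop succeeds iff ``SSD + stop latency < go
    RT`` (or the go process omits).  The SSD then moves one step up after
    a success, one step down after a failure, clamped to
    [floor, ceiling] — a one-up/one-down staircase whose equilibrium is
    the 50% inhibition point.
    """
    if staircase_step_ms <= 0:
        raise ValueError("staircase step must be positive")
    if not (ssd_floor_ms <= initial_ssd_ms <= ssd_ceiling_ms):
        raise ValueError("need floor <= initial SSD <= ceiling")
    rng = np.random.default_rng(seed)
    n = schedule.n_trials
    go_rt = agent.go_mu_ms + agent.go_sigma_ms * rng.standard_normal(n) + rng.exponential(
        agent.go_tau_ms, n
    )
    stop_lat = agent.stop_mu_ms + agent.stop_sigma_ms * rng.standard_normal(n)
    omitted = rng.random(n) < agent.omission_rate

    ssd = float(initial_ssd_ms)
    trace = []
    rows = []
    for i in range(n):
        practice = bool(schedule.is_practice[i])
        if schedule.is_stop[i]:
            success = omitted[i] or (ssd + stop_lat[i] < go_rt[i])
            rows.append(
                dict(
                    trial=i,
                    practice=practice,
                    type="stop",
                    ssd_ms=ssd,
                    rt_ms=np.nan if success else go_rt[i],
                    outcome="successful_stop" if success else "failed_stop",
                )
            )
            trace.append(ssd)
            ssd = ssd + staircase_step_ms if success else ssd - staircase_step_ms
            ssd = min(ssd_ceiling_ms, max(ssd_floor_ms, ssd))
        else:
            if omitted[i]:
                rows.append(
                    dict(trial=i, practice=practice, type="go", ssd_ms=np.nan,
                         rt_ms=np.nan, outcome="omission")
                )
            else:
                rows.append(
                    dict(trial=i, practice=practice, type="go", ssd_ms=np.nan,
                         rt_ms=go_rt[i], outcome="correct_go")
                )
    df = pd.DataFrame(rows)
    return SstSession(trials=df, staircase=np.asarray(trace), agent=agent)


def _stop_trials_after_burn_in(session: SstSession, burn_in: int) -> pd.DataFrame:
    stops = session.stop_trials()
    if len(stops) == 0:
        raise ValueError("session contains no stop trials")
    if burn_in >= len(stops):
        raise ValueError(f"burn-in {burn_in} discards all {len(stops)} stop trials")
    return stops.iloc[burn_in:]


def _check_convergence(session: SstSession):
    rate = session.stop_success_rate()
    if not (0.35 <= rate <= 0.65):
        warnings.warn(
            f"staircase did not converge near 50% inhibition (success rate {rate:.2f}); "
            "SSRT estimate may be unreliable",
            stacklevel=3,
        )


def ssrt_mean(session: SstSession, burn_in: int = DEFAULT_BURN_IN_STOP_TRIALS) -> float:
    """Mean-method SSRT: mean go RT minus mean SSD.

    The staircase holds inhibition success at 50%, so the mean SSD tracks
    the delay at which the race is even; subtracting it from the mean go
    RT estimates the stop-process latency.  ``burn_in`` discards the
    first stop trials while the staircase approaches equilibrium.
    """
    go = session.go_rts()
    if go.size == 0:
        raise ValueError("session contains no correct go trials")
    stops = _stop_trials_after_burn_in(session, burn_in)
    _check_convergence(session)
    return float(go.mean() - stops["ssd_ms"].mean())


def ssrt_integration(session: SstSession, burn_in: int = DEFAULT_BURN_IN_STOP_TRIALS) -> float:
    """Integration-method SSRT: p-th go-RT quantile minus mean SSD.

    p is the observed probability of responding on stop trials; go
    omissions are replaced by the maximum RT (they are the slowest
    finishers).  The quantile uses linear interpolation on the empirical
    distribution.  Returns NaN (with a warning) when no stop failed —
    p = 0 puts the quantile at the distribution's lower edge, which does
    not identify the stop latency.
    """
    df = session.trials
    go_sel = (df["type"] == "go") & ~df["practice"]
    go = df.loc[go_sel, "rt_ms"].to_numpy()
    if go.size == 0:
        raise ValueError("session contains no go trials")
    finite = go[np.isfinite(go)]
    if finite.size == 0:
        raise ValueError("all go trials were omissions")
    go_filled = np.where(np.isfinite(go), go, finite.max())

    stops = _stop_trials_after_burn_in(session, burn_in)
    _check_convergence(session)
    p = float((stops["outcome"] == "failed_stop").mean())
    if p == 0.0:
        warnings.warn("no failed stops; integration SSRT is undefined", stacklevel=2)
        return float("nan")
    q = float(np.quantile(go_filled, p, method="linear"))
    return q - float(stops["ssd_ms"].mean())
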