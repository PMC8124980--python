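"""Synthetic 1 Hz attention-meter streams and whole screening cohorts.

Real sessions come from a consumer single-electrode EEG headset whose
proprietary attention meter emits one integer in 0-100 per second.  For
testing and power analysis this module emulates such streams with a latent
stationary Gaussian AR(1) process — the simplest model with a tunable
mean, spread and second-to-second persistence — clipped to the meter range
and rounded to integers.

A cohort mixes a control-like profile and an ADHD-like profile.  The
defaults encode the qualitative contrast reported for school-age children
screened with such games: the ADHD-like group attends less on average and
more variably (control mean 60, sd 12; ADHD mean 48, sd 18; lag-1
autocorrelation 0.7 for both), which yields partial game completion in
both groups under the default level schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .engine import (
    GameConfig,
    SessionLog,
    default_config,
    per_level_mean_attention,
    run_session,
)
from .caras import CarasScores

__all__ = [
    "AttentionProfile",
    "CohortSpec",
    "SubjectRecord",
    "DEFAULT_CONTROL_PROFILE",
    "DEFAULT_ADHD_PROFILE",
    "default_cohort_spec",
    "simulate_stream",
    "simulate_cohort",
]


@dataclass(frozen=True)
class AttentionProfile:
    """Generative parameters of a synthetic attention meter.

    ``mean`` and ``sd`` are the stationary mean and standard deviation of
    the latent (pre-clipping) process in meter units; ``autocorr`` is its
    lag-1 autocorrelation.  Clipping to [0, 100] and integer rounding bias
    the realised moments slightly when the mean sits near either bound.
    """

    mean: float
    sd: float
    autocorr: float = 0.7
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.mean <= 100):
            raise ValueError(f"profile mean must lie in [0, 100], got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"profile sd must be >= 0, got {self.sd}")
        if not (0 <= self.autocorr < 1):
            raise ValueError(
                f"profile autocorr must lie in [0, 1), got {self.autocorr}"
            )


DEFAULT_CONTROL_PROFILE = AttentionProfile(mean=60.0, sd=12.0, autocorr=0.7, label="control")
DEFAULT_ADHD_PROFILE = AttentionProfile(mean=48.0, sd=18.0, autocorr=0.7, label="adhd")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one simulated screening cohort (default 52 + 23 children)."""

    n_control: int = 52
    n_adhd: int = 23
    control_profile: AttentionProfile = DEFAULT_CONTROL_PROFILE
    adhd_profile: AttentionProfile = DEFAULT_ADHD_PROFILE
    seed: int = 0
    config: GameConfig = field(default_factory=default_config)

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_adhd < 1:
            raise ValueError("both groups need at least one subject")


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    return CohortSpec(seed=seed)


@dataclass
class SubjectRecord:
    """One simulated (or imported) participant."""

    subject_id: str
    group: str
    log: SessionLog
    completed: bool
    level_means: dict[int, float]
    seed: int | None = None
    caras: CarasScores | None = None

    @property
    def overall_mean_attention(self) -> float:
        return float(np.mean(self.log.attention))


def simulate_stream(
    profile: AttentionProfile,
    n_seconds: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one synthetic attention stream of ``n_seconds`` integer samples.

    The latent process is stationary AR(1):
    ``x_t = mean + autocorr * (x_{t-1} - mean) + e_t`` with innovation
    variance ``sd**2 * (1 - autocorr**2)`` and ``x_0`` drawn from the
    stationary law, then clipped to [0, 100] and rounded.  The same seed
    always yields the same stream.
    """
    if n_seconds < 1:
        raise ValueError("n_seconds must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phi = profile.autocorr
    if profile.sd == 0:
        latent = np.full(n_seconds, profile.mean)
    else:
        innov_sd = profile.sd * np.sqrt(1.0 - phi * phi)
        shocks = rng.normal(0.0, innov_sd, size=n_seconds)
        shocks[0] = rng.normal(0.0, profile.sd)  # stationary start
        # deviations follow d_t = phi * d_{t-1} + e_t
        dev = lfilter([1.0], [1.0, -phi], shocks)
        latent = profile.mean + dev
    clipped = np.clip(latent, 0.0, 100.0)
    return np.rint(clipped).astype(np.int64)


def simulate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Simulate every subject of a cohort through a full game session.

    Each subject gets an independent per-subject seed derived from the
    cohort seed (recorded on the ``SubjectRecord`` so any single session
    can be regenerated from the manifest alone), a stream covering the
    session cap, and a played-out session log with per-level mean
    attention and a completion flag.
    """
    master = np.random.default_rng(spec.seed)
    subject_seeds = master.integers(0, 2**31, size=spec.n_control + spec.n_adhd)
    records: list[SubjectRecord] = []
    roster = [("control", spec.control_profile, spec.n_control), (
        "adhd",
        spec.adhd_profile,
        spec.n_adhd,
    )]
    idx = 0
    for group, profile, count in roster:
        for j in range(count):
            sid = f"{group}-{j + 1:03d}"
            sseed = int(subject_seeds[idx])
            idx += 1
            stream = simulate_stream(profile, spec.config.max_session_seconds, seed=sseed)
            log = run_session(stream, spec.config)
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    log=log,
                    completed=log.completed,
                    level_means=per_level_mean_attention(log),
                    seed=sseed,
                )
            )
    return records
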