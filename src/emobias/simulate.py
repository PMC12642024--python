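"""Synthetic 2AFC observers with known ground truth.

The observer model is a guess/lapse-augmented cumulative normal:

    P(happy | x) = gamma + (1 - gamma - lambda) * Phi((x - mu) / sigma)

One Bernoulli draw per scheduled trial, with an independent chance of
the response being omitted.  Cohorts embed a group x negative-affect
structure in the generating PSE, so downstream fitting, group tests and
moderation can be validated against truth.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from emobias.errors import ConfigError
from emobias.io import DESIGN_LEVELS, ParticipantRecord, validate_trials


@dataclass(frozen=True)
class ObserverParams:
    """Generating parameters of one simulated observer."""

    mu: float                    # PSE location, signed morph-%
    sigma: float                 # psychometric width, morph-% (> 0)
    guess: float = 0.0           # lower asymptote gamma in [0, 0.5)
    lapse: float = 0.0           # upper-asymptote deficit lambda in [0, 0.5)
    omission_rate: float = 0.0   # P(no response) per trial, in [0, 1)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ConfigError(f"sigma must be > 0, got {self.sigma}")
        if not 0 <= self.guess < 0.5:
            raise ConfigError(f"guess must be in [0, 0.5), got {self.guess}")
        if not 0 <= self.lapse < 0.5:
            raise ConfigError(f"lapse must be in [0, 0.5), got {self.lapse}")
        if self.guess + self.lapse >= 1:
            raise ConfigError("guess + lapse must be < 1")
        if not 0 <= self.omission_rate < 1:
            raise ConfigError(
                f"omission_rate must be in [0, 1), got {self.omission_rate}")


@dataclass(frozen=True)
class DesignSpec:
    """Trial schedule: ordered morph levels and trials per level."""

    levels: tuple[int, ...] = DESIGN_LEVELS
    trials_per_level: tuple[int, ...] = (4, 8, 8, 8, 8, 8, 8, 8, 4)

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.trials_per_level):
            raise ConfigError("levels and trials_per_level lengths differ")
        if any(n < 1 for n in self.trials_per_level):
            raise ConfigError("trials_per_level entries must be positive")

    @property
    def n_trials(self) -> int:
        return int(sum(self.trials_per_level))


def default_design() -> DesignSpec:
    """The 64-trial design: 8 trials at each of +/-40, +/-20, +/-10 and 0,
    and 4 at each of +/-80."""
    return DesignSpec()


@dataclass
class CohortConfig:
    """Generating parameters for a synthetic cohort.

    The true PSE of participant i follows

        mu_i = b0 + b_sa * SA_i + b_na * NAc_i + b_int * SA_i * NAc_i + eps_i

    with SA coded 0 = LSA / 1 = HSA, NAc the integer PANAS-NA score
    centered at the realized cohort mean, and eps ~ N(0, pse_residual_sd).
    Defaults mirror the cohort texture the pipeline is aimed at: 90 HSA
    vs 37 LSA, NA means/SDs of roughly 13.8/3.4 and 11.7/2.0, and about
    7% omitted trials.
    """

    n_hsa: int = 90
    n_lsa: int = 37
    na_mean_hsa: float = 13.81
    na_sd_hsa: float = 3.38
    na_mean_lsa: float = 11.68
    na_sd_lsa: float = 2.02
    b0: float = 3.0              # intercept: LSA PSE at mean NA, morph-%
    b_sa: float = 2.5            # HSA main effect, morph-%
    b_na: float = 0.3            # NA main effect, morph-% per NA point
    b_int: float = 1.2           # group x NA interaction, morph-% per NA point
    pse_residual_sd: float = 11.0
    sigma_log_mean: float = math.log(12.0)   # log-normal location of width
    sigma_log_sd: float = 0.35               # log-normal scale of width
    guess: float = 0.0
    lapse: float = 0.0
    omission_rate: float = 0.07
    na_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hsa < 2 or self.n_lsa < 2:
            raise ConfigError("each group needs at least 2 participants")
        if self.na_sd_hsa <= 0 or self.na_sd_lsa <= 0:
            raise ConfigError("na_sd must be > 0")
        if self.pse_residual_sd < 0:
            raise ConfigError("pse_residual_sd must be >= 0")
        if not 0 <= self.na_missing_rate < 1:
            raise ConfigError("na_missing_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "CohortConfig":
        known = {k: v for k, v in payload.items()
                 if k in cls.__dataclass_fields__}
        unknown = set(payload) - set(known)
        if unknown:
            raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
        return cls(**known)


def psychometric_probability(x, params: ObserverParams):
    """P(happy) at morph level(s) ``x`` under the observer model.

    Strictly increasing in x, bounded in (guess, 1 - lapse).
    """
    z = (np.asarray(x, dtype=float) - params.mu) / params.sigma
    p = params.guess + (1.0 - params.guess - params.lapse) * norm.cdf(z)
    if np.ndim(x) == 0:
        return float(p)
    return p


def simulate_observer(params: ObserverParams,
                      design: DesignSpec | None = None,
                      seed: int | np.random.Generator = 0,
                      participant_id: str = "obs",
                      n_faces: int = 8) -> pd.DataFrame:
    """Simulate one observer's trial table fragment.

    One Bernoulli draw per scheduled trial; each trial is independently
    omitted with ``params.omission_rate``.  Presentation order is
    shuffled, and trial_index runs 1..n.  Same seed => identical output.
    """
    design = design or default_design()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    levels = np.repeat(design.levels, design.trials_per_level)
    order = rng.permutation(len(levels))
    levels = levels[order]

    p_happy = np.array([psychometric_probability(x, params) for x in levels])
    happy = rng.random(len(levels)) < p_happy
    omitted = rng.random(len(levels)) < params.omission_rate
    faces = rng.integers(1, n_faces + 1, size=len(levels))

    response = np.where(omitted, "omitted", np.where(happy, "happy", "angry"))
    frame = pd.DataFrame({
        "participant_id": participant_id,
        "trial_index": np.arange(1, len(levels) + 1),
        "morph_level": levels.astype(int),
        "face_id": [f"F{f}" for f in faces],
        "response": response,
    })
    return validate_trials(frame)


def _clip_round_scale(values: np.ndarray, lo: int = 10, hi: int = 50) -> np.ndarray:
    """PANAS-style integerisation: round then clamp to the scale range."""
    return np.clip(np.rint(values), lo, hi).astype(int)


def _draw_questionnaires(rng: np.random.Generator, hsa: bool) -> tuple[int, int, int]:
    """BFNE-S, DASS-depression and PANAS-PA draws consistent with group
    membership and the inclusion gates."""
    if hsa:
        bfne = int(np.clip(np.rint(rng.normal(32.0, 4.4)), 25, 40))
        dass = int(np.clip(np.rint(rng.normal(8.6, 5.0)), 0, 17))
        pa = int(np.clip(np.rint(rng.normal(27.3, 8.2)), 10, 50))
    else:
        bfne = int(np.clip(np.rint(rng.normal(10.1, 1.6)), 8, 12))
        dass = int(np.clip(np.rint(rng.normal(5.4, 4.7)), 0, 17))
        pa = int(np.clip(np.rint(rng.normal(32.7, 8.2)), 10, 50))
    return bfne, dass, pa


def simulate_cohort(config: CohortConfig,
                    design: DesignSpec | None = None,
                    with_trials: bool = True,
                    ) -> tuple[pd.DataFrame, list[ParticipantRecord], pd.DataFrame]:
    """Simulate a full cohort: trials, participant metadata and truth.

    Per-participant randomness comes from substreams keyed by
    (seed, group, index), so changing one group's size never reshuffles
    the other's participants.  With ``with_trials=False`` only metadata
    and the ground-truth table are produced (fast path for calibration
    studies that work from true PSEs directly).

    Returns ``(trials, participants, truth)`` where ``truth`` holds one
    row per participant with the generating parameters and true PSE.
    """
    design = design or default_design()
    groups = [("HSA", i, np.random.default_rng([config.seed, 0, i]))
              for i in range(config.n_hsa)]
    groups += [("LSA", j, np.random.default_rng([config.seed, 1, j]))
               for j in range(config.n_lsa)]

    # Pass 1: draw NA for everyone, then center at the realized cohort mean.
    na_draws = []
    for sa_status, _, rng in groups:
        mean = config.na_mean_hsa if sa_status == "HSA" else config.na_mean_lsa
        sd = config.na_sd_hsa if sa_status == "HSA" else config.na_sd_lsa
        na_draws.append(int(_clip_round_scale(np.array([rng.normal(mean, sd)]))[0]))
    na = np.array(na_draws, dtype=float)
    na_centered = na - na.mean()

    trials_parts: list[pd.DataFrame] = []
    participants: list[ParticipantRecord] = []
    truth_rows: list[dict] = []
    for (sa_status, idx, rng), na_i, nac_i in zip(groups, na, na_centered):
        sa = 1.0 if sa_status == "HSA" else 0.0
        pid = f"{'H' if sa else 'L'}{idx + 1:03d}"
        eps = rng.normal(0.0, config.pse_residual_sd) if config.pse_residual_sd else 0.0
        mu = (config.b0 + config.b_sa * sa + config.b_na * nac_i
              + config.b_int * sa * nac_i + eps)
        sigma = float(np.exp(rng.normal(config.sigma_log_mean, config.sigma_log_sd)))
        params = ObserverParams(mu=mu, sigma=sigma, guess=config.guess,
                                lapse=config.lapse,
                                omission_rate=config.omission_rate)
        bfne, dass, pa = _draw_questionnaires(rng, hsa=bool(sa))
        na_missing = rng.random() < config.na_missing_rate
        participants.append(ParticipantRecord(
            participant_id=pid, sa_status=sa_status, bfne_s=bfne,
            dass_depression=dass,
            panas_pa=None if na_missing else pa,
            panas_na=None if na_missing else int(na_i)))
        truth_rows.append({
            "participant_id": pid, "sa_status": sa_status, "na": int(na_i),
            "na_centered": nac_i, "true_pse": mu, "sigma": sigma,
            "guess": config.guess, "lapse": config.lapse,
            "omission_rate": config.omission_rate})
        if with_trials:
            trials_parts.append(simulate_observer(
                params, design=design, seed=rng, participant_id=pid))

    trials = (pd.concat(trials_parts, ignore_index=True) if trials_parts
              else pd.DataFrame(columns=["participant_id", "trial_index",
                                         "morph_level", "face_id", "response"]))
    truth = pd.DataFrame(truth_rows)
    return trials, participants, truth
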