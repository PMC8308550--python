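"""Synthetic contralateral-thigh trial data.

Emulates a single-arm, double-blind, placebo-controlled design in which
each participant applies the active product to one (randomised) thigh and
the placebo to the other, so each woman is her own control.  Defaults match
the study conditions this package targets: 20 enrolled, two withdrawals
(weeks 7 and 8), 18 completers, visits at weeks 0/2/4/8/12/14, block-of-four
thigh randomisation, and reported outcome trajectories (e.g. herbal-thigh
Cellulite Severity Scale 13.4 → 12.1 → 9.9 over 12 weeks with SEMs rising
from 0.3 to 0.6 at n = 18).

Generative model per outcome value::

    value = trajectory(thigh, week)
          + participant_effect            # N(0, participant_sd²), shared by
                                          # both thighs of one woman
          + residual                      # N(0, residual_sd(week)²)

The shared participant effect produces the positive contralateral
correlation characteristic of paired designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeModel",
    "LikertQuestion",
    "TrialConfig",
    "TrialDataset",
    "default_trial_config",
    "simulate_trial",
    "simulate_grades",
    "simulate_likert",
]

THIGHS = ("placebo", "herbal")


@dataclass(frozen=True)
class OutcomeModel:
    """Descriptive trajectory and dispersion for one outcome.

    trajectory: thigh -> {week -> mean}.  residual_sd may be a scalar or a
    {week -> sd} mapping (the study's CSS dispersion grows over time).
    """

    trajectory: dict
    participant_sd: float
    residual_sd: object  # float | dict[int, float]

    def residual_at(self, week: int) -> float:
        if isinstance(self.residual_sd, dict):
            return float(self.residual_sd[week])
        return float(self.residual_sd)

    def validate(self, weeks) -> None:
        if self.participant_sd < 0:
            raise ValueError("participant_sd must be >= 0")
        for thigh in THIGHS:
            if thigh not in self.trajectory:
                raise ValueError(f"trajectory missing thigh {thigh!r}")
            missing = [w for w in weeks if w not in self.trajectory[thigh]]
            if missing:
                raise ValueError(
                    f"trajectory for {thigh!r} missing weeks {missing}"
                )
        for w in weeks:
            if self.residual_at(w) < 0:
                raise ValueError("residual_sd must be >= 0")


@dataclass(frozen=True)
class LikertQuestion:
    """Per-thigh mean/sd of a 1–5 agreement item."""

    text: str
    mean: dict  # thigh -> mean
    sd: float


@dataclass(frozen=True)
class TrialConfig:
    n_enrolled: int = 20
    withdrawal_weeks: tuple = (7, 8)
    weeks: tuple = (0, 2, 4, 8, 12, 14)
    outcome_models: dict = field(default_factory=dict)
    likert_model: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_enrolled < len(self.withdrawal_weeks):
            raise ValueError("cannot withdraw more participants than enrolled")
        for name, model in self.outcome_models.items():
            model.validate(self.weeks)

    @property
    def n_completers(self) -> int:
        return self.n_enrolled - len(self.withdrawal_weeks)


@dataclass(frozen=True)
class TrialDataset:
    """Long-format measurements plus the participant ledger.

    data: columns participant, thigh, week, outcome, value.
    ledger: columns participant, herbal_side, withdrawn_week (nullable Int),
    completed.
    """

    data: pd.DataFrame
    ledger: pd.DataFrame

    @property
    def completers(self) -> list:
        return self.ledger.loc[self.ledger["completed"], "participant"].tolist()

    def complete_cases(self) -> pd.DataFrame:
        return self.data[self.data["participant"].isin(self.completers)].copy()


def _interp_traj(anchors: dict, weeks) -> dict:
    """Linear interpolation of reported anchor means onto all visit weeks."""
    ws = sorted(anchors)
    return {
        w: float(np.interp(w, ws, [anchors[a] for a in ws])) for w in weeks
    }


def default_trial_config(seed: int = 0) -> TrialConfig:
    """Study-condition defaults.

    CSS herbal anchors are the reported 13.4 (wk 0), 12.1 (wk 2), 9.9 (wk 12)
    with a partial rebound to 10.9 after the untreated follow-up; weeks 4/8
    are linear interpolations.  Residual sds are set so the cross-sectional
    SD at n = 18 matches the reported SEMs (0.3 at baseline, 0.6 at week 12)
    given a shared participant sd of 1.0.  Secondary outcomes use their
    reported baselines with both arms improving comparably.
    """
    weeks = (0, 2, 4, 8, 12, 14)

    css = OutcomeModel(
        trajectory={
            "herbal": {**_interp_traj({0: 13.4, 2: 12.1, 12: 9.9}, weeks), 14: 10.9},
            "placebo": {**_interp_traj({0: 12.9, 12: 12.4}, weeks), 14: 12.5},
        },
        participant_sd=1.0,
        # total SD = sqrt(1 + r²) -> SEM(18): 0.30 at wk0 rising to 0.60 at wk12
        residual_sd={0: 0.78, 2: 0.78, 4: 1.3, 8: 1.8, 12: 2.34, 14: 2.34},
    )
    image_score = OutcomeModel(
        trajectory={
            "herbal": _interp_traj({0: 8675, 12: 6420, 14: 7000}, weeks),
            "placebo": _interp_traj({0: 8356, 14: 8356}, weeks),
        },
        participant_sd=3400.0,
        residual_sd=1200.0,
    )
    circ_lower = OutcomeModel(
        trajectory={
            "herbal": _interp_traj({0: 47.6, 2: 47.4, 4: 46.6, 12: 46.3, 14: 46.3}, weeks),
            "placebo": _interp_traj({0: 47.1, 2: 46.9, 12: 46.3, 14: 46.3}, weeks),
        },
        participant_sd=4.0,
        residual_sd=0.4,
    )
    circ_upper = OutcomeModel(
        trajectory={
            "herbal": _interp_traj({0: 55.5, 2: 55.3, 4: 54.6, 12: 54.5, 14: 54.5}, weeks),
            "placebo": _interp_traj({0: 55.4, 2: 55.2, 12: 54.6, 14: 54.6}, weeks),
        },
        participant_sd=4.5,
        residual_sd=0.4,
    )
    firmness_post = OutcomeModel(
        trajectory={t: {w: 0.95 for w in weeks} for t in THIGHS},
        participant_sd=0.015,
        residual_sd=0.008,
    )
    firmness_ant = OutcomeModel(
        trajectory={
            t: _interp_traj({0: 0.93, 12: 0.95, 14: 0.95}, weeks) for t in THIGHS
        },
        participant_sd=0.02,
        residual_sd=0.01,
    )
    blood_flow = OutcomeModel(
        trajectory={
            "herbal": _interp_traj({0: 0.42, 2: 0.42, 12: 0.50, 14: 0.50}, weeks),
            "placebo": _interp_traj({0: 0.40, 2: 0.40, 12: 0.48, 14: 0.48}, weeks),
        },
        participant_sd=0.11,
        residual_sd=0.04,
    )

    likert = (
        LikertQuestion("Gel texture good", {"placebo": 3.83, "herbal": 3.50}, 0.9),
        LikertQuestion("Emgel fragrance pleasant", {"placebo": 3.39, "herbal": 3.11}, 1.0),
        LikertQuestion("Gel well absorbed by the skin", {"placebo": 3.11, "herbal": 3.06}, 1.2),
        LikertQuestion("Overall satisfaction with emgel texture", {"placebo": 3.61, "herbal": 3.56}, 0.7),
        LikertQuestion("Your thighs are smoother", {"placebo": 3.44, "herbal": 3.78}, 0.9),
        LikertQuestion("Your thighs feel firmer", {"placebo": 3.17, "herbal": 3.44}, 1.1),
        LikertQuestion("Your thighs feel smaller", {"placebo": 2.83, "herbal": 3.33}, 1.1),
        LikertQuestion("Your cellulite appears to be reduced", {"placebo": 3.00, "herbal": 3.61}, 1.0),
        LikertQuestion("Overall satisfaction with the emgel", {"placebo": 3.61, "herbal": 4.11}, 0.9),
    )

    return TrialConfig(
        outcome_models={
            "css": css,
            "image_score": image_score,
            "circumference_lower": circ_lower,
            "circumference_upper": circ_upper,
            "firmness_posterior": firmness_post,
            "firmness_anterior": firmness_ant,
            "blood_flow": blood_flow,
        },
        likert_model=likert,
        seed=seed,
    )


def _allocate_blocks_of_four(n: int, rng: np.random.Generator) -> list:
    """Which side gets the herbal product, balanced within blocks of four."""
    sides = []
    while len(sides) < n:
        block = ["left", "left", "right", "right"]
        rng.shuffle(block)
        sides.extend(block)
    return sides[:n]


def simulate_trial(config: TrialConfig, seed: int | None = None) -> TrialDataset:
    """Draw one full trial dataset; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_enrolled
    participants = [f"P{i+1:02d}" for i in range(n)]
    herbal_side = _allocate_blocks_of_four(n, rng)

    withdrawn = rng.choice(n, size=len(config.withdrawal_weeks), replace=False)
    withdrawn_week = {
        participants[p]: w
        for p, w in zip(sorted(withdrawn), config.withdrawal_weeks)
    }

    records = []
    for name in config.outcome_models:  # insertion order: deterministic
        model = config.outcome_models[name]
        pe = rng.normal(0.0, model.participant_sd, size=n)
        for i, pid in enumerate(participants):
            cutoff = withdrawn_week.get(pid, np.inf)
            for week in config.weeks:
                if week > cutoff:
                    continue
                for thigh in THIGHS:
                    value = (
                        model.trajectory[thigh][week]
                        + pe[i]
                        + rng.normal(0.0, model.residual_at(week))
                    )
                    records.append((pid, thigh, week, name, value))

    data = pd.DataFrame(
        records, columns=["participant", "thigh", "week", "outcome", "value"]
    )
    ledger = pd.DataFrame(
        {
            "participant": participants,
            "herbal_side": herbal_side,
            "withdrawn_week": pd.array(
                [withdrawn_week.get(p) for p in participants], dtype="Int64"
            ),
            "completed": [p not in withdrawn_week for p in participants],
        }
    )
    return TrialDataset(data, ledger)


def simulate_grades(
    config: TrialConfig,
    dataset: TrialDataset,
    n_evaluators: int = 3,
    noise_sd: float = 0.3,
    biases: tuple | None = None,
    latent_outcome: str = "css",
    seed: int | None = None,
) -> pd.DataFrame:
    """Blinded-evaluator grades from the latent severity outcome.

    grade = clamp(round(latent/5 + bias_e + noise), 0, 3): the 0–15 latent
    scale maps onto the 0–3 grade with per-evaluator bias and noise.
    """
    if biases is None:
        biases = tuple(0.0 for _ in range(n_evaluators))
    if len(biases) != n_evaluators:
        raise ValueError("need one bias per evaluator")
    latent = dataset.data[dataset.data["outcome"] == latent_outcome]
    if latent.empty:
        raise ValueError(f"dataset has no latent outcome {latent_outcome!r}")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rows = []
    for rec in latent.itertuples(index=False):
        for e in range(n_evaluators):
            raw = rec.value / 5.0 + biases[e]
            if noise_sd > 0:
                raw += rng.normal(0.0, noise_sd)
            grade = int(np.clip(np.floor(raw + 0.5), 0, 3))
            rows.append((rec.participant, rec.thigh, rec.week, f"E{e+1}", grade))
    return pd.DataFrame(
        rows, columns=["participant_id", "thigh", "week", "evaluator_id", "grade"]
    )


def simulate_likert(
    config: TrialConfig,
    n_participants: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Paired 1–5 questionnaire responses per completer.

    Draws are normal, rounded to the nearest integer and clamped to 1..5
    (a discretised truncated normal); the two thighs are paired by
    participant.
    """
    if n_participants is None:
        n_participants = config.n_completers
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    rows = []
    for q in config.likert_model:
        for i in range(n_participants):
            pid = f"P{i+1:02d}"
            scores = {}
            for thigh in THIGHS:
                draw = rng.normal(q.mean[thigh], q.sd) if q.sd > 0 else q.mean[thigh]
                scores[thigh] = int(np.clip(np.floor(draw + 0.5), 1, 5))
            rows.append((q.text, pid, scores["placebo"], scores["herbal"]))
    return pd.DataFrame(
        rows, columns=["question", "participant", "placebo_score", "herbal_score"]
    )
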