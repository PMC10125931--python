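"""Within-participants two-condition experiment generator.

A focal diffusion parameter (drift rate ``v`` or threshold separation ``a``)
takes baseline values ``mu_1`` and ``mu_2`` in the two conditions and is
perturbed per participant and per cell:

    mu_ij = mu_j + eps_i^between + eps_ij^within

with ``eps^between ~ N(0, sigma_b2)`` drawn once per participant (shared by
both conditions) and ``eps^within ~ N(0, sigma_w2)`` drawn per participant x
condition cell.  The between-share of the variance implies a theoretical
between-condition correlation of the realized parameter across participants,

    r = sigma_b2 / (sigma_b2 + sigma_w2),

which :func:`theoretical_correlation` exposes.  Each participant additionally
gets a non-decision time ``t_er_i ~ N(t_er_mean, t_er_sd^2)`` shared by both
conditions, adding between-participant spread to mean RTs.

Varying the drift rate emulates a "real" difficulty/ability effect (RT and
accuracy move in opposite directions); varying the threshold separation
emulates a pure speed-accuracy trade-off (they move together).

By default the two conditions of a participant replay the same trial-noise
stream (common random numbers).  This couples the trial-level noise of the
two cells, which raises between-condition correlations of the aggregated
measures and shrinks the trial-noise share of paired condition differences
— the correlation/power regime of the reference validation study.  Set
``shared_trial_noise=False`` for fully independent trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd
import yaml

from .wiener import (
    DEFAULT_DT,
    DEFAULT_MAX_STEPS,
    DEFAULT_SIGMA,
    DiffusionParams,
    simulate_trials,
)

__all__ = [
    "DesignSpec",
    "ParameterDraw",
    "TRIAL_COLUMNS",
    "draw_parameters",
    "generate_experiment",
    "theoretical_correlation",
    "UndefinedCorrelationError",
    "read_trials",
    "write_trials",
]

#: Column schema of a long-format trial table.
TRIAL_COLUMNS = ("participant", "condition", "rt", "correct")

_FOCALS = ("drift", "threshold")
#: Cap on redraws of an invalid parameter realization before giving up.
_MAX_REDRAWS = 1000


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (zero variance components, or a constant
    variable downstream in :mod:`speedacc.inference`)."""


@dataclass(frozen=True)
class DesignSpec:
    """A two-condition within-participants design.

    ``focal`` names the manipulated diffusion parameter; ``mu`` holds its two
    condition baselines and ``fixed`` the value of the non-focal parameter.
    Defaults follow the reference simulation setup: noise scale ``sigma = 4``,
    non-decision time ``N(300, 20^2)`` ms per participant, ``n = 20``
    participants, 1000 trials per condition.
    """

    focal: str
    mu: Tuple[float, float]
    fixed: float
    sigma_b2: float
    sigma_w2: float
    t_er_mean: float = 300.0
    t_er_sd: float = 20.0
    sigma: float = DEFAULT_SIGMA
    n_participants: int = 20
    n_trials: int = 1000
    dt: float = DEFAULT_DT
    max_steps: int = DEFAULT_MAX_STEPS
    shared_trial_noise: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.focal not in _FOCALS:
            raise ValueError(f"focal must be one of {_FOCALS}, got {self.focal!r}")
        if len(self.mu) != 2:
            raise ValueError("exactly two conditions are supported; mu needs two values")
        object.__setattr__(self, "mu", (float(self.mu[0]), float(self.mu[1])))
        if self.sigma_b2 < 0 or self.sigma_w2 < 0:
            raise ValueError("variance components must be >= 0")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.n_trials < 1:
            raise ValueError("need at least 1 trial per condition")
        if self.t_er_sd < 0:
            raise ValueError("t_er_sd must be >= 0")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mu"] = list(self.mu)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        d = dict(d)
        d["mu"] = tuple(d["mu"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "DesignSpec":
        """Load a spec from a YAML or JSON file (JSON is a YAML subset)."""
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class ParameterDraw:
    """Realized focal parameter and non-decision time for one design cell."""

    participant: int
    condition: int
    mu_ij: float
    t_er_i: float


def theoretical_correlation(sigma_b2: float, sigma_w2: float) -> float:
    """Between-condition correlation of the perturbed parameter.

    Both conditions share the participant's between-deviation and add
    independent within-deviations, so across participants

        r = sigma_b2 / (sigma_b2 + sigma_w2).
    """
    if sigma_b2 < 0 or sigma_w2 < 0:
        raise ValueError("variance components must be >= 0")
    if sigma_b2 == 0 and sigma_w2 == 0:
        raise UndefinedCorrelationError(
            "correlation is undefined when both variance components are zero"
        )
    return sigma_b2 / (sigma_b2 + sigma_w2)


def _cell_params(spec: DesignSpec, draw: ParameterDraw) -> DiffusionParams:
    """Assemble DiffusionParams from a realized draw (start is always a/2)."""
    if spec.focal == "drift":
        v, a = draw.mu_ij, spec.fixed
    else:
        v, a = spec.fixed, draw.mu_ij
    return DiffusionParams(v=v, a=a, sigma=spec.sigma, t_er=draw.t_er_i)


def _valid_mu(spec: DesignSpec, mu_ij: float) -> bool:
    # Both v <= 0 and a <= 0 would invert/void the process; redraw those.
    return mu_ij > 0


def draw_parameters(spec: DesignSpec, rng: np.random.Generator) -> List[ParameterDraw]:
    """Draw realized focal parameters and non-decision times for every cell.

    One between-deviation and one ``t_er`` per participant (shared across
    conditions), one within-deviation per cell.  Realizations that would be
    invalid (non-positive focal parameter, negative ``t_er``) are redrawn;
    at the reference parameter values this is vanishingly rare.
    """
    sd_b = math.sqrt(spec.sigma_b2)
    sd_w = math.sqrt(spec.sigma_w2)
    draws: List[ParameterDraw] = []
    for i in range(1, spec.n_participants + 1):
        eps_b = sd_b * rng.standard_normal()
        t_er = spec.t_er_mean + spec.t_er_sd * rng.standard_normal()
        for _ in range(_MAX_REDRAWS):
            if t_er >= 0:
                break
            t_er = spec.t_er_mean + spec.t_er_sd * rng.standard_normal()
        else:
            raise RuntimeError("could not draw a non-negative t_er; check t_er_mean/t_er_sd")
        for j, mu_j in enumerate(spec.mu, start=1):
            mu_ij = mu_j + eps_b + sd_w * rng.standard_normal()
            for _ in range(_MAX_REDRAWS):
                if _valid_mu(spec, mu_ij):
                    break
                mu_ij = mu_j + eps_b + sd_w * rng.standard_normal()
            else:
                raise RuntimeError(
                    f"could not draw a valid focal parameter for participant {i}, "
                    f"condition {j}; check mu and variance components"
                )
            draws.append(ParameterDraw(participant=i, condition=j, mu_ij=mu_ij, t_er_i=t_er))
    return draws


def generate_experiment(
    spec: DesignSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate one full experiment; returns a long-format trial table.

    Columns: ``participant`` (int, 1-based), ``condition`` (int, 1 or 2),
    ``rt`` (float ms), ``correct`` (0/1 int).  Stream discipline: the given
    generator is split into one substream for the parameter draws and one
    per participant, so the table is bit-reproducible for a given seed and
    independent of scheduling.  With ``spec.shared_trial_noise`` (the
    default) both conditions of a participant restart from the same
    substream — common random numbers, which positively correlates the
    trial-level noise of a participant's two cells and thereby cancels part
    of it in paired condition differences; with it off, the substream is
    consumed sequentially (condition 1 then condition 2), making all trials
    independent.

    Trials exceeding ``spec.max_steps`` are dropped (negligible probability
    at the reference parameters); the per-cell trial count may then fall
    short of ``spec.n_trials``.
    """
    if rng is None:
        if spec.seed is None:
            raise ValueError("either pass an rng or set DesignSpec.seed")
        rng = np.random.default_rng(spec.seed)
    seed_children = rng.bit_generator.seed_seq.spawn(1 + spec.n_participants)
    param_rng = np.random.default_rng(seed_children[0])
    draws = draw_parameters(spec, param_rng)

    if spec.shared_trial_noise:
        # fresh generator per cell from the participant's seed: conditions
        # replay the same noise stream
        def cell_rng(d: ParameterDraw) -> np.random.Generator:
            return np.random.default_rng(seed_children[d.participant])
    else:
        seq_rngs = [np.random.default_rng(s) for s in seed_children[1:]]

        def cell_rng(d: ParameterDraw) -> np.random.Generator:
            return seq_rngs[d.participant - 1]

    parts: List[np.ndarray] = []
    conds: List[np.ndarray] = []
    rts: List[np.ndarray] = []
    corrects: List[np.ndarray] = []
    for draw in draws:
        sub = cell_rng(draw)
        params = _cell_params(spec, draw)
        rt, corr = simulate_trials(
            params, spec.n_trials, sub, dt=spec.dt, max_steps=spec.max_steps, on_max="drop"
        )
        k = rt.shape[0]
        parts.append(np.full(k, draw.participant, dtype=np.int64))
        conds.append(np.full(k, draw.condition, dtype=np.int64))
        rts.append(rt)
        corrects.append(corr.astype(np.int64))
    return pd.DataFrame(
        {
            "participant": np.concatenate(parts),
            "condition": np.concatenate(conds),
            "rt": np.concatenate(rts),
            "correct": np.concatenate(corrects),
        }
    )


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV with the canonical column schema."""
    out = trials.loc[:, list(TRIAL_COLUMNS)].copy()
    out["correct"] = out["correct"].astype(int)
    out.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial-table CSV written by :func:`write_trials` (lossless)."""
    df = pd.read_csv(
        path,
        dtype={"participant": np.int64, "condition": np.int64, "rt": np.float64, "correct": np.int64},
    )
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table {path} is missing columns: {sorted(missing)}")
    return df.loc[:, list(TRIAL_COLUMNS)]
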