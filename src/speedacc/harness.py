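"""Monte-Carlo study orchestration.

Repeats generate -> aggregate -> score -> paired t test over many simulated
experiments and summarizes each measure with its condition means, mean
effect size d_z, percentage of significant t tests, and the mean (and range)
of the between-condition correlation across participants — the row structure
of a power/type-I-error validation table.  Correlations are averaged on the
Fisher-z scale; everything else is an arithmetic mean across experiments.

Reproducibility: a master seed spawns one independent substream per
experiment, so the full study is bit-reproducible and any experiment can be
regenerated in isolation (:func:`experiment_rng`); experiments are
independent, so scheduling cannot change results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .design import DesignSpec, generate_experiment, read_trials, write_trials
from .inference import DegenerateTestError, UndefinedCorrelationError, paired_t
from .measures import MeasureContext, aggregate, compute_measures

__all__ = [
    "StudyConfig",
    "StudySummary",
    "DEFAULT_MEASURES",
    "SUMMARY_COLUMNS",
    "experiment_rng",
    "run_experiment",
    "run_study",
    "write_summary",
    "read_trials",
    "write_trials",
]

logger = logging.getLogger(__name__)

#: Measures reported by default (the validation-table set).
DEFAULT_MEASURES = ("mean_rt", "pc", "bis", "lisas", "lisas_cond", "lisas_bis")

#: Column order of the summary table.
SUMMARY_COLUMNS = (
    "measure",
    "mean_1",
    "mean_2",
    "mean_dz",
    "pct_significant",
    "mean_r",
    "min_r",
    "max_r",
    "n_excluded",
)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one Monte-Carlo study.

    ``n_experiments`` defaults to the full 1000-replication study; smaller
    counts trade Monte-Carlo precision for runtime.
    """

    design: DesignSpec
    n_experiments: int = 1000
    alpha: float = 0.05
    measures: Sequence[str] = DEFAULT_MEASURES
    seed: int = 0
    log_every: int = 0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        object.__setattr__(self, "measures", tuple(self.measures))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = self.design.to_dict()
        d["measures"] = list(self.measures)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        d["design"] = DesignSpec.from_dict(d["design"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class StudySummary:
    """Per-measure summary rows plus provenance (config echo and seed)."""

    table: pd.DataFrame
    config: dict
    n_experiments: int
    seed: int
    details: pd.DataFrame | None = None


def _fisher_mean(r: np.ndarray) -> float:
    """Average correlations on the Fisher-z scale (tanh of mean artanh).

    The sampling distribution of r is left-skewed near |r| = 1, so the
    arithmetic mean underestimates a common high correlation; averaging z
    transforms is the standard remedy.  NaNs (excluded experiments) are
    ignored; |r| = 1 is clipped just inside the open interval.
    """
    r = r[~np.isnan(r)]
    if r.size == 0:
        return float("nan")
    z = np.arctanh(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    return float(np.tanh(z.mean()))


def experiment_rng(master_seed: int, k: int, n_experiments: int) -> np.random.Generator:
    """Generator for experiment ``k`` of a study, derivable in isolation."""
    children = np.random.SeedSequence(master_seed).spawn(n_experiments)
    return np.random.default_rng(children[k])


def run_experiment(
    design: DesignSpec,
    rng: np.random.Generator,
    measures: Sequence[str] = DEFAULT_MEASURES,
) -> pd.DataFrame:
    """Generate, aggregate and score one experiment; returns scored cells."""
    trials = generate_experiment(design, rng)
    cells = aggregate(trials)
    return compute_measures(cells, measures=measures)


def run_study(config: StudyConfig) -> StudySummary:
    """Run the full Monte-Carlo study described by ``config``.

    For each experiment the scored cells are reduced, per measure, to a
    paired t test across participants (condition 1 minus condition 2), its
    effect size ``d_z``, and the between-condition Pearson correlation.
    Experiments where a measure's test or correlation is degenerate (zero
    variance) are logged and excluded for that measure, with the count
    reported in ``n_excluded``.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_experiments)
    records: List[dict] = []
    for k in range(config.n_experiments):
        rng = np.random.default_rng(children[k])
        scored = run_experiment(config.design, rng, measures=config.measures)
        cond1 = scored[scored["condition"] == 1].set_index("participant").sort_index()
        cond2 = scored[scored["condition"] == 2].set_index("participant").sort_index()
        for m in config.measures:
            rec = {"experiment": k, "measure": m}
            x1 = cond1[m].to_numpy(dtype=float)
            x2 = cond2[m].to_numpy(dtype=float)
            rec["mean_1"] = float(np.mean(x1))
            rec["mean_2"] = float(np.mean(x2))
            try:
                res = paired_t(x1, x2)
                rec["t"] = res.t
                rec["p"] = res.p
                rec["dz"] = res.dz
            except DegenerateTestError:
                logger.warning("experiment %d: degenerate paired t for %s; excluded", k, m)
                rec["t"] = rec["p"] = rec["dz"] = np.nan
            sa, sb = np.std(x1), np.std(x2)
            if sa > 0 and sb > 0:
                rec["r"] = float(np.corrcoef(x1, x2)[0, 1])
            else:
                logger.warning("experiment %d: constant %s in a condition; r excluded", k, m)
                rec["r"] = np.nan
            records.append(rec)
        if config.log_every and (k + 1) % config.log_every == 0:
            logger.info("completed %d/%d experiments", k + 1, config.n_experiments)

    details = pd.DataFrame.from_records(records)
    rows = []
    for m in config.measures:
        sub = details[details["measure"] == m]
        ok = sub["p"].notna()
        rows.append(
            {
                "measure": m,
                "mean_1": float(sub["mean_1"].mean()),
                "mean_2": float(sub["mean_2"].mean()),
                "mean_dz": float(sub.loc[ok, "dz"].mean()),
                "pct_significant": 100.0 * float((sub.loc[ok, "p"] < config.alpha).mean()),
                "mean_r": _fisher_mean(sub["r"].to_numpy(dtype=float)),
                "min_r": float(sub["r"].min(skipna=True)),
                "max_r": float(sub["r"].max(skipna=True)),
                "n_excluded": int((~ok).sum()),
            }
        )
    table = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    return StudySummary(
        table=table,
        config=config.to_dict(),
        n_experiments=config.n_experiments,
        seed=config.seed,
        details=details,
    )


def write_summary(summary: StudySummary, out_dir: str | Path, details: bool = False) -> None:
    """Write ``summary.csv`` and ``summary.json`` (plus optional details).

    The JSON echoes the full study configuration and master seed so a run
    can be reproduced from its output alone.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        summary.table.to_csv(out / "summary.csv", index=False)
        payload = {
            "config": summary.config,
            "seed": summary.seed,
            "n_experiments": summary.n_experiments,
            "summary": summary.table.to_dict(orient="records"),
        }
        (out / "summary.json").write_text(json.dumps(payload, indent=2))
        if details and summary.details is not None:
            summary.details.to_csv(out / "details.csv", index=False)
    except OSError as exc:
        raise OSError(f"failed writing study summary under {out}: {exc}") from exc
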