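"""Combined speed-accuracy performance measures.

Trial tables are first aggregated to participant x condition cells
(:func:`aggregate`): mean RT over *correct* trials, proportion correct (PC)
over all trials, and the trial-level standard deviations that the LISAS
family rescales by.  The measures then differ only in which variance brings
RT and accuracy to a common scale:

``bis``
    Balanced Integration Score: z(PC) - z(mean RT), each z-standardized with
    the mean and SD *across the aggregated cells* (the data points a t test
    or ANOVA would see).  Unit-free; higher = better; sums to zero over the
    standardization scope; invariant to positive affine transforms of either
    constituent.
``bis_rt_scaled``
    BIS mapped onto the mean-RT scale: grand mean RT - S^RTbar * BIS.  A
    negative affine image of BIS (lower = better).
``lisas``
    Linear Integrated Speed-Accuracy Score:
    mean RT + (S_i^RT / S_i^E) * PE, where S_i^RT and S_i^E are the
    *across-trial* SDs of participant i's correct RTs and 0/1 error
    indicator, pooled over all of that participant's conditions.  RT-scaled;
    lower = better.
``lisas_cond``
    LISAS with the trial SDs computed separately per cell.
``lisas_bis``
    LISAS with BIS's across-cell SDs in place of the trial SDs:
    mean RT + (S^RTbar / S^PE) * PE.  Within one experiment this equals
    ``bis_rt_scaled`` plus a constant, so it inherits BIS's behavior.
``ies`` / ``rcs``
    Baselines: Inverse Efficiency Score (mean RT / PC) and Rate Correct
    Score (correct responses per ms of total response time in the cell).

Because BIS standardizes with the across-cell variance, condition contrasts
on BIS are unchanged by any positive affine rescaling of RT or PC; LISAS,
scaled by trial variability, is not (this asymmetry is the point of the
comparison, not a defect to be corrected).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CELL_COLUMNS",
    "MEASURES",
    "MeasureContext",
    "AggregationError",
    "DegenerateVarianceError",
    "UndefinedMeasureError",
    "aggregate",
    "bis",
    "bis_rt_scaled",
    "lisas",
    "lisas_cond",
    "lisas_bis",
    "ies",
    "rcs",
    "compute_measures",
]

#: Columns produced by :func:`aggregate`.
CELL_COLUMNS = (
    "participant",
    "condition",
    "n",
    "n_correct",
    "mean_rt",
    "pc",
    "pe",
    "sum_rt_all",
    "sd_rt_participant",
    "sd_e_participant",
    "sd_rt_cell",
    "sd_e_cell",
)

#: Measures understood by :func:`compute_measures` (cell statistics plus scores).
MEASURES = (
    "mean_rt",
    "pc",
    "bis",
    "bis_rt_scaled",
    "lisas",
    "lisas_cond",
    "lisas_bis",
    "ies",
    "rcs",
)


class AggregationError(ValueError):
    """A design cell cannot be aggregated (e.g. no correct trials)."""


class DegenerateVarianceError(ValueError):
    """An across-cell SD needed for standardization is zero."""


class UndefinedMeasureError(ValueError):
    """A measure is undefined for a cell (e.g. IES with PC = 0)."""


def _sd(x: np.ndarray, ddof: int) -> float:
    """Sample SD; 0.0 when there are not enough values for the denominator."""
    x = np.asarray(x, dtype=float)
    if x.size <= ddof:
        return 0.0
    return float(np.std(x, ddof=ddof))


def aggregate(trials: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Aggregate a long-format trial table to participant x condition cells.

    Mean RT uses correct trials only; PC uses all trials.  The participant-
    pooled SDs (``sd_rt_participant`` over correct-trial RTs,
    ``sd_e_participant`` over the 0/1 error indicator of all trials) pool
    across all of that participant's conditions; the ``*_cell`` SDs use the
    cell's own trials.  ``ddof=1`` gives sample SDs (default); ``ddof=0``
    makes the cell error SD equal exactly sqrt(PE*(1-PE)).

    Raises :class:`AggregationError` if a cell is empty or has no correct
    trial (its mean correct RT would be undefined).
    """
    trials = trials.loc[:, ["participant", "condition", "rt", "correct"]]
    correct = trials["correct"].astype(bool)

    rows = []
    for pid, ptab in trials.groupby("participant", sort=True):
        pcorr = ptab["correct"].astype(bool)
        sd_rt_part = _sd(ptab.loc[pcorr, "rt"].to_numpy(), ddof)
        # SD of the error indicator equals the SD of the correct indicator.
        sd_e_part = _sd(1.0 - pcorr.to_numpy(dtype=float), ddof)
        for cid, cell in ptab.groupby("condition", sort=True):
            ccorr = cell["correct"].astype(bool)
            n = len(cell)
            n_correct = int(ccorr.sum())
            if n_correct == 0:
                raise AggregationError(
                    f"cell participant={pid}, condition={cid} has no correct trials"
                )
            rows.append(
                {
                    "participant": pid,
                    "condition": cid,
                    "n": n,
                    "n_correct": n_correct,
                    "mean_rt": float(cell.loc[ccorr, "rt"].mean()),
                    "pc": n_correct / n,
                    "pe": 1.0 - n_correct / n,
                    "sum_rt_all": float(cell["rt"].sum()),
                    "sd_rt_participant": sd_rt_part,
                    "sd_e_participant": sd_e_part,
                    "sd_rt_cell": _sd(cell.loc[ccorr, "rt"].to_numpy(), ddof),
                    "sd_e_cell": _sd(1.0 - ccorr.to_numpy(dtype=float), ddof),
                }
            )
    return pd.DataFrame(rows, columns=list(CELL_COLUMNS))


@dataclass(frozen=True)
class MeasureContext:
    """Across-cell means and SDs used for BIS-style standardization.

    The scope is whatever set of cells the context was built from (default:
    all participant x condition cells of one experiment; build separate
    contexts per group when scores should be equated within groups).
    """

    grand_mean_rt: float
    grand_mean_pc: float
    sd_mean_rt: float
    sd_pc: float
    ddof: int = 1

    @property
    def grand_mean_pe(self) -> float:
        return 1.0 - self.grand_mean_pc

    @property
    def sd_pe(self) -> float:
        # PE = 1 - PC is a reflection, so the across-cell SDs coincide.
        return self.sd_pc

    @classmethod
    def from_cells(cls, cells: pd.DataFrame, ddof: int = 1) -> "MeasureContext":
        return cls(
            grand_mean_rt=float(cells["mean_rt"].mean()),
            grand_mean_pc=float(cells["pc"].mean()),
            sd_mean_rt=_sd(cells["mean_rt"].to_numpy(), ddof),
            sd_pc=_sd(cells["pc"].to_numpy(), ddof),
            ddof=ddof,
        )

    def require_nondegenerate(self) -> None:
        if self.sd_mean_rt <= 0 or self.sd_pc <= 0:
            raise DegenerateVarianceError(
                f"across-cell SDs must be positive for standardization "
                f"(sd_mean_rt={self.sd_mean_rt}, sd_pc={self.sd_pc})"
            )


def _context(cells: pd.DataFrame, context: MeasureContext | None) -> MeasureContext:
    return MeasureContext.from_cells(cells) if context is None else context


def bis(cells: pd.DataFrame, context: MeasureContext | None = None) -> pd.Series:
    """Balanced Integration Score per cell: z(PC) - z(mean RT).

    Standardization uses the across-cell means/SDs in ``context`` (computed
    from ``cells`` when omitted).  Over the standardization scope the scores
    sum to zero.  Higher = better performance.
    """
    ctx = _context(cells, context)
    ctx.require_nondegenerate()
    z_pc = (cells["pc"] - ctx.grand_mean_pc) / ctx.sd_pc
    z_rt = (cells["mean_rt"] - ctx.grand_mean_rt) / ctx.sd_mean_rt
    return (z_pc - z_rt).rename("bis")


def bis_rt_scaled(cells: pd.DataFrame, context: MeasureContext | None = None) -> pd.Series:
    """BIS rescaled to the mean-RT scale: grand mean RT - S^RTbar * BIS.

    A negative affine image of :func:`bis` (lower = better); its mean over
    the standardization scope equals the grand mean RT.
    """
    ctx = _context(cells, context)
    return (ctx.grand_mean_rt - ctx.sd_mean_rt * bis(cells, ctx)).rename("bis_rt_scaled")


def _lisas_like(cells: pd.DataFrame, sd_rt: pd.Series, sd_e: pd.Series, name: str) -> pd.Series:
    sd_rt_arr = sd_rt.to_numpy(dtype=float)
    sd_e_arr = sd_e.to_numpy(dtype=float)
    # S^E = 0 means no errors in scope, and then PE = 0 too: the PE term's
    # limit is 0, so the score degenerates to mean RT rather than 0/0.
    ratio = np.zeros_like(sd_e_arr)
    nz = sd_e_arr > 0
    ratio[nz] = sd_rt_arr[nz] / sd_e_arr[nz]
    return pd.Series(
        cells["mean_rt"].to_numpy() + ratio * cells["pe"].to_numpy(),
        index=cells.index,
        name=name,
    )


def lisas(cells: pd.DataFrame) -> pd.Series:
    """LISAS per cell: mean RT + (S_i^RT / S_i^E) * PE.

    The SDs are across-trial SDs pooled over all of participant i's
    conditions (correct trials for the RT SD, all trials for the error SD).
    A participant with no errors anywhere has S_i^E = 0; the PE term is then
    0 (its limit), so LISAS reduces to mean RT.  Lower = better.
    """
    return _lisas_like(cells, cells["sd_rt_participant"], cells["sd_e_participant"], "lisas")


def lisas_cond(cells: pd.DataFrame) -> pd.Series:
    """LISAS with the trial SDs computed within each cell only."""
    return _lisas_like(cells, cells["sd_rt_cell"], cells["sd_e_cell"], "lisas_cond")


def lisas_bis(cells: pd.DataFrame, context: MeasureContext | None = None) -> pd.Series:
    """LISAS with BIS's across-cell SDs: mean RT + (S^RTbar / S^PE) * PE.

    Within one standardization scope this is ``bis_rt_scaled`` shifted by a
    constant, so condition contrasts and t statistics match BIS's (up to the
    sign flip shared with all RT-scaled measures).
    """
    ctx = _context(cells, context)
    if ctx.sd_pe <= 0:
        raise DegenerateVarianceError(f"across-cell SD of PE must be positive, got {ctx.sd_pe}")
    return (cells["mean_rt"] + (ctx.sd_mean_rt / ctx.sd_pe) * cells["pe"]).rename("lisas_bis")


def ies(cells: pd.DataFrame) -> pd.Series:
    """Inverse Efficiency Score: mean RT / PC (lower = better)."""
    if (cells["pc"] <= 0).any():
        bad = cells.loc[cells["pc"] <= 0, ["participant", "condition"]].iloc[0]
        raise UndefinedMeasureError(
            f"IES undefined at PC = 0 (participant={bad['participant']}, "
            f"condition={bad['condition']})"
        )
    return (cells["mean_rt"] / cells["pc"]).rename("ies")


def rcs(cells: pd.DataFrame) -> pd.Series:
    """Rate Correct Score: correct responses / total RT (responses per ms)."""
    if (cells["sum_rt_all"] <= 0).any():
        raise UndefinedMeasureError("RCS undefined for a cell with non-positive total RT")
    return (cells["n_correct"] / cells["sum_rt_all"]).rename("rcs")


def compute_measures(
    cells: pd.DataFrame,
    measures: Sequence[str] = MEASURES,
    context: MeasureContext | None = None,
) -> pd.DataFrame:
    """Score cells on the requested measures; returns cells + score columns."""
    ctx = _context(cells, context)
    out = cells.loc[:, ["participant", "condition", "mean_rt", "pc"]].copy()
    funcs = {
        "bis": lambda: bis(cells, ctx),
        "bis_rt_scaled": lambda: bis_rt_scaled(cells, ctx),
        "lisas": lambda: lisas(cells),
        "lisas_cond": lambda: lisas_cond(cells),
        "lisas_bis": lambda: lisas_bis(cells, ctx),
        "ies": lambda: ies(cells),
        "rcs": lambda: rcs(cells),
    }
    for name in measures:
        if name in ("mean_rt", "pc"):
            continue
        if name not in funcs:
            raise KeyError(f"unknown measure {name!r}; known: {MEASURES}")
        out[name] = funcs[name]()
    return out
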