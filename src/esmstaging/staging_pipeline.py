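"""The cross-lagged staging analysis, end to end.

Builds within-day lagged pairs from an ESM dataset, fits the nine
cross-lagged models (each state at time t regressed on each state at
t-1, with severity subgroup as moderator), runs the severity-interaction
likelihood-ratio test per cell, and renders the subgroup-coefficient
table.  Cross-lagged effects are deliberately not adjusted for
autoregressive effects, and no within/between-person decomposition is
attempted — design parity with the analysis this reproduces.

Each cell is fit through a convergence-rescue ladder: (1) raw variables,
(2) predictor centered at the grand mean, (3) outcome shifted +0.5 (a
1.5-7.5 scale), (4) both.  The first rescaling under which both the
moderator and the covariate model converge wins, and is recorded, since
the interaction test is only valid when both nested fits share one
scale.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from esmstaging.descriptives import SeverityGrouping
from esmstaging.igglmm import GlmmFit, GlmmSpec, InteractionTest, fit_glmm, lrt
from esmstaging.synthetic_esm import STATES, EsmDataset

__all__ = [
    "StagingCell",
    "StagingTable",
    "StagingVerdict",
    "build_lagged_pairs",
    "run_nine_models",
    "staging_verdict",
    "format_staging_table",
    "format_coefficient",
    "format_p",
]

RESCUE_LADDER = (
    {"rescale_outcome_shift": 0.0, "rescale_predictor_center": False},
    {"rescale_outcome_shift": 0.0, "rescale_predictor_center": True},
    {"rescale_outcome_shift": 0.5, "rescale_predictor_center": False},
    {"rescale_outcome_shift": 0.5, "rescale_predictor_center": True},
)


def build_lagged_pairs(
    dataset: EsmDataset, grouping: SeverityGrouping | None = None
) -> pd.DataFrame:
    """Pair each completed assessment with the previous one on the same day.

    The lag is the immediately preceding *completed* beep within the
    person-day (never crossing days).  Per-state missing values
    propagate into the pair, so each model later drops exactly the pairs
    lacking its own outcome or predictor.  With ``grouping`` given, a
    severity_group column is attached.
    """
    frame = dataset.frame.sort_values(["person_id", "day", "beep"], kind="mergesort")
    lagged = frame.groupby(["person_id", "day"], sort=False)[list(STATES)].shift(1)
    pairs = frame.copy()
    for s in STATES:
        pairs[f"{s}_lag"] = lagged[s]
    # a pair row exists whenever there IS a previous completed beep
    prev_beep = frame.groupby(["person_id", "day"], sort=False)["beep"].shift(1)
    pairs = pairs[prev_beep.notna()].reset_index(drop=True)
    if grouping is not None:
        pairs["severity_group"] = pairs["person_id"].map(grouping.group_of_person)
    return pairs


def pair_table_digest(pairs: pd.DataFrame) -> str:
    """Stable digest of the pair rows (used to assert both response
    families saw identical data)."""
    cols = ["person_id", "day", "beep"] + list(STATES) + [f"{s}_lag" for s in STATES]
    raw = pairs[cols].round(9).to_csv(index=False).encode()
    return hashlib.sha256(raw).hexdigest()[:16]


@dataclass
class StagingCell:
    outcome: str
    predictor: str
    moderator_fit: GlmmFit | None
    covariate_fit: GlmmFit | None
    interaction: InteractionTest | None
    rescaling: dict
    ladder_step: int  # 1..4, or 0 if nothing converged
    converged: bool

    def group_coefficients(self) -> pd.DataFrame | None:
        if self.moderator_fit is None:
            return None
        rows = [t for t in self.moderator_fit.coefficients.index if t.startswith("slope_g")]
        return self.moderator_fit.coefficients.loc[rows]


@dataclass
class StagingTable:
    family: str
    cells: dict = field(default_factory=dict)  # (outcome, predictor) -> StagingCell
    pair_digest: str = ""
    n_pairs: int = 0

    def cell(self, outcome: str, predictor: str) -> StagingCell:
        return self.cells[(outcome, predictor)]


@dataclass(frozen=True)
class StagingVerdict:
    flags: dict  # (outcome, predictor) -> True / False / None (indeterminate)
    n_supporting: int


def _fit_ladder(
    pairs: pd.DataFrame,
    outcome: str,
    predictor: str,
    family: str,
    start_theta=None,
    **fit_kwargs,
):
    """Walk the rescue ladder until both nested models converge."""
    last = (None, None, 0, {})
    for step, rescale in enumerate(RESCUE_LADDER, start=1):
        spec_m = GlmmSpec(
            outcome=outcome, predictor=predictor, response_family=family,
            severity_role="moderator", **rescale,
        )
        spec_c = GlmmSpec(
            outcome=outcome, predictor=predictor, response_family=family,
            severity_role="covariate", **rescale,
        )
        try:
            fit_m = fit_glmm(spec_m, pairs, start_theta=start_theta, **fit_kwargs)
            theta_m = np.asarray(fit_m.diagnostics.get("theta"))
            fit_c = fit_glmm(spec_c, pairs, start_theta=theta_m, **fit_kwargs)
        except (ValueError, np.linalg.LinAlgError):
            continue
        last = (fit_m, fit_c, step, fit_m.rescaling)
        if fit_m.converged and fit_c.converged:
            return fit_m, fit_c, step, fit_m.rescaling, True
    fit_m, fit_c, step, rescaling = last
    return fit_m, fit_c, step, rescaling, False


def run_nine_models(
    pairs: pd.DataFrame,
    grouping: SeverityGrouping | None = None,
    family: str = "ig",
    outcomes=STATES,
    predictors=STATES,
    **fit_kwargs,
) -> StagingTable:
    """Fit every (outcome, predictor) cross-lagged cell with severity
    moderation and its interaction LRT.

    ``pairs`` must carry a severity_group column (attach one via
    ``build_lagged_pairs(dataset, grouping)``).  Single-predictor models
    only: each cell's model contains one lagged state, unadjusted for
    the others.  A cell whose ladder never converges is kept, marked
    non-converged.
    """
    if "severity_group" not in pairs.columns:
        if grouping is None:
            raise ValueError("pairs lack severity_group and no grouping given")
        pairs = pairs.copy()
        pairs["severity_group"] = pairs["person_id"].map(grouping.group_of_person)
    table = StagingTable(
        family=family, pair_digest=pair_table_digest(pairs), n_pairs=len(pairs)
    )
    for outcome in outcomes:
        for predictor in predictors:
            fit_m, fit_c, step, rescaling, ok = _fit_ladder(
                pairs, outcome, f"{predictor}_lag", family, **fit_kwargs,
            )
            test = None
            if ok:
                test = lrt(fit_m, fit_c)
            table.cells[(outcome, predictor)] = StagingCell(
                outcome=outcome, predictor=predictor,
                moderator_fit=fit_m, covariate_fit=fit_c,
                interaction=test, rescaling=rescaling,
                ladder_step=step if ok else 0, converged=ok,
            )
    return table


def staging_verdict(table: StagingTable, alpha: float = 0.05) -> StagingVerdict:
    """Flag cells showing 'increasing connection strength with severity'.

    A cell supports staging when its subgroup coefficients are
    non-decreasing from the lowest to the highest severity group (ties
    count as non-decreasing) AND the severity-interaction LRT is
    significant at ``alpha``.  Non-converged cells are indeterminate.
    """
    flags = {}
    count = 0
    for key, cell in table.cells.items():
        if not cell.converged or cell.interaction is None:
            flags[key] = None
            continue
        coefs = cell.group_coefficients()["estimate"].to_numpy()
        monotone = bool(np.all(np.diff(coefs) >= 0))
        flag = monotone and cell.interaction.p_value < alpha
        flags[key] = flag
        count += int(flag)
    return StagingVerdict(flags=flags, n_supporting=count)


def format_coefficient(estimate: float, ci_low: float, ci_high: float) -> str:
    """Render one subgroup coefficient cell: '0.049 (-0.002; 0.100)'."""
    return f"{estimate:.3f} ({ci_low:.3f}; {ci_high:.3f})"


def format_p(p: float) -> str:
    """Three-decimal p value; anything below 0.0005 prints as '0.000'."""
    return "0.000" if p < 0.0005 else f"{p:.3f}"


_STATE_LABEL = {"na": "Negative affect", "pa": "Positive affect", "par": "Paranoia"}


def format_staging_table(table: StagingTable) -> str:
    """Render the 3x3 grid of subgroup coefficients, one text block per
    outcome, with the interaction LRT row and rescaling footnotes."""
    if not table.cells:
        return ""
    lines = []
    outcomes = sorted({k[0] for k in table.cells}, key=list(STATES).index)
    predictors = sorted({k[1] for k in table.cells}, key=list(STATES).index)
    n_groups = 0
    for outcome in outcomes:
        lines.append(
            f"{_STATE_LABEL[outcome]} at moment t predicted by mental states "
            f"at moment t-1, by severity subgroup"
        )
        header = ["Severity subgroup"] + [
            f"{_STATE_LABEL[p]} at t-1" + _footnote_marks(table.cell(outcome, p))
            for p in predictors
        ]
        lines.append("\t".join(header))
        coef_blocks = {}
        for p in predictors:
            cell = table.cell(outcome, p)
            cf = cell.group_coefficients()
            coef_blocks[p] = cf
            if cf is not None:
                n_groups = max(n_groups, len(cf))
        for g in range(1, n_groups + 1):
            row = [f"Symptom severity-level {g}"]
            for p in predictors:
                cf = coef_blocks[p]
                if cf is None or f"slope_g{g}" not in cf.index:
                    row.append("(not converged)")
                    continue
                est, _, lo, hi = cf.loc[f"slope_g{g}"]
                star = "*" if (lo > 0 or hi < 0) else ""
                row.append(format_coefficient(est, lo, hi) + star)
            lines.append("\t".join(row))
        row = ["Significance of interaction with severity"]
        for p in predictors:
            cell = table.cell(outcome, p)
            if cell.interaction is None:
                row.append("(not converged)")
            else:
                t = cell.interaction
                row.append(
                    f"Chi-sq = {t.chi_sq:.3f}; df = {t.df}; p = {format_p(t.p_value)}"
                )
        lines.append("\t".join(row))
        lines.append("")
    lines.append("a Independent variable rescaled (grand mean = 0)")
    lines.append("b Dependent variable rescaled (+0.5)")
    lines.append("* p < 0.05")
    return "\n".join(lines)


def _footnote_marks(cell: StagingCell) -> str:
    marks = ""
    if cell.rescaling.get("predictor_centered"):
        marks += " a"
    if cell.rescaling.get("outcome_shift"):
        marks += " b"
    return marks


def staging_table_frame(table: StagingTable) -> pd.DataFrame:
    """Tidy one-row-per-cell summary of the staging table."""
    rows = []
    for (outcome, predictor), cell in table.cells.items():
        row = {
            "outcome": outcome,
            "predictor": predictor,
            "converged": cell.converged,
            "ladder_step": cell.ladder_step,
            "outcome_shift": cell.rescaling.get("outcome_shift", 0.0),
            "predictor_centered": cell.rescaling.get("predictor_centered", False),
        }
        cf = cell.group_coefficients()
        if cf is not None:
            for g, term in enumerate(cf.index, start=1):
                row[f"B_g{g}"] = cf.loc[term, "estimate"]
                row[f"ci_low_g{g}"] = cf.loc[term, "ci_low"]
                row[f"ci_high_g{g}"] = cf.loc[term, "ci_high"]
        if cell.interaction is not None:
            row["lrt_chi_sq"] = cell.interaction.chi_sq
            row["lrt_df"] = cell.interaction.df
            row["lrt_p"] = cell.interaction.p_value
        rows.append(row)
    return pd.DataFrame(rows)
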