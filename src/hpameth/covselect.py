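"""Greedy forward covariate selection by nested-model F tests.

At each step every remaining candidate is added to the current model and the
improvement in fit is assessed with the extra-sum-of-squares F test; the
candidate with the smallest p enters if p < alpha (default 0.10). Selection
stops when no candidate qualifies. Ties break on candidate name so the
result does not depend on column order. The full evaluation trace is kept so
the alternative reading (each candidate tested alone against the base model)
can be recovered from the step-1 rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SelectionTrace", "forward_select", "DEFAULT_CANDIDATES"]

#: Clinical covariates screened against each phenotype of interest.
DEFAULT_CANDIDATES = [
    "hypersexuality",
    "depression",
    "ctq_total",
    "tsh_t4",
    "hba1c",
    "cortisol_baseline",
    "acth_baseline",
    "testosterone",
    "tnf_alpha",
    "il6",
]


@dataclass
class SelectionTrace:
    """Per-evaluation records plus the final selected covariate set."""

    steps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["step", "candidate", "F", "p", "accepted"]
        )
    )
    selected: list[str] = field(default_factory=list)


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("singular design")
    resid = y - X @ coef
    return float(resid @ resid), X.shape[0] - rank


def forward_select(
    y, candidates: pd.DataFrame, alpha: float = 0.10
) -> SelectionTrace:
    """Greedy forward selection of covariates for a linear model of ``y``.

    Binary outcomes are modelled with the same linear-model ANOVA (a
    linear probability model); pass the 0/1 coding directly.
    """
    y = np.asarray(y, dtype=float)
    if candidates.shape[1] and y.size < candidates.shape[1] + 2:
        raise ValueError("need n >= number of candidates + 2")
    trace = SelectionTrace()
    if candidates.shape[1] == 0:
        return trace
    names = sorted(candidates.columns)
    selected: list[str] = []
    records = []
    step = 0
    while True:
        step += 1
        remaining = [c for c in names if c not in selected]
        if not remaining:
            break
        X0 = np.column_stack(
            [np.ones(y.size)] + [candidates[c].to_numpy(float) for c in selected]
        )
        try:
            rss0, df0 = _rss(y, X0)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular design with covariates {selected}"
            ) from err
        best = None
        for cand in remaining:
            X1 = np.column_stack([X0, candidates[cand].to_numpy(float)])
            try:
                rss1, df1 = _rss(y, X1)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    f"singular design when adding covariate {cand!r}"
                ) from err
            if rss1 <= 0 or df1 <= 0:
                F, p = np.inf, 0.0
            else:
                F = (rss0 - rss1) / (rss1 / df1)
                p = float(stats.f.sf(F, 1, df1))
            records.append({"step": step, "candidate": cand, "F": float(F), "p": p})
            if best is None or (p, cand) < best[:2]:
                best = (p, cand, F)
        p_best, cand_best, _ = best
        for rec in records:
            if rec["step"] == step:
                rec["accepted"] = rec["candidate"] == cand_best and p_best < alpha
        if p_best < alpha:
            selected.append(cand_best)
        else:
            break
    trace.steps = pd.DataFrame.from_records(
        records, columns=["step", "candidate", "F", "p", "accepted"]
    )
    trace.selected = selected
    return trace
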