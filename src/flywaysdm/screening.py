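"""Two-step predictor selection.

Step one removes predictors with zero percent contribution in a preliminary
all-variable model. Step two iterates over the remaining pairwise Pearson
correlations (computed at the species' occurrence cells): while any pair has
``|r|`` at or above the threshold, the currently most-correlated pair is
found and its lower-contribution member dropped (tie: the later in input
order). The surviving set therefore has no pair at or above the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import OccurrenceSet, RasterStack

__all__ = ["ScreeningResult", "pearson_at_points", "select_variables", "screen_stack"]


@dataclass
class ScreeningResult:
    kept: list[str]
    dropped: list[tuple[str, str]]  # (name, reason)
    correlation: pd.DataFrame
    contributions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        reason = dict(self.dropped)
        rows = [
            dict(
                variable=v,
                contribution=self.contributions.get(v, np.nan),
                kept=v in self.kept,
                reason=reason.get(v, ""),
            )
            for v in self.contributions
        ]
        return pd.DataFrame(rows)


def pearson_at_points(
    stack: RasterStack,
    occ: OccurrenceSet,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson r over layer values at the occurrence cells.

    Zero-variance layers get undefined (NaN) correlations with a warning;
    the selection step treats those as |r| = 0.
    """
    variables = variables or list(stack.names)
    rows, cols = occ.unique_cells(stack.grid)
    vals = stack.values_at_cells(rows, cols, variables)
    finite = np.all(np.isfinite(vals), axis=1)
    vals = vals[finite]
    if vals.shape[0] < 3:
        raise ValueError("need at least 3 occurrence cells with finite covariates")
    sd = vals.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        names = [v for v, d in zip(variables, degenerate) if d]
        warnings.warn(f"zero variance at occurrence points for {names}; r undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vals, rowvar=False)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=variables, columns=variables)


def select_variables(
    contributions: dict[str, float],
    correlation: pd.DataFrame,
    r_threshold: float = 0.8,
) -> ScreeningResult:
    if not (0 < r_threshold <= 1):
        raise ValueError("r_threshold must lie in (0, 1]")
    names = list(contributions)
    if set(correlation.index) != set(names):
        raise ValueError("correlation matrix must cover exactly the contribution names")
    order = {v: i for i, v in enumerate(names)}
    dropped: list[tuple[str, str]] = []

    alive = [v for v in names if contributions[v] != 0]
    dropped += [(v, "zero_contribution") for v in names if contributions[v] == 0]

    R = correlation.abs().fillna(0.0)
    while len(alive) > 1:
        best, best_pair = -1.0, None
        for i, a in enumerate(alive):
            for b in alive[i + 1:]:
                r = float(R.loc[a, b])
                if r > best:
                    best, best_pair = r, (a, b)
        if best < r_threshold or best_pair is None:
            break
        a, b = best_pair
        # drop the lower contribution; tie -> later in input order
        if contributions[a] < contributions[b]:
            loser, winner = a, b
        elif contributions[b] < contributions[a]:
            loser, winner = b, a
        else:
            loser, winner = (a, b) if order[a] > order[b] else (b, a)
        alive.remove(loser)
        dropped.append((loser, f"correlated_with:{winner}"))
    return ScreeningResult(alive, dropped, correlation, dict(contributions))


def screen_stack(
    stack: RasterStack,
    occ: OccurrenceSet,
    contributions: dict[str, float],
    variables: list[str] | None = None,
    r_threshold: float = 0.8,
) -> ScreeningResult:
    """Convenience wrapper: correlation at points + two-step selection."""
    variables = variables or list(stack.names)
    corr = pearson_at_points(stack, occ, variables)
    return select_variables({v: contributions[v] for v in variables}, corr, r_threshold)
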