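"""BIC-driven choice of the regularization weights (lambda1, lambda2).

Candidates on a grid are each fitted with the block-coordinate solver and
scored with a Gaussian-likelihood BIC where model complexity is the number
of nonzero transition coefficients (the lasso degrees-of-freedom
convention):

    BIC = n_eff * ln(RSS / n_eff) + df * ln(n_eff),

with n_eff = N * K * (T-1) residuals, RSS the unpenalized reconstruction
loss at the solution, and df = #{|w| > zero_tol}.  The pair with the
smallest BIC wins; ties go to the larger (lambda1, lambda2), i.e. the
smoother/sparser model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import InferenceConfig, get_logger
from .inference import TransitionNetworkModel, TransitionNetworkResults

__all__ = ["BICGrid", "bic_score", "select_lambdas", "default_grid"]

logger = get_logger("selection")

NEG_INF_BIC = float("-inf")


def default_grid() -> list[tuple[float, float]]:
    """The default 5 x 5 logarithmic grid over {1e-3 .. 10}^2."""
    vals = [1e-3, 1e-2, 1e-1, 1.0, 10.0]
    return [(l1, l2) for l1 in vals for l2 in vals]


def bic_score(
    result: TransitionNetworkResults,
    model: TransitionNetworkModel | None = None,
    zero_tol: float = 1e-6,
) -> tuple[float, int, int]:
    """Return ``(bic, df, n_eff)`` for a fitted transition series.

    ``n_eff`` counts one residual per (pseudo-sample, template, transition).
    A zero RSS (perfect fit) yields a -inf sentinel with a warning.
    """
    model = model or result.model
    n_eff = model.n_samples * model.n_templates * model.n_transitions
    rss = model.objective_terms(result.series).loss
    df = int((np.abs(result.params) > zero_tol).sum())
    if rss <= 0:
        warnings.warn("perfect fit (RSS = 0); BIC is -inf", stacklevel=2)
        return NEG_INF_BIC, df, n_eff
    bic = n_eff * float(np.log(rss / n_eff)) + df * float(np.log(n_eff))
    return bic, df, n_eff


@dataclass
class BICGrid:
    """Scores for every (lambda1, lambda2) candidate plus the selected pair."""

    candidates: list[tuple[float, float]]
    bic_values: list[float]
    df_values: list[int]
    rss_values: list[float]
    n_eff: int
    selected_index: int
    results: list[TransitionNetworkResults] = field(default_factory=list, repr=False)

    @property
    def selected(self) -> tuple[float, float]:
        return self.candidates[self.selected_index]

    @property
    def selected_result(self) -> TransitionNetworkResults:
        return self.results[self.selected_index]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "lambda1": [c[0] for c in self.candidates],
                "lambda2": [c[1] for c in self.candidates],
                "rss": self.rss_values,
                "df": self.df_values,
                "bic": self.bic_values,
            }
        )
        df["selected"] = False
        df.loc[self.selected_index, "selected"] = True
        return df


def select_lambdas(
    data,
    grid: list[tuple[float, float]] | None = None,
    config: InferenceConfig | None = None,
    zero_tol: float = 1e-6,
) -> BICGrid:
    """Fit every grid candidate with BCD and pick the BIC minimizer.

    Deterministic given the data and config; grid order does not affect the
    selection (ties are broken by the larger (lambda1, lambda2) pair).
    """
    grid = default_grid() if grid is None else list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    config = config or InferenceConfig()
    model = TransitionNetworkModel(data, config)
    bics: list[float] = []
    dfs: list[int] = []
    rsss: list[float] = []
    results: list[TransitionNetworkResults] = []
    n_eff = model.n_samples * model.n_templates * model.n_transitions
    for lam1, lam2 in grid:
        m = TransitionNetworkModel(data, config.with_lambdas(lam1, lam2))
        res = m.fit(method="bcd")
        if not res.converged:
            logger.warning(
                "candidate (lambda1=%g, lambda2=%g) did not converge; retained",
                lam1, lam2,
            )
        bic, df, n_eff = bic_score(res, m, zero_tol)
        bics.append(bic)
        dfs.append(df)
        rsss.append(m.objective_terms(res.series).loss)
        results.append(res)
    best = min(range(len(grid)), key=lambda i: (bics[i], -grid[i][0], -grid[i][1]))
    logger.info(
        "BIC selected lambda1=%g, lambda2=%g (bic=%.4g, df=%d)",
        grid[best][0], grid[best][1], bics[best], dfs[best],
    )
    return BICGrid(
        candidates=grid,
        bic_values=bics,
        df_values=dfs,
        rss_values=rsss,
        n_eff=n_eff,
        selected_index=best,
        results=results,
    )
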