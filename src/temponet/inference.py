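"""Estimation of time-varying, sparse, temporally smooth transition matrices.

The dynamical model links template levels at consecutive time points,

    v_{t+1} = W^(t) v_t ,   t = 1 .. T-1,

where ``v_t`` is the K-vector of template levels at time t and ``W^(t)`` is a
K x K coefficient matrix: entry (i, j) is the effect of template j at time t
on template i at time t+1 (positive = activation-like, negative =
depression).  The matrices are estimated by minimizing

    (1/N) sum_n sum_{t_hat} sum_{t in window(t_hat)}
          w(t, t_hat) ||v_{t+1}^n - W^(t_hat) v_t^n||^2
    + lambda1 * sum_{t1<t2} M(t1, t2) ||W^(t1) - W^(t2)||_F^2
    + lambda2 * sum_t ||W^(t)||_1 ,

i.e. a sliding-window weighted reconstruction loss over the N pseudo-sample
matrices, a temporal-smoothness penalty between nearby transition matrices,
and an entrywise L1 penalty that drives most edges exactly to zero.

Two solvers are provided.  The production solver is block coordinate
descent (:meth:`TransitionNetworkModel.fit` with ``method="bcd"``): one
transition matrix is updated at a time by proximal-gradient iteration with
backtracking and soft-thresholding, cycling until the total objective
stabilizes.  The reference solver (``method="oracle"``) minimizes the fully
vectorized problem jointly via a positive/negative variable split (turning
the L1 term into a linear one over bound constraints) with L-BFGS-B, plus an
exact active-set polish; it is restricted to small instances and exists to
cross-check the production path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .config import InferenceConfig, WindowWeighting, get_logger

__all__ = [
    "TransitionSeries",
    "ObjectiveTerms",
    "TransitionNetworkModel",
    "TransitionNetworkResults",
    "window_weight",
    "objective",
    "fit_bcd",
    "fit_qp_oracle",
    "lambda_max",
    "export_network",
]

logger = get_logger("inference")

_ORACLE_MAX_VARS = 2000


@dataclass
class TransitionSeries:
    """The T-1 estimated (or true) transition matrices of a K-template system."""

    matrices: list[np.ndarray]

    def __post_init__(self) -> None:
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        if not self.matrices:
            raise ValueError("a transition series needs at least one matrix")
        k = self.matrices[0].shape[0]
        for m in self.matrices:
            if m.shape != (k, k):
                raise ValueError("all transition matrices must be K x K")
            if not np.all(np.isfinite(m)):
                raise ValueError("transition matrices must be finite")

    @property
    def n_transitions(self) -> int:
        return len(self.matrices)

    @property
    def n_templates(self) -> int:
        return self.matrices[0].shape[0]

    def as_array(self) -> np.ndarray:
        return np.stack(self.matrices)

    def l1_norm(self) -> float:
        return float(sum(np.abs(m).sum() for m in self.matrices))

    @classmethod
    def zeros(cls, n_transitions: int, n_templates: int) -> "TransitionSeries":
        return cls([np.zeros((n_templates, n_templates)) for _ in range(n_transitions)])


@dataclass(frozen=True)
class ObjectiveTerms:
    """Per-term decomposition of the fitting objective."""

    loss: float
    smoothness: float
    sparsity: float
    lambda1: float
    lambda2: float

    @property
    def total(self) -> float:
        return self.loss + self.lambda1 * self.smoothness + self.lambda2 * self.sparsity


def window_weight(t: int, t_hat: int, window: WindowWeighting) -> float:
    """Weight of transition ``t`` in the forward window centred at ``t_hat``."""
    return window.weight(t, t_hat)


class TransitionNetworkModel:
    """Time-varying transition-matrix model for template dynamics.

    Parameters
    ----------
    data : sequence of (K, T) arrays
        The N pseudo-sample data matrices (templates x time points).
    config : InferenceConfig
        Window, smoothness indicator, regularization weights, tolerances.

    Notes
    -----
    All solver work runs on sufficient statistics: for the block centred at
    transition s the loss is  E_s - 2<W, B_s> + tr(W A_s W'), with

        A_s = sum_{t in win(s)} w(t,s) * mean_n v_t v_t',
        B_s = sum_{t in win(s)} w(t,s) * mean_n v_{t+1} v_t',

    so the fitting cost does not grow with N once the statistics are formed.
    """

    def __init__(self, data, config: InferenceConfig | None = None):
        self.config = config or InferenceConfig()
        arr = np.stack([np.asarray(d, dtype=float) for d in data])
        if arr.ndim != 3:
            raise ValueError("data must be a sequence of K x T matrices")
        self.data = arr
        self.n_samples, self.n_templates, self.n_times = arr.shape
        if self.n_times < 2:
            raise ValueError("need at least two time points")
        self.n_transitions = self.n_times - 1
        self._build_stats()

    @classmethod
    def from_templates(
        cls, pseudo_matrices, config: InferenceConfig | None = None
    ) -> "TransitionNetworkModel":
        """Build from the pseudo-replicate matrices emitted by the clustering stage."""
        return cls(pseudo_matrices, config)

    # ---------------------------------------------------------------- stats
    def _build_stats(self) -> None:
        v = self.data  # (N, K, T)
        n_tr = self.n_transitions
        # per-transition moments, averaged over samples
        c = np.einsum("nkt,nlt->tkl", v[:, :, :-1], v[:, :, :-1]) / self.n_samples
        d = np.einsum("nkt,nlt->tkl", v[:, :, 1:], v[:, :, :-1]) / self.n_samples
        e = np.einsum("nkt,nkt->t", v[:, :, 1:], v[:, :, 1:]) / self.n_samples
        offsets, weights = self.config.window.offsets_and_weights()
        self._A = np.zeros((n_tr, self.n_templates, self.n_templates))
        self._B = np.zeros_like(self._A)
        self._E = np.zeros(n_tr)
        for s in range(n_tr):
            for off, w in zip(offsets, weights):
                t = s + off
                if t >= n_tr:
                    break
                self._A[s] += w * c[t]
                self._B[s] += w * d[t]
                self._E[s] += w * e[t]
        self._M = self.config.indicator.matrix(n_tr)
        # Lipschitz constants of each block's smooth part
        self._lipschitz = np.array(
            [
                2.0 * (np.linalg.eigvalsh(self._A[s])[-1] + self.config.lambda1 * self._M[s].sum())
                for s in range(n_tr)
            ]
        )

    # ------------------------------------------------------------ objective
    def objective_terms(self, series: TransitionSeries) -> ObjectiveTerms:
        """Evaluate loss, smoothness and sparsity terms at a given series."""
        if series.n_transitions != self.n_transitions or series.n_templates != self.n_templates:
            raise ValueError(
                f"series shape ({series.n_transitions} x {series.n_templates}^2) does "
                f"not match model ({self.n_transitions} x {self.n_templates}^2)"
            )
        loss = 0.0
        for s, w in enumerate(series.matrices):
            loss += self._E[s] - 2.0 * np.vdot(w, self._B[s]) + np.vdot(w @ self._A[s], w)
        smooth = 0.0
        for s in range(self.n_transitions):
            for t in range(s + 1, self.n_transitions):
                if self._M[s, t] > 0:
                    diff = series.matrices[s] - series.matrices[t]
                    smooth += self._M[s, t] * np.vdot(diff, diff)
        return ObjectiveTerms(
            loss=float(loss),
            smoothness=float(smooth),
            sparsity=series.l1_norm(),
            lambda1=self.config.lambda1,
            lambda2=self.config.lambda2,
        )

    def lambda_max(self) -> float:
        """Smallest L1 weight at which the all-zero series is optimal.

        At W = 0 the smooth gradient of block s is -2 B_s (the smoothness
        term vanishes), so zero is a solution exactly when lambda2 bounds
        every entry of 2 B_s in magnitude.
        """
        return float(max(2.0 * np.abs(self._B[s]).max() for s in range(self.n_transitions)))

    # ------------------------------------------------------------- solvers
    def fit(self, method: str = "bcd", start: TransitionSeries | None = None) -> "TransitionNetworkResults":
        if method == "bcd":
            return self._fit_bcd(start)
        if method in ("oracle", "qp"):
            return self._fit_oracle()
        raise ValueError(f"unknown method {method!r}")

    def _block_smooth_value_grad(self, s: int, w: np.ndarray, others: list[np.ndarray]):
        """Smooth part (loss + coupled smoothness) of block s and its gradient."""
        lam1 = self.config.lambda1
        val = self._E[s] - 2.0 * np.vdot(w, self._B[s]) + np.vdot(w @ self._A[s], w)
        grad = 2.0 * (w @ self._A[s] - self._B[s])
        m_row = self._M[s]
        m_sum = m_row.sum()
        if lam1 > 0 and m_sum > 0:
            p = np.zeros_like(w)
            for t, m in enumerate(m_row):
                if m > 0 and t != s:
                    diff = w - others[t]
                    val += lam1 * m * np.vdot(diff, diff)
                    p += m * others[t]
            grad += 2.0 * lam1 * (m_sum * w - p)
        return float(val), grad

    def _prox_block(self, s: int, w0: np.ndarray, others: list[np.ndarray]) -> np.ndarray:
        """Solve one block subproblem by proximal gradient with backtracking."""
        cfg = self.config
        lam2 = cfg.lambda2
        lip = max(self._lipschitz[s], 1e-12)
        step = 1.0 / lip
        w = w0.copy()
        f, g = self._block_smooth_value_grad(s, w, others)
        obj = f + lam2 * np.abs(w).sum()
        for _ in range(cfg.max_inner_iter):
            trial_step = 2.0 * step  # try a slightly bolder step, then backtrack
            while True:
                z = w - trial_step * g
                w_new = np.sign(z) * np.maximum(np.abs(z) - trial_step * lam2, 0.0)
                f_new, g_new = self._block_smooth_value_grad(s, w_new, others)
                diff = w_new - w
                quad = f + np.vdot(g, diff) + np.vdot(diff, diff) / (2.0 * trial_step)
                if f_new <= quad + 1e-15 * (1.0 + abs(f)):
                    break
                trial_step *= 0.5
                if trial_step < 1e-2 / lip:  # guaranteed-descent step
                    trial_step = 1.0 / lip
                    z = w - trial_step * g
                    w_new = np.sign(z) * np.maximum(np.abs(z) - trial_step * lam2, 0.0)
                    f_new, g_new = self._block_smooth_value_grad(s, w_new, others)
                    break
            step = trial_step
            obj_new = f_new + lam2 * np.abs(w_new).sum()
            delta = obj - obj_new
            w, f, g, obj = w_new, f_new, g_new, obj_new
            if delta <= cfg.tol_inner * (1.0 + abs(obj)):
                break
        return w

    def _fit_bcd(self, start: TransitionSeries | None = None) -> "TransitionNetworkResults":
        cfg = self.config
        n_tr, k = self.n_transitions, self.n_templates
        if start is not None:
            mats = [m.copy() for m in start.matrices]
        else:
            mats = [np.zeros((k, k)) for _ in range(n_tr)]
        history: list[float] = []
        prev = self.objective_terms(TransitionSeries([m.copy() for m in mats])).total
        history.append(prev)
        converged = False
        cycles = 0
        for cycle in range(cfg.max_cycles):
            cycles = cycle + 1
            for s in range(n_tr):
                mats[s] = self._prox_block(s, mats[s], mats)
            total = self.objective_terms(TransitionSeries([m.copy() for m in mats])).total
            history.append(total)
            if prev - total <= cfg.tol_outer * (1.0 + abs(total)):
                converged = True
                prev = total
                break
            prev = total
        if not converged:
            logger.warning(
                "BCD did not converge in %d cycles (last objective %.6g)",
                cfg.max_cycles, history[-1],
            )
        series = TransitionSeries(mats)
        return TransitionNetworkResults(
            model=self,
            series=series,
            objective=self.objective_terms(series),
            method="bcd",
            converged=converged,
            n_cycles=cycles,
            objective_history=history,
        )

    # ---------------------------------------------------------- oracle path
    def _joint_quadratic(self):
        """Hessian-free representation of the joint smooth objective.

        Variables: x = concat of row-major vec(W_s).  Smooth part is
        x' H x - 2 c' x + e0 with H assembled from I_K (x) A_s diagonal
        blocks and the smoothness coupling.
        """
        n_tr, k = self.n_transitions, self.n_templates
        p = k * k
        lam1 = self.config.lambda1
        h = np.zeros((n_tr * p, n_tr * p))
        c = np.empty(n_tr * p)
        eye = np.eye(k)
        for s in range(n_tr):
            h[s * p:(s + 1) * p, s * p:(s + 1) * p] = np.kron(eye, self._A[s])
            c[s * p:(s + 1) * p] = self._B[s].ravel()
        if lam1 > 0:
            big_eye = np.eye(p)
            for s in range(n_tr):
                for t in range(s + 1, n_tr):
                    m = self._M[s, t]
                    if m > 0:
                        h[s * p:(s + 1) * p, s * p:(s + 1) * p] += lam1 * m * big_eye
                        h[t * p:(t + 1) * p, t * p:(t + 1) * p] += lam1 * m * big_eye
                        h[s * p:(s + 1) * p, t * p:(t + 1) * p] -= lam1 * m * big_eye
                        h[t * p:(t + 1) * p, s * p:(s + 1) * p] -= lam1 * m * big_eye
        return h, c, float(self._E.sum())

    def _fit_oracle(self) -> "TransitionNetworkResults":
        n_tr, k = self.n_transitions, self.n_templates
        n_vars = n_tr * k * k
        if n_vars > _ORACLE_MAX_VARS:
            raise ValueError(
                f"oracle solver limited to {_ORACLE_MAX_VARS} variables; "
                f"instance has {n_vars}"
            )
        lam2 = self.config.lambda2
        h, c, e0 = self._joint_quadratic()

        def fun(pq: np.ndarray):
            x = pq[:n_vars] - pq[n_vars:]
            hx = h @ x
            val = float(x @ hx - 2.0 * c @ x + e0 + lam2 * pq.sum())
            g = 2.0 * (hx - c)
            return val, np.concatenate([g + lam2, -g + lam2])

        x0 = np.zeros(2 * n_vars)
        res = minimize(
            fun,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * n_vars),
            options={"maxiter": 200000, "maxfun": 400000, "ftol": 1e-18, "gtol": 1e-12},
        )
        x = res.x[:n_vars] - res.x[n_vars:]
        x = self._polish_support(h, c, e0, lam2, x)
        mats = [x[s * k * k:(s + 1) * k * k].reshape(k, k) for s in range(n_tr)]
        series = TransitionSeries(mats)
        return TransitionNetworkResults(
            model=self,
            series=series,
            objective=self.objective_terms(series),
            method="oracle",
            converged=True,
            n_cycles=int(res.nit),
            objective_history=[self.objective_terms(series).total],
        )

    @staticmethod
    def _polish_support(h, c, e0, lam2, x, tol=1e-9):
        """Exact KKT solve on the detected support (signs fixed), if it helps."""

        def value(v):
            return float(v @ (h @ v) - 2.0 * c @ v + e0 + lam2 * np.abs(v).sum())

        base = value(x)
        support = np.abs(x) > max(tol, 1e-12)
        if lam2 == 0:
            support[:] = True
        if not support.any():
            return x
        idx = np.nonzero(support)[0]
        signs = np.sign(x[idx])
        hs = h[np.ix_(idx, idx)]
        rhs = c[idx] - 0.5 * lam2 * signs
        try:
            sol = np.linalg.lstsq(hs, rhs, rcond=None)[0]
        except np.linalg.LinAlgError:
            return x
        if lam2 > 0 and np.any(np.sign(sol) * signs < 0):
            return x
        cand = np.zeros_like(x)
        cand[idx] = sol
        if lam2 > 0:
            # off-support subgradient check
            g_off = 2.0 * (h @ cand - c)[~support]
            if g_off.size and np.abs(g_off).max() > lam2 * (1 + 1e-6):
                return x
        return cand if value(cand) <= base else x


@dataclass
class TransitionNetworkResults:
    """Fitted transition matrices with objective diagnostics.

    ``objective_history`` records the total objective once per BCD cycle
    (including the starting value) and is non-increasing.
    """

    model: TransitionNetworkModel
    series: TransitionSeries
    objective: ObjectiveTerms
    method: str
    converged: bool
    n_cycles: int
    objective_history: list[float]

    @property
    def params(self) -> np.ndarray:
        """(T-1, K, K) array of estimated coefficients."""
        return self.series.as_array()

    def n_edges(self, threshold: float = 1e-3) -> int:
        return int((np.abs(self.params) > threshold).sum())

    def to_edge_frame(self, threshold: float = 1e-3) -> pd.DataFrame:
        """Directed edges (source template -> target template) per transition."""
        rows = []
        for t, w in enumerate(self.series.matrices, start=1):
            ii, jj = np.nonzero(np.abs(w) > threshold)
            for i, j in zip(ii, jj):
                rows.append(
                    {
                        "source": f"template_{j + 1}",
                        "target": f"template_{i + 1}",
                        "transition": t,
                        "weight": float(w[i, j]),
                        "sign": "+" if w[i, j] > 0 else "-",
                    }
                )
        return pd.DataFrame(rows, columns=["source", "target", "transition", "weight", "sign"])

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        o = self.objective
        lines = [
            "Time-varying transition network fit",
            "=" * 51,
            f"templates (K):        {self.series.n_templates}",
            f"transitions (T-1):    {self.series.n_transitions}",
            f"pseudo-samples (N):   {self.model.n_samples}",
            f"solver:               {self.method}",
            f"converged:            {self.converged} ({self.n_cycles} cycles)",
            f"lambda1 (smoothness): {o.lambda1:g}",
            f"lambda2 (sparsity):   {o.lambda2:g}",
            "-" * 51,
            f"loss term:            {o.loss:.6g}",
            f"smoothness term:      {o.smoothness:.6g}",
            f"L1 term:              {o.sparsity:.6g}",
            f"total objective:      {o.total:.6g}",
            f"nonzero coefficients: {self.n_edges(1e-6)} of "
            f"{self.series.n_transitions * self.series.n_templates ** 2}",
        ]
        return "\n".join(lines)


# ------------------------------------------------------- functional surface

def objective(series: TransitionSeries, data, config: InferenceConfig) -> ObjectiveTerms:
    """Per-term objective of a series on a set of K x T data matrices."""
    return TransitionNetworkModel(data, config).objective_terms(series)


def fit_bcd(data, config: InferenceConfig) -> TransitionNetworkResults:
    """Fit by block coordinate descent (production solver)."""
    return TransitionNetworkModel(data, config).fit(method="bcd")


def fit_qp_oracle(data, config: InferenceConfig) -> TransitionNetworkResults:
    """Jointly solve the fully vectorized problem (small-instance reference)."""
    return TransitionNetworkModel(data, config).fit(method="oracle")


def lambda_max(data, config: InferenceConfig) -> float:
    """Smallest sparsity weight that forces the all-zero solution."""
    return TransitionNetworkModel(data, config).lambda_max()


def export_network(
    result: TransitionNetworkResults,
    path: str | Path,
    edge_threshold: float = 1e-3,
    fmt: str = "edge-list",
) -> Path:
    """Write the inferred directed network to ``path``.

    Formats: ``edge-list`` (TSV with source, target, transition, weight,
    sign), ``sif`` (Simple Interaction Format; the relation encodes the
    transition index and sign), ``graphml`` (via networkx; one edge per
    (transition, source, target) with weight/sign attributes).
    """
    if edge_threshold < 0:
        raise ValueError("edge_threshold must be non-negative")
    path = Path(path)
    edges = result.to_edge_frame(edge_threshold)
    if fmt == "edge-list":
        edges.to_csv(path, sep="\t", index=False, float_format="%.12g")
    elif fmt == "sif":
        with open(path, "w") as fh:
            for _, row in edges.iterrows():
                fh.write(f"{row.source}\tt{row.transition}{row.sign}\t{row.target}\n")
    elif fmt == "graphml":
        import networkx as nx

        g = nx.MultiDiGraph()
        for k in range(result.series.n_templates):
            g.add_node(f"template_{k + 1}")
        for _, row in edges.iterrows():
            g.add_edge(
                row.source,
                row.target,
                transition=int(row.transition),
                weight=float(row.weight),
                sign=row.sign,
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    logger.info("wrote %d edges to %s (%s)", len(edges), path, fmt)
    return path
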