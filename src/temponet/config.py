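"""Shared configuration objects, TOML config loading, and logging helpers.

The inference stage is controlled by three small value objects:

* :class:`WindowWeighting` — the forward sliding window that lets several
  adjacent transitions contribute, with decaying weight, to the regression
  for one transition matrix.
* :class:`SmoothnessIndicator` — the temporal-proximity indicator ``M(t1,t2)``
  that weights the squared Frobenius distance between transition matrices
  at nearby transitions (hard cutoff or Gaussian-soft).
* :class:`InferenceConfig` — regularization weights, solver tolerances and
  iteration caps, pseudo-sample count and seed.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "WindowWeighting",
    "SmoothnessIndicator",
    "InferenceConfig",
    "load_config",
    "config_from_dict",
    "get_logger",
    "setup_logging",
]

_LOGGER_NAME = "temponet"


def get_logger(child: str | None = None) -> logging.Logger:
    """Return the package logger (or a named child of it)."""
    name = _LOGGER_NAME if child is None else f"{_LOGGER_NAME}.{child}"
    return logging.getLogger(name)


def setup_logging(level: int | str = logging.INFO, stream=None) -> logging.Logger:
    """Attach a timestamped stream handler to the package logger."""
    logger = get_logger()
    logger.setLevel(level)
    if not logger.handlers:
        handler = logging.StreamHandler(stream or sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
    return logger


@dataclass(frozen=True)
class WindowWeighting:
    """Forward sliding window with decaying weights.

    The regression for the transition matrix centred at transition ``t_hat``
    also uses the transitions ``t_hat+1 .. t_hat+delta`` (clipped at the last
    valid transition), each down-weighted by distance from the centre.

    Parameters
    ----------
    delta : int
        Window extent in transition steps (0 disables the window).
    decay : {"gaussian", "exponential"}
        Functional form of the decay.
    sigma : float
        Decay scale; the weight at the centre is always 1.
    """

    delta: int = 2
    decay: str = "gaussian"
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("window delta must be a non-negative integer")
        if self.decay not in ("gaussian", "exponential"):
            raise ValueError(f"unknown decay {self.decay!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def weight(self, t: int, t_hat: int) -> float:
        """Weight of transition ``t`` in the window centred at ``t_hat``."""
        d = t - t_hat
        if d < 0 or d > self.delta:
            return 0.0
        if self.decay == "gaussian":
            return float(np.exp(-(d**2) / (2.0 * self.sigma**2)))
        return float(np.exp(-d / self.sigma))

    def offsets_and_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """All in-window offsets ``0..delta`` and their weights."""
        d = np.arange(self.delta + 1)
        if self.decay == "gaussian":
            w = np.exp(-(d.astype(float) ** 2) / (2.0 * self.sigma**2))
        else:
            w = np.exp(-d.astype(float) / self.sigma)
        return d, w


@dataclass(frozen=True)
class SmoothnessIndicator:
    """Temporal proximity indicator ``M(t1, t2)`` for the smoothness penalty.

    ``hard`` gives 1 for ``0 < |t1-t2| <= radius`` else 0; ``soft`` gives
    ``exp(-(t1-t2)^2 / tau)``.  The diagonal is always excluded.
    """

    kind: str = "hard"
    radius: int = 1
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("hard", "soft"):
            raise ValueError(f"unknown indicator kind {self.kind!r}")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def matrix(self, n_transitions: int) -> np.ndarray:
        """Symmetric (n_transitions x n_transitions) indicator with zero diagonal."""
        idx = np.arange(n_transitions)
        dist = np.abs(idx[:, None] - idx[None, :])
        if self.kind == "hard":
            m = ((dist > 0) & (dist <= self.radius)).astype(float)
        else:
            m = np.exp(-(dist.astype(float) ** 2) / self.tau)
            np.fill_diagonal(m, 0.0)
        return m


@dataclass(frozen=True)
class InferenceConfig:
    """Regularization weights and solver settings for transition inference.

    ``lambda1`` weighs the temporal-smoothness penalty, ``lambda2`` the
    entrywise L1 sparsity penalty.  The reconstruction loss is averaged over
    the ``n_pseudo`` data matrices so the lambdas keep the same meaning
    regardless of how many pseudo-replicates are drawn.
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    window: WindowWeighting = field(default_factory=WindowWeighting)
    indicator: SmoothnessIndicator = field(default_factory=SmoothnessIndicator)
    n_pseudo: int = 20
    tol_outer: float = 1e-6
    tol_inner: float = 1e-8
    max_cycles: int = 500
    max_inner_iter: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be non-negative")
        if self.tol_outer <= 0 or self.tol_inner <= 0:
            raise ValueError("tolerances must be positive")
        if self.n_pseudo < 1:
            raise ValueError("n_pseudo must be at least 1")

    def with_lambdas(self, lambda1: float, lambda2: float) -> "InferenceConfig":
        return replace(self, lambda1=lambda1, lambda2=lambda2)


def load_config(path: str | Path) -> dict:
    """Read a TOML run configuration.

    Recognised sections are ``[input]``, ``[filter]``, ``[cluster]``,
    ``[infer]``, ``[bic]`` and ``[synthetic]``; unknown sections are kept
    verbatim so callers can extend the format.
    """
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def config_from_dict(d: dict) -> InferenceConfig:
    """Build an :class:`InferenceConfig` from the ``[infer]`` section of a config."""
    window = WindowWeighting(
        delta=int(d.get("window", 2)),
        decay=str(d.get("decay", "gaussian")),
        sigma=float(d.get("sigma", 1.0)),
    )
    ind = str(d.get("indicator", "hard:1"))
    if ":" in ind:
        kind, _, param = ind.partition(":")
    else:
        kind, param = ind, ""
    if kind == "hard":
        indicator = SmoothnessIndicator(kind="hard", radius=int(param or 1))
    else:
        indicator = SmoothnessIndicator(kind="soft", tau=float(param or 1.0))
    return InferenceConfig(
        lambda1=float(d.get("lambda1", 0.0)),
        lambda2=float(d.get("lambda2", 0.0)),
        window=window,
        indicator=indicator,
        n_pseudo=int(d.get("n_pseudo", 20)),
        tol_outer=float(d.get("tol_outer", 1e-6)),
        tol_inner=float(d.get("tol_inner", 1e-8)),
        max_cycles=int(d.get("max_cycles", 500)),
        max_inner_iter=int(d.get("max_inner_iter", 5000)),
        seed=int(d.get("seed", 0)),
    )


def asdict_config(cfg: InferenceConfig) -> dict:
    """JSON-serializable snapshot of a config (for run manifests)."""
    return dataclasses.asdict(cfg)
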