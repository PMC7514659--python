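"""Shared data containers: time series, transition ensembles, reports, densities."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ContractError

logger = logging.getLogger(__name__)

#: hard floor on ensemble size for any estimation call
MIN_ENSEMBLE = 100
#: below this an estimation warning is logged
SMALL_ENSEMBLE = 10_000


@dataclass
class TimeSeries:
    """A uniformly sampled bivariate stationary series.

    ``dt_sample`` is the time between stored points (the observational
    resolution available to estimators; lags must be multiples of it).
    """

    dt_sample: float
    x: np.ndarray
    y: np.ndarray
    model: str = "unknown"
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ContractError(
                f"x and y must be equal-length 1-D arrays, got {self.x.shape} / {self.y.shape}"
            )
        if self.dt_sample <= 0:
            raise ContractError("dt_sample must be > 0")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ContractError("series contains non-finite values")

    def __len__(self) -> int:
        return self.x.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) * self.dt_sample


@dataclass
class TransitionEnsemble:
    """Samples of the state-pair combination (x_t, y_t, x_{t+tau}, y_{t+tau}).

    Rows are draws (possibly from overlapping windows of a stationary
    series) of the two successive states separated by the lag ``tau``.
    """

    tau: float
    samples: np.ndarray
    model: str = "unknown"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 4:
            raise ContractError(
                f"samples must be (n, 4), got shape {self.samples.shape}"
            )
        if self.tau <= 0:
            raise ContractError("tau must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ContractError("ensemble contains non-finite values")
        if self.n < MIN_ENSEMBLE:
            raise ContractError(
                f"ensemble has {self.n} samples; at least {MIN_ENSEMBLE} required"
            )
        if self.n < SMALL_ENSEMBLE:
            logger.warning(
                "ensemble has only %d samples; estimates will be noisy", self.n
            )

    @property
    def n(self) -> int:
        return self.samples.shape[0]


@dataclass
class IrrevReport:
    """Scalar irreversibility/information measures (nats) at one lag tau.

    ``phi_xy``  mapping irreversibility of the joint series;
    ``phi_x``   marginal mapping irreversibility of the signal;
    ``phi_cond`` conditional mapping irreversibility phi_xy - phi_x;
    ``bte``     backward transfer entropy T_{y->x}(-tau) = I(x_t; y_{t+tau} | x_{t+tau});
    ``fte``     forward transfer entropy T_{y->x}(tau) = I(y_t; x_{t+tau} | x_t);
    ``causal_influence`` C_{x->y}(tau) = I(x_t; y_{t+tau}) - R(tau);
    ``redundancy``       R(tau).
    """

    tau: float
    phi_xy: float
    phi_x: float
    phi_cond: float
    bte: float
    fte: float
    causal_influence: float | None = None
    redundancy: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class IFTResult:
    """Monte-Carlo check of an integral fluctuation theorem.

    ``mean_exponential`` should be statistically compatible with 1.
    """

    mean_exponential: float
    standard_error: float
    n: int
    theorem: str
    method: str = "plain"

    def __post_init__(self) -> None:
        if self.mean_exponential <= 0:
            raise ContractError("mean_exponential must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GridDensity:
    """Irreversibility density on a grid of current states (x_t, y_t).

    Axes are in units of the stationary standard deviations; ``psi`` has
    shape ``(len(x_axis), len(y_axis))`` in nats per unit (SD-scaled) area.
    Unoccupied bins of empirical densities are NaN and excluded from the
    quadrature.
    """

    x_axis: np.ndarray
    y_axis: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.x_axis = np.asarray(self.x_axis, dtype=float)
        self.y_axis = np.asarray(self.y_axis, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.psi.shape != (self.x_axis.size, self.y_axis.size):
            raise ContractError(
                f"psi shape {self.psi.shape} does not match axes "
                f"({self.x_axis.size}, {self.y_axis.size})"
            )

    def quadrature(self) -> float:
        """Integral of psi over the grid (trapezoid on full grids, cell sum
        on masked empirical grids)."""
        if np.any(np.isnan(self.psi)):
            dx = float(np.median(np.diff(self.x_axis)))
            dy = float(np.median(np.diff(self.y_axis)))
            return float(np.nansum(self.psi) * dx * dy)
        inner = np.trapezoid(self.psi, self.y_axis, axis=1)
        return float(np.trapezoid(inner, self.x_axis))
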