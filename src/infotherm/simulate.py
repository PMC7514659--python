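"""Seeded Euler-Maruyama simulation of the linear and receptor-ligand models.

Two stationary bivariate models are integrated:

* the linear signal-response model (OU signal, deterministic linear
  response) — Gaussian increments enter the signal only;
* the receptor-ligand model

      dx = -(x - 1) dt + x dW_x
      dy = [kon (1 - y) x^h / (1 + x^h) - koff y] dt + y (1 - y) dW_y

  where x is the ligand concentration (mean-reverting geometric Brownian
  motion with mean 1) and y the fraction of activated receptors, bounded
  in (0, 1) by its multiplicative noise; trajectories are hard-clamped at
  a configurable epsilon from the boundaries and clamp activations are
  monitored.

Replicated short runs (vectorized across replicas) decorrelate transition
samples; a single long run is a special case (n_replicas=1).  All
randomness flows from the config seed through one numpy Generator, so
identical configs give bit-identical series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .blrm import BLRMParams, stationary_cov
from .containers import TimeSeries, TransitionEnsemble
from .errors import ContractError

logger = logging.getLogger(__name__)

_NOISE_CHUNK = 8192  # steps of pre-generated increments per block


@dataclass(frozen=True)
class RLParams:
    """Receptor-ligand kinetic constants (Hill constant fixed at K = <x> = 1).

    kon  : binding rate (1/time, > 0)
    koff : unbinding rate (1/time, > 0)
    h    : Hill cooperativity coefficient (>= 1)
    """

    kon: float = 5.0
    koff: float = 1.0
    h: float = 2.0

    def __post_init__(self) -> None:
        if self.kon <= 0 or self.koff <= 0:
            raise ContractError("kon and koff must be > 0")
        if self.h < 1:
            raise ContractError("Hill coefficient h must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Integration controls.

    n_steps is the number of post-burn-in steps per replica; store_every
    (defaults to dt) sets the sampling interval of the stored series.
    """

    dt: float
    n_steps: int
    burn_in: float
    seed: int = 0
    n_replicas: int = 1
    store_every: float | None = None
    boundary_eps: float = 1e-9
    allow_coarse_dt: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_steps <= 0 or self.n_replicas <= 0:
            raise ContractError("dt, n_steps and n_replicas must be positive")
        if self.burn_in < 0:
            raise ContractError("burn_in must be >= 0")
        if self.store_every is not None:
            stride = self.store_every / self.dt
            if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
                raise ContractError(
                    f"store_every={self.store_every} must be a positive multiple of dt={self.dt}"
                )

    @property
    def stride(self) -> int:
        return 1 if self.store_every is None else int(round(self.store_every / self.dt))

    @property
    def dt_sample(self) -> float:
        return self.dt * self.stride


def _check_dt(cfg: SimConfig, timescales: tuple[float, ...], model: str) -> None:
    tmin = min(timescales)
    if cfg.dt > 0.01 * tmin:
        msg = (
            f"dt={cfg.dt} exceeds 1% of the fastest {model} timescale ({tmin:g}); "
            "integration bias may be significant"
        )
        if not cfg.allow_coarse_dt:
            raise ContractError(msg + " (set allow_coarse_dt=True to override)")
        logger.warning(msg)


def _finalize(
    xs: list[np.ndarray],
    ys: list[np.ndarray],
    cfg: SimConfig,
    model: str,
    params: dict,
) -> TimeSeries | list[TimeSeries]:
    X = np.asarray(xs)  # (n_stored, n_replicas)
    Y = np.asarray(ys)
    series = [
        TimeSeries(
            dt_sample=cfg.dt_sample,
            x=X[:, r],
            y=Y[:, r],
            model=model,
            seed=cfg.seed,
            params=params,
        )
        for r in range(cfg.n_replicas)
    ]
    return series[0] if cfg.n_replicas == 1 else series


def simulate_blrm(params: BLRMParams, cfg: SimConfig) -> TimeSeries | list[TimeSeries]:
    """Euler-Maruyama integration of the linear model.

    The signal receives Gaussian increments of variance D^2 dt; the
    response is integrated deterministically.  Initial states are drawn
    from the analytic stationary law (or zero when D = 0, whose relaxation
    is the documented noiseless check).
    """
    _check_dt(cfg, (params.trel, 1.0 / params.beta), "BLRM")
    rng = np.random.default_rng(cfg.seed)
    nrep = cfg.n_replicas
    if params.D > 0:
        L = np.linalg.cholesky(stationary_cov(params))
        z0 = rng.standard_normal((nrep, 2)) @ L.T
        x, y = z0[:, 0].copy(), z0[:, 1].copy()
    else:
        x, y = np.ones(nrep), np.zeros(nrep)
    sdt = np.sqrt(cfg.dt) * params.D
    burn_steps = int(round(cfg.burn_in / cfg.dt))
    total = burn_steps + cfg.n_steps
    stride = cfg.stride
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    step = 0
    while step < total:
        m = min(_NOISE_CHUNK, total - step)
        W = rng.standard_normal((m, nrep)) * sdt
        for i in range(m):
            y = y + (params.alpha * x - params.beta * y) * cfg.dt
            x = x + (-x / params.trel) * cfg.dt + W[i]
            step += 1
            if step > burn_steps and (step - burn_steps) % stride == 0:
                xs.append(x.copy())
                ys.append(y.copy())
    return _finalize(
        xs, ys, cfg, "blrm",
        {"trel": params.trel, "D": params.D, "alpha": params.alpha, "beta": params.beta},
    )


def simulate_receptor_ligand(
    params: RLParams, cfg: SimConfig
) -> TimeSeries | list[TimeSeries]:
    """Euler-Maruyama integration of the receptor-ligand model.

    Multiplicative noises x dW_x and y(1-y) dW_y; trajectories are clamped
    to x >= boundary_eps and boundary_eps <= y <= 1 - boundary_eps.  If
    clamping fires on more than 0.1% of steps a warning advises a finer dt.
    """
    _check_dt(cfg, (1.0, 1.0 / params.koff, 1.0 / params.kon), "receptor-ligand")
    rng = np.random.default_rng(cfg.seed)
    nrep = cfg.n_replicas
    x = np.ones(nrep)
    half_act = params.kon * 0.5
    y = np.full(nrep, half_act / (half_act + params.koff))
    sdt = np.sqrt(cfg.dt)
    eps = cfg.boundary_eps
    burn_steps = int(round(cfg.burn_in / cfg.dt))
    total = burn_steps + cfg.n_steps
    stride = cfg.stride
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    clamps = 0
    step = 0
    while step < total:
        m = min(_NOISE_CHUNK, total - step)
        W = rng.standard_normal((m, 2, nrep)) * sdt
        for i in range(m):
            xh = x**params.h
            hill = xh / (1.0 + xh)
            x = x + (1.0 - x) * cfg.dt + x * W[i, 0]
            y = y + (params.kon * (1.0 - y) * hill - params.koff * y) * cfg.dt \
                + y * (1.0 - y) * W[i, 1]
            low = (x < eps).sum() + (y < eps).sum() + (y > 1.0 - eps).sum()
            if low:
                clamps += int(low)
                np.clip(x, eps, None, out=x)
                np.clip(y, eps, 1.0 - eps, out=y)
            step += 1
            if step > burn_steps and (step - burn_steps) % stride == 0:
                xs.append(x.copy())
                ys.append(y.copy())
    if clamps > 0.001 * total * nrep:
        logger.warning(
            "boundary clamp fired on %d of %d replica-steps (> 0.1%%); "
            "consider a smaller dt", clamps, total * nrep,
        )
    return _finalize(
        xs, ys, cfg, "receptor_ligand",
        {"kon": params.kon, "koff": params.koff, "h": params.h},
    )


def white_noise_series(
    n: int, dt_sample: float = 1.0, seed: int = 0
) -> TimeSeries:
    """An i.i.d. standard-normal bivariate series — the reversible control."""
    rng = np.random.default_rng(seed)
    return TimeSeries(
        dt_sample=dt_sample,
        x=rng.standard_normal(n),
        y=rng.standard_normal(n),
        model="white_noise",
        seed=seed,
    )


def make_transition_ensemble(
    series: TimeSeries | list[TimeSeries], tau: float
) -> TransitionEnsemble:
    """All overlapping (x_t, y_t, x_{t+tau}, y_{t+tau}) quadruples at lag tau.

    *tau* must be an integer multiple of the series' sampling interval;
    windows never cross replica boundaries when a list is given.
    """
    many = series if isinstance(series, list) else [series]
    if not many:
        raise ContractError("no series given")
    dt = many[0].dt_sample
    if any(abs(s.dt_sample - dt) > 1e-12 * dt for s in many):
        raise ContractError("all series must share the same dt_sample")
    ratio = tau / dt
    lag = int(round(ratio))
    if lag < 1 or abs(ratio - lag) > 1e-6:
        nearest = max(1, lag) * dt
        raise ContractError(
            f"tau={tau} is not a multiple of dt_sample={dt}; nearest valid tau is {nearest}"
        )
    blocks = []
    for s in many:
        if len(s) <= lag:
            raise ContractError(
                f"series of length {len(s)} too short for lag {lag} samples"
            )
        blocks.append(
            np.column_stack([s.x[:-lag], s.y[:-lag], s.x[lag:], s.y[lag:]])
        )
    return TransitionEnsemble(
        tau=lag * dt,
        samples=np.vstack(blocks),
        model=many[0].model,
        seed=many[0].seed,
    )
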