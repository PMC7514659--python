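"""Exact analytics for the basic linear response model (BLRM).

The model couples an Ornstein-Uhlenbeck signal to a deterministic linear
response (response noise taken to zero):

    dx = -x / trel dt + D dW
    dy/dt = alpha x - beta y

Because the dynamics is linear with Gaussian noise, the stationary law of
the state pair (x_t, y_t, x_{t+tau}, y_{t+tau}) is a zero-mean Gaussian
whose covariance follows from the continuous Lyapunov equation and the
matrix exponential of the drift.  Every measure offered here — mapping
irreversibility, its signal marginal, backward/forward transfer entropy,
causal influence and redundancy, the steady-state information flow, and
the irreversibility density over current states — is evaluated in closed
form from that 4x4 covariance.

Time-swapped ("backward") statistics are obtained by exchanging the
(x_t, y_t) and (x_{t+tau}, y_{t+tau}) blocks of the covariance, which is
the correct backward law under stationarity.

For very large lags the cross-covariance decays like exp(-tau/trel) and
exp(-beta tau); beyond lag ~ 35 relaxation times the measures fall below
float64 cancellation noise.  Passing ``dps`` (decimal digits) switches
the computation to arbitrary-precision arithmetic so the asymptotic
ratios remain well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm, solve_triangular

from .containers import GridDensity, IrrevReport, TransitionEnsemble
from .errors import ContractError, SingularCovarianceError
from .gaussian import chol_lower, gaussian_cmi, gaussian_kl, gaussian_mi, validate_cov

import logging

logger = logging.getLogger(__name__)

#: permutation that exchanges the time-t and time-(t+tau) blocks
SWAP = (2, 3, 0, 1)


@dataclass(frozen=True)
class BLRMParams:
    """Constants of the linear signal-response model.

    trel  : relaxation time of the signal (> 0)
    D     : noise amplitude of the signal (>= 0; analytic measures need > 0)
    alpha : coupling strength, response units per signal unit per time (!= 0)
    beta  : response relaxation rate, 1/time (> 0)

    After standardization the information measures depend on (beta * trel)
    and tau / trel only.
    """

    trel: float
    D: float = 1.0
    alpha: float = 1.0
    beta: float = 0.2

    def __post_init__(self) -> None:
        if self.trel <= 0:
            raise ContractError("trel must be > 0")
        if self.D < 0:
            raise ContractError("D must be >= 0")
        if self.alpha == 0:
            raise ContractError("alpha must be nonzero")
        if self.beta <= 0:
            raise ContractError("beta must be > 0")


@dataclass
class LaggedJointGaussian:
    """Zero-mean Gaussian law of (x_t, y_t, x_{t+tau}, y_{t+tau})."""

    tau: float
    sigma4: np.ndarray

    def __post_init__(self) -> None:
        self.sigma4 = validate_cov(self.sigma4, "sigma4")
        if self.sigma4.shape != (4, 4):
            raise ContractError("sigma4 must be 4x4")
        if self.tau <= 0:
            raise ContractError("tau must be > 0")

    @property
    def stationary(self) -> np.ndarray:
        """The 2x2 single-time block (equal at t and t+tau by stationarity)."""
        return self.sigma4[:2, :2]

    @property
    def cross(self) -> np.ndarray:
        """Cov(z_{t+tau}, z_t), the lower-left block."""
        return self.sigma4[2:, :2]

    def swapped(self) -> np.ndarray:
        """Covariance of the time-swapped combination."""
        return swap_blocks(self.sigma4)


def swap_blocks(sigma4: np.ndarray) -> np.ndarray:
    """Exchange the (x_t, y_t) and (x_{t+tau}, y_{t+tau}) blocks."""
    idx = np.asarray(SWAP)
    return sigma4[np.ix_(idx, idx)]


def drift_matrix(params: BLRMParams) -> np.ndarray:
    return np.array([[-1.0 / params.trel, 0.0], [params.alpha, -params.beta]])


def stationary_cov(params: BLRMParams) -> np.ndarray:
    """Stationary covariance of (x, y): the solution of A S + S A' + diag(D^2, 0) = 0.

    The triangular drift gives the closed form
    Sxx = D^2 trel / 2, Sxy = alpha Sxx / (beta + 1/trel), Syy = alpha Sxy / beta.
    """
    sxx = params.D**2 * params.trel / 2.0
    sxy = params.alpha * sxx / (params.beta + 1.0 / params.trel)
    syy = params.alpha * sxy / params.beta
    return np.array([[sxx, sxy], [sxy, syy]])


def lagged_gaussian(params: BLRMParams, tau: float) -> LaggedJointGaussian:
    """The 4x4 lagged joint Gaussian at lag *tau* (> 0)."""
    if tau <= 0:
        raise ContractError("tau must be > 0")
    if params.D == 0:
        raise ContractError("analytic measures require D > 0 (degenerate law at D=0)")
    S = stationary_cov(params)
    G = expm(drift_matrix(params) * tau) @ S  # Cov(z_{t+tau}, z_t)
    sigma4 = np.block([[S, G.T], [G, S]])
    return LaggedJointGaussian(tau=tau, sigma4=sigma4)


def _causal_pieces(sigma4: np.ndarray) -> tuple[float, float]:
    """(causal influence, redundancy) from the 4-variable covariance."""
    i1 = gaussian_mi(sigma4, [0], [1])          # I(x_t; y_t)
    i2 = gaussian_mi(sigma4, [3], [0, 1])       # I(y_{t+tau}; (x_t, y_t))
    i_lag = gaussian_mi(sigma4, [0], [3])       # I(x_t; y_{t+tau})
    # R = (I1 + I2) - 0.5 ln(e^{2 I1} + e^{2 I2} - 1), evaluated stably
    m = max(2.0 * i1, 2.0 * i2)
    log_sum = m + np.log(np.exp(2.0 * i1 - m) + np.exp(2.0 * i2 - m) - np.exp(-m))
    redundancy = (i1 + i2) - 0.5 * log_sum
    causal = i_lag - redundancy
    if causal < 0:
        if causal < -1e-10:
            logger.warning("causal influence %.3e < 0; clipping", causal)
        causal = max(causal, 0.0)
    return causal, redundancy


def causal_influence(
    params: BLRMParams, tau: float, dps: int | None = None
) -> tuple[float, float]:
    """Causal influence C_{x->y}(tau) and redundancy R(tau), in nats."""
    if dps is not None:
        rep = _mp_report(params, tau, dps)
        return rep.causal_influence, rep.redundancy
    ljg = lagged_gaussian(params, tau)
    return _causal_pieces(ljg.sigma4)


def irreversibility(
    params: BLRMParams, tau: float, dps: int | None = None
) -> IrrevReport:
    """All scalar measures of the BLRM at lag *tau*.

    phi_xy is the KL divergence between the lagged joint Gaussian and its
    block-swapped counterpart; phi_x is the same for the (x_t, x_{t+tau})
    marginal and vanishes identically because the OU autocovariance is
    symmetric in its two times; the backward transfer entropy is
    I(x_t; y_{t+tau} | x_{t+tau}) and the forward one I(y_t; x_{t+tau} | x_t),
    the latter identically zero in the absence of feedback.

    Set ``dps`` to evaluate in arbitrary precision (needed for tau many
    times the slowest relaxation time, where float64 underflows).
    """
    if dps is not None:
        return _mp_report(params, tau, dps)
    ljg = lagged_gaussian(params, tau)
    S4 = ljg.sigma4
    try:
        phi_xy = gaussian_kl(S4, ljg.swapped())
    except SingularCovarianceError as exc:
        raise SingularCovarianceError(
            f"{exc}; at tau={tau} the lagged joint law is numerically singular "
            "(the small-tau limit diverges) — use a larger tau"
        ) from exc
    marg = S4[np.ix_([0, 2], [0, 2])]
    phi_x = gaussian_kl(marg, marg[np.ix_([1, 0], [1, 0])])
    bte = gaussian_cmi(S4, [0], [3], [2])
    fte = gaussian_cmi(S4, [1], [2], [0])
    causal, redundancy = _causal_pieces(S4)
    return IrrevReport(
        tau=tau,
        phi_xy=phi_xy,
        phi_x=phi_x,
        phi_cond=phi_xy - phi_x,
        bte=bte,
        fte=fte,
        causal_influence=causal,
        redundancy=redundancy,
    )


def information_flow(params: BLRMParams) -> float:
    """Steady-state information flow from signal to response, nats per unit time.

    With the response noise taken to zero the probability current in the y
    direction is J_y = p(x, y) (alpha x - beta y), and the Gaussian integral
    of J_y d(ln p(x|y))/dy collapses to alpha * Sxy / Syy (= beta for every
    parameter set of this model).  It equals the small-tau slope of the
    causal influence.
    """
    S = stationary_cov(params)
    return float(params.alpha * S[0, 1] / S[1, 1])


def psi_density(
    params: BLRMParams,
    tau: float,
    grid_sd: float = 6.0,
    grid_n: int = 400,
) -> GridDensity:
    """Mapping-irreversibility density over current states (x_t, y_t).

    At each grid node, psi = p(x_t, y_t) times the KL divergence between
    the forward conditional p(z_{t+tau} | z_t) and the backward conditional
    p(z_{t-tau} | z_t); both are Gaussian with state-linear means.  Axes are
    in stationary-SD units and psi is scaled so that its quadrature over
    the grid equals the mapping irreversibility.
    """
    if tau <= 0:
        raise ContractError("tau must be > 0")
    if grid_sd < 4.0:
        logger.warning(
            "psi grid spans only +-%.1f SD; quadrature will miss tail mass", grid_sd
        )
    ljg = lagged_gaussian(params, tau)
    S = ljg.stationary
    G = ljg.cross
    Sinv = np.linalg.inv(S)
    Kf = G @ Sinv                       # forward conditional mean map
    Kb = G.T @ Sinv                     # backward conditional mean map
    Sf = S - G @ Sinv @ G.T
    Sb = S - G.T @ Sinv @ G
    Lb = chol_lower(Sb, "backward conditional covariance")
    Lf = chol_lower(Sf, "forward conditional covariance")
    A = solve_triangular(Lb, Lf, lower=True)
    ld_b = 2.0 * np.sum(np.log(np.diag(Lb)))
    ld_f = 2.0 * np.sum(np.log(np.diag(Lf)))
    c0 = 0.5 * (np.sum(A * A) - 2.0 + ld_b - ld_f)
    Delta = Kf - Kb
    W = solve_triangular(Lb, Delta, lower=True)
    M = W.T @ W                          # quadratic form of the mean gap

    sx, sy = np.sqrt(S[0, 0]), np.sqrt(S[1, 1])
    u = np.linspace(-grid_sd, grid_sd, grid_n)
    v = np.linspace(-grid_sd, grid_sd, grid_n)
    X = u[:, None] * sx
    Y = v[None, :] * sy
    # stationary density of (x_t, y_t)
    det = S[0, 0] * S[1, 1] - S[0, 1] ** 2
    quad_p = (S[1, 1] * X**2 - 2 * S[0, 1] * X * Y + S[0, 0] * Y**2) / det
    pdf = np.exp(-0.5 * quad_p) / (2.0 * np.pi * np.sqrt(det))
    kl_grid = c0 + 0.5 * (M[0, 0] * X**2 + 2 * M[0, 1] * X * Y + M[1, 1] * Y**2)
    psi = pdf * kl_grid * sx * sy       # SD-unit axes absorb the Jacobian
    return GridDensity(x_axis=u, y_axis=v, psi=psi)


def sample_transitions(
    ljg: LaggedJointGaussian, n: int, seed: int | np.random.Generator = 0
) -> TransitionEnsemble:
    """Draw *n* exact samples of (x_t, y_t, x_{t+tau}, y_{t+tau})."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = chol_lower(ljg.sigma4, "sigma4")
    Z = rng.standard_normal((n, 4)) @ L.T
    return TransitionEnsemble(
        tau=ljg.tau,
        samples=Z,
        model="blrm-exact",
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


# ----------------------------------------------------------------------
# arbitrary-precision path (large-tau asymptotics)

def _mp_sigma4(params: BLRMParams, tau: float, mp) -> "object":
    a = mp.mpf(-1.0) / mp.mpf(params.trel)
    b = -mp.mpf(params.beta)
    c = mp.mpf(params.alpha)
    sxx = mp.mpf(params.D) ** 2 * mp.mpf(params.trel) / 2
    sxy = c * sxx / (mp.mpf(params.beta) + 1 / mp.mpf(params.trel))
    syy = c * sxy / mp.mpf(params.beta)
    S = mp.matrix([[sxx, sxy], [sxy, syy]])
    ea, eb = mp.e ** (a * tau), mp.e ** (b * tau)
    if a == b:  # degenerate eigenvalues of the triangular drift
        E = mp.matrix([[ea, 0], [c * tau * ea, eb]])
    else:
        E = mp.matrix([[ea, 0], [c * (ea - eb) / (a - b), eb]])
    G = E * S
    S4 = mp.zeros(4)
    for i in range(2):
        for j in range(2):
            S4[i, j] = S[i, j]
            S4[2 + i, 2 + j] = S[i, j]
            S4[2 + i, j] = G[i, j]
            S4[i, 2 + j] = G[j, i]
    return S4


def _mp_sub(M, idx, mp):
    return mp.matrix([[M[i, j] for j in idx] for i in idx])


def _mp_logdet(M, mp):
    L = mp.cholesky(M)
    return 2 * mp.fsum(mp.log(L[i, i]) for i in range(M.rows))


def _mp_kl(P, Q, mp):
    d = P.rows
    QiP = Q**-1 * P
    tr = mp.fsum(QiP[i, i] for i in range(d))
    return 0.5 * (tr - d + _mp_logdet(Q, mp) - _mp_logdet(P, mp))


def _mp_cmi(S4, a, b, c, mp):
    return 0.5 * (
        _mp_logdet(_mp_sub(S4, a + c, mp), mp)
        + _mp_logdet(_mp_sub(S4, b + c, mp), mp)
        - _mp_logdet(_mp_sub(S4, c, mp), mp)
        - _mp_logdet(_mp_sub(S4, a + b + c, mp), mp)
    )


def _mp_mi(S4, a, b, mp):
    return 0.5 * (
        _mp_logdet(_mp_sub(S4, a, mp), mp)
        + _mp_logdet(_mp_sub(S4, b, mp), mp)
        - _mp_logdet(_mp_sub(S4, a + b, mp), mp)
    )


def _mp_report(params: BLRMParams, tau: float, dps: int) -> IrrevReport:
    import mpmath

    if tau <= 0:
        raise ContractError("tau must be > 0")
    with mpmath.workdps(dps):
        mp = mpmath.mp
        S4 = _mp_sigma4(params, tau, mpmath)
        Ssw = _mp_sub(S4, list(SWAP), mpmath)
        phi_xy = _mp_kl(S4, Ssw, mpmath)
        marg = _mp_sub(S4, [0, 2], mpmath)
        marg_sw = _mp_sub(S4, [2, 0], mpmath)
        phi_x = _mp_kl(marg, marg_sw, mpmath)
        bte = _mp_cmi(S4, [0], [3], [2], mpmath)
        fte = _mp_cmi(S4, [1], [2], [0], mpmath)
        i1 = _mp_mi(S4, [0], [1], mpmath)
        i2 = _mp_mi(S4, [3], [0, 1], mpmath)
        i_lag = _mp_mi(S4, [0], [3], mpmath)
        redundancy = 0.5 * mpmath.log(
            mpmath.e ** (2 * (i1 + i2))
            / (mpmath.e ** (2 * i1) + mpmath.e ** (2 * i2) - 1)
        )
        causal = i_lag - redundancy
        return IrrevReport(
            tau=tau,
            phi_xy=float(phi_xy),
            phi_x=float(phi_x),
            phi_cond=float(phi_xy - phi_x),
            bte=float(bte),
            fte=float(fte),
            causal_influence=float(causal),
            redundancy=float(redundancy),
        )


def suggested_dps(params: BLRMParams, tau: float, margin: int = 40) -> int:
    """Decimal digits needed to resolve the measures at lag *tau*.

    The measures decay like the square of the slowest-mode correlation
    e^{-tau * min(1/trel, beta)}; the returned precision resolves that
    magnitude against O(1) cancellation with *margin* digits to spare.
    """
    exponent = 2.0 * tau * min(1.0 / params.trel, params.beta)
    return int(np.ceil(exponent / np.log(10.0))) + margin


def irreversibility_ratio(
    params: BLRMParams, tau: float, dps: int = 60
) -> float:
    """phi_xy / bte evaluated in arbitrary precision (safe at extreme tau)."""
    import mpmath

    dps = max(dps, suggested_dps(params, tau))
    with mpmath.workdps(dps):
        S4 = _mp_sigma4(params, tau, mpmath)
        Ssw = _mp_sub(S4, list(SWAP), mpmath)
        phi_xy = _mp_kl(S4, Ssw, mpmath)
        bte = _mp_cmi(S4, [0], [3], [2], mpmath)
        return float(phi_xy / bte)
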