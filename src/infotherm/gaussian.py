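"""Zero-mean multivariate-Gaussian information kernel.

Every information measure in this package — KL divergence between forward
and time-swapped transition laws, mutual information, conditional mutual
information — reduces for Gaussian ensembles to combinations of
log-determinants of covariance blocks.  This module provides those
primitives with explicit numerical contracts:

* log-determinants always go through a Cholesky factorization (stable up
  to condition numbers ~1e12), never through a raw determinant;
* matrices that fail Cholesky raise :class:`SingularCovarianceError`
  naming the offending input; an optional *explicit* jitter may be passed
  by the caller, nothing is regularized silently;
* tiny negative results from floating-point cancellation (> -1e-10) are
  clipped to zero and logged; larger negatives raise, since they indicate
  invalid inputs rather than round-off.

All quantities are in nats (natural logarithm throughout).
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .errors import ContractError, SingularCovarianceError

logger = logging.getLogger(__name__)

#: relative tolerance for the symmetry check on covariance inputs
SYMMETRY_RTOL = 1e-10
#: negative results larger (in magnitude) than this raise instead of clipping
NEGATIVE_CLIP = 1e-10

Blocks = Sequence[int]


def validate_cov(cov: np.ndarray, name: str = "cov") -> np.ndarray:
    """Check that *cov* is a square symmetric real matrix; return it symmetrized.

    Symmetry is required to within ``SYMMETRY_RTOL`` relative to the largest
    entry.  Positive definiteness is *not* checked here; it is enforced where
    a factorization is actually needed.
    """
    arr = np.asarray(cov, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ContractError(f"{name} must be a square matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ContractError(f"{name} contains non-finite entries")
    scale = np.abs(arr).max() or 1.0
    asym = np.abs(arr - arr.T).max()
    if asym > SYMMETRY_RTOL * scale:
        raise ContractError(
            f"{name} is not symmetric: max asymmetry {asym:.3e} exceeds "
            f"{SYMMETRY_RTOL:.1e} relative tolerance"
        )
    return 0.5 * (arr + arr.T)


def chol_lower(cov: np.ndarray, name: str = "cov", jitter: float = 0.0) -> np.ndarray:
    """Lower-triangular Cholesky factor, or raise naming the matrix.

    ``jitter`` (default 0, never applied silently) is added to the diagonal
    to handle near-degenerate inputs such as the noiseless-response limit.
    """
    mat = cov if jitter == 0.0 else cov + jitter * np.eye(cov.shape[0])
    if jitter:
        logger.info("explicit jitter %.3e applied to %s", jitter, name)
    try:
        return cholesky(mat, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise SingularCovarianceError(
            f"{name} is not positive definite (Cholesky failed: {exc})"
        ) from exc
    except Exception as exc:
        raise SingularCovarianceError(
            f"{name} is not positive definite (Cholesky failed: {exc})"
        ) from exc


def logdet(cov: np.ndarray, name: str = "cov", jitter: float = 0.0) -> float:
    """log det of a positive-definite matrix via its Cholesky factor."""
    L = chol_lower(validate_cov(cov, name), name, jitter)
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def _clip_nonneg(value: float, what: str) -> float:
    """Clip tiny negative cancellation noise to 0; raise on real negatives."""
    if value < 0.0:
        if value >= -NEGATIVE_CLIP:
            logger.debug("clipped %s = %.3e to 0 (cancellation noise)", what, value)
            return 0.0
        raise ContractError(
            f"{what} evaluated to {value:.6e} < -{NEGATIVE_CLIP:.0e}; "
            "inputs are inconsistent (not round-off)"
        )
    return value


def gaussian_kl(p_cov: np.ndarray, q_cov: np.ndarray, jitter: float = 0.0) -> float:
    """KL divergence D(N(0, p_cov) || N(0, q_cov)) in nats.

    Returns ``0.5 * [trace(q_cov^-1 p_cov) - dim + ln det q_cov - ln det p_cov]``.
    Both matrices must be strictly positive definite and of equal dimension.
    """
    P = validate_cov(p_cov, "p_cov")
    Q = validate_cov(q_cov, "q_cov")
    if P.shape != Q.shape:
        raise ContractError(f"dimension mismatch: p_cov {P.shape} vs q_cov {Q.shape}")
    d = P.shape[0]
    Lp = chol_lower(P, "p_cov", jitter)
    Lq = chol_lower(Q, "q_cov", jitter)
    # trace(Q^-1 P) = || Lq^-1 Lp ||_F^2
    A = solve_triangular(Lq, Lp, lower=True)
    trace_term = float(np.sum(A * A))
    ld_q = 2.0 * float(np.sum(np.log(np.diag(Lq))))
    ld_p = 2.0 * float(np.sum(np.log(np.diag(Lp))))
    return _clip_nonneg(0.5 * (trace_term - d + ld_q - ld_p), "gaussian_kl")


def _check_blocks(dim: int, *blocks: Blocks) -> list[list[int]]:
    out = []
    seen: set[int] = set()
    for blk in blocks:
        idx = list(blk)
        if any((not 0 <= i < dim) for i in idx):
            raise ContractError(f"block index out of range for dim {dim}: {idx}")
        if seen.intersection(idx):
            raise ContractError(f"blocks overlap: {sorted(seen.intersection(idx))}")
        seen.update(idx)
        out.append(idx)
    return out


def _sub(cov: np.ndarray, idx: list[int]) -> np.ndarray:
    return cov[np.ix_(idx, idx)]


def gaussian_mi(joint_cov: np.ndarray, block_a: Blocks, block_b: Blocks) -> float:
    """Mutual information I(a; b) in nats for a zero-mean Gaussian.

    ``0.5 * [ln det Sigma_a + ln det Sigma_b - ln det Sigma_ab] >= 0``.
    Blocks must be disjoint index sets into *joint_cov*.
    """
    S = validate_cov(joint_cov, "joint_cov")
    a, b = _check_blocks(S.shape[0], block_a, block_b)
    if not a or not b:
        raise ContractError("blocks must be non-empty")
    val = 0.5 * (
        logdet(_sub(S, a), "Sigma_a")
        + logdet(_sub(S, b), "Sigma_b")
        - logdet(_sub(S, a + b), "Sigma_ab")
    )
    return _clip_nonneg(val, "gaussian_mi")


def gaussian_cmi(
    joint_cov: np.ndarray, block_a: Blocks, block_b: Blocks, block_c: Blocks
) -> float:
    """Conditional mutual information I(a; b | c) in nats for a zero-mean Gaussian.

    ``0.5 * [ln det Sigma_ac + ln det Sigma_bc - ln det Sigma_c - ln det Sigma_abc]``.
    An empty conditioning block falls back to :func:`gaussian_mi`.
    """
    S = validate_cov(joint_cov, "joint_cov")
    a, b, c = _check_blocks(S.shape[0], block_a, block_b, block_c)
    if not a or not b:
        raise ContractError("blocks a and b must be non-empty")
    if not c:
        return gaussian_mi(S, a, b)
    val = 0.5 * (
        logdet(_sub(S, a + c), "Sigma_ac")
        + logdet(_sub(S, b + c), "Sigma_bc")
        - logdet(_sub(S, c), "Sigma_c")
        - logdet(_sub(S, a + b + c), "Sigma_abc")
    )
    return _clip_nonneg(val, "gaussian_cmi")


def gaussian_logpdf(cov: np.ndarray, samples: np.ndarray, name: str = "cov") -> np.ndarray:
    """Log-density of zero-mean N(0, cov) at each row of *samples* (n, d)."""
    S = validate_cov(cov, name)
    Z = np.atleast_2d(np.asarray(samples, dtype=float))
    d = S.shape[0]
    if Z.shape[1] != d:
        raise ContractError(f"samples have {Z.shape[1]} columns, expected {d}")
    L = chol_lower(S, name)
    W = solve_triangular(L, Z.T, lower=True)
    ld = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (np.sum(W * W, axis=0) + d * np.log(2.0 * np.pi) + ld)
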