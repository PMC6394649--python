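"""Small linear-algebra helpers shared by the FOCE engine and the bias correction.

The whitening (COV^{-1/2}) used to build CWRES and the colouring (COV^{+1/2})
used to back-transform a CWRES bias into a prediction bias must be inverses of
one another, so both are derived from the same factorisation of the conditional
covariance.
"""

from __future__ import annotations

import numpy as np

#: relative diagonal jitter added when a conditional covariance is near-singular
JITTER_REL = 1e-10
#: eigenvalue ratio below which a matrix is considered near-singular
SINGULAR_RATIO = 1e-12


class FactorizationError(np.linalg.LinAlgError):
    """Conditional covariance could not be factorised even after jitter."""


def ensure_psd(mat: np.ndarray, name: str = "matrix", tol: float = 1e-8) -> np.ndarray:
    """Validate that ``mat`` is symmetric positive semi-definite.

    Returns the symmetrised matrix; raises ``ValueError`` with the offending
    eigenvalue otherwise.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10, rtol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    sym = 0.5 * (mat + mat.T)
    if sym.size:
        evals = np.linalg.eigvalsh(sym)
        scale = max(abs(evals[-1]), 1.0)
        if evals[0] < -tol * scale:
            raise ValueError(
                f"{name} is not positive semi-definite (min eigenvalue {evals[0]:.3g})"
            )
    return sym


def apply_jitter(cov: np.ndarray) -> np.ndarray:
    """Add ``1e-10 * mean(diag)`` to the diagonal if the matrix is near-singular."""
    evals = np.linalg.eigvalsh(cov)
    if evals[0] < SINGULAR_RATIO * max(evals[-1], 0.0):
        cov = cov + JITTER_REL * np.mean(np.diag(cov)) * np.eye(cov.shape[0])
    return cov


def sym_sqrt_pair(cov: np.ndarray, method: str = "sym"):
    """Return ``(C_half, C_neg_half)`` for a positive-definite covariance.

    method="sym" uses the symmetric (eigendecomposition) square root;
    method="chol" uses the lower Cholesky factor and its inverse.  The pair is
    always mutually inverse: ``C_neg_half @ C_half = I``.
    """
    cov = apply_jitter(0.5 * (cov + cov.T))
    if method == "sym":
        evals, vecs = np.linalg.eigh(cov)
        if evals[0] <= 0:
            raise FactorizationError(
                f"covariance not positive definite (min eigenvalue {evals[0]:.3g})"
            )
        root = np.sqrt(evals)
        half = (vecs * root) @ vecs.T
        neg_half = (vecs / root) @ vecs.T
        return half, neg_half
    if method == "chol":
        try:
            lower = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise FactorizationError(str(exc)) from exc
        inv_lower = np.linalg.inv(lower)
        return lower, inv_lower
    raise ValueError(f"unknown square-root method {method!r}")


def sym_sqrt_psd(mat: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix (eigenvalues clipped at zero)."""
    mat = 0.5 * (mat + np.asarray(mat).T)
    evals, vecs = np.linalg.eigh(mat)
    evals = np.clip(evals, 0.0, None)
    return (vecs * np.sqrt(evals)) @ vecs.T
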