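"""Phase-coupling optimization (PCO).

Supervised spatial filtering: find real-valued filters ``w`` whose
projection of the analytic (complex) signal is maximally phase-coupled to
a target trace ``z`` (the produced audio here).  The objective is the mean
vector length

    MVL(w) = | (1/Ns) * sum_t  z_t * (w^T y_t) / |w^T y_t| |,

the magnitude of the time-average of target-weighted unit phasors.  MVL is
differentiable but not concave in ``w``, so each component is the best of
several seeded random-restart quasi-Newton ascents; components are
extracted sequentially, each restricted to the orthogonal complement of
the previous filters in the whitened space.

Antiphase solutions (``w`` and ``-w``) have identical MVL; filters are not
sign-normalized, and downstream metrics treat phase 0 and pi as
equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, signal

__all__ = [
    "PCOModel",
    "ArtifactSelection",
    "analytic_signal",
    "mvl",
    "fit_pco",
    "select_artifact_components",
    "whitening_matrix",
]

#: guard added to |w^T y_t| against division by zero
EPS = 1e-12
#: eigenvalue-whitening rank truncation at this condition number
WHITEN_COND = 1e8
#: optimizer stopping tolerance on the MVL change
GTOL = 1e-8
MAXITER = 500


@dataclass
class PCOModel:
    """Fitted PCO: filters in whitened SSD space, sorted by decreasing MVL."""

    W: np.ndarray  # k x k, columns are filters in the whitened space
    mvls: np.ndarray
    M_white: np.ndarray  # k x k whitening applied before optimization
    n_restarts: int
    seed: int

    @property
    def k(self) -> int:
        return self.W.shape[0]


@dataclass(frozen=True)
class ArtifactSelection:
    """How many of the top-MVL components are deemed artifactual."""

    m: int
    method: str = "elbow"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("at least one artifact component must be selected")
        if self.method not in ("elbow", "fixed"):
            raise ValueError(f"unknown selection method {self.method!r}")


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Rowwise analytic signal ``x + i*Hilbert(x)``."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    if x.shape[-1] < 8:
        raise ValueError("signal too short for an analytic representation")
    return signal.hilbert(x, axis=-1)


def mvl(w: np.ndarray, Y: np.ndarray, z: np.ndarray) -> float:
    """Mean vector length of the projection ``w^T Y`` against target ``z``."""
    c = np.asarray(w, dtype=float) @ Y
    mag = np.abs(c)
    if np.all(mag < EPS):
        raise ValueError("all-zero projection")
    u = c / (mag + EPS)
    return float(np.abs(np.mean(z * u)))


def _mvl_and_grad(w: np.ndarray, Y: np.ndarray, z: np.ndarray) -> tuple[float, np.ndarray]:
    """MVL and its analytic gradient with respect to a real filter ``w``.

    With c_t = w^T y_t, u_t = c_t/|c_t| and g = mean(z_t u_t):
        d g / d w  = mean_t z_t (y_t/|c_t| - c_t Re(conj(c_t) y_t)/|c_t|^3)
        d|g|/ d w  = Re(conj(g) dg/dw) / |g|
    """
    c = w @ Y  # (Ns,) complex
    mag = np.abs(c) + EPS
    u = c / mag
    zu = z * u
    g = np.mean(zu)
    val = np.abs(g)
    # dg/dw, complex (k,)
    inv = z / mag
    term1 = Y @ inv / Y.shape[1]
    re_cy = np.real(np.conj(c)[None, :] * Y)  # (k, Ns)
    term2 = re_cy @ (z * c / mag**3) / Y.shape[1]
    dg = term1 - term2
    if val < 1e-300:
        return val, np.zeros_like(w)
    grad = np.real(np.conj(g) * dg) / val
    return val, grad


def _neg_mvl_unit(v: np.ndarray, Y: np.ndarray, z: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative MVL evaluated at ``v/||v||`` with the chain-rule gradient."""
    nrm = np.linalg.norm(v)
    if nrm == 0:
        return 0.0, np.zeros_like(v)
    w = v / nrm
    val, grad = _mvl_and_grad(w, Y, z)
    # project out the radial direction (objective is scale invariant)
    grad_v = (grad - np.dot(grad, w) * w) / nrm
    return -val, -grad_v


def whitening_matrix(X_real: np.ndarray, cond: float = WHITEN_COND) -> np.ndarray:
    """Eigenvalue (PCA) whitening matrix of ``channels x samples`` data.

    Square ``k x k``; eigendirections whose variance falls below
    ``max_eig / cond`` are zeroed rather than amplified.
    """
    X_real = np.atleast_2d(np.asarray(X_real, dtype=float))
    cov = X_real @ X_real.T / X_real.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    good = evals > evals.max() / cond
    inv_sqrt = np.where(good, 1.0 / np.sqrt(np.where(good, evals, 1.0)), 0.0)
    return (evecs * inv_sqrt[None, :]) @ evecs.T


def fit_pco(
    Y_ssd: np.ndarray,
    z: np.ndarray,
    n_restarts: int = 10,
    seed: int = 0,
) -> PCOModel:
    """Extract all ``k`` phase-coupled components from SSD-space data.

    ``Y_ssd`` is the complex analytic signal in SSD space (``k x samples``);
    it is whitened internally from the covariance of its real part.  ``z``
    must be the z-scored target trace of the same length.  Components are
    extracted by deflation; each is the best of ``n_restarts`` seeded
    quasi-Newton ascents of the MVL from random unit starts.  Filters are
    returned sorted by achieved MVL, descending.
    """
    Y_ssd = np.atleast_2d(np.asarray(Y_ssd, dtype=complex))
    z = np.asarray(z, dtype=float).ravel()
    k, ns = Y_ssd.shape
    if k == 0:
        raise ValueError("no SSD components to optimize over")
    if z.size != ns:
        raise ValueError("target and data lengths differ")

    M = whitening_matrix(np.real(Y_ssd))
    Yw = M @ Y_ssd
    rng = np.random.default_rng(seed)

    filters = np.zeros((k, k))
    mvls = np.zeros(k)
    basis = np.eye(k)  # orthonormal basis of the remaining search space
    for comp in range(k):
        dim = basis.shape[1]
        Yp = basis.T @ Yw  # data in the deflated subspace
        if dim == 1:
            v_best = np.ones(1)
            best = mvl(v_best, Yp, z)
        else:
            best, v_best = -np.inf, None
            for _ in range(n_restarts):
                v0 = rng.standard_normal(dim)
                v0 /= np.linalg.norm(v0)
                res = optimize.minimize(
                    _neg_mvl_unit,
                    v0,
                    args=(Yp, z),
                    jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": MAXITER, "gtol": GTOL, "ftol": 1e-12},
                )
                if not np.isfinite(res.fun):
                    raise RuntimeError("non-finite PCO objective")
                val = -res.fun
                if val > best:
                    best, v_best = val, res.x / np.linalg.norm(res.x)
        w = basis @ v_best
        filters[:, comp] = w
        mvls[comp] = best
        if dim > 1:
            # restrict subsequent searches to the orthogonal complement
            comp_basis = linalg.null_space(v_best[None, :])
            basis = basis @ comp_basis
        else:
            basis = np.zeros((k, 0))
    order = np.argsort(mvls)[::-1]
    return PCOModel(
        W=filters[:, order],
        mvls=mvls[order],
        M_white=M,
        n_restarts=n_restarts,
        seed=seed,
    )


def select_artifact_components(
    mvls: np.ndarray, method: str = "elbow", fixed_m: int | None = None
) -> ArtifactSelection:
    """Pick the number ``m`` of artifactual components from the MVL trace.

    The elbow rule takes the point of maximum discrete curvature (largest
    second difference) of the descending MVL trace, clamped to
    ``[1, k-1]``; with ``k <= 2`` components, ``m = 1``.
    """
    mvls = np.asarray(mvls, dtype=float)
    k = mvls.size
    if k < 1:
        raise ValueError("empty MVL trace")
    if method == "fixed":
        if fixed_m is None:
            raise ValueError("fixed selection requires fixed_m")
        return ArtifactSelection(int(np.clip(fixed_m, 1, max(k - 1, 1))), "fixed")
    if k <= 2:
        return ArtifactSelection(1, "elbow")
    d2 = mvls[:-2] - 2 * mvls[1:-1] + mvls[2:]  # curvature at indices 1..k-2
    m = int(np.argmax(d2)) + 1
    return ArtifactSelection(int(np.clip(m, 1, k - 1)), "elbow")
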