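"""Sector detection: PCA, ICOD, SCA, ICA and the Recovery statistic.

Selection on an additive trait confines highly weighted sequences near a
plane perpendicular to the mutational-effect vector, so the vector shows
up as a *small-variance* mode of the covariance matrix C.  PCA can read
it from the last principal component, but strong conservation disrupts
that.  The ICOD transform is robust: invert C, zero the diagonal of
C^-1 (which is dominated by conservation), and read the sector from the
*first* eigenvector of the result — in the small-coupling regime the
off-diagonal of C^-1 is proportional to kappa * Delta_l Delta_l', an
outer product whose top eigenvector is Delta itself.

Recovery = sum_l |nu_l Delta_l| / (||nu|| ||Delta||) scores how well an
inferred mode nu matches Delta; it is 1 for nu parallel to Delta (up to
per-site signs) and has random expectation sqrt(2/(pi L)) sum|Delta| /
||Delta|| for unit vectors uniform on the sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ensembles import CovarianceResult, WeightedEnsemble, covariance
from .trait_models import MutationalEffectVector

__all__ = [
    "SpectralResult",
    "RecoveryReport",
    "pca",
    "icod",
    "recovery",
    "recovery_random_expectation",
    "sca_matrix",
    "ica_disentangle",
    "count_outliers",
    "recovery_report",
]


@dataclass
class SpectralResult:
    """Eigendecomposition of a symmetric site matrix, eigenvalues descending."""

    eigenvalues: np.ndarray       # (K,) descending
    eigenvectors: np.ndarray      # (L, K), column j pairs with eigenvalues[j]
    matrix_kind: str              # "covariance" | "icod" | "sca"
    matrix: np.ndarray | None = None
    source: dict = field(default_factory=dict)

    @property
    def first(self) -> np.ndarray:
        """Eigenvector of the largest eigenvalue."""
        return self.eigenvectors[:, 0]

    @property
    def last(self) -> np.ndarray:
        """Eigenvector of the smallest eigenvalue."""
        return self.eigenvectors[:, -1]


@dataclass
class RecoveryReport:
    recovery_per_mode: np.ndarray
    random_expectation: float
    best_mode_index: int


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|component| entry positive."""
    out = vecs.copy()
    for j in range(out.shape[1]):
        k = int(np.argmax(np.abs(out[:, j])))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _eigh_descending(A: np.ndarray, matrix_kind: str, source: dict | None = None) -> SpectralResult:
    if not np.allclose(A, A.T, atol=1e-8 * max(1.0, float(np.abs(A).max()))):
        raise ValueError("matrix is not symmetric within tolerance")
    A = 0.5 * (A + A.T)
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1]
    return SpectralResult(
        eigenvalues=vals[order],
        eigenvectors=_fix_signs(vecs[:, order]),
        matrix_kind=matrix_kind,
        matrix=A,
        source=source or {},
    )


def pca(cov: CovarianceResult) -> SpectralResult:
    """Principal component analysis: diagonalize the covariance matrix."""
    return _eigh_descending(cov.C, "covariance")


def icod(cov: CovarianceResult, regularization: float | None = None) -> SpectralResult:
    """Inverse Covariance Off-Diagonal transform.

    Inverts C, zeroes the diagonal of C^-1 and eigendecomposes; the FIRST
    eigenvector (largest eigenvalue) is the sector estimate.  Singular
    covariance matrices need a pseudocount at the covariance step (or a
    ridge ``regularization`` added to the diagonal here).
    """
    C = cov.C
    if regularization:
        C = C + regularization * np.eye(C.shape[0])
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "covariance matrix is singular; recompute it with a pseudocount "
            "(e.g. covariance(ensemble, pseudocount=0.01)) or pass a ridge "
            "regularization"
        ) from err
    cond = np.linalg.cond(C)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"covariance matrix is ill-conditioned (cond={cond:.2e}); recompute "
            "with a pseudocount, e.g. covariance(ensemble, pseudocount=0.01)"
        )
    tilde = Cinv.copy()
    np.fill_diagonal(tilde, 0.0)
    return _eigh_descending(tilde, "icod", {"regularization": regularization})


def recovery(nu: np.ndarray, delta: MutationalEffectVector | np.ndarray) -> float:
    """Recovery = sum_l |nu_l Delta_l| / (||nu|| ||Delta||), in [0, 1].

    Blind to per-site sign flips and to overall rescaling of either vector.
    """
    d = delta.effects if isinstance(delta, MutationalEffectVector) else np.asarray(delta, float)
    if d.ndim > 1:
        d = d.ravel()
    nu = np.asarray(nu, dtype=float).ravel()
    if nu.shape != d.shape:
        raise ValueError(f"length mismatch: mode {nu.shape} vs effects {d.shape}")
    nn, nd = np.linalg.norm(nu), np.linalg.norm(d)
    if nn == 0 or nd == 0:
        raise ValueError("Recovery is undefined for a zero vector")
    return float(np.sum(np.abs(nu * d)) / (nn * nd))


def recovery_random_expectation(
    delta: MutationalEffectVector | np.ndarray,
    n_draws: int = 10000,
    seed: int = 0,
) -> float:
    """Monte-Carlo expectation of Recovery for nu uniform on the unit sphere.

    The large-L closed form sqrt(2/(pi L)) * sum|Delta| / ||Delta|| is
    available from :func:`recovery_random_closed_form`.
    """
    d = delta.effects if isinstance(delta, MutationalEffectVector) else np.asarray(delta, float)
    d = d.ravel()
    L = d.size
    if L < 2:
        raise ValueError("need L >= 2")
    rng = np.random.default_rng(seed)
    nu = rng.standard_normal((n_draws, L))
    nu /= np.linalg.norm(nu, axis=1, keepdims=True)
    vals = np.abs(nu * d).sum(axis=1) / np.linalg.norm(d)
    return float(vals.mean())


def recovery_random_closed_form(delta: MutationalEffectVector | np.ndarray) -> float:
    """Large-L approximation sqrt(2/(pi L)) * sum_l |Delta_l| / ||Delta||."""
    d = delta.effects if isinstance(delta, MutationalEffectVector) else np.asarray(delta, float)
    d = d.ravel()
    return float(math.sqrt(2.0 / (math.pi * d.size)) * np.abs(d).sum() / np.linalg.norm(d))


def conservation_factor(p: np.ndarray, background: float = 0.5) -> np.ndarray:
    """Binary SCA positional weight phi_l = |ln[P_l(1-qbar) / ((1-P_l) qbar)]|."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError(
            "site frequencies at 0 or 1 make the conservation factor diverge; "
            "apply a pseudocount first"
        )
    return np.abs(np.log(p * (1 - background) / ((1 - p) * background)))


def sca_matrix(
    ensemble: WeightedEnsemble,
    background_freq: float = 0.5,
    pseudocount: float = 0.01,
) -> SpectralResult:
    """Statistical Coupling Analysis matrix C~_ll' = |phi_l C_ll' phi_l'|.

    The sector estimate lives in the FIRST eigenvector; for Recovery
    comparisons against a mutational-effect vector take the square root of
    its components (see :func:`sca_first_mode`).
    """
    cov = covariance(ensemble, pseudocount=pseudocount)
    phi = conservation_factor(cov.mutant_fractions, background=background_freq)
    tilde = np.abs(phi[:, None] * cov.C * phi[None, :])
    return _eigh_descending(tilde, "sca", {"background_freq": background_freq,
                                           "pseudocount": pseudocount})


def sca_first_mode(spectral: SpectralResult) -> np.ndarray:
    """Square root of |first SCA eigenvector| components, for Recovery use."""
    return np.sqrt(np.abs(spectral.first))


def count_outliers(eigenvalues: np.ndarray, n_mads: float = 6.0) -> int:
    """Number of eigenvalues above median + n_mads * MAD (outlier rule)."""
    vals = np.asarray(eigenvalues, dtype=float)
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    if mad == 0:
        mad = np.finfo(float).eps
    return int(np.sum(vals > med + n_mads * mad))


def _kurtosis(y: np.ndarray) -> np.ndarray:
    """Excess kurtosis of each column of a centered, unit-variance array."""
    return np.mean(y**4, axis=0) - 3.0


def _best_pair_angle(y: np.ndarray, n_grid: int = 180) -> float:
    """Rotation angle in [0, pi/2) maximizing the summed squared kurtosis
    of a whitened column pair (the contrast is pi/2-periodic)."""
    thetas = np.linspace(0.0, np.pi / 2, n_grid, endpoint=False)
    best_theta, best_val = 0.0, -np.inf
    for theta in thetas:
        c, s = np.cos(theta), np.sin(theta)
        rot = y @ np.array([[c, -s], [s, c]])
        val = float(np.sum(_kurtosis(rot) ** 2))
        if val > best_val:
            best_val, best_theta = val, theta
    # local refinement around the grid optimum
    lo, hi = best_theta - np.pi / (2 * n_grid), best_theta + np.pi / (2 * n_grid)
    for theta in np.linspace(lo, hi, 50):
        c, s = np.cos(theta), np.sin(theta)
        rot = y @ np.array([[c, -s], [s, c]])
        val = float(np.sum(_kurtosis(rot) ** 2))
        if val > best_val:
            best_val, best_theta = val, theta
    return best_theta % (np.pi / 2)


def ica_disentangle(
    spectral: SpectralResult,
    n_components: int | None = None,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> list[np.ndarray]:
    """Rotate the top eigenvectors by ICA to separate selected traits.

    When several traits are under selection at once each trait's effect
    vector is mixed across the outlier eigenvectors (their eigenvalues
    are near-degenerate because every trait is selected at comparable
    strength).  The site-indexed components of those eigenvectors are
    whitened and then rotated by Jacobi sweeps over column pairs, each
    sweep maximizing the summed squared excess kurtosis — the rotation
    that makes components maximally non-Gaussian, i.e. sector-localized.
    Deterministic: the contrast is optimized by exhaustive angle search,
    so the ``seed`` only matters for tie-breaking randomness (none in
    practice).  Raises if Jacobi sweeps do not converge.
    """
    K = spectral.eigenvectors.shape[1]
    if n_components is None:
        n_components = max(1, count_outliers(spectral.eigenvalues))
    if n_components > K:
        raise ValueError(f"n_components={n_components} exceeds available modes {K}")
    if n_components == 1:
        return [spectral.first]

    X0 = spectral.eigenvectors[:, :n_components]        # (L, n) site signals
    Xc = X0 - X0.mean(axis=0)
    # PCA whitening of the centered component columns
    cov = Xc.T @ Xc / Xc.shape[0]
    w, V = np.linalg.eigh(cov)
    w = np.maximum(w, 1e-15)
    transform = V @ np.diag(1.0 / np.sqrt(w))           # accumulates rotations
    Z = Xc @ transform

    converged = False
    for _sweep in range(max_iter):
        max_angle = 0.0
        for i in range(n_components - 1):
            for j in range(i + 1, n_components):
                theta = _best_pair_angle(Z[:, [i, j]])
                # fold to the smallest equivalent rotation
                angle = min(theta, np.pi / 2 - theta)
                max_angle = max(max_angle, angle)
                c, s = np.cos(theta), np.sin(theta)
                rot = np.array([[c, -s], [s, c]])
                Z[:, [i, j]] = Z[:, [i, j]] @ rot
                transform[:, [i, j]] = transform[:, [i, j]] @ rot
        if max_angle < max(tol, 1e-3):
            converged = True
            break
    if not converged:
        raise RuntimeError(f"ICA Jacobi rotations did not converge within {max_iter} sweeps")

    # Applying the full transform to the UNCENTERED eigenvectors restores
    # each separated source's mean offset (the centering shift cancels
    # exactly when the mixture lies in the eigenvector span).
    S = X0 @ transform
    comps = []
    for j in range(n_components):
        v = S[:, j]
        v = v / np.linalg.norm(v)
        k = int(np.argmax(np.abs(v)))
        if v[k] < 0:
            v = -v
        comps.append(v)
    # order components by decreasing peak magnitude for determinism
    comps.sort(key=lambda v: -float(np.max(np.abs(v))))
    return comps


def recovery_report(
    spectral: SpectralResult,
    delta: MutationalEffectVector,
    n_draws: int = 10000,
    seed: int = 0,
) -> RecoveryReport:
    """Recovery of every mode against Delta plus the random baseline."""
    vals = np.array([recovery(spectral.eigenvectors[:, j], delta)
                     for j in range(spectral.eigenvectors.shape[1])])
    rand = recovery_random_expectation(delta, n_draws=n_draws, seed=seed)
    return RecoveryReport(vals, rand, int(np.argmax(vals)))
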