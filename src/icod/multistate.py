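"""q-state extension of the covariance / ICOD pipeline (q = 21 for proteins).

Real alignments have 20 amino acids plus the gap.  Each site is one-hot
encoded over the q-1 states other than a per-site gauge (reference)
state, frequencies are regularized by a pseudocount toward the uniform
distribution, and the ICOD transform generalizes by zeroing the
(q-1)x(q-1) diagonal blocks of the inverse covariance and compressing
every off-diagonal block to its Frobenius norm.  The top eigenvector of
the compressed matrix scores sites by overall mutational effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensembles import WeightedEnsemble
from .spectral import SpectralResult, _eigh_descending, _fix_signs

__all__ = [
    "ALPHABET",
    "MultistateCovariance",
    "CompressedMatrix",
    "EncodedAlignment",
    "encode_alignment",
    "multistate_covariance",
    "icod_multistate",
    "conservation_score",
    "read_alignment_fasta",
]

#: gap first so that state 0 is the gap; amino acids alphabetical
ALPHABET = "-ACDEFGHIKLMNPQRSTVWY"
CHAR_TO_STATE = {c: i for i, c in enumerate(ALPHABET)}
CHAR_TO_STATE["."] = 0
CHAR_TO_STATE["X"] = 0  # unknown residue treated as gap
STATE_TO_CHAR = dict(enumerate(ALPHABET))


@dataclass
class EncodedAlignment:
    """Gap-filtered, state-indexed alignment ready for covariance."""

    states: np.ndarray          # (M, L') ints in [0, q)
    weights: np.ndarray         # (M,) normalized sequence weights
    q: int
    gauge_states: np.ndarray    # (L',) per-site reference state
    retained_sites: np.ndarray  # (L',) 0-based indices into the original columns
    fully_conserved: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class MultistateCovariance:
    """Covariance over the q-1 non-gauge states of each retained site."""

    C: np.ndarray               # (L'(q-1), L'(q-1)) symmetric
    frequencies: np.ndarray     # (L', q) row-stochastic (pseudocounted)
    pseudocount: float
    q: int
    gauge_states: np.ndarray
    retained_sites: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.frequencies.shape[0]

    def block(self, l: int, m: int) -> np.ndarray:
        s = self.q - 1
        return self.C[l * s : (l + 1) * s, m * s : (m + 1) * s]


@dataclass
class CompressedMatrix:
    """Site-level matrix of Frobenius norms of inverse-covariance blocks."""

    F: np.ndarray
    retained_sites: np.ndarray
    compression: str = "frobenius"


def read_alignment_fasta(path: str) -> list[str]:
    seqs, cur = [], None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith((";", "#")):
                continue
            if line.startswith(">"):
                cur = []
                seqs.append(cur)
            else:
                if cur is None:
                    raise ValueError("sequence data before first header")
                cur.append(line.upper())
    out = ["".join(s) for s in seqs]
    if not out:
        raise ValueError(f"no sequences in {path}")
    return out


def encode_alignment(
    msa: list[str] | np.ndarray,
    gauge: str = "consensus",
    gap_threshold: float = 0.15,
    reference: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    q: int = 21,
) -> EncodedAlignment:
    """Index states, drop gappy columns, and fix the per-site gauge.

    Columns whose gap frequency exceeds ``gap_threshold`` are removed.
    ``gauge='consensus'`` picks the most frequent state per site (ties
    broken by state order, i.e. alphabetical amino-acid order);
    ``gauge='given_reference'`` uses the supplied ``reference`` states.
    """
    if isinstance(msa, np.ndarray):
        states = np.asarray(msa, dtype=int)
    else:
        lengths = {len(s) for s in msa}
        if len(lengths) != 1:
            raise ValueError("alignment sequences must all have the same length")
        states = np.array([[CHAR_TO_STATE[c] for c in s] for s in msa], dtype=int)
    if states.size == 0:
        raise ValueError("empty alignment")
    M, L = states.shape
    if weights is None:
        weights = np.full(M, 1.0 / M)
    else:
        weights = np.asarray(weights, float)
        weights = weights / weights.sum()

    gap_freq = weights @ (states == 0)
    retained = np.flatnonzero(gap_freq <= gap_threshold)
    if retained.size == 0:
        raise ValueError("gap filtering removed every column")
    sub = states[:, retained]

    if gauge == "consensus":
        gauge_states = np.empty(retained.size, dtype=int)
        for j in range(retained.size):
            counts = np.bincount(sub[:, j], weights=weights, minlength=q)
            gauge_states[j] = int(np.argmax(counts))  # argmax ties -> lowest state
    elif gauge == "given_reference":
        if reference is None:
            raise ValueError("gauge='given_reference' requires reference states")
        reference = np.asarray(reference, dtype=int)
        gauge_states = reference[retained] if reference.size == L else reference
    else:
        raise ValueError(f"unknown gauge {gauge!r}")

    conserved = np.flatnonzero([(len(np.unique(sub[:, j])) == 1) for j in range(sub.shape[1])])
    return EncodedAlignment(sub, weights, q, gauge_states, retained, conserved)


def multistate_covariance(encoded: EncodedAlignment, pseudocount: float = 0.0) -> MultistateCovariance:
    """Pseudocounted q-state covariance on the non-gauge states.

    f1~_l(a) = (1-L)f_l(a) + L/q;  f2~_ll'(a,b) = (1-L)f_ll'(a,b) + L/q^2
    for l != l', with the same-site pair term tied to f1~; the covariance
    C = f2~ - f1~ f1~ is then restricted to the q-1 non-gauge states per
    site.
    """
    lam = pseudocount
    if not (0.0 <= lam < 1.0):
        raise ValueError("pseudocount must lie in [0, 1)")
    X = encoded.states
    w = encoded.weights
    M, L = X.shape
    q = encoded.q

    onehot = np.zeros((M, L, q))
    onehot[np.arange(M)[:, None], np.arange(L)[None, :], X] = 1.0

    f1 = np.einsum("m,mla->la", w, onehot)
    flat = onehot.reshape(M, L * q)
    f2 = (flat * w[:, None]).T @ flat  # (L*q, L*q)

    f1t = (1 - lam) * f1 + lam / q
    f2t = (1 - lam) * f2 + lam / q**2
    # same-site blocks: f_ll(a,b) = delta_ab f_l(a), pseudocounted toward L/q
    for l in range(L):
        blk = np.diag(f1t[l])
        f2t[l * q : (l + 1) * q, l * q : (l + 1) * q] = blk

    C_full = f2t - np.outer(f1t.ravel(), f1t.ravel())

    # restrict to non-gauge states
    keep = []
    for l in range(L):
        for a in range(q):
            if a != encoded.gauge_states[l]:
                keep.append(l * q + a)
    keep = np.array(keep)
    C = C_full[np.ix_(keep, keep)]
    C = 0.5 * (C + C.T)
    return MultistateCovariance(C, f1t, lam, q, encoded.gauge_states, encoded.retained_sites)


def icod_multistate(cov: MultistateCovariance) -> tuple[CompressedMatrix, SpectralResult]:
    """q-state ICOD: invert, zero diagonal blocks, Frobenius-compress, diagonalize.

    Returns the compressed site-level matrix F (diagonal zero) and its
    eigendecomposition; per-site sector scores are the absolute components
    of the first eigenvector.
    """
    s = cov.q - 1
    L = cov.n_sites
    try:
        Cinv = np.linalg.inv(cov.C)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "q-state covariance is singular; recompute with a pseudocount "
            "(e.g. multistate_covariance(encoded, pseudocount=0.02))"
        ) from err
    for l in range(L):
        Cinv[l * s : (l + 1) * s, l * s : (l + 1) * s] = 0.0
    F = np.zeros((L, L))
    for l in range(L):
        for m in range(l + 1, L):
            F[l, m] = F[m, l] = np.linalg.norm(Cinv[l * s : (l + 1) * s, m * s : (m + 1) * s])
    spec = _eigh_descending(F, "icod")
    return CompressedMatrix(F, cov.retained_sites), spec


def site_scores(spec: SpectralResult) -> np.ndarray:
    """Per-site sector score: |component| of the first eigenvector."""
    return np.abs(spec.first)


def ranked_sites(spec: SpectralResult, retained_sites: np.ndarray) -> list[tuple[int, float]]:
    """(1-based original site, score) sorted by descending score."""
    scores = site_scores(spec)
    order = np.argsort(scores)[::-1]
    return [(int(retained_sites[i]) + 1, float(scores[i])) for i in order]


def conservation_score(
    frequencies: np.ndarray,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Per-site Kullback-Leibler divergence from a background distribution.

    Default background is uniform over the q states; a fully conserved
    site then scores ln q.
    """
    f = np.asarray(frequencies, dtype=float)
    if f.ndim == 1:
        f = f[None, :]
    L, q = f.shape
    if background is None:
        background = np.full(q, 1.0 / q)
    background = np.asarray(background, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(f / background), 0.0)
    return terms.sum(axis=1)
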