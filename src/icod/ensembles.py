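"""Selected sequence ensembles and the site covariance matrix.

Selection weights sequences by the Boltzmann distribution
P(S) = exp(w(S)) / Z.  This module produces ensembles three ways —
exhaustive enumeration (exact, small L), importance sampling from the
uniform proposal with Boltzmann reweighting, and Metropolis MCMC — and
computes the weighted mutant fractions <S_l>* and covariance matrix
C_ll' = <(S_l - <S_l>*)(S_l' - <S_l'>*)>* that every detector downstream
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trait_models import (
    MultiTraitSelection,
    MutationalEffectVector,
    SelectionSpec,
    fitness_from_traits,
    multi_trait_fitness_from_sequences,
    trait_values,
)

__all__ = [
    "WeightedEnsemble",
    "CovarianceResult",
    "enumerate_ensemble",
    "sample_ensemble",
    "covariance",
    "write_fasta",
    "read_fasta",
]

ENUM_MAX_L = 20
BINARY_FASTA_MAP = {0: "A", 1: "M"}


@dataclass
class WeightedEnsemble:
    """Sequences with normalized statistical weights."""

    sequences: np.ndarray        # (M, L) int states
    weights: np.ndarray          # (M,) nonnegative, sums to 1
    alphabet: str = "binary"     # "binary" or "q21" etc.
    q: int = 2
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.int8)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.sequences.ndim != 2 or self.sequences.shape[0] < 1:
            raise ValueError("sequences must be a non-empty (M, L) array")
        if self.weights.shape != (self.sequences.shape[0],):
            raise ValueError("one weight per sequence required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        total = self.weights.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            if total <= 0:
                raise ValueError("all weights are zero; selection removed every sequence")
            self.weights = self.weights / total
        self.provenance.setdefault("ess", float(self.effective_sample_size))

    @property
    def M(self) -> int:
        return self.sequences.shape[0]

    @property
    def L(self) -> int:
        return self.sequences.shape[1]

    @property
    def effective_sample_size(self) -> float:
        return float(1.0 / np.sum(self.weights**2))


@dataclass
class CovarianceResult:
    """Weighted site covariance with its frequencies and pseudocount."""

    C: np.ndarray                # (L, L) symmetric
    mutant_fractions: np.ndarray  # (L,) weighted P(S_l = 1)
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if not np.allclose(self.C, self.C.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")


def _normalize(raw: np.ndarray) -> np.ndarray:
    total = raw.sum()
    if total <= 0:
        raise ValueError(
            "selection gave zero total weight; widen the window or move its center"
        )
    return raw / total


def enumerate_ensemble(
    delta: MutationalEffectVector,
    selection: SelectionSpec,
    L: int | None = None,
) -> WeightedEnsemble:
    """Exact Boltzmann ensemble over all 2^L binary sequences (L <= 20)."""
    if not delta.is_binary:
        raise ValueError("exhaustive enumeration supports the binary alphabet only")
    L = delta.L if L is None else L
    if L != delta.L:
        raise ValueError("L disagrees with the effect vector")
    if L > ENUM_MAX_L:
        raise ValueError(
            f"L={L} too large for enumeration (2^L sequences); use sample_ensemble"
        )
    selection = selection.resolve(delta)
    bits = ((np.arange(2**L)[:, None] >> np.arange(L)[None, :]) & 1).astype(np.int8)
    w = fitness_from_traits(trait_values(bits, delta), selection)
    finite = ~np.isneginf(w)
    raw = np.zeros(w.shape)
    if np.any(finite):
        raw[finite] = np.exp(w[finite] - w[finite].max())
    return WeightedEnsemble(
        bits,
        _normalize(raw),
        provenance={"sampler": "enumerate", "selection": selection.to_json()},
    )


def sample_ensemble(
    delta: MutationalEffectVector,
    selection: SelectionSpec,
    n_samples: int,
    seed: int,
    method: str = "importance",
    msel: MultiTraitSelection | None = None,
    burn_in_sweeps: int = 10,
    thin_flips: int | None = None,
) -> WeightedEnsemble:
    """Sample a selected ensemble of binary sequences.

    importance: uniform random sequences reweighted by exp(fitness) — the
    scheme of drawing unselected sequences and selectively weighting them.
    mcmc: Metropolis single-site flips targeting the Boltzmann
    distribution; uniform weights after burn-in (default 10*L sweeps) and
    thinning (default L flips between kept samples).

    ``msel`` switches to multi-trait selection; ``delta``/``selection``
    are then ignored for the fitness but delta still fixes L.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    L = delta.L if msel is None else msel.L
    q = 2 if delta.is_binary else delta.q
    rng = np.random.default_rng(seed)

    def _fitness(seqs: np.ndarray) -> np.ndarray:
        if msel is not None:
            return multi_trait_fitness_from_sequences(seqs, msel)
        return fitness_from_traits(trait_values(seqs, delta), resolved)

    resolved = selection.resolve(delta) if msel is None else None

    if method == "importance":
        seqs = rng.integers(0, q, size=(n_samples, L), dtype=np.int8)
        w = _fitness(seqs)
        finite = ~np.isneginf(w)
        raw = np.zeros(n_samples)
        if np.any(finite):
            raw[finite] = np.exp(w[finite] - w[finite].max())
        weights = _normalize(raw)
        prov = {
            "sampler": "importance",
            "seed": int(seed),
            "n_samples": int(n_samples),
            "acceptance_fraction": float(np.mean(finite)),
        }
        ens = WeightedEnsemble(
            seqs, weights,
            alphabet="binary" if q == 2 else f"q{q}",
            q=q,
            provenance=prov,
        )
        if ens.effective_sample_size < 50:
            ens.provenance["warning"] = (
                f"low effective sample size {ens.effective_sample_size:.1f} < 50"
            )
        return ens

    if method == "mcmc":
        if q != 2:
            raise ValueError("the MCMC sampler supports the binary alphabet only")
        thin = L if thin_flips is None else thin_flips
        # trait values update incrementally under single-site flips
        if msel is not None:
            deltas = np.stack([d.effects for d, _ in msel.traits])          # (N, L)
            specs = [spec.resolve(d) for d, spec in msel.traits]
        else:
            deltas = delta.effects[None, :]
            specs = [resolved]

        def logw(traits: np.ndarray) -> float:
            return float(sum(fitness_from_traits(t, s) for t, s in zip(traits, specs)))

        state = rng.integers(0, 2, size=L, dtype=np.int8)
        traits = deltas @ state
        for _ in range(1000):
            if np.isfinite(logw(traits)):
                break
            state = rng.integers(0, 2, size=L, dtype=np.int8)
            traits = deltas @ state
        else:
            raise ValueError("could not find a starting state with nonzero weight")
        current_w = logw(traits)
        burn_flips = burn_in_sweeps * L * L  # burn_in_sweeps*L sweeps of L flips
        total_flips = burn_flips + n_samples * thin
        out = np.empty((n_samples, L), dtype=np.int8)
        kept = n_accept = 0
        flip_sites = rng.integers(0, L, size=total_flips)
        unif = rng.random(total_flips)
        for t in range(total_flips):
            l = flip_sites[t]
            sign = 1.0 - 2.0 * state[l]            # +Delta if 0->1, -Delta if 1->0
            new_traits = traits + sign * deltas[:, l]
            w_new = logw(new_traits)
            if w_new >= current_w or unif[t] < np.exp(w_new - current_w):
                state[l] ^= 1
                traits = new_traits
                current_w = w_new
                n_accept += 1
            if t >= burn_flips and (t - burn_flips + 1) % thin == 0 and kept < n_samples:
                out[kept] = state
                kept += 1
        prov = {
            "sampler": "mcmc",
            "seed": int(seed),
            "n_samples": int(n_samples),
            "burn_in_sweeps": int(burn_in_sweeps * L),
            "thin_flips": int(thin),
            "acceptance_rate": float(n_accept / max(total_flips, 1)),
        }
        return WeightedEnsemble(out[:kept], np.full(kept, 1.0 / kept), provenance=prov)

    raise ValueError(f"unknown sampling method {method!r}")


def covariance(ensemble: WeightedEnsemble, pseudocount: float = 0.0) -> CovarianceResult:
    """Weighted site covariance C_ll' = <S_l S_l'>* - <S_l>*<S_l'>*.

    A pseudocount ``Lambda`` mixes the single and pair frequencies with
    the uniform distribution before the covariance is formed:
    f1 -> (1-Lambda) f1 + Lambda/2, off-diagonal f2 -> (1-Lambda) f2 +
    Lambda/4 (diagonal of f2 stays tied to f1).
    """
    if not (0.0 <= pseudocount < 1.0):
        raise ValueError("pseudocount must lie in [0, 1)")
    S = ensemble.sequences.astype(float)
    w = ensemble.weights
    f1 = w @ S
    f2 = (S * w[:, None]).T @ S
    np.fill_diagonal(f2, f1)  # S_l^2 = S_l for binary states
    lam = pseudocount
    f1t = (1 - lam) * f1 + lam / 2.0
    f2t = (1 - lam) * f2 + lam / 4.0
    np.fill_diagonal(f2t, f1t)
    C = f2t - np.outer(f1t, f1t)
    C = 0.5 * (C + C.T)
    return CovarianceResult(C, f1t, pseudocount=lam)


# ---------------------------------------------------------------------------
# FASTA interchange.  Binary sequences map 0 -> 'A', 1 -> 'M' (declared in a
# header comment); weights travel in a sidecar TSV written next to the FASTA.

def write_fasta(path: str, ensemble: WeightedEnsemble, weights_path: str | None = None) -> None:
    with open(path, "w") as fh:
        if ensemble.alphabet == "binary":
            fh.write("; binary alphabet: A=0 (reference), M=1 (mutant)\n")
        for i, seq in enumerate(ensemble.sequences):
            fh.write(f">seq{i}\n")
            if ensemble.alphabet == "binary":
                fh.write("".join(BINARY_FASTA_MAP[int(s)] for s in seq) + "\n")
            else:
                from .multistate import STATE_TO_CHAR

                fh.write("".join(STATE_TO_CHAR[int(s)] for s in seq) + "\n")
    if weights_path is not None:
        with open(weights_path, "w") as fh:
            fh.write("sequence\tweight\n")
            for i, w in enumerate(ensemble.weights):
                fh.write(f"seq{i}\t{float(w)!r}\n")


def read_fasta(path: str, weights_path: str | None = None) -> WeightedEnsemble:
    names, seqs = [], []
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(";") or line.startswith("#"):
                continue
            if line.startswith(">"):
                names.append(line[1:].split()[0])
                seqs.append([])
                current = seqs[-1]
            else:
                if current is None:
                    raise ValueError("sequence data before first FASTA header")
                current.append(line)
    strings = ["".join(parts) for parts in seqs]
    if not strings:
        raise ValueError(f"no sequences in {path}")
    letters = set("".join(strings))
    if letters <= {"A", "M", "0", "1"}:
        mapping = {"A": 0, "M": 1, "0": 0, "1": 1}
        arr = np.array([[mapping[c] for c in s] for s in strings], dtype=np.int8)
        alphabet, q = "binary", 2
    else:
        from .multistate import CHAR_TO_STATE

        arr = np.array([[CHAR_TO_STATE[c] for c in s] for s in strings], dtype=np.int8)
        alphabet, q = "q21", 21
    if weights_path is not None:
        wmap = {}
        with open(weights_path) as fh:
            next(fh)
            for line in fh:
                name, w = line.split("\t")
                wmap[name] = float(w)
        weights = np.array([wmap[n] for n in names])
    else:
        weights = np.full(len(strings), 1.0 / len(strings))
    return WeightedEnsemble(arr, weights, alphabet=alphabet, q=q)
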