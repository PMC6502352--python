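"""Additive traits and selection models.

A protein trait ``T`` is additive when it is a sum of independent per-site
mutational contributions,

    T(a) = sum_l Delta_l(a_l),

with the reference state at every site contributing exactly zero.  Natural
selection acting on a *nonlinear* function of such a trait (a Gaussian
window, a threshold, ...) induces correlations between sites — global
epistasis — even though the trait itself carries no pairwise terms.  This
module defines the mutational-effect vector, the selection functional
forms, and the map from a sequence to trait value, fitness and Boltzmann
weight.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence as SeqType

import numpy as np

__all__ = [
    "MutationalEffectVector",
    "SelectionSpec",
    "MultiTraitSelection",
    "trait_value",
    "fitness",
    "weight",
    "multi_trait_fitness",
    "read_delta_tsv",
    "write_delta_tsv",
]

NEG_INF = float("-inf")


@dataclass
class MutationalEffectVector:
    """Per-site (binary) or per-site-per-state (q-state) effects on a trait.

    For the binary model ``effects`` has shape (L,): ``effects[l]`` is the
    trait change of mutating site ``l`` away from the reference.  For the
    q-state model ``effects`` has shape (L, q) and ``effects[l, ref]`` is
    exactly 0 at the per-site reference state.
    """

    effects: np.ndarray
    trait_name: str = "trait"
    units: str = ""
    reference_states: np.ndarray | None = None  # (L,) ints, q-state only

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.ndim not in (1, 2):
            raise ValueError("effects must be a length-L vector or an L x q matrix")
        if self.effects.shape[0] < 1:
            raise ValueError("need at least one site (L >= 1)")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("all mutational effects must be finite")
        if self.effects.ndim == 2:
            if self.reference_states is None:
                self.reference_states = np.zeros(self.L, dtype=int)
            else:
                self.reference_states = np.asarray(self.reference_states, dtype=int)
            ref = self.effects[np.arange(self.L), self.reference_states]
            if not np.all(ref == 0.0):
                raise ValueError("reference-state effect must be exactly 0 at every site")

    @property
    def L(self) -> int:
        return self.effects.shape[0]

    @property
    def q(self) -> int | None:
        return None if self.effects.ndim == 1 else self.effects.shape[1]

    @property
    def is_binary(self) -> bool:
        return self.effects.ndim == 1

    def sum_sq(self) -> float:
        """Sum of squared effects (binary) used by the default selection strength."""
        if self.is_binary:
            return float(np.sum(self.effects**2))
        return float(np.sum(self.effects**2))


def _unselected_moments(delta: MutationalEffectVector) -> tuple[float, float]:
    """Mean and variance of the trait under the unselected ensemble.

    Unselected means every state equally likely at each site independently:
    for binary sequences p(1) = 1/2; for q states each has probability 1/q.
    """
    if delta.is_binary:
        d = delta.effects
        return float(np.sum(d) / 2.0), float(np.sum(d**2) / 4.0)
    mean = float(np.sum(np.mean(delta.effects, axis=1)))
    var = float(np.sum(np.var(delta.effects, axis=1)))
    return mean, var


@dataclass
class SelectionSpec:
    """Functional form of selection acting on an additive trait.

    Forms
    -----
    gaussian   : fitness w = -(kappa/2) (T - t_star)^2
    quartic    : w = -(kappa4/2) (T - t_star)^4
    rectangular: w = 0 for |T - t_star| <= half_width, else -inf (weight 0)
    threshold  : w = 0 for T > t_threshold, else -inf

    ``kappa`` defaults to 10 / sum(Delta^2) so the selection window scales
    with the width of the unselected trait distribution.  ``kappa4``
    defaults to kappa^2 / 2, which places the e-fold half-width of the
    quartic window at the same trait offset sqrt(2/kappa) as the gaussian
    default.  ``gamma`` is the relative selection bias
    (t_star - <T>) / std(T) under the unselected ensemble.
    """

    form: str = "gaussian"
    kappa: float | None = None
    t_star: float = 0.0
    half_width: float | None = None
    t_threshold: float | None = None
    kappa4: float | None = None
    gamma: float | None = None

    _FORMS = ("gaussian", "quartic", "rectangular", "threshold")

    def __post_init__(self) -> None:
        if self.form not in self._FORMS:
            raise ValueError(f"unknown selection form {self.form!r}; expected one of {self._FORMS}")
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError("selection strength kappa must be > 0")
        if self.form == "rectangular" and self.half_width is not None and self.half_width <= 0:
            raise ValueError("rectangular half_width must be > 0")

    def resolve(self, delta: MutationalEffectVector) -> "SelectionSpec":
        """Fill defaults that depend on the mutational-effect vector.

        Returns a new spec with kappa, kappa4 and gamma populated.
        """
        kappa = self.kappa
        if kappa is None:
            # Binary default 10/sum(Delta^2); since the unselected trait
            # variance there is sum(Delta^2)/4 this is kappa = 5/(2 var T),
            # which is the form that carries over to the q-state alphabet.
            if delta.is_binary:
                ss = delta.sum_sq()
                if ss <= 0:
                    raise ValueError("cannot default kappa: sum of squared effects is zero")
                kappa = 10.0 / ss
            else:
                _m, var = _unselected_moments(delta)
                if var <= 0:
                    raise ValueError("cannot default kappa: unselected trait variance is zero")
                kappa = 2.5 / var
        kappa4 = self.kappa4
        if kappa4 is None:
            kappa4 = kappa**2 / 2.0
        mean, var = _unselected_moments(delta)
        std = math.sqrt(var) if var > 0 else float("nan")
        gamma = (self.t_star - mean) / std if std > 0 else float("nan")
        return SelectionSpec(
            form=self.form,
            kappa=kappa,
            t_star=self.t_star,
            half_width=self.half_width,
            t_threshold=self.t_threshold,
            kappa4=kappa4,
            gamma=gamma,
        )

    @classmethod
    def from_gamma(
        cls,
        delta: MutationalEffectVector,
        gamma: float,
        form: str = "gaussian",
        kappa: float | None = None,
        half_width: float | None = None,
    ) -> "SelectionSpec":
        """Build a spec whose window center sits ``gamma`` unselected
        standard deviations above the unselected trait mean."""
        mean, var = _unselected_moments(delta)
        center = mean + gamma * math.sqrt(var)
        if form == "threshold":
            spec = cls(form=form, t_threshold=center)
        else:
            spec = cls(form=form, kappa=kappa, t_star=center, half_width=half_width)
        return spec.resolve(delta)

    def to_json(self) -> str:
        payload = {
            "form": self.form,
            "kappa": self.kappa,
            "t_star": self.t_star,
            "half_width": self.half_width,
            "t_threshold": self.t_threshold,
            "kappa4": self.kappa4,
            "kappa4_default_rule": "kappa^2/2 (matches gaussian e-fold half-width sqrt(2/kappa))",
            "gamma": self.gamma,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SelectionSpec":
        d = json.loads(text)
        d.pop("kappa4_default_rule", None)
        return cls(**d)


@dataclass
class MultiTraitSelection:
    """Simultaneous gaussian selection on several additive traits."""

    traits: list[tuple[MutationalEffectVector, SelectionSpec]]

    def __post_init__(self) -> None:
        if len(self.traits) < 1:
            raise ValueError("need at least one trait")
        L0 = self.traits[0][0].L
        q0 = self.traits[0][0].q
        for d, _ in self.traits:
            if d.L != L0 or d.q != q0:
                raise ValueError("all traits must share the same length and alphabet")

    @property
    def L(self) -> int:
        return self.traits[0][0].L


def trait_value(sequence: SeqType[int] | np.ndarray, delta: MutationalEffectVector) -> float:
    """Evaluate the additive trait T = sum_l Delta_l(a_l) for one sequence."""
    seq = np.asarray(sequence, dtype=int)
    if seq.shape[-1] != delta.L:
        raise ValueError(f"sequence length {seq.shape[-1]} != effect-vector length {delta.L}")
    if delta.is_binary:
        if np.any((seq < 0) | (seq > 1)):
            raise ValueError("binary sequences must contain only 0/1 states")
        return float(seq @ delta.effects)
    if np.any((seq < 0) | (seq >= delta.q)):
        raise ValueError(f"states must lie in [0, {delta.q})")
    return float(np.sum(delta.effects[np.arange(delta.L), seq]))


def trait_values(sequences: np.ndarray, delta: MutationalEffectVector) -> np.ndarray:
    """Vectorized trait evaluation for an (M, L) array of sequences."""
    seqs = np.asarray(sequences, dtype=int)
    if seqs.ndim == 1:
        seqs = seqs[None, :]
    if seqs.shape[1] != delta.L:
        raise ValueError("sequence length mismatch")
    if delta.is_binary:
        return seqs @ delta.effects
    return delta.effects[np.arange(delta.L)[None, :], seqs].sum(axis=1)


def _fitness_from_trait(t: np.ndarray | float, spec: SelectionSpec) -> np.ndarray | float:
    t = np.asarray(t, dtype=float)
    if spec.form == "gaussian":
        if spec.kappa is None:
            raise ValueError("gaussian selection requires kappa (call spec.resolve(delta))")
        out = -(spec.kappa / 2.0) * (t - spec.t_star) ** 2
    elif spec.form == "quartic":
        if spec.kappa4 is None:
            raise ValueError("quartic selection requires kappa4 (call spec.resolve(delta))")
        out = -(spec.kappa4 / 2.0) * (t - spec.t_star) ** 4
    elif spec.form == "rectangular":
        if spec.half_width is None:
            raise ValueError("rectangular selection requires half_width")
        inside = np.abs(t - spec.t_star) <= spec.half_width  # boundary ties included
        out = np.where(inside, 0.0, NEG_INF)
    elif spec.form == "threshold":
        if spec.t_threshold is None:
            raise ValueError("threshold selection requires t_threshold")
        out = np.where(t > spec.t_threshold, 0.0, NEG_INF)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown selection form {spec.form!r}")
    return float(out) if out.ndim == 0 else out


def fitness(
    sequence: SeqType[int] | np.ndarray,
    selection: SelectionSpec,
    delta: MutationalEffectVector,
) -> float:
    """Log relative fitness w(sequence); -inf encodes zero weight."""
    return float(_fitness_from_trait(trait_value(sequence, delta), selection))


def fitness_from_traits(traits: np.ndarray, selection: SelectionSpec) -> np.ndarray:
    """Fitness for an array of pre-computed trait values."""
    return np.asarray(_fitness_from_trait(traits, selection))


def weight(
    sequence: SeqType[int] | np.ndarray,
    selection: SelectionSpec,
    delta: MutationalEffectVector,
) -> float:
    """Unnormalized Boltzmann weight exp(w); underflow clamps to 0."""
    w = fitness(sequence, selection, delta)
    if w == NEG_INF:
        return 0.0
    return float(np.exp(w))


def multi_trait_fitness(sequence: SeqType[int] | np.ndarray, msel: MultiTraitSelection) -> float:
    """Sum of per-trait gaussian fitness terms, w = -sum_i (kappa_i/2)(T_i - T_i*)^2."""
    return float(sum(fitness(sequence, spec, d) for d, spec in msel.traits))


def multi_trait_fitness_from_sequences(
    sequences: np.ndarray, msel: MultiTraitSelection
) -> np.ndarray:
    total = np.zeros(np.asarray(sequences).shape[0] if np.asarray(sequences).ndim > 1 else 1)
    for d, spec in msel.traits:
        total = total + fitness_from_traits(trait_values(sequences, d), spec)
    return total


# ---------------------------------------------------------------------------
# TSV interchange: columns site (1-based), [state], delta; header required.

def write_delta_tsv(path: str, delta: MutationalEffectVector) -> None:
    with open(path, "w") as fh:
        if delta.is_binary:
            fh.write("site\tdelta\n")
            for i, d in enumerate(delta.effects, start=1):
                fh.write(f"{i}\t{float(d)!r}\n")
        else:
            fh.write("site\tstate\tdelta\n")
            for i in range(delta.L):
                for a in range(delta.q):
                    fh.write(f"{i + 1}\t{a}\t{float(delta.effects[i, a])!r}\n")


def read_delta_tsv(path: str, trait_name: str = "trait") -> MutationalEffectVector:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty mutational-effect file {path}")
    header = lines[0].split("\t")
    rows = [ln.split("\t") for ln in lines[1:]]
    if header[:2] == ["site", "delta"]:
        sites = np.array([int(r[0]) for r in rows])
        vals = np.array([float(r[1]) for r in rows])
        effects = np.zeros(sites.max())
        effects[sites - 1] = vals
        return MutationalEffectVector(effects, trait_name=trait_name)
    if header[:3] == ["site", "state", "delta"]:
        sites = np.array([int(r[0]) for r in rows])
        states = np.array([int(r[1]) for r in rows])
        vals = np.array([float(r[2]) for r in rows])
        L, q = sites.max(), states.max() + 1
        effects = np.zeros((L, q))
        effects[sites - 1, states] = vals
        return MutationalEffectVector(effects, trait_name=trait_name)
    raise ValueError("unrecognized header; expected 'site\\tdelta' or 'site\\tstate\\tdelta'")
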