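"""Synthetic mutational-effect vectors and toy structures.

Sector-structured effect vectors place a few large-magnitude effects
(the sector) on random sites against a weak background, mirroring the
strongly heterogeneous effect magnitudes seen in the elastic-network
trait.  Everything here is a pure function of its spec and seed, so the
whole detection pipeline is testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elastic_network import CarbonStructure
from .trait_models import MutationalEffectVector

__all__ = [
    "SectorSpec",
    "make_delta",
    "make_delta_pair",
    "make_multistate_delta",
    "make_toy_structure",
]


@dataclass
class SectorSpec:
    """Recipe for a sector-structured mutational-effect vector.

    ``n_sector_sites`` sites carry effects of magnitude uniform in
    [0.5, 1.5] * effect_scale_sector; the rest use
    effect_scale_background.  Bounded magnitudes keep the sector strictly
    separated from the background at the default scale ratio of 10.
    ``sign_policy='all_negative'`` makes every effect negative (weakening
    a spring never lowers a fixed-deformation energy); ``'mixed'`` draws
    random signs.
    """

    L: int = 100
    n_sector_sites: int = 20
    effect_scale_sector: float = 10.0
    effect_scale_background: float = 1.0
    sign_policy: str = "all_negative"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_sector_sites <= self.L):
            raise ValueError("need 1 <= n_sector_sites <= L")
        if self.effect_scale_sector <= 0 or self.effect_scale_background <= 0:
            raise ValueError("effect scales must be > 0")
        if self.effect_scale_sector < self.effect_scale_background:
            raise ValueError("sector scale must be >= background scale")
        if self.sign_policy not in ("all_negative", "mixed"):
            raise ValueError("sign_policy must be 'all_negative' or 'mixed'")


def _draw_effects(rng: np.random.Generator, n: int, scale: float, policy: str) -> np.ndarray:
    mag = scale * rng.uniform(0.5, 1.5, size=n)
    if policy == "all_negative":
        return -mag
    return mag * rng.choice([-1.0, 1.0], size=n)


def make_delta(spec: SectorSpec, sector_sites: np.ndarray | None = None) -> MutationalEffectVector:
    """Draw a sector-structured effect vector; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    if sector_sites is None:
        sector_sites = rng.choice(spec.L, size=spec.n_sector_sites, replace=False)
    sector_sites = np.asarray(sector_sites, dtype=int)
    effects = _draw_effects(rng, spec.L, spec.effect_scale_background, spec.sign_policy)
    effects[sector_sites] = _draw_effects(
        rng, sector_sites.size, spec.effect_scale_sector, spec.sign_policy
    )
    vec = MutationalEffectVector(effects, trait_name="synthetic_sector")
    vec.sector_sites = np.sort(sector_sites)  # attach for test introspection
    return vec


def make_delta_pair(
    spec: SectorSpec,
    overlap_fraction: float,
) -> tuple[MutationalEffectVector, MutationalEffectVector]:
    """Two sector vectors whose site sets overlap by the requested fraction.

    The shared-site count is round(overlap_fraction * n_sector_sites);
    effect values stay independent even on shared sites.  At 100% overlap
    the site sets coincide.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1]")
    n = spec.n_sector_sites
    n_shared = int(round(overlap_fraction * n))
    n_total = 2 * n - n_shared
    if n_total > spec.L:
        raise ValueError(
            f"infeasible overlap: two {n}-site sectors sharing {n_shared} sites "
            f"need {n_total} sites but L={spec.L}"
        )
    rng = np.random.default_rng(spec.seed)
    sites = rng.choice(spec.L, size=n_total, replace=False)
    shared = sites[:n_shared]
    only1 = sites[n_shared : n_shared + (n - n_shared)]
    only2 = sites[n_shared + (n - n_shared) :]
    sites1 = np.concatenate([shared, only1]).astype(int)
    sites2 = np.concatenate([shared, only2]).astype(int)
    spec1 = SectorSpec(spec.L, n, spec.effect_scale_sector, spec.effect_scale_background,
                       spec.sign_policy, seed=spec.seed + 1)
    spec2 = SectorSpec(spec.L, n, spec.effect_scale_sector, spec.effect_scale_background,
                       spec.sign_policy, seed=spec.seed + 2)
    return make_delta(spec1, sites1), make_delta(spec2, sites2)


def make_multistate_delta(L: int, q: int, spec: SectorSpec) -> MutationalEffectVector:
    """q-state sector effect matrix with reference state 0 (all zeros column).

    The per-site root-mean-square effect across non-reference states
    carries the sector/background structure.
    """
    if q < 2:
        raise ValueError("need q >= 2")
    base = SectorSpec(L, spec.n_sector_sites, spec.effect_scale_sector,
                      spec.effect_scale_background, spec.sign_policy, spec.seed)
    rng = np.random.default_rng(base.seed)
    sector_sites = rng.choice(L, size=base.n_sector_sites, replace=False)
    scales = np.full(L, base.effect_scale_background)
    scales[sector_sites] = base.effect_scale_sector
    effects = np.zeros((L, q))
    raw = _draw_effects(rng, L * (q - 1), 1.0, base.sign_policy).reshape(L, q - 1)
    effects[:, 1:] = raw * scales[:, None]
    vec = MutationalEffectVector(effects, trait_name="synthetic_sector_qstate")
    vec.sector_sites = np.sort(sector_sites)
    return vec


def make_toy_structure(
    n_residues: int,
    geometry: str = "helix",
    seed: int = 0,
    displaced_residues: np.ndarray | None = None,
    displacement_scale: float = 1.0,
) -> tuple[CarbonStructure, CarbonStructure]:
    """Reproducible toy CA/CB structure plus a locally displaced copy.

    ``helix`` places C-alphas on an ideal alpha-helical spiral (rise 1.5 A,
    100 deg twist, radius 2.3 A); ``random_coil`` makes a self-avoiding-ish
    random walk with 3.8 A steps.  C-betas sit 1.5 A radially outward.
    The copy displaces the designated residues (default: the central
    third) coherently to mimic a conformational change.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    if geometry == "helix":
        t = np.arange(n_residues)
        theta = np.deg2rad(100.0) * t
        ca = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * t], axis=1)
        radial = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
    elif geometry == "random_coil":
        steps = rng.standard_normal((n_residues - 1, 3))
        steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
        ca = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        radial = rng.standard_normal((n_residues, 3))
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    cb = ca + 1.5 * radial
    ids = list(range(1, n_residues + 1))
    ref = CarbonStructure(ids, ca, cb)

    if displaced_residues is None:
        lo, hi = n_residues // 3, 2 * n_residues // 3 + 1
        displaced_residues = np.arange(lo, hi)
    displaced_residues = np.asarray(displaced_residues, dtype=int)
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    ca2, cb2 = ca.copy(), cb.copy()
    ca2[displaced_residues] += displacement_scale * direction
    cb2[displaced_residues] += displacement_scale * direction
    moved = CarbonStructure(ids, ca2, cb2)
    return ref, moved
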