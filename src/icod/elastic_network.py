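"""Elastic-network model of a protein and the deformation-energy trait.

Each residue contributes its alpha carbon and (except glycine) its beta
carbon as network nodes; every carbon pair closer than a cutoff d_c in the
reference structure is joined by a harmonic spring.  The energetic cost of
a fixed conformational change delta_r is E = (1/2) delta_r^T M delta_r,
with M the network Hessian.  A "mutation" at residue l weakens every
spring incident on that residue's C-beta by a factor (1 - epsilon); to
first order in epsilon the resulting energy change is additive across
sites, which makes the deformation energy an additive trait whose
mutational-effect vector this module computes.

Spring constants follow the standard C-alpha/C-beta network: 2 for
backbone-adjacent C-alpha pairs, 1 for other C-alpha pairs and for
C-alpha/C-beta pairs, 0.5 for C-beta pairs, with cutoff d_c = 7.5 A.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .trait_models import MutationalEffectVector

logger = logging.getLogger(__name__)

__all__ = [
    "CarbonStructure",
    "ElasticNetwork",
    "Deformation",
    "PerturbationResult",
    "read_pdb_carbons",
    "build_network",
    "hessian",
    "deformation_energy",
    "mutational_effects",
    "superpose",
    "DEFAULT_CUTOFF",
    "DEFAULT_EPSILON",
    "DEFAULT_CONSTANTS",
]

DEFAULT_CUTOFF = 7.5  # Angstrom
DEFAULT_EPSILON = 0.2
#: spring constants keyed by (role_i, role_j, backbone_adjacent)
DEFAULT_CONSTANTS = {
    ("CA", "CA", True): 2.0,
    ("CA", "CA", False): 1.0,
    ("CA", "CB", True): 1.0,
    ("CA", "CB", False): 1.0,
    ("CB", "CB", True): 0.5,
    ("CB", "CB", False): 0.5,
}


@dataclass
class CarbonStructure:
    """Ordered C-alpha / C-beta coordinates for one chain.

    ``residue_ids`` are 1-based author residue identifiers (with chain and
    insertion code folded into the key for PDB input); ``ca`` is (L, 3);
    ``cb`` is (L, 3) with NaN rows for residues lacking a C-beta (glycine).
    """

    residue_ids: list
    ca: np.ndarray
    cb: np.ndarray

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.cb = np.asarray(self.cb, dtype=float)
        if self.ca.shape != (len(self.residue_ids), 3) or self.cb.shape != self.ca.shape:
            raise ValueError("coordinate arrays must be (L, 3)")

    @property
    def L(self) -> int:
        return len(self.residue_ids)

    def has_cb(self, i: int) -> bool:
        return bool(np.all(np.isfinite(self.cb[i])))


def read_pdb_carbons(path: str, chain_id: str | None = None, model_index: int = 0) -> CarbonStructure:
    """Read CA/CB coordinates from ATOM records of a PDB file.

    Uses the highest-occupancy conformer for alternate locations and keys
    residues by (chain, author number, insertion code).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", path)[model_index]
    residue_ids, cas, cbs = [], [], []
    for chain in model:
        if chain_id is not None and chain.id != chain_id:
            continue
        for res in chain:
            het, seq, icode = res.id
            if het.strip():
                continue  # skip HETATM water/ligand
            if "CA" not in res:
                raise ValueError(f"residue {chain.id}{seq}{icode.strip()} has no C-alpha")
            ca_atom = res["CA"]
            if ca_atom.is_disordered():
                ca_atom = max(ca_atom.disordered_get_list(), key=lambda a: a.get_occupancy())
            cas.append(ca_atom.get_coord())
            if "CB" in res:
                cb_atom = res["CB"]
                if cb_atom.is_disordered():
                    cb_atom = max(cb_atom.disordered_get_list(), key=lambda a: a.get_occupancy())
                cbs.append(cb_atom.get_coord())
            else:
                cbs.append(np.full(3, np.nan))
            residue_ids.append((chain.id, seq, icode))
    if not residue_ids:
        raise ValueError(f"no protein residues found in {path}")
    return CarbonStructure(residue_ids, np.array(cas), np.array(cbs))


@dataclass
class ElasticNetwork:
    """Harmonic spring network over CA/CB nodes of one structure."""

    positions: np.ndarray         # (N, 3) node coordinates
    node_residue: np.ndarray      # (N,) 0-based residue index of each node
    node_role: list               # (N,) "CA" or "CB"
    springs: list                 # (i, j, rest_length, k) with i < j node indices
    L: int                        # number of residues

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    def cb_node(self, residue: int) -> int | None:
        """Node index of the residue's C-beta, or None (glycine)."""
        for n in np.flatnonzero(self.node_residue == residue):
            if self.node_role[n] == "CB":
                return int(n)
        return None

    def write_edge_list(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("node_i\tnode_j\trole_i\trole_j\trest_length\tk\n")
            for i, j, r, k in self.springs:
                fh.write(f"{i}\t{j}\t{self.node_role[i]}\t{self.node_role[j]}\t{r:.6f}\t{k}\n")


@dataclass
class Deformation:
    """A fixed displacement field over the network nodes (3N vector, A)."""

    displacement: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float).ravel()
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement must be finite")


@dataclass
class PerturbationResult:
    """First-order mutational effects on the deformation energy."""

    delta: MutationalEffectVector
    epsilon: float
    baseline_energy: float
    exact_single_mutant_energies: np.ndarray


def build_network(
    structure: CarbonStructure,
    cutoff: float = DEFAULT_CUTOFF,
    constants: dict | None = None,
) -> ElasticNetwork:
    """Connect every carbon pair within ``cutoff`` with a harmonic spring."""
    constants = DEFAULT_CONSTANTS if constants is None else constants
    positions, node_residue, node_role = [], [], []
    for i in range(structure.L):
        positions.append(structure.ca[i])
        node_residue.append(i)
        node_role.append("CA")
        if structure.has_cb(i):
            positions.append(structure.cb[i])
            node_residue.append(i)
            node_role.append("CB")
    positions = np.array(positions)
    node_residue = np.array(node_residue)
    n = len(positions)
    springs = []
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(positions[i] - positions[j]))
            if d > cutoff or d == 0.0:
                continue
            adjacent = abs(int(node_residue[i]) - int(node_residue[j])) == 1
            role_key = tuple(sorted((node_role[i], node_role[j])))
            k = constants[(role_key[0], role_key[1], adjacent)]
            springs.append((i, j, d, k))
    if not springs:
        raise ValueError("empty elastic network: no carbon pair within the cutoff")
    return ElasticNetwork(positions, node_residue, node_role, springs, structure.L)


def _spring_factors(network: ElasticNetwork, mutant_sequence: np.ndarray, epsilon: float) -> np.ndarray:
    """Per-spring multiplicative factor (1-eps)^(# mutated C-beta endpoints)."""
    seq = np.asarray(mutant_sequence, dtype=int)
    if seq.shape != (network.L,):
        raise ValueError(f"sequence length {seq.shape} != residue count {network.L}")
    factors = np.ones(len(network.springs))
    for s, (i, j, _r, _k) in enumerate(network.springs):
        for node in (i, j):
            if network.node_role[node] == "CB" and seq[network.node_residue[node]] == 1:
                factors[s] *= 1.0 - epsilon
    return factors


def hessian(
    network: ElasticNetwork,
    mutant_sequence: np.ndarray | None = None,
    epsilon: float = 0.0,
) -> np.ndarray:
    """Assemble the 3N x 3N Hessian of the (possibly mutated) network.

    Each spring contributes the positive-semidefinite block k (d d^T) on
    the unit bond direction; mutations rescale spring constants by
    (1 - epsilon) per mutated C-beta endpoint.
    """
    n = network.n_nodes
    if mutant_sequence is None:
        mutant_sequence = np.zeros(network.L, dtype=int)
    factors = _spring_factors(network, mutant_sequence, epsilon)
    M = np.zeros((3 * n, 3 * n))
    for s, (i, j, _r, k) in enumerate(network.springs):
        d = network.positions[j] - network.positions[i]
        d = d / np.linalg.norm(d)
        block = (k * factors[s]) * np.outer(d, d)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        M[si, si] += block
        M[sj, sj] += block
        M[si, sj] -= block
        M[sj, si] -= block
    return M


def deformation_energy(
    network: ElasticNetwork,
    mutant_sequence: np.ndarray,
    epsilon: float,
    deformation: Deformation,
) -> float:
    """E = (1/2) delta_r^T M delta_r for a fixed displacement field."""
    dr = deformation.displacement
    if dr.size != 3 * network.n_nodes:
        raise ValueError(f"displacement has {dr.size} components, expected {3 * network.n_nodes}")
    M = hessian(network, mutant_sequence, epsilon)
    return float(0.5 * dr @ M @ dr)


def mutational_effects(
    network: ElasticNetwork,
    deformation: Deformation,
    epsilon: float = DEFAULT_EPSILON,
) -> PerturbationResult:
    """First-order mutational-effect vector of the deformation energy.

    Delta_l = epsilon * (1/2) dr^T M^(1,l) dr, where M^(1,l) is the Hessian
    derivative with respect to weakening all springs on residue l's C-beta
    (M^(1,l) = -sum of those springs' blocks).  Residues without a C-beta
    get Delta_l = 0.  Exact single-mutant energy changes at the given
    epsilon are returned alongside for validation.
    """
    dr = deformation.displacement
    if dr.size != 3 * network.n_nodes:
        raise ValueError("displacement dimension mismatch")
    base = deformation_energy(network, np.zeros(network.L, dtype=int), 0.0, deformation)

    # per-spring energy contribution (1/2) k (d . (dr_j - dr_i))^2 / |d|^0
    spring_energy = np.zeros(len(network.springs))
    for s, (i, j, _r, k) in enumerate(network.springs):
        d = network.positions[j] - network.positions[i]
        d = d / np.linalg.norm(d)
        rel = dr[3 * j : 3 * j + 3] - dr[3 * i : 3 * i + 3]
        spring_energy[s] = 0.5 * k * (d @ rel) ** 2

    delta = np.zeros(network.L)
    exact = np.zeros(network.L)
    no_cb = []
    for l in range(network.L):
        cb = network.cb_node(l)
        if cb is None:
            no_cb.append(l)
            continue
        incident = [s for s, (i, j, _r, _k) in enumerate(network.springs) if cb in (i, j)]
        delta[l] = -epsilon * float(np.sum(spring_energy[incident]))
        seq = np.zeros(network.L, dtype=int)
        seq[l] = 1
        exact[l] = deformation_energy(network, seq, epsilon, deformation) - base
    if no_cb:
        logger.warning("residues without C-beta get Delta=0: %s", no_cb)
    dvec = MutationalEffectVector(delta, trait_name="deformation_energy", units="ENM energy")
    return PerturbationResult(dvec, epsilon, base, exact)


def superpose(structure_a: CarbonStructure, structure_b: CarbonStructure) -> Deformation:
    """Kabsch superposition of b onto a over shared C-alphas; returns the
    residual displacement field over all network nodes of ``structure_a``.

    Residues present in only one structure are excluded (zero displacement
    contribution) with a warning.
    """
    ids_a = {rid: i for i, rid in enumerate(structure_a.residue_ids)}
    ids_b = {rid: i for i, rid in enumerate(structure_b.residue_ids)}
    shared = [rid for rid in structure_a.residue_ids if rid in ids_b]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared residues for superposition")
    missing = [rid for rid in structure_a.residue_ids if rid not in ids_b]
    if missing:
        warnings.warn(f"{len(missing)} residues missing from the second structure are "
                      "excluded from the deformation", stacklevel=2)

    A = structure_a.ca[[ids_a[r] for r in shared]]
    B = structure_b.ca[[ids_b[r] for r in shared]]
    cA, cB = A.mean(axis=0), B.mean(axis=0)
    H = (B - cB).T @ (A - cA)
    U, _S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T  # rotates centered B coords onto A frame

    def transform(x: np.ndarray) -> np.ndarray:
        return (R @ (x - cB).T).T + cA

    # displacement over all nodes of the reference network layout
    disp = []
    for i, rid in enumerate(structure_a.residue_ids):
        j = ids_b.get(rid)
        if j is None:
            disp.append(np.zeros(3))
        else:
            disp.append(transform(structure_b.ca[j][None, :])[0] - structure_a.ca[i])
        if structure_a.has_cb(i):
            if j is not None and structure_b.has_cb(j):
                disp.append(transform(structure_b.cb[j][None, :])[0] - structure_a.cb[i])
            else:
                disp.append(np.zeros(3))
    return Deformation(np.concatenate(disp), source="superpose")
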