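"""Ground-truth-bearing synthetic inputs.

Two generators back the validation of the analysis pipeline:

* :func:`generate_globule` — compact bead-model "proteins": residues are
  packed inside a sphere, residues in the inner 60% of the radius draw
  their type from a core composition and the rest from a surface
  composition, and every residue carries a Cα plus one pseudo side-chain
  atom whose element matches its residue class.  The planted core/surface
  labels are returned alongside, so shell classification and composition
  recovery can be scored against truth.

* :func:`evolve_along_tree` — alignments simulated along a known tree
  under a reversible amino-acid model with optional indels, with the true
  sequences of every internal node emitted, so ancestral reconstruction
  can be scored against the simulated root.

Both are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .asr import AMINO_ACIDS, RateModel, build_cprev
from .structure_io import ONE_TO_THREE, Atom, Residue, Structure, _vdw_radius

logger = logging.getLogger(__name__)

__all__ = [
    "GlobuleSpec",
    "EvolutionSpec",
    "SimulatedAlignment",
    "generate_globule",
    "evolve_along_tree",
    "balanced_tree",
    "composition_vector",
    "DEFAULT_CORE_COMPOSITION",
    "DEFAULT_SURFACE_COMPOSITION",
]

# pseudo side-chain atom (name, element) per residue type; Gly has none
_SIDECHAIN_ATOM: dict[str, tuple[str, str]] = {
    "ASP": ("OD1", "O"), "GLU": ("OE1", "O"),
    "LYS": ("NZ", "N"), "ARG": ("NH1", "N"), "HIS": ("NE2", "N"),
    "SER": ("OG", "O"), "THR": ("OG1", "O"), "ASN": ("OD1", "O"),
    "GLN": ("OE1", "O"), "TYR": ("OH", "O"), "TRP": ("NE1", "N"),
    "CYS": ("SG", "S"), "MET": ("SD", "S"),
}


def composition_vector(weights: dict[str, float]) -> np.ndarray:
    """Normalised 20-vector over :data:`AMINO_ACIDS` from letter weights."""
    vec = np.zeros(20)
    for aa, w in weights.items():
        if aa not in AMINO_ACIDS:
            raise ValueError(f"unknown amino acid {aa!r}")
        vec[AMINO_ACIDS.index(aa)] = w
    if vec.sum() <= 0:
        raise ValueError("composition weights must sum to a positive value")
    return vec / vec.sum()


# rough globular-protein flavour: hydrophobic interior, polar/charged
# exterior; exact values are a generator convention, not an estimate
DEFAULT_CORE_COMPOSITION = composition_vector({
    "A": 12, "V": 12, "L": 14, "I": 10, "F": 7, "M": 4, "W": 2, "Y": 4,
    "G": 9, "C": 3, "S": 5, "T": 5, "P": 3, "N": 2, "Q": 2, "H": 2,
    "D": 1.5, "E": 1.5, "K": 0.5, "R": 0.5,
})
DEFAULT_SURFACE_COMPOSITION = composition_vector({
    "A": 6, "V": 4, "L": 4, "I": 3, "F": 2, "M": 1, "W": 1, "Y": 3,
    "G": 7, "C": 1, "S": 8, "T": 7, "P": 5, "N": 6, "Q": 5, "H": 2,
    "D": 8, "E": 10, "K": 10, "R": 7,
})


@dataclass
class GlobuleSpec:
    """Parameters of a planted-composition bead globule.

    Residues deeper than ``burial_depth`` below the packing-sphere surface
    are planted as core; the depth convention (rather than a fixed radius
    fraction) tracks the physical solvent-burial horizon, which sits a
    roughly constant distance below the surface regardless of protein
    size.
    """

    n_residues: int
    surface_composition: np.ndarray = field(
        default_factory=lambda: DEFAULT_SURFACE_COMPOSITION.copy())
    core_composition: np.ndarray = field(
        default_factory=lambda: DEFAULT_CORE_COMPOSITION.copy())
    packing_radius: float = 1.9     # Å; min bead separation = 2× this
    packing_factor: float = 1.5     # sphere radius = factor · r · n^{1/3}
    burial_depth: float = 4.0       # Å below surface where core starts
    filler_scale: float = 1.7       # Å; tetrahedral filler atom offset
    sidechain_arm: float = 2.5      # Å; class-bearing pseudo atom offset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be at least 1")
        for name in ("surface_composition", "core_composition"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (20,) or vec.min() < 0 \
                    or not np.isclose(vec.sum(), 1.0, atol=1e-6):
                raise ValueError(f"{name} must be a probability 20-vector")
            setattr(self, name, vec / vec.sum())


# fixed tetrahedral directions for the space-filling carbon cluster that
# stands in for each residue's body
_TETRAHEDRON = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                        dtype=float) / np.sqrt(3.0)


def generate_globule(spec: GlobuleSpec,
                     ) -> tuple[Structure, dict[tuple[str, int, str], str]]:
    """Build a bead globule; returns (structure, planted labels).

    Beads are rejection-packed inside a sphere of radius
    packing_factor · packing_radius · n^{1/3} (≈30% volume fraction,
    below random-sequential-addition jamming).  Each residue is rendered
    as a Cα plus a tetrahedron of filler carbons — so that interior
    residues are genuinely solvent-inaccessible, as in a packed protein —
    plus one class-bearing pseudo side-chain atom pointing radially
    outward (surface) or inward (core).  Labels map residue key →
    "core" | "surface" according to the planted burial-depth rule.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    sphere_radius = spec.packing_factor * spec.packing_radius * n ** (1.0 / 3.0)
    min_sep2 = (2.0 * spec.packing_radius) ** 2

    positions: list[np.ndarray] = []
    max_attempts = 5000
    for _ in range(n):
        for attempt in range(max_attempts):
            p = rng.uniform(-sphere_radius, sphere_radius, size=3)
            if p @ p > sphere_radius ** 2:
                continue
            if all(np.sum((p - q) ** 2) >= min_sep2 for q in positions):
                positions.append(p)
                break
        else:
            raise RuntimeError(
                "bead packing failed; increase packing_radius or sphere size")

    aa_letters = np.array(list(AMINO_ACIDS))
    structure = Structure(id=f"globule_seed{spec.seed}",
                          metadata={"seed": spec.seed})
    residues: list[Residue] = []
    labels: dict[tuple[str, int, str], str] = {}
    core_cut = sphere_radius - spec.burial_depth
    for i, pos in enumerate(positions):
        radial = float(np.linalg.norm(pos))
        label = "core" if radial <= core_cut else "surface"
        comp = spec.core_composition if label == "core" \
            else spec.surface_composition
        one = rng.choice(aa_letters, p=comp)
        res_type = ONE_TO_THREE[one]
        residue = Residue(chain_id="A", seq_id=i + 1, res_type=res_type)
        residue.atoms.append(Atom(name="CA", element="C", position=pos,
                                  vdw_radius=_vdw_radius("C"),
                                  is_sidechain=False))
        for k, vertex in enumerate(_TETRAHEDRON, start=1):
            residue.atoms.append(Atom(
                name=f"CB{k}", element="C",
                position=pos + spec.filler_scale * vertex,
                vdw_radius=_vdw_radius("C"), is_sidechain=True))
        sc = _SIDECHAIN_ATOM.get(res_type)
        if sc is not None:
            direction = pos / radial if radial > 1e-9 else np.array([0, 0, 1.0])
            if label == "core":
                direction = -direction
            name, element = sc
            residue.atoms.append(Atom(
                name=name, element=element,
                position=pos + spec.sidechain_arm * direction,
                vdw_radius=_vdw_radius(element), is_sidechain=True))
        residues.append(residue)
        labels[residue.key] = label
    structure.chains["A"] = residues
    return structure, labels


# ---------------------------------------------------------------------------
# sequence evolution

@dataclass
class EvolutionSpec:
    """Parameters of a tree-structured sequence simulation.

    ``indel_rate`` is the expected number of indel events per site per
    unit branch length; event lengths are geometric with the given mean,
    insertions and deletions equally likely.
    """

    tree: dendropy.Tree
    root_sequence: str | None = None
    root_length: int = 200
    model: RateModel | None = None
    indel_rate: float = 0.0
    mean_indel_length: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.indel_rate < 0 or self.mean_indel_length < 1:
            raise ValueError("indel_rate ≥ 0 and mean_indel_length ≥ 1 required")
        if self.root_sequence is None and self.root_length < 1:
            raise ValueError("root_length must be positive")


@dataclass
class SimulatedAlignment:
    """Simulation output: aligned leaves, aligned internal truths, tree."""

    leaves: dict[str, str]
    internals: dict[str, str]       # node label → aligned true sequence
    tree: dendropy.Tree
    root_label: str
    seed: int

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.leaves.values())))


def balanced_tree(n_leaves: int, total_depth: float,
                  prefix: str = "t") -> dendropy.Tree:
    """Fully balanced binary tree with equal branch lengths.

    ``n_leaves`` must be a power of two; every root-to-leaf path has
    length ``total_depth`` expected substitutions per site.
    """
    levels = int(np.log2(n_leaves))
    if 2 ** levels != n_leaves:
        raise ValueError("n_leaves must be a power of two")
    edge = total_depth / levels

    def newick(depth: int, index: int) -> str:
        if depth == levels:
            return f"{prefix}{index}:{edge}"
        left = newick(depth + 1, 2 * index)
        right = newick(depth + 1, 2 * index + 1)
        return f"({left},{right}):{edge}" if depth else f"({left},{right});"

    tree = dendropy.Tree.get(data=newick(0, 0), schema="newick")
    tree.is_rooted = True
    return tree


def _sample_states(p_rows: np.ndarray, states: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Vectorised categorical draw: next state per site from P rows."""
    cum = np.cumsum(p_rows[states], axis=1)
    u = rng.random(len(states))
    return np.minimum((u[:, None] > cum).sum(axis=1), 19)


def evolve_along_tree(spec: EvolutionSpec) -> SimulatedAlignment:
    """Simulate sequences down the tree; returns the aligned leaves and
    the true aligned sequences of every internal node.

    The root is drawn from the model's equilibrium frequencies unless
    given.  Substitutions are sampled per site from P(t) = exp(Qt) per
    branch; indels follow a Poisson process along branches with geometric
    lengths, applied left-to-right, and appear as gap columns in the
    output alignment (insertions create fresh columns).
    """
    model = spec.model or build_cprev()
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree

    if spec.root_sequence is not None:
        root_states = np.array([AMINO_ACIDS.index(c)
                                for c in spec.root_sequence.upper()])
    else:
        root_states = rng.choice(20, size=spec.root_length,
                                 p=model.frequencies)

    # global alignment coordinates: every simulated site has a column id;
    # ``master`` keeps the left-to-right order of all columns ever created
    master: list[int] = list(range(len(root_states)))
    next_id = len(root_states)

    # label internal nodes deterministically (preorder)
    counter = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label is None:
            node.label = f"anc{counter}"
            counter += 1

    sequences: dict[str, dict[int, int]] = {}  # node label → col id → state

    def record(node: dendropy.Node, cols: list[int], states: np.ndarray) -> None:
        label = node.taxon.label if node.is_leaf() else node.label
        sequences[label] = dict(zip(cols, states.tolist()))

    def descend(node: dendropy.Node, cols: list[int],
                states: np.ndarray) -> None:
        nonlocal next_id
        record(node, cols, states)
        for child in node.child_nodes():
            t = child.edge.length if child.edge.length is not None else 0.0
            child_cols = list(cols)
            child_states = states.copy()
            if t > 0 and len(child_states):
                p = model.transition_matrix(t)
                child_states = _sample_states(p, child_states, rng)
            if spec.indel_rate > 0 and len(child_states):
                n_events = rng.poisson(spec.indel_rate * len(child_states) * t)
                for _ in range(n_events):
                    length = rng.geometric(1.0 / spec.mean_indel_length)
                    if not len(child_states):
                        break
                    if rng.random() < 0.5:  # deletion
                        start = rng.integers(0, len(child_states))
                        stop = min(start + length, len(child_states))
                        del child_cols[start:stop]
                        child_states = np.delete(child_states,
                                                 np.s_[start:stop])
                    else:  # insertion
                        at = int(rng.integers(0, len(child_states) + 1))
                        new_ids = list(range(next_id, next_id + length))
                        next_id += length
                        new_states = rng.choice(20, size=length,
                                                p=model.frequencies)
                        # splice fresh columns into the master order next
                        # to this lineage's anchor column
                        anchor = master.index(child_cols[at - 1]) + 1 \
                            if at > 0 else 0
                        master[anchor:anchor] = new_ids
                        child_cols[at:at] = new_ids
                        child_states = np.concatenate(
                            [child_states[:at], new_states, child_states[at:]])
            descend(child, child_cols, child_states)

    descend(tree.seed_node, list(range(len(root_states))), root_states)

    def to_aligned(chars: dict[int, int]) -> str:
        return "".join(AMINO_ACIDS[chars[cid]] if cid in chars else "-"
                       for cid in master)

    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    leaves = {lab: to_aligned(seq) for lab, seq in sequences.items()
              if lab in leaf_labels}
    internals = {lab: to_aligned(seq) for lab, seq in sequences.items()
                 if lab not in leaf_labels}
    return SimulatedAlignment(
        leaves=leaves, internals=internals, tree=tree,
        root_label=tree.seed_node.label, seed=spec.seed)
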