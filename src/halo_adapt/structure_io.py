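"""Coordinate, sequence and tree I/O.

A thin, explicit data model (:class:`Atom` / :class:`Residue` /
:class:`Structure`) sits on top of Biopython's PDB parser so that the
downstream accessibility and superposition code works with plain numpy
arrays and named fields rather than library-specific objects.  Newick
handling is delegated to dendropy; its :class:`dendropy.Tree` is the tree
carrier type used throughout the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBFormatError",
    "NewickValidationError",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "read_pdb",
    "write_pdb",
    "extract_sequence",
    "chain_breaks",
    "read_newick",
    "write_newick",
    "read_fasta",
    "write_fasta",
]

# Bondi-style van der Waals radii (Å).  Elements outside this table fall
# back to the carbon radius with a logged warning.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class PDBFormatError(ValueError):
    """Raised when a coordinate file contains no usable ATOM records."""


class NewickValidationError(ValueError):
    """Raised when a parsed tree violates a structural requirement."""


@dataclass
class Atom:
    """A single atom: label, element, Cartesian position and vdW radius."""

    name: str
    element: str
    position: np.ndarray
    vdw_radius: float
    occupancy: float = 1.0
    is_sidechain: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdw_radius must be positive")


@dataclass
class Residue:
    """One residue: identity plus its ordered atoms.

    ``seq_id`` keeps the author numbering of the source PDB file (1-based
    with insertion codes); positional indices used internally are 0-based.
    """

    chain_id: str
    seq_id: int
    res_type: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.insertion_code)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_type, "X")

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None


@dataclass
class Structure:
    """Hierarchical coordinate model: chains of residues of atoms."""

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def residues(self, chain: str | None = None) -> Iterator[Residue]:
        if chain is not None:
            yield from self.chains[chain]
        else:
            for residues in self.chains.values():
                yield from residues

    def atoms(self, chain: str | None = None) -> Iterator[Atom]:
        for residue in self.residues(chain):
            yield from residue.atoms

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.residues())

    def coordinates(self, chain: str | None = None) -> np.ndarray:
        return np.array([a.position for a in self.atoms(chain)], dtype=float)

    def ca_coordinates(self, chain: str | None = None) -> np.ndarray:
        """Cα positions in residue order; residues missing a Cα are skipped."""
        coords = []
        for residue in self.residues(chain):
            ca = residue.get_atom("CA")
            if ca is not None:
                coords.append(ca.position)
        return np.array(coords, dtype=float)


def _vdw_radius(element: str) -> float:
    radius = VDW_RADII.get(element.upper())
    if radius is None:
        logger.warning("element %r not in radius table; using default %.2f Å",
                       element, DEFAULT_VDW_RADIUS)
        return DEFAULT_VDW_RADIUS
    return radius


def read_pdb(path: str | Path, structure_id: str | None = None) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Only the first MODEL is read.  HETATM records (waters, ions, ligands)
    are excluded from the protein model; their residue names are retained
    in ``metadata['hetero']``.  Alternate locations resolve to the highest
    occupancy, ties to altloc 'A'.  Unknown residue names are kept as UNK.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure_id = structure_id or path.stem

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_structure = parser.get_structure(structure_id, str(path))

    try:
        model = next(bio_structure.get_models())
    except StopIteration:  # pragma: no cover - parser always yields a model
        raise PDBFormatError(f"{path}: no coordinate model found") from None

    structure = Structure(id=structure_id)
    hetero: list[str] = []
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, seq_id, icode = bio_res.id
            if hetflag.strip():  # HETATM (water 'W' or ligand 'H_XXX')
                hetero.append(bio_res.resname.strip())
                continue
            res_name = bio_res.resname.strip()
            if res_name not in THREE_TO_ONE and res_name != "UNK":
                logger.warning("unknown residue name %r at %s%s; kept as UNK",
                               res_name, bio_chain.id, seq_id)
                res_name = "UNK"
            residue = Residue(
                chain_id=bio_chain.id,
                seq_id=seq_id,
                insertion_code=icode.strip(),
                res_type=res_name,
            )
            for bio_atom in bio_res:
                if bio_atom.is_disordered():
                    # highest occupancy wins; ties resolve to altloc 'A'
                    alts = sorted(
                        bio_atom.disordered_get_list(),
                        key=lambda a: (-(a.get_occupancy() or 0.0),
                                       a.get_altloc()),
                    )
                    bio_atom = alts[0]
                name = bio_atom.get_name()
                element = (bio_atom.element or name[:1]).strip().upper()
                residue.atoms.append(Atom(
                    name=name,
                    element=element,
                    position=bio_atom.get_coord(),
                    vdw_radius=_vdw_radius(element),
                    occupancy=bio_atom.get_occupancy() or 1.0,
                    is_sidechain=name not in BACKBONE_ATOMS,
                ))
            if residue.atoms:
                residues.append(residue)
        if residues:
            structure.chains[bio_chain.id] = residues

    if structure.n_atoms == 0:
        raise PDBFormatError(f"{path}: no ATOM records")
    keys = [res.key for res in structure.residues()]
    if len(keys) != len(set(keys)):
        raise PDBFormatError(f"{path}: duplicate residue identifiers")
    structure.metadata["hetero"] = hetero
    return structure


def write_pdb(structure: Structure, path: str | Path,
              remarks: Iterable[str] = ()) -> None:
    """Write a Structure as fixed-width PDB ATOM records (one model)."""
    lines: list[str] = []
    for remark in remarks:
        lines.append(f"REMARK 999 {remark}"[:80])
    serial = 1
    for chain_id, residues in structure.chains.items():
        for res in residues:
            for atom in res.atoms:
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                x, y, z = atom.position
                lines.append(
                    f"ATOM  {serial:>5d} {name:<4s} {res.res_type:>3s} "
                    f"{chain_id:1s}{res.seq_id:>4d}{res.insertion_code or ' ':1s}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{0.0:6.2f}          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def extract_sequence(structure: Structure, chain: str | None = None) -> str:
    """One-letter sequence of a chain in residue order (UNK → 'X').

    Chain breaks (gaps in author numbering) are not inserted as gap
    characters; use :func:`chain_breaks` to locate them.  An empty/omitted
    chain id on a single-chain structure selects that chain.
    """
    chain = _resolve_chain(structure, chain)
    return "".join(res.one_letter for res in structure.chains[chain])


def chain_breaks(structure: Structure, chain: str | None = None) -> list[tuple[int, int]]:
    """(seq_id before, seq_id after) pairs where author numbering jumps."""
    chain = _resolve_chain(structure, chain)
    residues = structure.chains[chain]
    breaks = []
    for prev, nxt in zip(residues, residues[1:]):
        if not prev.insertion_code and not nxt.insertion_code \
                and nxt.seq_id - prev.seq_id > 1:
            breaks.append((prev.seq_id, nxt.seq_id))
    return breaks


def _resolve_chain(structure: Structure, chain: str | None) -> str:
    if not chain:
        if len(structure.chains) != 1:
            raise KeyError(
                f"chain id required: structure has chains {sorted(structure.chains)}")
        chain = next(iter(structure.chains))
        logger.info("no chain requested; using single chain %r", chain)
    if chain not in structure.chains:
        raise KeyError(f"chain {chain!r} not in {sorted(structure.chains)}")
    return chain


# ---------------------------------------------------------------------------
# Newick trees (dendropy carrier)

def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise NewickValidationError("duplicate leaf labels")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            if not np.isfinite(edge.length):
                raise NewickValidationError("non-finite branch length")
            if edge.length < 0:
                raise NewickValidationError(
                    f"negative branch length {edge.length}")
    if not tree.is_rooted:
        logger.info("unrooted tree: rooting at the first internal node")
        tree.is_rooted = True
    return tree


def read_newick(path: str | Path) -> dendropy.Tree | list[dendropy.Tree]:
    """Read one or more Newick trees (one per line).

    Returns a single tree for a one-tree file, otherwise a list.  Unrooted
    trees are rooted at the first internal node with a logged notice;
    negative branch lengths raise :class:`NewickValidationError`.
    """
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    if len(trees) == 0:
        raise NewickValidationError(f"{path}: no trees found")
    validated = [_validate_tree(t) for t in trees]
    return validated[0] if len(validated) == 1 else validated


def write_newick(trees: dendropy.Tree | Iterable[dendropy.Tree],
                 path: str | Path) -> None:
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    with open(path, "w") as handle:
        for tree in trees:
            handle.write(tree.as_string(schema="newick",
                                        suppress_rooting=True))


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id, in file order."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns."""
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
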