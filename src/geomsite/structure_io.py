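"""Structure parsing, residue graphs, and binding-residue labeling.

A protein chain is reduced to five points per residue — the backbone N,
CA (C-alpha), C and O atoms plus R, the centroid of the heavy sidechain
atoms — giving a coordinate matrix of shape ``(n, 5, 3)`` in Angstroms.
This module reads PDB/mmCIF files into that representation, builds the
C-alpha radius graph used for message passing, and derives binding-residue
labels from protein-ligand complexes with the van-der-Waals contact rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger("geomsite")

#: order of the five points kept per residue
ATOM_ORDER = ("N", "CA", "C", "O", "R")

#: the ten ligand tasks, in the fixed task-axis order used everywhere
LIGAND_TYPES = ("DNA", "RNA", "peptide", "protein", "ATP", "HEM", "ZN", "CA", "MG", "MN")

#: metal-ion tasks (protein-level scores use a smaller top-k for these)
METAL_LIGANDS = frozenset({"ZN", "CA", "MG", "MN"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# common modified residues mapped to their parent standard residue
NONSTANDARD_MAP = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO", "SEP": "SER",
    "TPO": "THR", "PTR": "TYR", "CSO": "CYS", "MLY": "LYS", "M3L": "LYS",
    "KCX": "LYS", "CME": "CYS", "HIC": "HIS",
}

# Bondi-style van der Waals radii (Angstrom); fallback for unknowns is 1.7
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "ZN": 1.39, "CA": 2.31, "MG": 1.73, "MN": 1.97, "FE": 1.94,
    "CU": 1.40, "NI": 1.63, "CO": 1.92, "NA": 2.27, "K": 2.75,
}
FALLBACK_VDW = 1.7

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class StructureParseError(ValueError):
    """Unreadable or malformed structure file."""


class ChainNotFoundError(KeyError):
    """Requested chain id absent from the file."""


class EmptyStructureError(ValueError):
    """No residue survived the backbone-completeness filters."""


@dataclass
class ProteinStructure:
    """Five-point-per-residue representation of one protein chain.

    ``coords[i]`` holds the (N, CA, C, O, R) positions of residue ``i``;
    ``atoms[i]`` optionally retains all heavy atoms of that residue as
    ``(element, xyz)`` pairs for contact-based labeling.
    """

    chain_id: str
    sequence: str
    coords: np.ndarray  # (n, 5, 3)
    residue_ids: list[str]
    atoms: list[list[tuple[str, np.ndarray]]] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (5, 3):
            raise ValueError(f"coords must be (n, 5, 3), got {self.coords.shape}")
        if len(self.sequence) != self.coords.shape[0]:
            raise ValueError("sequence length does not match coords")
        if len(self.residue_ids) != self.coords.shape[0]:
            raise ValueError("residue_ids length does not match coords")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_residues

    @property
    def ca(self) -> np.ndarray:
        """(n, 3) array of C-alpha coordinates."""
        return self.coords[:, 1, :]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Rigid-body copy: ``x -> R x + t`` applied to every point."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        coords = self.coords @ rotation.T + translation
        atoms = None
        if self.atoms is not None:
            atoms = [
                [(el, xyz @ rotation.T + translation) for el, xyz in res]
                for res in self.atoms
            ]
        return ProteinStructure(self.chain_id, self.sequence, coords,
                                list(self.residue_ids), atoms)


@dataclass
class ResidueGraph:
    """Directed residue graph; edge ``(j, i)`` carries the message j -> i."""

    n_nodes: int
    edges: np.ndarray  # (E, 2) int array of (source j, target i)
    radius: float
    includes_self_loops: bool

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


@dataclass
class BindingAnnotation:
    """Per-residue binary labels for one ligand task of one protein."""

    ligand_type: str
    labels: np.ndarray  # (n,) int {0,1}; meaningful only if mask is True
    mask: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.mask and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


def sidechain_centroid(heavy_sidechain_atoms, ca) -> np.ndarray:
    """Arithmetic mean of the heavy sidechain atoms; glycine (empty) -> CA."""
    ca = np.asarray(ca, dtype=np.float64)
    if not np.all(np.isfinite(ca)):
        raise ValueError("non-finite CA coordinate")
    atoms = np.asarray(heavy_sidechain_atoms, dtype=np.float64).reshape(-1, 3)
    if atoms.shape[0] == 0:
        return ca.copy()
    if not np.all(np.isfinite(atoms)):
        raise ValueError("non-finite sidechain coordinates")
    return atoms.mean(axis=0)


def _select_altloc(atom_group):
    """From a list of gemmi atoms sharing a name, pick one conformer.

    Highest occupancy wins; ties prefer altloc 'A' (then lexicographic).
    """
    return max(atom_group, key=lambda a: (a.occ, a.altloc in ("", "A"), a.altloc == "A"))


def _read_structure_file(path: str) -> gemmi.Structure:
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse structure file {path!r}: {exc}") from exc
    st.setup_entities()
    return st


def parse_structure(path: str, chain: str | None = None,
                    keep_atoms: bool = True) -> ProteinStructure:
    """Parse one chain of a PDB or mmCIF file into a :class:`ProteinStructure`.

    Residues missing any of N/CA/C/O are dropped with a warning. Modified
    residues with a known parent (e.g. MSE) are renamed; unknown ones are
    dropped. HETATM ligands and waters never enter the protein chain.
    """
    st = _read_structure_file(path)
    if len(st) == 0:
        raise StructureParseError(f"no models in {path!r}")
    model = st[0]
    chain_ids = [ch.name for ch in model]
    if chain is None:
        if not chain_ids:
            raise EmptyStructureError(f"no chains in {path!r}")
        chain = chain_ids[0]
    if chain not in chain_ids:
        raise ChainNotFoundError(f"chain {chain!r} not in {chain_ids}")

    seq: list[str] = []
    coords: list[np.ndarray] = []
    residue_ids: list[str] = []
    all_atoms: list[list[tuple[str, np.ndarray]]] = []
    for res in model[chain]:
        name = res.name.upper()
        if name in NONSTANDARD_MAP:
            name = NONSTANDARD_MAP[name]
        if name not in THREE_TO_ONE:
            if res.is_water() or res.het_flag == "H":
                continue
            logger.warning("dropping unmapped residue %s %s", res.name, res.seqid)
            continue
        # collapse altlocs: best conformer per atom name
        by_name: dict[str, list] = {}
        for atom in res:
            if atom.element.name == "H" or atom.name.startswith("H"):
                continue
            by_name.setdefault(atom.name, []).append(atom)
        picked = {n: _select_altloc(g) for n, g in by_name.items()}
        if not all(a in picked for a in ("N", "CA", "C", "O")):
            logger.warning("dropping residue %s%s (incomplete backbone)",
                           res.seqid.num, res.seqid.icode.strip())
            continue
        pos = {n: np.array([a.pos.x, a.pos.y, a.pos.z]) for n, a in picked.items()}
        side = [pos[n] for n in picked if n not in BACKBONE_ATOMS]
        r = sidechain_centroid(side, pos["CA"])
        coords.append(np.stack([pos["N"], pos["CA"], pos["C"], pos["O"], r]))
        seq.append(THREE_TO_ONE[name])
        residue_ids.append(f"{res.seqid.num}{res.seqid.icode.strip()}")
        if keep_atoms:
            all_atoms.append([(picked[n].element.name.upper(), pos[n]) for n in picked])

    if not coords:
        raise EmptyStructureError(f"no complete residues in chain {chain!r} of {path!r}")
    return ProteinStructure(
        chain_id=chain,
        sequence="".join(seq),
        coords=np.stack(coords),
        residue_ids=residue_ids,
        atoms=all_atoms if keep_atoms else None,
    )


_ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def write_structure(structure: ProteinStructure, path: str) -> None:
    """Write the five-point representation as a PDB file.

    Backbone atoms are written verbatim; the sidechain centroid R is written
    as a CB pseudo-atom unless it coincides with CA (glycine convention), so
    a parse -> write -> parse round trip reproduces the coordinates.
    """
    st = gemmi.Structure()
    st.name = "geomsite"
    model = gemmi.Model("1")
    ch = gemmi.Chain(structure.chain_id or "A")
    for i, aa in enumerate(structure.sequence):
        rid = structure.residue_ids[i]
        num = int("".join(c for c in rid if c.isdigit() or c == "-") or i + 1)
        icode = "".join(c for c in rid if c.isalpha())
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(aa, "ALA")
        res.seqid = gemmi.SeqId(num, icode or " ")
        names = ["N", "CA", "C", "O"]
        pts = [structure.coords[i, k] for k in range(4)]
        r = structure.coords[i, 4]
        if np.linalg.norm(r - structure.coords[i, 1]) > 1e-9:
            names.append("CB")
            pts.append(r)
        for name, p in zip(names, pts):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(*p)
            atom.occ = 1.0
            res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.write_pdb(str(path))


def build_radius_graph(structure: ProteinStructure, radius: float = 15.0,
                       self_loops: bool = True) -> ResidueGraph:
    """C-alpha radius graph: directed edge (j, i) iff ``|CA_i - CA_j| < radius``.

    The distance test is strictly ``<``. Self-loops (i, i) are appended when
    requested; the attention update sums over N(i) and i itself.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    ca = structure.ca
    n = ca.shape[0]
    tree = cKDTree(ca)
    # query_pairs uses <=; shrink by epsilon-free exact filter afterwards
    pairs = np.array(sorted(tree.query_pairs(radius)), dtype=np.int64).reshape(-1, 2)
    if pairs.size:
        d = np.linalg.norm(ca[pairs[:, 0]] - ca[pairs[:, 1]], axis=1)
        pairs = pairs[d < radius]
    edges = np.concatenate([pairs, pairs[:, ::-1]], axis=0) if pairs.size else np.empty((0, 2), np.int64)
    if self_loops:
        loops = np.stack([np.arange(n)] * 2, axis=1)
        edges = np.concatenate([edges, loops], axis=0)
    # sort by target then source for a reproducible edge ordering
    if edges.size:
        order = np.lexsort((edges[:, 0], edges[:, 1]))
        edges = edges[order]
    return ResidueGraph(n_nodes=n, edges=edges, radius=radius,
                        includes_self_loops=self_loops)


def vdw_radius(element: str, strict: bool = False) -> float:
    el = element.upper()
    if el in VDW_RADII:
        return VDW_RADII[el]
    if strict:
        raise KeyError(f"no van der Waals radius for element {element!r}")
    logger.warning("unknown element %r; using fallback vdW radius %.2f A",
                   element, FALLBACK_VDW)
    return FALLBACK_VDW


def label_binding_residues(protein: ProteinStructure, ligand_atoms,
                           strict_elements: bool = False) -> np.ndarray:
    """Binary binding labels by the vdW contact rule.

    A residue is a binding residue iff some heavy-atom pair (one atom in the
    residue, one in the ligand) is closer than the sum of the two atoms' van
    der Waals radii plus 0.5 A (strict ``<``). Hydrogens are ignored.
    """
    if protein.atoms is None:
        raise ValueError("protein was parsed without atom records (keep_atoms=False)")
    ligand_atoms = [(el, np.asarray(xyz, float)) for el, xyz in ligand_atoms
                    if el.upper() != "H"]
    labels = np.zeros(protein.n_residues, dtype=np.int64)
    if not ligand_atoms:
        return labels
    lig_xyz = np.stack([xyz for _, xyz in ligand_atoms])
    lig_r = np.array([vdw_radius(el, strict_elements) for el, _ in ligand_atoms])
    for i, res_atoms in enumerate(protein.atoms):
        heavy = [(el, xyz) for el, xyz in res_atoms if el.upper() != "H"]
        if not heavy:
            continue
        res_xyz = np.stack([xyz for _, xyz in heavy])
        res_r = np.array([vdw_radius(el, strict_elements) for el, _ in heavy])
        d = np.linalg.norm(res_xyz[:, None, :] - lig_xyz[None, :, :], axis=2)
        thr = res_r[:, None] + lig_r[None, :] + 0.5
        if np.any(d < thr):
            labels[i] = 1
    return labels


def extract_ligand_atoms(path: str, ligand_chain: str | None = None,
                         ligand_name: str | None = None):
    """Heavy atoms of HETATM ligand residues as ``(element, xyz)`` pairs.

    Filter by chain id and/or residue name (e.g. ATP, HEM, ZN); waters are
    always excluded.
    """
    st = _read_structure_file(path)
    out = []
    for ch in st[0]:
        if ligand_chain is not None and ch.name != ligand_chain:
            continue
        for res in ch:
            if res.is_water():
                continue
            if res.name.upper() in NONSTANDARD_MAP or res.name.upper() in THREE_TO_ONE:
                continue
            if ligand_name is not None and res.name.upper() != ligand_name.upper():
                continue
            for atom in res:
                el = atom.element.name.upper()
                if el == "H":
                    continue
                out.append((el, np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
    return out


def residue_table(structure: ProteinStructure, columns: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-residue table (chain, residue_id, aa, one column per ligand task)."""
    data = {
        "chain": [structure.chain_id] * structure.n_residues,
        "residue_id": list(structure.residue_ids),
        "aa": list(structure.sequence),
    }
    for name, values in columns.items():
        values = np.asarray(values)
        if values.shape[0] != structure.n_residues:
            raise ValueError(f"column {name!r} length mismatch")
        data[name] = values
    return pd.DataFrame(data)


def write_residue_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_residue_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"residue_id": str})
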