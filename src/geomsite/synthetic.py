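"""Synthetic structures with planted, geometry-determined binding sites.

The generator builds chemically plausible backbones (ideal bond lengths
and fold-specific torsions via natural-extension-of-reference-frame
placement), adds a sidechain-centroid pseudo-atom per residue, and plants
featureless ligand probe atoms next to geometrically distinctive residues.
A residue is labeled binding when any of its five points lies within the
rule radius of a probe. Because probe anchors are chosen by deterministic
predicates on the backbone conformation (secondary-structure runs and run
boundaries), the labels are a function of geometry that a
structure-aware model can learn but a sequence-only model cannot.
Per-(protein, task) annotation masks emulate partially labeled
multi-task data.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .structure_io import (BindingAnnotation, LIGAND_TYPES, ProteinStructure,
                           residue_table, write_residue_table, write_structure)

logger = logging.getLogger("geomsite")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ideal backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5

TORSIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
}


class GenerationError(RuntimeError):
    """The generator could not satisfy its label constraints."""


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic multi-task binding-site dataset."""

    n_proteins: int = 200
    length_range: tuple[int, int] = (30, 100)
    fold: str = "mixed"               # helix | strand | coil | mixed
    n_tasks: int = 3
    probe_count: int | None = None    # None: one probe per anchor residue
    probe_offset: float = 6.5         # A outward from the sidechain centroid
    rule_radius: float = 8.0          # A labeling radius around each probe
    mask_density: float = 0.7         # P(task annotated for a protein)
    noise: float = 0.05               # coordinate jitter sigma, A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < 5:
            raise ValueError("minimum length is 5")
        if self.rule_radius <= 0:
            raise ValueError("rule_radius must be positive")
        if not 0 <= self.mask_density <= 1:
            raise ValueError("mask_density must be in [0, 1]")

    def task_names(self) -> list[str]:
        return [LIGAND_TYPES[i % len(LIGAND_TYPES)] for i in range(self.n_tasks)]


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given a-b-c with |c-d| = bond, angle(b,c,d) and
    torsion(a,b,c,d)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(tor),
                        bond * np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _sample_torsions(length: int, fold: str, rng: np.random.Generator):
    """(phi, psi) per residue, degrees; mixed folds alternate helix and
    extended runs so every chain carries both basins."""
    phi = np.empty(length)
    psi = np.empty(length)
    if fold in TORSIONS:
        p, s = TORSIONS[fold]
        phi[:], psi[:] = p, s
        phi += rng.normal(0, 3, length)
        psi += rng.normal(0, 3, length)
    elif fold == "coil":
        phi[:] = rng.uniform(-160, -50, length)
        psi[:] = rng.uniform(-60, 160, length)
    elif fold == "mixed":
        i = 0
        kind = "helix" if rng.random() < 0.5 else "strand"
        while i < length:
            run = int(rng.integers(6, 15)) if kind == "helix" else int(rng.integers(4, 11))
            run = min(run, length - i)
            p, s = TORSIONS[kind]
            phi[i:i + run] = p + rng.normal(0, 4, run)
            psi[i:i + run] = s + rng.normal(0, 4, run)
            i += run
            kind = "strand" if kind == "helix" else "helix"
    else:
        raise ValueError(f"unknown fold {fold!r}")
    return phi, psi


def generate_backbone(length: int, fold: str = "mixed", seed: int = 0,
                      noise: float = 0.0, chain_id: str = "A") -> ProteinStructure:
    """Build one chain with ideal covalent geometry and fold torsions.

    N/CA/C are placed by sequential natural-extension; O sits in the
    peptide plane anti to the next amide nitrogen; R lies along the
    pseudo-C-beta direction at 1.5-2.5 A from CA (R = CA for glycine).
    """
    if length < 5:
        raise ValueError("length must be >= 5")
    rng = np.random.default_rng(seed)
    phi, psi = _sample_torsions(length, fold, rng)
    omega = 180.0 + rng.normal(0, 2, length)

    N = np.empty((length, 3))
    CA = np.empty((length, 3))
    C = np.empty((length, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(length - 1):
        N[i + 1] = _nerf(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi[i])
        CA[i + 1] = _nerf(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, omega[i])
        C[i + 1] = _nerf(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi[i + 1])

    O = np.empty((length, 3))
    for i in range(length):
        # carbonyl O anti to the following amide N (psi - 180 torsion)
        O[i] = _nerf(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi[i] - 180.0)

    sequence = "".join(rng.choice(list(AMINO_ACIDS)) for _ in range(length))
    R = np.empty((length, 3))
    r_dist = rng.uniform(1.5, 2.5, length)
    for i in range(length):
        if sequence[i] == "G":
            R[i] = CA[i]
            continue
        d1 = N[i] - CA[i]
        d2 = C[i] - CA[i]
        d1 /= np.linalg.norm(d1)
        d2 /= np.linalg.norm(d2)
        bis = -(d1 + d2)
        bis /= np.linalg.norm(bis)
        perp = np.cross(d2, d1)
        perp /= np.linalg.norm(perp)
        direction = bis * np.cos(np.radians(54.0)) + perp * np.sin(np.radians(54.0))
        R[i] = CA[i] + r_dist[i] * direction

    coords = np.stack([N, CA, C, O, R], axis=1)
    if noise > 0:
        coords = coords + rng.normal(0, noise, coords.shape)
    return ProteinStructure(
        chain_id=chain_id, sequence=sequence, coords=coords,
        residue_ids=[str(i + 1) for i in range(length)],
    )


# ---------------------------------------------------------------------------
# geometry-determined probe anchors
# ---------------------------------------------------------------------------

def _backbone_states(structure: ProteinStructure) -> np.ndarray:
    """Coarse per-residue conformation labels (H / E / C) from torsions."""
    from .residue_features import _fallback_ss, SS8_STATES
    onehot = _fallback_ss(structure)
    idx = onehot.argmax(axis=1)
    return np.array([SS8_STATES[k] for k in idx])


def _anchor_residues(structure: ProteinStructure, task: int) -> np.ndarray:
    """Deterministic geometric predicate selecting probe anchor residues.

    Task predicates cycle through: strand-interior residues; helix residues
    at a run boundary; helix-interior residues. All are functions of the
    backbone conformation alone.
    """
    states = _backbone_states(structure)
    n = len(states)
    is_h = states == "H"
    is_e = states == "E"
    boundary = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - 2), min(n, i + 3)
        boundary[i] = len(set(states[lo:hi])) > 1
    kind = task % 3
    if kind == 0:
        sel = is_e & ~boundary
    elif kind == 1:
        sel = is_h & boundary
    else:
        sel = is_h & ~boundary
    return np.flatnonzero(sel)


def plant_binding_site(structure: ProteinStructure, task: int,
                       probe_count: int | None = None,
                       rule_radius: float = 8.0,
                       seed: int = 0,
                       probe_offset: float = 6.5,
                       max_resample: int = 100):
    """Plant probe pseudo-atoms and derive per-residue binary labels.

    Probes sit ``probe_offset`` A outward from each anchor residue's
    sidechain centroid (with seeded jitter); a residue is positive iff the
    minimum distance from its five points to any probe is below
    ``rule_radius`` (strict). Guarantees at least one positive and one
    negative label, re-jittering up to ``max_resample`` times.
    """
    if structure.n_residues == 0:
        raise ValueError("empty structure")
    rng = np.random.default_rng(seed)
    anchors = _anchor_residues(structure, task)
    if anchors.size == 0:
        anchors = rng.choice(structure.n_residues, size=1)
    if probe_count is not None and probe_count < anchors.size:
        # deterministic thinning: evenly spaced anchors along the chain
        anchors = anchors[np.linspace(0, anchors.size - 1, probe_count).astype(int)]

    X = structure.coords
    center = X[:, 1].mean(axis=0)
    for _ in range(max_resample):
        probes = []
        for a in anchors:
            r = X[a, 4]
            direction = r - X[a, 1]
            if np.linalg.norm(direction) < 1e-9:
                direction = r - center
            if np.linalg.norm(direction) < 1e-9:
                direction = np.array([0.0, 0.0, 1.0])
            direction = direction / np.linalg.norm(direction)
            probes.append(r + probe_offset * direction + rng.normal(0, 0.5, 3))
        probes = np.stack(probes)
        d = np.linalg.norm(X[:, :, None, :] - probes[None, None, :, :], axis=3)
        labels = (d.min(axis=(1, 2)) < rule_radius).astype(np.int64)
        if 0 < labels.sum() < len(labels):
            ann = BindingAnnotation(ligand_type=LIGAND_TYPES[task % len(LIGAND_TYPES)],
                                    labels=labels, mask=True)
            return ann, probes
    raise GenerationError(
        f"could not plant a mixed-label site for task {task} after {max_resample} tries")


@dataclass
class SyntheticProtein:
    name: str
    structure: ProteinStructure
    annotations: list[BindingAnnotation]   # one per task; mask False => unlabeled
    probes: dict[int, np.ndarray]

    @property
    def task_mask(self) -> np.ndarray:
        return np.array([a.mask for a in self.annotations], dtype=bool)

    def label_matrix(self) -> np.ndarray:
        """(n, T) labels with zeros in masked columns."""
        return np.stack([a.labels if a.mask else np.zeros(len(self.structure), np.int64)
                         for a in self.annotations], axis=1)


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    proteins: list[SyntheticProtein]

    def __len__(self) -> int:
        return len(self.proteins)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Reproducible dataset of structures, labels and task masks."""
    if spec.mask_density == 0:
        raise GenerationError(
            "mask_density 0 leaves every protein without an annotated task; "
            "each training protein needs at least one")
    rng = np.random.default_rng(spec.seed)
    proteins = []
    for p in range(spec.n_proteins):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        structure = generate_backbone(length, spec.fold,
                                      seed=int(rng.integers(2**31)),
                                      noise=spec.noise)
        mask = rng.random(spec.n_tasks) < spec.mask_density
        while not mask.any():
            mask = rng.random(spec.n_tasks) < spec.mask_density
        annotations = []
        probes = {}
        for t in range(spec.n_tasks):
            if mask[t]:
                ann, pr = plant_binding_site(
                    structure, t, probe_count=spec.probe_count,
                    rule_radius=spec.rule_radius,
                    seed=int(rng.integers(2**31)),
                    probe_offset=spec.probe_offset)
                probes[t] = pr
            else:
                ann = BindingAnnotation(
                    ligand_type=LIGAND_TYPES[t % len(LIGAND_TYPES)],
                    labels=np.zeros(length, np.int64), mask=False)
            annotations.append(ann)
        proteins.append(SyntheticProtein(name=f"synth{p:04d}", structure=structure,
                                         annotations=annotations, probes=probes))
    return SyntheticDataset(spec=spec, proteins=proteins)


def write_dataset(dataset: SyntheticDataset, out_dir: str) -> str:
    """Write PDB structures, per-task label TSVs and a training manifest.

    Returns the manifest path. The manifest has columns (name, structure,
    chain, then one label-file column per task, NA where unannotated); the
    spec is stored alongside as JSON for provenance.
    """
    import json
    os.makedirs(out_dir, exist_ok=True)
    tasks = dataset.spec.task_names()
    rows = []
    for prot in dataset.proteins:
        pdb_path = os.path.join(out_dir, f"{prot.name}.pdb")
        write_structure(prot.structure, pdb_path)
        row = {"name": prot.name, "structure": pdb_path,
               "chain": prot.structure.chain_id}
        for t, task in enumerate(tasks):
            ann = prot.annotations[t]
            if ann.mask:
                lab_path = os.path.join(out_dir, f"{prot.name}.{task}.labels.tsv")
                df = residue_table(prot.structure, {task: ann.labels})
                write_residue_table(df, lab_path)
                row[task] = lab_path
            else:
                row[task] = "NA"
        rows.append(row)
    manifest = os.path.join(out_dir, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    with open(os.path.join(out_dir, "spec.json"), "w") as fh:
        json.dump(asdict(dataset.spec), fh, indent=1)
    return manifest
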