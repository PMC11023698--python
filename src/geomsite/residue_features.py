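"""Per-residue non-geometric features.

Three ingredients feed the node representation besides backbone geometry:
a pluggable per-residue sequence embedding (a language-model matrix in
production, one-hot as the self-contained default), structural properties
(relative solvent accessibility and an 8-state secondary-structure
one-hot, from a DSSP file or a built-in geometric fallback), and min-max
normalization of the embedding block to [0, 1] with statistics fitted on
training data only.
"""

from __future__ import annotations

import hashlib
import logging
import subprocess
from dataclasses import dataclass

import h5py
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ProteinStructure

logger = logging.getLogger("geomsite")

#: fixed residue alphabet used by the one-hot provider
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: 8-state secondary structure order; '-'/' '/'C' all mean coil (index 7)
SS8_STATES = "HBEGITSC"

# Theoretical maximum accessible surface areas (A^2) per residue type
# (Tien et al. style theoretical values), used to turn ASA into RSA.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# radii for the five pseudo-atoms (N, CA, C, O, R) in the geometric fallback
_PSEUDO_RADII = np.array([1.55, 1.70, 1.70, 1.52, 2.00])


@dataclass
class NormalizationStats:
    """Per-feature min/max fitted on the training set (leakage guard:
    fitting and applying are separate calls)."""

    v_min: np.ndarray
    v_max: np.ndarray

    def __post_init__(self) -> None:
        self.v_min = np.atleast_1d(np.asarray(self.v_min, float))
        self.v_max = np.atleast_1d(np.asarray(self.v_max, float))
        if self.v_min.shape != self.v_max.shape:
            raise ValueError("v_min / v_max shape mismatch")
        if np.any(self.v_max < self.v_min):
            raise ValueError("v_max < v_min")

    @classmethod
    def fit(cls, values: np.ndarray) -> "NormalizationStats":
        values = np.asarray(values, float)
        return cls(v_min=values.min(axis=0), v_max=values.max(axis=0))

    def to_dict(self) -> dict:
        return {"v_min": self.v_min.tolist(), "v_max": self.v_max.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(np.asarray(d["v_min"]), np.asarray(d["v_max"]))


def minmax_normalize(values: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """(v - v_min) / (v_max - v_min), clipped to [0, 1].

    Values outside the training range are clipped; constant features
    (v_max == v_min) map to 0.
    """
    values = np.asarray(values, float)
    if values.shape[-1] != stats.v_min.shape[0]:
        raise ValueError(
            f"feature width {values.shape[-1]} != stats width {stats.v_min.shape[0]}")
    span = stats.v_max - stats.v_min
    out = np.zeros_like(values)
    np.divide(values - stats.v_min, span, out=out, where=span > 0)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# embedding providers
# ---------------------------------------------------------------------------

class EmbeddingProvider:
    """Contract: ``embed(sequence)`` returns a finite (n, dim) matrix."""

    name: str = "base"
    dim: int = 0

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, sequence: str) -> np.ndarray:
        out = np.asarray(self.embed(sequence), dtype=np.float64)
        if out.shape != (len(sequence), self.dim):
            raise ValueError(
                f"provider {self.name!r} returned {out.shape}, "
                f"expected ({len(sequence)}, {self.dim})")
        if not np.all(np.isfinite(out)):
            raise ValueError(f"provider {self.name!r} returned non-finite values")
        return out


class OneHotProvider(EmbeddingProvider):
    """20-dim one-hot rows; unknown residues get an all-zero row."""

    name = "onehot"
    dim = 20

    def embed(self, sequence: str) -> np.ndarray:
        return onehot_embedding(sequence)


class FileProvider(EmbeddingProvider):
    """Loads a precomputed dense matrix (.npy or whitespace TSV) per protein."""

    name = "file"

    def __init__(self, path: str, dim: int | None = None):
        self.path = str(path)
        if self.path.endswith(".npy"):
            self._matrix = np.load(self.path)
        else:
            self._matrix = np.loadtxt(self.path, dtype=np.float64, ndmin=2)
        self.dim = int(dim or self._matrix.shape[1])

    def embed(self, sequence: str) -> np.ndarray:
        if self._matrix.shape[0] != len(sequence):
            raise ValueError("embedding table rows != sequence length")
        return self._matrix


class ExternalCommandProvider(EmbeddingProvider):
    """Runs ``command <<< sequence`` and parses whitespace-separated rows."""

    name = "external-command"

    def __init__(self, command: list[str], dim: int):
        self.command = list(command)
        self.dim = int(dim)

    def embed(self, sequence: str) -> np.ndarray:
        proc = subprocess.run(self.command, input=sequence.encode(),
                              capture_output=True, check=True)
        return np.loadtxt(proc.stdout.decode().splitlines(), ndmin=2)


def get_provider(name: str, **kwargs) -> EmbeddingProvider:
    if name == "onehot":
        return OneHotProvider()
    if name == "file":
        return FileProvider(**kwargs)
    if name == "external-command":
        return ExternalCommandProvider(**kwargs)
    raise ValueError(f"unknown embedding provider {name!r}")


def onehot_embedding(sequence: str) -> np.ndarray:
    out = np.zeros((len(sequence), 20))
    for i, aa in enumerate(sequence):
        k = _AA_INDEX.get(aa.upper())
        if k is not None:
            out[i, k] = 1.0
    return out


class EmbeddingCache:
    """HDF5-backed embedding store keyed by provider name + sequence hash;
    a cache hit returns a bit-identical matrix."""

    def __init__(self, path: str):
        self.path = str(path)

    @staticmethod
    def key(provider_name: str, sequence: str) -> str:
        h = hashlib.sha256(sequence.encode()).hexdigest()
        return f"{provider_name}/{h}"

    def get_or_compute(self, provider: EmbeddingProvider, sequence: str) -> np.ndarray:
        key = self.key(provider.name, sequence)
        with h5py.File(self.path, "a") as f:
            if key in f:
                return f[key][()]
            emb = provider(sequence)
            f.create_dataset(key, data=emb)
            return emb


# ---------------------------------------------------------------------------
# structural properties: RSA + 8-state secondary structure
# ---------------------------------------------------------------------------

@dataclass
class StructuralProperties:
    rsa: np.ndarray        # (n,) in [0, 1]
    ss_onehot: np.ndarray  # (n, 8), rows sum to 1

    def __post_init__(self) -> None:
        self.rsa = np.asarray(self.rsa, float)
        self.ss_onehot = np.asarray(self.ss_onehot, float)
        if np.any(self.rsa < 0) or np.any(self.rsa > 1):
            raise ValueError("RSA outside [0, 1]")
        if not np.allclose(self.ss_onehot.sum(axis=1), 1.0):
            raise ValueError("secondary-structure rows must sum to 1")

    @property
    def matrix(self) -> np.ndarray:
        """(n, 9) block: RSA column followed by the SS one-hot."""
        return np.concatenate([self.rsa[:, None], self.ss_onehot], axis=1)


def ss8_onehot(states) -> np.ndarray:
    out = np.zeros((len(states), 8))
    for i, s in enumerate(states):
        s = (s or "C").upper()
        if s in ("-", " ", "P"):
            s = "C"
        out[i, SS8_STATES.index(s) if s in SS8_STATES else 7] = 1.0
    return out


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def shrake_rupley_asa(coords: np.ndarray, radii: np.ndarray,
                      n_points: int = 960, probe: float = 1.4) -> np.ndarray:
    """Per-atom accessible surface area by sphere-point sampling.

    Each atom's solvent-expanded sphere (radius + probe) is sampled with a
    golden-spiral lattice; a point is accessible if it lies outside every
    other atom's expanded sphere. ASA = accessible fraction * sphere area.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    m = coords.shape[0]
    pts = _sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    asa = np.zeros(m)
    max_r = expanded.max()
    for a in range(m):
        r = expanded[a]
        surf = coords[a] + r * pts
        neighbors = [b for b in tree.query_ball_point(coords[a], r + max_r) if b != a]
        free = np.ones(n_points, dtype=bool)
        for b in neighbors:
            d = np.linalg.norm(surf - coords[b], axis=1)
            free &= d >= expanded[b]
        asa[a] = 4.0 * np.pi * r * r * free.mean()
    return asa


def _fallback_ss(structure: ProteinStructure) -> np.ndarray:
    """Coarse 8-state assignment from backbone torsions (H/E/C populated)."""
    from .geometry import _dihedrals_vectorized  # local import avoids a cycle
    X = structure.coords
    n = X.shape[0]
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    if n > 1:
        phi[1:] = np.degrees(_dihedrals_vectorized(X[:-1, 2], X[1:, 0], X[1:, 1], X[1:, 2]))
        psi[:-1] = np.degrees(_dihedrals_vectorized(X[:-1, 0], X[:-1, 1], X[:-1, 2], X[1:, 0]))
    states = []
    for i in range(n):
        p, s = phi[i], psi[i]
        if np.isfinite(p) and np.isfinite(s) and -100 <= p <= -30 and -80 <= s <= -5:
            states.append("H")
        elif np.isfinite(p) and p < -90 and np.isfinite(s) and (s > 90 or s < -150):
            states.append("E")
        else:
            states.append("C")
    return ss8_onehot(states)


def structural_properties(structure: ProteinStructure,
                          dssp_path: str | None = None,
                          n_points: int = 960,
                          probe: float = 1.4) -> StructuralProperties:
    """RSA and SS8 one-hot, from a DSSP output file or the geometric fallback.

    The fallback estimates ASA with Shrake-Rupley sampling over the
    five-point pseudo-atoms and assigns H/E/C from backbone torsions; it is
    coarse but self-contained, requiring no external program.
    """
    if dssp_path is not None:
        return _properties_from_dssp(structure, dssp_path)
    coords = structure.coords.reshape(-1, 3)
    radii = np.tile(_PSEUDO_RADII, structure.n_residues)
    asa = shrake_rupley_asa(coords, radii, n_points=n_points, probe=probe)
    per_res = asa.reshape(structure.n_residues, 5).sum(axis=1)
    max_asa = np.array([MAX_ASA.get(a, 200.0) for a in structure.sequence])
    rsa = np.clip(per_res / max_asa, 0.0, 1.0)
    return StructuralProperties(rsa=rsa, ss_onehot=_fallback_ss(structure))


def _properties_from_dssp(structure: ProteinStructure, dssp_path: str) -> StructuralProperties:
    from Bio.PDB.DSSP import make_dssp_dict
    try:
        dssp, _ = make_dssp_dict(str(dssp_path))
    except Exception as exc:
        raise ValueError(f"cannot parse DSSP file {dssp_path!r}: {exc}") from exc
    rsa = np.zeros(structure.n_residues)
    states = []
    for i, rid in enumerate(structure.residue_ids):
        num = int("".join(c for c in rid if c.isdigit() or c == "-"))
        icode = "".join(c for c in rid if c.isalpha()) or " "
        key = (structure.chain_id, (" ", num, icode))
        if key not in dssp:
            raise ValueError(
                f"residue {rid} of chain {structure.chain_id!r} missing from DSSP output")
        aa, ss, acc = dssp[key][0], dssp[key][1], dssp[key][2]
        rsa[i] = min(float(acc) / MAX_ASA.get(structure.sequence[i], 200.0), 1.0)
        states.append(ss)
    return StructuralProperties(rsa=rsa, ss_onehot=ss8_onehot(states))
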