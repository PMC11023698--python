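"""SE(3)-invariant geometric featurization of residue graphs.

Every residue gets a local orthonormal frame built from its backbone
(N, CA, C) atoms; distances are expanded in Gaussian radial basis
functions, directions are expressed in the receiving residue's frame, and
relative frame rotations are encoded as unit quaternions. Because every
scalar is a distance, a frame-relative direction component, or an angle
function, the full feature set is invariant under rigid-body motion but
not under reflection (torsion signs and quaternions flip chirality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import ProteinStructure, ResidueGraph

logger = logging.getLogger("geomsite")

#: bump when the feature layout changes; checkpoints refuse mismatches
FEATURE_VERSION = "geomsite-features-1"

_ATOMS = ("N", "CA", "C", "O", "R")
# unordered intra-residue atom pairs, lexicographic in _ATOMS order
_NODE_PAIRS = [(a, b) for a in range(5) for b in range(a + 1, 5)]
# direction features use every atom except CA itself
_DIR_ATOMS = (0, 2, 3, 4)

DEGENERATE_EPS = 1e-8


class DegenerateFrameError(ValueError):
    """N, CA, C are collinear or coincident; no local frame exists."""


@dataclass
class RBFConfig:
    """Gaussian radial basis expansion of a scalar distance.

    Centers are evenly spaced on [0, d_max]; the width defaults to the
    center spacing so neighboring bases overlap at ~0.6 of their peak.
    """

    n_bases: int = 16
    d_max: float = 20.0
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.n_bases < 2:
            raise ValueError("need at least 2 bases")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if self.sigma is None:
            self.sigma = self.d_max / (self.n_bases - 1)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(0.0, self.d_max, self.n_bases)

    def to_dict(self) -> dict:
        return {"n_bases": self.n_bases, "d_max": self.d_max, "sigma": self.sigma}


@dataclass
class LocalFrame:
    origin: np.ndarray  # CA position
    Q: np.ndarray       # 3x3 rotation, columns [b, n, b x n]


@dataclass
class NodeGeometry:
    intra_distances: np.ndarray   # (10, n_bases)
    directions: np.ndarray        # (4, 3) frame-relative unit vectors
    angle_features: np.ndarray    # (12,) sin/cos of alpha,beta,gamma,phi,psi,omega


@dataclass
class EdgeGeometry:
    inter_distances: np.ndarray   # (5, 5, n_bases), [A of i, B of j]
    directions: np.ndarray        # (5, 3) atoms of j in frame of i
    orientation: np.ndarray       # (4,) unit quaternion (w, x, y, z)


def node_feature_dim(cfg: RBFConfig) -> int:
    return 10 * cfg.n_bases + 12 + 12


def edge_feature_dim(cfg: RBFConfig) -> int:
    return 25 * cfg.n_bases + 15 + 4


def rbf_encode(d, cfg: RBFConfig) -> np.ndarray:
    """Gaussian RBF expansion; component k is exp(-(d - c_k)^2 / (2 sigma^2))."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    diff = d[..., None] - cfg.centers
    return np.exp(-(diff ** 2) / (2.0 * cfg.sigma ** 2))


def _safe_unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalize; vectors shorter than the degeneracy epsilon become zero."""
    norm = np.linalg.norm(v, axis=axis, keepdims=True)
    out = np.divide(v, norm, out=np.zeros_like(v), where=norm > DEGENERATE_EPS)
    return out


def build_local_frame(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> LocalFrame:
    """Local frame of one residue from its N, CA, C atoms.

    u = CA - N, v = C - CA; b is the unit negative bisector of (u, v), the
    frame normal is u x v normalized, and Q = [b, n, b x n] columnwise.
    """
    n = np.asarray(n, float)
    ca = np.asarray(ca, float)
    c = np.asarray(c, float)
    u = ca - n
    v = c - ca
    cross = np.cross(u, v)
    if np.linalg.norm(cross) < DEGENERATE_EPS:
        raise DegenerateFrameError("N, CA, C are collinear or coincident")
    b = (u - v) / np.linalg.norm(u - v)
    nvec = cross / np.linalg.norm(cross)
    Q = np.stack([b, nvec, np.cross(b, nvec)], axis=1)
    return LocalFrame(origin=ca.copy(), Q=Q)


def build_frames(structure: ProteinStructure) -> tuple[np.ndarray, np.ndarray]:
    """Frames for all residues: (n, 3, 3) rotations + boolean degenerate flags.

    Degenerate residues (collinear backbone) get the identity frame and are
    flagged rather than raising, so malformed coordinates never crash a run.
    """
    X = structure.coords
    u = X[:, 1] - X[:, 0]
    v = X[:, 2] - X[:, 1]
    cross = np.cross(u, v)
    cnorm = np.linalg.norm(cross, axis=1)
    degenerate = cnorm < DEGENERATE_EPS
    if degenerate.any():
        logger.warning("%d residue(s) with degenerate local frame; identity used",
                       int(degenerate.sum()))
    b = _safe_unit(u - v)
    nvec = _safe_unit(cross)
    Q = np.stack([b, nvec, np.cross(b, nvec)], axis=2)
    Q[degenerate] = np.eye(3)
    return Q, degenerate


def quaternion_from_rotation(M: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) of a proper rotation matrix.

    The sign ambiguity q = -q is resolved by making the first nonzero
    component non-negative; 180-degree rotations (w = 0) are handled by the
    same rule.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.shape != (3, 3):
        raise ValueError("expected a 3x3 matrix")
    if np.max(np.abs(M.T @ M - np.eye(3))) > 1e-4 or abs(np.linalg.det(M) - 1) > 1e-4:
        raise ValueError("matrix is not a proper rotation")
    q = Rotation.from_matrix(M).as_quat()  # (x, y, z, w)
    q = np.array([q[3], q[0], q[1], q[2]])
    return _canonicalize_sign(q[None, :])[0]


def _canonicalize_sign(q: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip each quaternion so its first nonzero component is >= 0."""
    q = q / np.linalg.norm(q, axis=1, keepdims=True)
    nz = np.abs(q) > tol
    first = np.where(nz.any(axis=1), nz.argmax(axis=1), 0)
    sign = np.sign(q[np.arange(len(q)), first])
    sign[sign == 0] = 1.0
    return q * sign[:, None]


def _batch_quaternions(R: np.ndarray) -> np.ndarray:
    """(m, 3, 3) rotations -> (m, 4) canonical (w, x, y, z) quaternions."""
    if R.shape[0] == 0:
        return np.zeros((0, 4))
    q = Rotation.from_matrix(R).as_quat()
    q = np.concatenate([q[:, 3:4], q[:, :3]], axis=1)
    return _canonicalize_sign(q)


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b of the triple (a, b, c), in radians."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle of four points, in radians in (-pi, pi]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1          # IUPAC convention: eclipsed (cis) is 0
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    w = b0 - np.dot(b0, b1u) * b1u
    x = b2 - np.dot(b2, b1u) * b1u
    return float(np.arctan2(np.dot(np.cross(b1u, w), x), np.dot(w, x)))


def _angles_vectorized(a, b, c):
    u = a - b
    v = c - b
    num = (u * v).sum(-1)
    den = np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    return np.arccos(np.clip(num / np.maximum(den, 1e-12), -1.0, 1.0))


def _dihedrals_vectorized(p0, p1, p2, p3):
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = b1 / np.maximum(np.linalg.norm(b1, axis=-1, keepdims=True), 1e-12)
    w = b0 - (b0 * b1u).sum(-1, keepdims=True) * b1u
    x = b2 - (b2 * b1u).sum(-1, keepdims=True) * b1u
    return np.arctan2((np.cross(b1u, w) * x).sum(-1), (w * x).sum(-1))


def _node_angle_block(X: np.ndarray) -> np.ndarray:
    """(n, 12) sin/cos of (alpha, beta, gamma, phi, psi, omega).

    alpha_i = angle N-CA-C within i; beta_i = CA_i-C_i-N_{i+1};
    gamma_i = C_i-N_{i+1}-CA_{i+1}; phi/psi/omega are the backbone torsions.
    Angles needing a missing neighbor are encoded as (sin, cos) = (0, 0),
    a sentinel unreachable by any real angle.
    """
    n = X.shape[0]
    N, CA, C = X[:, 0], X[:, 1], X[:, 2]
    ang = np.zeros((n, 6))
    defined = np.zeros((n, 6), dtype=bool)
    ang[:, 0] = _angles_vectorized(N, CA, C)
    defined[:, 0] = True
    if n > 1:
        ang[:-1, 1] = _angles_vectorized(CA[:-1], C[:-1], N[1:])
        ang[:-1, 2] = _angles_vectorized(C[:-1], N[1:], CA[1:])
        ang[1:, 3] = _dihedrals_vectorized(C[:-1], N[1:], CA[1:], C[1:])    # phi
        ang[:-1, 4] = _dihedrals_vectorized(N[:-1], CA[:-1], C[:-1], N[1:])  # psi
        ang[:-1, 5] = _dihedrals_vectorized(CA[:-1], C[:-1], N[1:], CA[1:])  # omega
        defined[:-1, 1] = defined[:-1, 2] = True
        defined[1:, 3] = True
        defined[:-1, 4] = defined[:-1, 5] = True
    feats = np.zeros((n, 12))
    feats[:, 0::2] = np.where(defined, np.sin(ang), 0.0)
    feats[:, 1::2] = np.where(defined, np.cos(ang), 0.0)
    return feats


def node_geometry_matrix(structure: ProteinStructure, Q: np.ndarray,
                         cfg: RBFConfig) -> np.ndarray:
    """All per-residue geometric features, shape (n, 10*n_bases + 24)."""
    X = structure.coords
    n = X.shape[0]
    a_idx = [p[0] for p in _NODE_PAIRS]
    b_idx = [p[1] for p in _NODE_PAIRS]
    d = np.linalg.norm(X[:, a_idx] - X[:, b_idx], axis=2)       # (n, 10)
    rbf = rbf_encode(d, cfg).reshape(n, -1)
    w = X[:, _DIR_ATOMS] - X[:, 1:2]                             # (n, 4, 3)
    w = _safe_unit(w)
    dirs = np.einsum("nji,nkj->nki", Q, w).reshape(n, -1)        # Q^T w
    return np.concatenate([rbf, dirs, _node_angle_block(X)], axis=1)


def edge_geometry_matrix(structure: ProteinStructure, graph: ResidueGraph,
                         Q: np.ndarray, cfg: RBFConfig) -> np.ndarray:
    """Per-edge geometric features, shape (E, 25*n_bases + 19).

    Edge (j, i) is featurized in the frame of the receiving residue i:
    RBF distances for all 25 atom pairs (A of i) x (B of j), frame-i-relative
    unit directions of j's five atoms from CA_i, and the quaternion of
    Q_i^T Q_j. A self-loop (i, i) therefore yields a zero CA direction and
    the identity quaternion with no special-casing.
    """
    X = structure.coords
    E = graph.n_edges
    if E == 0:
        return np.zeros((0, edge_feature_dim(cfg)))
    j_idx = graph.edges[:, 0]
    i_idx = graph.edges[:, 1]
    Ai = X[i_idx]                                               # (E, 5, 3)
    Bj = X[j_idx]
    d = np.linalg.norm(Ai[:, :, None, :] - Bj[:, None, :, :], axis=3)
    rbf = rbf_encode(d, cfg).reshape(E, -1)
    w = _safe_unit(Bj - X[i_idx, 1][:, None, :])
    dirs = np.einsum("eji,ekj->eki", Q[i_idx], w).reshape(E, -1)
    rel = np.einsum("eji,ejk->eik", Q[i_idx], Q[j_idx])          # Q_i^T Q_j
    quat = _batch_quaternions(rel)
    return np.concatenate([rbf, dirs, quat], axis=1)


def node_geometry(structure: ProteinStructure, i: int, frames: np.ndarray,
                  cfg: RBFConfig) -> NodeGeometry:
    """Structured view of residue i's geometric features."""
    row = node_geometry_matrix(structure, frames, cfg)[i]
    nb = cfg.n_bases
    return NodeGeometry(
        intra_distances=row[: 10 * nb].reshape(10, nb),
        directions=row[10 * nb: 10 * nb + 12].reshape(4, 3),
        angle_features=row[10 * nb + 12:],
    )


def edge_geometry(structure: ProteinStructure, i: int, j: int,
                  frames: np.ndarray, cfg: RBFConfig) -> EdgeGeometry:
    """Structured geometric features of the directed edge j -> i."""
    g = ResidueGraph(n_nodes=structure.n_residues,
                     edges=np.array([[j, i]]), radius=np.inf,
                     includes_self_loops=(i == j))
    row = edge_geometry_matrix(structure, g, frames, cfg)[0]
    nb = cfg.n_bases
    return EdgeGeometry(
        inter_distances=row[: 25 * nb].reshape(5, 5, nb),
        directions=row[25 * nb: 25 * nb + 15].reshape(5, 3),
        orientation=row[25 * nb + 15:],
    )


@dataclass
class FeatureBundle:
    """Geometric node/edge features for one structure + its graph."""

    node_features: np.ndarray
    edge_features: np.ndarray
    edge_index: np.ndarray           # (E, 2) as (source j, target i)
    rbf_config: RBFConfig
    feature_version: str = FEATURE_VERSION
    degenerate_frames: np.ndarray | None = None


def featurize_structure(structure: ProteinStructure, graph: ResidueGraph,
                        cfg: RBFConfig | None = None) -> FeatureBundle:
    """End-to-end geometric featurization of a structure and its graph."""
    cfg = cfg or RBFConfig()
    Q, degenerate = build_frames(structure)
    return FeatureBundle(
        node_features=node_geometry_matrix(structure, Q, cfg),
        edge_features=edge_geometry_matrix(structure, graph, Q, cfg),
        edge_index=graph.edges.copy(),
        rbf_config=cfg,
        degenerate_frames=degenerate,
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
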