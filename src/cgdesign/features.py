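"""Rotation- and translation-invariant node and edge features.

Every geometric quantity is expressed either as a distance, a sequence
offset, or a vector/rotation measured in the per-residue local frame
``Q_i = [b, n, b x n]`` built from the backbone bond vectors
``u = CA - N`` and ``v = C - CA`` (b = (u-v)/|u-v|, n = (u x v)/|u x v|),
so the full feature bundle is invariant under rigid motions of the input
coordinates.

Default layout:

* node features, 88 dims per residue:
  4 unit vectors CA->{N, C, O, virtual CB} in the local frame (12),
  sin/cos of the three backbone bond angles and of omega/phi/psi (12),
  RBF-encoded distances CA->{N, C, O, virtual CB} (4 x 16 = 64);
* edge features, 1119 dims per directed edge (j -> i):
  25 inter-residue unit vectors between the 5 backbone atoms (incl. virtual
  CB) rotated into the target frame Q_i (75),
  all 8 x 8 interatomic distances (5 backbone + 3 learnable virtual atoms)
  RBF-encoded (64 x 16 = 1024),
  the unit quaternion of the relative rotation Q_i^T Q_j (4),
  a sinusoidal encoding of the signed sequence offset i - j (16).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import ContactGraph, virtual_cbeta
from .structures import BackboneStructure

RBF_DIM = 16
RBF_MIN = 2.0
RBF_MAX = 22.0
PE_DIM = 16
N_VIRTUAL_ATOMS = 3
NODE_FEATURE_DIM = 12 + 12 + 4 * RBF_DIM  # 88
EDGE_FEATURE_DIM = 75 + 64 * RBF_DIM + 4 + PE_DIM  # 1119

_DEGENERATE_EPS = 1e-8


def _unit(x: np.ndarray, axis: int = -1) -> np.ndarray:
    norm = np.linalg.norm(x, axis=axis, keepdims=True)
    return x / np.where(norm < _DEGENERATE_EPS, 1.0, norm)


def local_frames(structure: BackboneStructure) -> np.ndarray:
    """Per-residue orthonormal right-handed frames, shape (L, 3, 3).

    Columns are [b, n, b x n]. Degenerate geometry (collinear u, v) falls
    back to the identity frame for that residue.
    """
    u = structure.coords_CA - structure.coords_N
    v = structure.coords_C - structure.coords_CA
    b_raw = u - v
    n_raw = np.cross(u, v)
    b_norm = np.linalg.norm(b_raw, axis=1)
    n_norm = np.linalg.norm(n_raw, axis=1)
    degenerate = (b_norm < _DEGENERATE_EPS) | (n_norm < _DEGENERATE_EPS)
    b = _unit(b_raw)
    n = _unit(n_raw)
    frames = np.stack([b, n, np.cross(b, n)], axis=2)  # columns
    frames[degenerate | ~structure.mask] = np.eye(3)
    return frames


def rbf_encode(d: np.ndarray) -> np.ndarray:
    """Gaussian radial basis encoding of distances (any input shape).

    16 centers evenly spaced on [2, 22] A; width equal to the center
    spacing. Appends a trailing axis of size 16.
    """
    d = np.asarray(d, dtype=float)
    centers = np.linspace(RBF_MIN, RBF_MAX, RBF_DIM)
    sigma = (RBF_MAX - RBF_MIN) / (RBF_DIM - 1)
    return np.exp(-(((d[..., None] - centers) / sigma) ** 2))


def positional_encode(offset: np.ndarray) -> np.ndarray:
    """Sinusoidal encoding of signed sequence offsets, trailing 16-dim axis.

    Eight geometric frequencies; even slots are sines, odd slots cosines.
    """
    offset = np.asarray(offset, dtype=float)
    k = np.arange(PE_DIM // 2)
    freq = 1.0 / (10000.0 ** (2.0 * k / PE_DIM))
    angles = offset[..., None] * freq
    out = np.empty(offset.shape + (PE_DIM,))
    out[..., 0::2] = np.sin(angles)
    out[..., 1::2] = np.cos(angles)
    return out


def relative_quaternion(Q_i: np.ndarray, Q_j: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) of the relative rotation Q_i^T Q_j.

    Accepts single frames (3, 3) or stacks (..., 3, 3). The sign is fixed by
    w >= 0 (first nonzero component positive when w == 0).
    """
    R = np.swapaxes(np.asarray(Q_i), -1, -2) @ np.asarray(Q_j)
    single = R.ndim == 2
    R = R.reshape((-1, 3, 3))
    # Shepperd's method, branch chosen per matrix for numerical stability
    q = np.empty((R.shape[0], 4))
    for idx in range(R.shape[0]):
        m = R[idx]
        tr = np.trace(m)
        choices = np.array([tr, m[0, 0], m[1, 1], m[2, 2]])
        case = int(np.argmax(choices))
        if case == 0:
            s = np.sqrt(tr + 1.0) * 2
            q[idx] = [0.25 * s,
                      (m[2, 1] - m[1, 2]) / s,
                      (m[0, 2] - m[2, 0]) / s,
                      (m[1, 0] - m[0, 1]) / s]
        elif case == 1:
            s = np.sqrt(1.0 + m[0, 0] - m[1, 1] - m[2, 2]) * 2
            q[idx] = [(m[2, 1] - m[1, 2]) / s,
                      0.25 * s,
                      (m[0, 1] + m[1, 0]) / s,
                      (m[0, 2] + m[2, 0]) / s]
        elif case == 2:
            s = np.sqrt(1.0 + m[1, 1] - m[0, 0] - m[2, 2]) * 2
            q[idx] = [(m[0, 2] - m[2, 0]) / s,
                      (m[0, 1] + m[1, 0]) / s,
                      0.25 * s,
                      (m[1, 2] + m[2, 1]) / s]
        else:
            s = np.sqrt(1.0 + m[2, 2] - m[0, 0] - m[1, 1]) * 2
            q[idx] = [(m[1, 0] - m[0, 1]) / s,
                      (m[0, 2] + m[2, 0]) / s,
                      (m[1, 2] + m[2, 1]) / s,
                      0.25 * s]
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    for idx in range(q.shape[0]):
        nz = np.flatnonzero(np.abs(q[idx]) > 1e-12)
        if nz.size and q[idx, nz[0]] < 0:
            q[idx] = -q[idx]
    return q[0] if single else q.reshape(np.asarray(Q_i).shape[:-2] + (4,))


@dataclass
class VirtualAtomParams:
    """Learnable coefficients (x, y, z) of the three virtual atoms.

    Each atom sits at ``x*u + y*v + z*(u x v) + CA`` with the coefficient
    triple constrained to the unit sphere; :meth:`normalized` projects onto
    the constraint and is applied on every evaluation.
    """

    coeffs: np.ndarray  # (N_VIRTUAL_ATOMS, 3)

    @classmethod
    def initialize(cls, seed: int = 0) -> "VirtualAtomParams":
        rng = np.random.default_rng(seed)
        raw = rng.normal(size=(N_VIRTUAL_ATOMS, 3))
        return cls(coeffs=raw / np.linalg.norm(raw, axis=1, keepdims=True))

    def normalized(self) -> np.ndarray:
        coeffs = np.asarray(self.coeffs, dtype=float)
        norms = np.linalg.norm(coeffs, axis=1, keepdims=True)
        if np.any(norms < _DEGENERATE_EPS):
            raise ValueError("virtual-atom coefficient triple has zero norm")
        return coeffs / norms


def virtual_atom_positions(params: VirtualAtomParams,
                           structure: BackboneStructure) -> np.ndarray:
    """Positions of the learnable virtual atoms, shape (L, n_atoms, 3)."""
    coeffs = params.normalized()
    u = structure.coords_CA - structure.coords_N
    v = structure.coords_C - structure.coords_CA
    w = np.cross(u, v)
    basis = np.stack([u, v, w], axis=1)  # (L, 3, 3): rows u, v, uxv
    pos = np.einsum("ak,lkd->lad", coeffs, basis)
    return pos + structure.coords_CA[:, None, :]


def _dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle of p0-p1-p2-p3 (IUPAC sign convention)."""
    b0 = p0 - p1
    b1 = _unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.einsum("...d,...d->...", b0, b1)[..., None] * b1
    w = b2 - np.einsum("...d,...d->...", b2, b1)[..., None] * b1
    x = np.einsum("...d,...d->...", v, w)
    y = np.einsum("...d,...d->...", np.cross(b1, v), w)
    return np.arctan2(y, x)


def _bond_angle(a, b, c) -> np.ndarray:
    ba = _unit(a - b)
    bc = _unit(c - b)
    cosang = np.clip(np.einsum("...d,...d->...", ba, bc), -1.0, 1.0)
    return np.arccos(cosang)


def node_features(structure: BackboneStructure,
                  frames: np.ndarray | None = None) -> np.ndarray:
    """Per-residue invariant features, shape (L, 88). Masked rows are zero."""
    if frames is None:
        frames = local_frames(structure)
    L = structure.length
    CA = structure.coords_CA
    cb = virtual_cbeta(structure)
    cb = np.where(structure.mask[:, None], cb, CA)  # inert placeholder
    partners = [structure.coords_N, structure.coords_C, structure.coords_O, cb]

    vec_feats = np.zeros((L, 12))
    dist_feats = np.zeros((L, 4 * RBF_DIM))
    for a, X in enumerate(partners):
        w = X - CA
        local = np.einsum("lji,lj->li", frames, _unit(w))  # Q^T w
        vec_feats[:, 3 * a:3 * a + 3] = local
        dist_feats[:, RBF_DIM * a:RBF_DIM * (a + 1)] = rbf_encode(
            np.linalg.norm(w, axis=1))

    # angle features need i-1 / i+1; zero-filled at termini or masked gaps
    angle_feats = np.zeros((L, 12))
    prev_ok = np.zeros(L, dtype=bool)
    next_ok = np.zeros(L, dtype=bool)
    prev_ok[1:] = structure.mask[1:] & structure.mask[:-1]
    next_ok[:-1] = structure.mask[:-1] & structure.mask[1:]
    N, C = structure.coords_N, structure.coords_C

    idx = np.flatnonzero(prev_ok)
    if idx.size:
        ang = _bond_angle(C[idx - 1], N[idx], CA[idx])       # C(i-1)-N-CA
        omega = _dihedral(CA[idx - 1], C[idx - 1], N[idx], CA[idx])
        phi = _dihedral(C[idx - 1], N[idx], CA[idx], C[idx])
        angle_feats[idx, 0] = np.sin(ang)
        angle_feats[idx, 1] = np.cos(ang)
        angle_feats[idx, 6] = np.sin(omega)
        angle_feats[idx, 7] = np.cos(omega)
        angle_feats[idx, 8] = np.sin(phi)
        angle_feats[idx, 9] = np.cos(phi)
    idx = np.flatnonzero(structure.mask)
    if idx.size:
        ang = _bond_angle(N[idx], CA[idx], C[idx])            # N-CA-C
        angle_feats[idx, 2] = np.sin(ang)
        angle_feats[idx, 3] = np.cos(ang)
    idx = np.flatnonzero(next_ok)
    if idx.size:
        ang = _bond_angle(CA[idx], C[idx], N[idx + 1])        # CA-C-N(i+1)
        psi = _dihedral(N[idx], CA[idx], C[idx], N[idx + 1])
        angle_feats[idx, 4] = np.sin(ang)
        angle_feats[idx, 5] = np.cos(ang)
        angle_feats[idx, 10] = np.sin(psi)
        angle_feats[idx, 11] = np.cos(psi)

    out = np.concatenate([vec_feats, angle_feats, dist_feats], axis=1)
    out[~structure.mask] = 0.0
    return out


def edge_features(structure: BackboneStructure, graph: ContactGraph,
                  frames: np.ndarray | None = None,
                  params: VirtualAtomParams | None = None) -> np.ndarray:
    """Per-edge invariant features, shape (E, 1119).

    For the directed edge (j -> i) the unit vectors point from atoms of the
    source residue j to atoms of the target residue i and are expressed in
    the target frame Q_i; the sequence offset encoded is i - j.
    """
    if frames is None:
        frames = local_frames(structure)
    if params is None:
        params = VirtualAtomParams.initialize()
    cb = virtual_cbeta(structure)
    cb = np.where(structure.mask[:, None], cb, structure.coords_CA)
    backbone5 = np.stack(
        [structure.coords_N, structure.coords_CA, structure.coords_C,
         structure.coords_O, cb], axis=1)  # (L, 5, 3)
    vatoms = virtual_atom_positions(params, structure)  # (L, 3, 3)
    atoms8 = np.concatenate([backbone5, vatoms], axis=1)  # (L, 8, 3)

    src, dst = graph.src, graph.dst
    E = graph.n_edges
    if E == 0:
        return np.zeros((0, EDGE_FEATURE_DIM))

    # 25 unit vectors (5 backbone atoms each side) in the target frame
    diff5 = backbone5[dst][:, None, :, :] - backbone5[src][:, :, None, :]
    unit5 = _unit(diff5)  # (E, 5, 5, 3), [source atom, target atom]
    local = np.einsum("eji,estj->esti", frames[dst], unit5)
    vec_block = local.reshape(E, 75)

    # 8 x 8 interatomic distances, RBF-encoded
    diff8 = atoms8[dst][:, None, :, :] - atoms8[src][:, :, None, :]
    dists = np.linalg.norm(diff8, axis=-1)  # (E, 8, 8)
    dist_block = rbf_encode(dists).reshape(E, 64 * RBF_DIM)

    quat_block = relative_quaternion(frames[dst], frames[src])
    pe_block = positional_encode(dst.astype(float) - src.astype(float))

    return np.concatenate([vec_block, dist_block, quat_block, pe_block], axis=1)


@dataclass
class FeatureBundle:
    """Featurization output plus the configuration that produced it."""

    node: np.ndarray  # (L, NODE_FEATURE_DIM)
    edge: np.ndarray  # (E, EDGE_FEATURE_DIM)
    frames: np.ndarray  # (L, 3, 3)
    config: dict = field(default_factory=dict)

    def save(self, path) -> None:
        """Write to a compressed array container with a JSON config echo."""
        import json
        np.savez_compressed(path, node=self.node, edge=self.edge,
                            frames=self.frames,
                            config=json.dumps(self.config))

    @classmethod
    def load(cls, path) -> "FeatureBundle":
        import json
        with np.load(path, allow_pickle=False) as archive:
            return cls(node=archive["node"], edge=archive["edge"],
                       frames=archive["frames"],
                       config=json.loads(str(archive["config"])))


def featurize(structure: BackboneStructure, graph: ContactGraph,
              params: VirtualAtomParams | None = None) -> FeatureBundle:
    """Assemble the full invariant feature bundle for one structure."""
    frames = local_frames(structure)
    node = node_features(structure, frames)
    edge = edge_features(structure, graph, frames, params)
    return FeatureBundle(
        node=node, edge=edge, frames=frames,
        config={
            "node_dim": NODE_FEATURE_DIM,
            "edge_dim": EDGE_FEATURE_DIM,
            "rbf_dim": RBF_DIM,
            "pe_dim": PE_DIM,
            "n_virtual_atoms": N_VIRTUAL_ATOMS,
            "graph_mode": graph.mode,
            "cutoff": graph.cutoff,
            "k": graph.k,
        },
    )
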