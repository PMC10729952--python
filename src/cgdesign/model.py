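"""The contact-graph network: stacked edge-then-node update blocks.

Each block first refreshes every directed edge state from its endpoint nodes
(basic update), optionally enriched by the reverse edge (symmetric update)
and by two-hop edge compositions through shared neighbors (second-order
edges), merges the candidate updates with a selective kernel, and then
refreshes node states from attention over incoming edges plus a graph-wide
global context. Decoding is one-shot: a single forward pass emits 20-way
logits for every residue.

The three virtual atoms that enter the edge distance features are learnable;
their coefficient triples live on the unit sphere and gradients flow through
the distance-RBF encoding, so the initial featurization of those 39 atom
pairs is rebuilt inside :meth:`CgnnModel.forward` rather than cached.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, concat, segment_softmax, segment_sum, softmax
from .features import (EDGE_FEATURE_DIM, NODE_FEATURE_DIM, RBF_DIM, RBF_MAX,
                       RBF_MIN, N_VIRTUAL_ATOMS, VirtualAtomParams,
                       local_frames, node_features, positional_encode,
                       relative_quaternion, virtual_cbeta)
from .graph import ContactGraph, build_cgraph, build_knn
from .layers import MLP, FFN, Dropout, LayerNorm, Linear, Module
from .structures import BackboneStructure

#: value emitted in logit rows of masked residues
MASKED_LOGIT_SENTINEL = np.nan


@dataclass
class ModelConfig:
    """Architecture and graph-construction switches.

    The ablation rows of the architecture study are pure configurations:
    ``use_symmetric=False, use_soe=False`` is the basic-edge-update model;
    ``use_soe=True, use_symmetric=False`` keeps only second-order edges;
    ``use_sk_edges=False`` / ``use_sk_nodes=False`` replace the selective
    kernels with average pooling.
    """

    width: int = 128
    blocks: int = 10
    dropout: float = 0.1
    use_symmetric: bool = True
    use_soe: bool = True
    use_sk_edges: bool = True
    use_sk_nodes: bool = True
    graph_mode: str = "cgraph"  # "cgraph" | "knn"
    cutoff: float = 12.0
    k: int = 30
    n_classes: int = 20
    ffn_expansion: int = 2
    sk_reduction: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.blocks < 1:
            raise ValueError("width and blocks must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.graph_mode not in ("cgraph", "knn"):
            raise ValueError("graph_mode must be 'cgraph' or 'knn'")
        if self.graph_mode == "knn" and self.use_symmetric:
            raise ValueError(
                "symmetric edge updates need reverse edges, which a KNN "
                "graph does not guarantee; set use_symmetric=False")


class SelectiveKernel(Module):
    """Soft per-dimension gating across candidate update branches.

    The branch sum is squeezed by an MLP; per-branch excitation MLPs emit
    dimension-wise logits that a softmax across branches turns into weights
    summing to one per dimension.
    """

    def __init__(self, dim: int, n_branches: int, rng: np.random.Generator,
                 reduction: int = 2):
        d_sq = max(dim // reduction, 8)
        self.squeeze = MLP(dim, d_sq, rng)
        self.excite = [MLP(d_sq, dim, rng) for _ in range(n_branches)]

    def __call__(self, branches: list[Tensor]) -> Tensor:
        total = branches[0]
        for b in branches[1:]:
            total = total + b
        squeezed = self.squeeze(total)
        logits = [mlp(squeezed) for mlp in self.excite[:len(branches)]]
        shift = np.maximum.reduce([w.data for w in logits])
        exps = [(w - shift).exp() for w in logits]
        denom = exps[0]
        for z in exps[1:]:
            denom = denom + z
        merged = branches[0] * (exps[0] / denom)
        for f, z in zip(branches[1:], exps[1:]):
            merged = merged + f * (z / denom)
        return merged


def _average(branches: list[Tensor]) -> Tensor:
    total = branches[0]
    for b in branches[1:]:
        total = total + b
    return total / float(len(branches))


class EdgeBlock(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.width
        self.cfg = cfg
        self.mlp_basic = MLP(3 * d, d, rng, d_hidden=d)
        self.mlp_e2 = MLP(d, d, rng, d_hidden=d)
        if cfg.use_symmetric:
            self.mlp_sym = MLP(2 * d, d, rng, d_hidden=d)
        if cfg.use_soe:
            self.mlp_soe = MLP(3 * d, d, rng, d_hidden=d)
        n_branches = 1 + int(cfg.use_symmetric) + int(cfg.use_soe)
        if cfg.use_sk_edges:
            self.sk = SelectiveKernel(d, n_branches, rng, cfg.sk_reduction)
        self.norm1 = LayerNorm(d)
        self.norm2 = LayerNorm(d)
        self.ffn = FFN(d, rng, cfg.ffn_expansion)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, h: Tensor, e: Tensor, graph: "_CompactGraph",
                 rng, training: bool) -> Tensor:
        cfg = self.cfg
        ehat = self.mlp_basic(concat(
            [h.gather(graph.src), e, h.gather(graph.dst)], axis=-1))
        branches: list[Tensor] = []
        if cfg.use_symmetric:
            branches.append(self.mlp_sym(concat(
                [ehat, ehat.gather(graph.reverse_index)], axis=-1)))
        if cfg.use_soe:
            if graph.soe_edge.size:
                triples = self.mlp_soe(concat(
                    [ehat.gather(graph.soe_in), ehat.gather(graph.soe_out),
                     ehat.gather(graph.soe_edge)], axis=-1))
                sums = segment_sum(triples, graph.soe_edge, graph.n_edges)
                counts = np.maximum(graph.soe_counts, 1)[:, None]
                branches.append(sums / counts)
            else:
                branches.append(ehat * 0.0)
        branches.append(self.mlp_e2(ehat))
        merged = self.sk(branches) if cfg.use_sk_edges else _average(branches)
        e1 = self.norm1(e + self.drop(merged, rng, training))
        return self.norm2(e1 + self.drop(self.ffn(e1), rng, training))


class NodeBlock(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.width
        self.cfg = cfg
        self.mlp_q = MLP(d, d, rng, d_hidden=d)
        self.mlp_k = MLP(d, d, rng, d_hidden=d)
        self.mlp_v = MLP(3 * d, d, rng, d_hidden=d)
        self.mlp_gate = MLP(d, d, rng, d_hidden=d)
        self.mlp_gval = MLP(d, d, rng, d_hidden=d)
        self.mlp_gout = MLP(2 * d, d, rng, d_hidden=d)
        if cfg.use_sk_nodes:
            self.sk = SelectiveKernel(d, 2, rng, cfg.sk_reduction)
        self.norm1 = LayerNorm(d)
        self.norm2 = LayerNorm(d)
        self.ffn = FFN(d, rng, cfg.ffn_expansion)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, h: Tensor, e: Tensor, graph: "_CompactGraph",
                 rng, training: bool) -> Tensor:
        cfg = self.cfg
        n = graph.n_nodes
        # local: attention over incoming edges
        q = self.mlp_q(h)
        k = self.mlp_k(e)
        logits = (q.gather(graph.dst) * k).sum(axis=-1, keepdims=True)
        attn = segment_softmax(logits, graph.dst, n)
        values = self.mlp_v(concat(
            [h.gather(graph.src), e, h.gather(graph.dst)], axis=-1))
        h_local = segment_sum(attn * values, graph.dst, n)
        # global: per-dimension softmax over all nodes of the graph
        gate = softmax(self.mlp_gate(h), axis=0)
        gval = self.mlp_gval(h)
        G = (gate * gval).sum(axis=0, keepdims=True)
        G_rep = G.gather(np.zeros(n, dtype=int))
        h_global = self.mlp_gout(concat([h, G_rep], axis=-1))
        merged = (self.sk([h_local, h_global]) if cfg.use_sk_nodes
                  else _average([h_local, h_global]))
        h1 = self.norm1(h + merged)  # no dropout on this residual
        return self.norm2(h1 + self.drop(self.ffn(h1), rng, training))


@dataclass
class _CompactGraph:
    """Graph re-indexed over unmasked residues only."""

    n_nodes: int
    n_edges: int
    src: np.ndarray
    dst: np.ndarray
    reverse_index: np.ndarray
    soe_edge: np.ndarray
    soe_in: np.ndarray
    soe_out: np.ndarray
    soe_counts: np.ndarray


@dataclass
class EncodedStructure:
    """Cached constant featurization of one structure.

    Everything except the virtual-atom-dependent distance features is
    precomputed here; the 39 atom pairs that involve a learnable virtual atom
    are rebuilt differentiably at each forward pass from ``basis`` (the
    per-residue u/v/uxv frame) and the cached backbone atom positions.
    """

    structure: BackboneStructure
    graph: ContactGraph
    compact: _CompactGraph
    node_idx: np.ndarray  # original indices of unmasked residues
    node_const: np.ndarray  # (n, NODE_FEATURE_DIM)
    const_block: np.ndarray  # (E, 95): 75 unit vectors + quaternion + offset
    backbone5: np.ndarray  # (n, 5, 3)
    basis: np.ndarray  # (n, 3, 3) rows u, v, u x v
    ca: np.ndarray  # (n, 3)
    labels: np.ndarray | None  # (n,) int class labels or None


# column indices of the initial edge feature vector: the 8x8 RBF distance
# block (rows 75..1098) depends on the learnable virtual atoms, the rest
# (unit vectors, quaternion, positional encoding) is geometry-constant
_EDGE_PARAM_COLS = np.arange(75, 75 + 64 * RBF_DIM)
_EDGE_CONST_COLS = np.concatenate(
    [np.arange(75), np.arange(75 + 64 * RBF_DIM, EDGE_FEATURE_DIM)])


class CgnnModel(Module):
    """10-block (by default) contact-graph network with a 20-way head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.width
        self.virtual_atoms = Tensor(
            VirtualAtomParams.initialize(config.seed).coeffs,
            requires_grad=True)
        self.node_proj = Linear(NODE_FEATURE_DIM, d, rng)
        self.node_norm = LayerNorm(d)
        self.edge_proj = Linear(EDGE_FEATURE_DIM, d, rng)
        self.edge_norm = LayerNorm(d)
        self.edge_blocks = [EdgeBlock(config, rng) for _ in range(config.blocks)]
        self.node_blocks = [NodeBlock(config, rng) for _ in range(config.blocks)]
        self.head = MLP(d, config.n_classes, rng, d_hidden=d)

    # -- graph + constant featurization --------------------------------------
    def build_graph(self, structure: BackboneStructure) -> ContactGraph:
        if self.config.graph_mode == "cgraph":
            return build_cgraph(structure, cutoff=self.config.cutoff)
        return build_knn(structure, k=self.config.k)

    def encode_structure(self, structure: BackboneStructure,
                         ) -> EncodedStructure:
        graph = self.build_graph(structure)
        if self.config.use_symmetric and np.any(graph.reverse_index < 0):
            raise ValueError(
                "symmetric edge updates require a symmetric graph; "
                "set use_symmetric=False for KNN graphs")
        node_idx = np.flatnonzero(structure.mask)
        remap = -np.ones(structure.length, dtype=int)
        remap[node_idx] = np.arange(node_idx.size)
        compact = _CompactGraph(
            n_nodes=node_idx.size, n_edges=graph.n_edges,
            src=remap[graph.src], dst=remap[graph.dst],
            reverse_index=graph.reverse_index,
            soe_edge=graph.soe_edge, soe_in=graph.soe_in,
            soe_out=graph.soe_out, soe_counts=graph.soe_counts,
        )
        frames = local_frames(structure)
        node_const = node_features(structure, frames)[node_idx]

        cb = virtual_cbeta(structure)
        cb = np.where(structure.mask[:, None], cb, structure.coords_CA)
        backbone5_full = np.stack(
            [structure.coords_N, structure.coords_CA, structure.coords_C,
             structure.coords_O, cb], axis=1)
        src, dst = graph.src, graph.dst
        E = graph.n_edges
        if E:
            diff5 = backbone5_full[dst][:, None, :, :] - backbone5_full[src][:, :, None, :]
            norm = np.linalg.norm(diff5, axis=-1, keepdims=True)
            unit5 = diff5 / np.where(norm < 1e-8, 1.0, norm)
            vec_block = np.einsum("eji,estj->esti", frames[dst], unit5
                                  ).reshape(E, 75)
            quat = relative_quaternion(frames[dst], frames[src])
            pe = positional_encode(dst.astype(float) - src.astype(float))
            const_block = np.concatenate([vec_block, quat, pe], axis=1)
        else:
            const_block = np.zeros((0, 95))

        u = structure.coords_CA - structure.coords_N
        v = structure.coords_C - structure.coords_CA
        basis = np.stack([u, v, np.cross(u, v)], axis=1)

        labels = None
        if structure.native_seq is not None:
            from .constants import AA_INDEX
            labels = np.array(
                [AA_INDEX.get(structure.native_seq[i], -1) for i in node_idx],
                dtype=int)
        return EncodedStructure(
            structure=structure, graph=graph, compact=compact,
            node_idx=node_idx, node_const=node_const, const_block=const_block,
            backbone5=backbone5_full[node_idx],
            basis=basis[node_idx], ca=structure.coords_CA[node_idx],
            labels=labels,
        )

    # -- differentiable initial edge features --------------------------------
    def _virtual_positions(self, enc: EncodedStructure) -> list[Tensor]:
        """Per-virtual-atom positions as (n, 3) tensors (unit-sphere coeffs)."""
        positions = []
        for a in range(N_VIRTUAL_ATOMS):
            row = self.virtual_atoms.gather(np.array([a]))  # (1, 3)
            norm = (row ** 2).sum(axis=-1, keepdims=True).sqrt()
            unit_row = row / norm
            p = (unit_row @ enc.basis).reshape(enc.compact.n_nodes, 3)
            positions.append(p + enc.ca)
        return positions

    def _distance_rbf_tensor(self, enc: EncodedStructure) -> Tensor:
        """The 8x8 interatomic distance-RBF block, shape (E, 1024), with
        gradients flowing into the virtual-atom coefficients."""
        comp = enc.compact
        E = comp.n_edges
        centers = np.linspace(RBF_MIN, RBF_MAX, RBF_DIM)
        sigma = (RBF_MAX - RBF_MIN) / (RBF_DIM - 1)
        vpos = self._virtual_positions(enc)

        def atoms8(idx: np.ndarray) -> Tensor:
            parts = [Tensor(enc.backbone5[idx].reshape(E, 15))]
            parts += [p.gather(idx) for p in vpos]
            return concat(parts, axis=-1).reshape(E, 8, 3)

        a_src = atoms8(comp.src).reshape(E, 8, 1, 3)
        a_dst = atoms8(comp.dst).reshape(E, 1, 8, 3)
        diff = a_dst - a_src  # (E, 8 source, 8 target, 3)
        d = ((diff ** 2).sum(axis=-1, keepdims=True) + 1e-12).sqrt()
        rbf = (-(((d - centers) / sigma) ** 2)).exp()  # (E, 8, 8, 16)
        return rbf.reshape(E, 64 * RBF_DIM)

    def _initial_edge_state(self, enc: EncodedStructure) -> Tensor:
        """Project the 1119-dim initial edge features to model width.

        The projection weight is split by feature column: geometry-constant
        columns multiply a cached block, the virtual-atom-dependent distance
        columns multiply the differentiable RBF block.
        """
        W = self.edge_proj.weight
        out = (Tensor(enc.const_block) @ W.gather(_EDGE_CONST_COLS)
               + self._distance_rbf_tensor(enc) @ W.gather(_EDGE_PARAM_COLS)
               + self.edge_proj.bias)
        return self.edge_norm(out)

    # -- forward --------------------------------------------------------------
    def forward_encoded(self, enc: EncodedStructure,
                        rng: np.random.Generator | None = None,
                        training: bool = False) -> Tensor:
        """Logits for the unmasked residues of one encoded structure, (n, 20)."""
        h = self.node_norm(self.node_proj(Tensor(enc.node_const)))
        e = self._initial_edge_state(enc)
        for edge_block, node_block in zip(self.edge_blocks, self.node_blocks):
            e = edge_block(h, e, enc.compact, rng, training)
            h = node_block(h, e, enc.compact, rng, training)
        return self.head(h)

    def forward(self, structure: BackboneStructure,
                rng: np.random.Generator | None = None,
                training: bool = False) -> np.ndarray:
        """One-shot logits, shape (L, 20); masked rows carry NaN sentinels."""
        enc = self.encode_structure(structure)
        logits = self.forward_encoded(enc, rng, training)
        out = np.full((structure.length, self.config.n_classes),
                      MASKED_LOGIT_SENTINEL)
        out[enc.node_idx] = logits.data
        return out

    # -- reporting and persistence -------------------------------------------
    def describe(self) -> str:
        lines = [f"{'module':<28}{'parameters':>12}"]
        groups = [
            ("virtual_atoms", self.virtual_atoms.data.size),
            ("node projection", self.node_proj.n_parameters()
             + self.node_norm.n_parameters()),
            ("edge projection", self.edge_proj.n_parameters()
             + self.edge_norm.n_parameters()),
        ]
        for i, (eb, nb) in enumerate(zip(self.edge_blocks, self.node_blocks)):
            groups.append((f"block {i} (edge)", eb.n_parameters()))
            groups.append((f"block {i} (node)", nb.n_parameters()))
        groups.append(("output head", self.head.n_parameters()))
        for name, count in groups:
            lines.append(f"{name:<28}{count:>12,}")
        lines.append(f"{'total':<28}{self.n_parameters():>12,}")
        return "\n".join(lines)

    def save(self, path) -> None:
        arrays = {f"param_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, config=json.dumps(asdict(self.config)),
                 format_version="1", **arrays)

    @classmethod
    def load(cls, path) -> "CgnnModel":
        with np.load(path, allow_pickle=False) as archive:
            config = ModelConfig(**json.loads(str(archive["config"])))
            model = cls(config)
            arrays = [archive[f"param_{i}"]
                      for i in range(len(model.parameters()))]
        model.load_state_arrays(arrays)
        return model
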