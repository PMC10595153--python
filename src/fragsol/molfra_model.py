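"""The MolFra fragment-pair attention network for logS regression.

One siamese network embeds both fragments of every pair.  Per fragment:
atom states are initialized by a linear projection of the 40-d atom features
(neighbor messages in layer 1 additionally carry the 10-d bond features of
the connecting edge, projected from the 50-d concatenation); a stack of
graph-attention layers aggregates 1-hop messages with per-target softmax
weights, and a per-layer GRU cell merges the aggregated context into the
atom state.  A supernode — a virtual node linked to every atom, initialized
to the mean atom state — is then updated by molecule-level attention+GRU
steps in which it is the sole target; its final state is the fragment
embedding.  Pair embeddings are the elementwise sum of the two fragment
embeddings, the molecule embedding is the mean over all pairs, and a single
affine head maps it to the scalar logS prediction.

Molecules without any breakable bond (single atoms, pure ring systems) are
embedded by the same network applied once to the whole molecule; the same
path is exposed directly as the null-fragment ablation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, segment_mean, segment_softmax, segment_sum
from .chem_io import DEFAULT_FEATURES, FeatureConfig, MolecularGraph
from .fragmentation import enumerate_fragment_pairs


class ConfigError(ValueError):
    pass


class CheckpointMismatchError(ValueError):
    """Checkpoint was produced under a different featurization scheme."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden_width`` (F) is the embedding dimension carried by every atom and
    supernode state.  ``atom_layers`` and ``mol_layers`` are the depth of the
    atom-level and molecule-level (supernode) attention+GRU stacks.  Dropout
    is applied to attention weights and GRU inputs during training only.
    """

    hidden_width: int = 128
    atom_layers: int = 3
    mol_layers: int = 2
    dropout_rate: float = 0.002
    leaky_slope: float = 0.01
    seed: int = 0

    def validate(self):
        if self.hidden_width < 1 or self.atom_layers < 1 or self.mol_layers < 1:
            raise ConfigError("hidden_width, atom_layers and mol_layers must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")


@dataclass
class AtomStateSet:
    """Per-atom embedding rows (N x F) at a given layer."""

    states: np.ndarray
    layer: int = 0


@dataclass
class SupernodeGraph:
    """Star graph: supernode state at row 0, atom states below it."""

    node_states: np.ndarray  # (N+1, F)


@dataclass
class FragmentEmbedding:
    vector: np.ndarray  # (F,)


@dataclass
class MoleculeEmbedding:
    vector: np.ndarray  # (F,)


# ---------------------------------------------------------------------------
# compiled graph batches


@dataclass
class CompiledUnits:
    """Flattened fragment units of one molecule, ready for batched passes.

    Fragments are concatenated: ``atom_frag`` maps atom rows to fragment ids,
    ``frag_pair`` maps fragments to pair ids.  ``edge_src``/``edge_tgt`` hold
    both directions of every intra-fragment bond; ``edge_x`` is the 50-d
    [source atom features, bond features] concatenation used by the layer-1
    neighbor projection.  ``m`` is the molecule's fragment-pair count (0 when
    the whole-molecule fallback was compiled).
    """

    atom_x: np.ndarray
    edge_src: np.ndarray
    edge_tgt: np.ndarray
    edge_x: np.ndarray
    atom_frag: np.ndarray
    frag_pair: np.ndarray
    n_frags: int
    n_pairs: int
    m: int


def _fragment_arrays(g: MolecularGraph):
    srcs, tgts, ex = [], [], []
    for idx, (u, v) in enumerate(g.bonds):
        bf = g.bond_features[idx]
        for t, s in ((u, v), (v, u)):
            tgts.append(t)
            srcs.append(s)
            ex.append(np.concatenate([g.atom_features[s], bf]))
    width = g.atom_features.shape[1] + g.bond_features.shape[1]
    edge_x = np.stack(ex) if ex else np.zeros((0, width), dtype=np.float32)
    return (
        np.array(srcs, dtype=np.intp),
        np.array(tgts, dtype=np.intp),
        edge_x,
    )


def compile_molecule(
    g: MolecularGraph, null_fragment: bool = False
) -> CompiledUnits:
    """Flatten a molecule's fragment pairs (or the whole molecule) into arrays."""
    if null_fragment:
        frags, frag_pair, m = [g], [0], 0
    else:
        pairs = enumerate_fragment_pairs(g)
        m = len(pairs)
        if m == 0:
            frags, frag_pair = [g], [0]
        else:
            frags, frag_pair = [], []
            for p_idx, p in enumerate(pairs):
                frags.extend([p.frag1, p.frag2])
                frag_pair.extend([p_idx, p_idx])

    atom_x, srcs, tgts, ex, atom_frag = [], [], [], [], []
    offset = 0
    for f_idx, frag in enumerate(frags):
        s, t, e = _fragment_arrays(frag)
        atom_x.append(frag.atom_features)
        srcs.append(s + offset)
        tgts.append(t + offset)
        ex.append(e)
        atom_frag.append(np.full(frag.n_atoms, f_idx, dtype=np.intp))
        offset += frag.n_atoms
    return CompiledUnits(
        atom_x=np.concatenate(atom_x, axis=0),
        edge_src=np.concatenate(srcs),
        edge_tgt=np.concatenate(tgts),
        edge_x=np.concatenate(ex, axis=0),
        atom_frag=np.concatenate(atom_frag),
        frag_pair=np.array(frag_pair, dtype=np.intp),
        n_frags=len(frags),
        n_pairs=max(frag_pair) + 1,
        m=m,
    )


def _merge_units(units: list) -> CompiledUnits:
    """Disjoint union of several molecules' compiled units."""
    atom_off = frag_off = pair_off = 0
    ax, es, et, ex, af, fp = [], [], [], [], [], []
    for u in units:
        ax.append(u.atom_x)
        es.append(u.edge_src + atom_off)
        et.append(u.edge_tgt + atom_off)
        ex.append(u.edge_x)
        af.append(u.atom_frag + frag_off)
        fp.append(u.frag_pair + pair_off)
        atom_off += u.atom_x.shape[0]
        frag_off += u.n_frags
        pair_off += u.n_pairs
    return CompiledUnits(
        atom_x=np.concatenate(ax, axis=0),
        edge_src=np.concatenate(es),
        edge_tgt=np.concatenate(et),
        edge_x=np.concatenate(ex, axis=0),
        atom_frag=np.concatenate(af),
        frag_pair=np.concatenate(fp),
        n_frags=frag_off,
        n_pairs=pair_off,
        m=-1,
    )


# ---------------------------------------------------------------------------
# the network


class MolFraNetwork:
    """Parameter container plus forward passes (single-molecule and batched).

    One parameter set serves every fragment of every molecule (siamese
    weight sharing), so the parameter count is independent of molecule size
    and of the number of fragment pairs.
    """

    def __init__(
        self,
        cfg: ModelConfig = ModelConfig(),
        feature_cfg: FeatureConfig = DEFAULT_FEATURES,
        dtype=np.float32,
    ):
        cfg.validate()
        self.cfg = cfg
        self.feature_cfg = feature_cfg
        self.dtype = np.dtype(dtype)
        self.params: dict = {}
        self.stats = {"pair_enumerations": 0}
        self._last_attention: list = []
        rng = np.random.default_rng(cfg.seed)
        F = cfg.hidden_width
        Fn, Fe = feature_cfg.atom_width, feature_cfg.bond_width
        self._add_linear(rng, "target_init", Fn, F)
        self._add_linear(rng, "neighbor_init", Fn + Fe, F)
        for l in range(cfg.atom_layers):
            self._add_attention(rng, f"atom{l}", F)
        for t in range(cfg.mol_layers):
            self._add_attention(rng, f"mol{t}", F)
        self._add_linear(rng, "head", F, 1)

    # -- parameter plumbing ---------------------------------------------

    def _glorot(self, rng, fan_in, fan_out, shape):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(
            rng.uniform(-limit, limit, size=shape).astype(self.dtype), requires_grad=True
        )

    def _add_linear(self, rng, name, fan_in, fan_out):
        self.params[f"{name}/W"] = self._glorot(rng, fan_in, fan_out, (fan_in, fan_out))
        self.params[f"{name}/b"] = Tensor(np.zeros(fan_out, dtype=self.dtype), requires_grad=True)

    def _add_attention(self, rng, name, F):
        self.params[f"{name}/W"] = self._glorot(rng, F, F, (F, F))
        self.params[f"{name}/s"] = self._glorot(rng, 2 * F, 1, (2 * F,))
        for gate in ("z", "r", "h"):
            self.params[f"{name}/gru/W{gate}"] = self._glorot(rng, F, F, (F, F))
            self.params[f"{name}/gru/U{gate}"] = self._glorot(rng, F, F, (F, F))
            self.params[f"{name}/gru/b{gate}"] = Tensor(np.zeros(F, dtype=self.dtype), requires_grad=True)

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    # -- building blocks -------------------------------------------------

    def _gru(self, prefix: str, h: Tensor, x: Tensor) -> Tensor:
        p = self.params
        z = (x @ p[f"{prefix}/gru/Wz"] + h @ p[f"{prefix}/gru/Uz"] + p[f"{prefix}/gru/bz"]).sigmoid()
        r = (x @ p[f"{prefix}/gru/Wr"] + h @ p[f"{prefix}/gru/Ur"] + p[f"{prefix}/gru/br"]).sigmoid()
        n = (x @ p[f"{prefix}/gru/Wh"] + (r * h) @ p[f"{prefix}/gru/Uh"] + p[f"{prefix}/gru/bh"]).tanh()
        return (1.0 - z) * n + z * h

    def _attention_step(
        self, prefix, h_tgt, nb, tgt_idx, n_targets, training, rng, record=False
    ):
        """Per-target softmax attention over neighbor states, then elu(sum).

        ``h_tgt``: (T, F) target states; ``nb``: (E, F) neighbor states per
        directed edge; ``tgt_idx``: target row of each edge.  The same
        projection W scores and carries the message.  Targets with no
        incident edge receive a zero context.
        """
        p = self.params
        z_t = h_tgt @ p[f"{prefix}/W"]
        z_nb = nb @ p[f"{prefix}/W"]
        pair = concat([z_t.take(tgt_idx), z_nb], axis=1)
        eps = (pair @ p[f"{prefix}/s"]).leaky_relu(self.cfg.leaky_slope)
        alpha = segment_softmax(eps, tgt_idx, n_targets)
        if record:
            self._last_attention.append((alpha.data.copy(), np.asarray(tgt_idx), n_targets))
        if training and self.cfg.dropout_rate > 0.0 and rng is not None:
            keep = (rng.random(alpha.data.shape) >= self.cfg.dropout_rate)
            keep = keep.astype(alpha.data.dtype) / (1.0 - self.cfg.dropout_rate)
            alpha = alpha * Tensor(keep)
        msgs = z_nb * alpha.reshape(-1, 1)
        return segment_sum(msgs, tgt_idx, n_targets).elu()

    def _dropout(self, x: Tensor, training, rng) -> Tensor:
        if not training or self.cfg.dropout_rate <= 0.0 or rng is None:
            return x
        keep = (rng.random(x.data.shape) >= self.cfg.dropout_rate)
        return x * Tensor(keep.astype(x.data.dtype) / (1.0 - self.cfg.dropout_rate))

    # -- batched forward ---------------------------------------------------

    def forward_units(
        self,
        units: CompiledUnits,
        pair_mol: np.ndarray,
        n_mols: int,
        training: bool = False,
        rng=None,
        record_attention: bool = False,
    ) -> Tensor:
        """Predictions (n_mols,) for a batch of compiled fragment units."""
        p = self.params
        if record_attention:
            self._last_attention = []
        n_atoms = units.atom_x.shape[0]
        h = Tensor(units.atom_x.astype(self.dtype)) @ p["target_init/W"] + p["target_init/b"]
        nb0 = Tensor(units.edge_x.astype(self.dtype)) @ p["neighbor_init/W"] + p["neighbor_init/b"]
        for l in range(self.cfg.atom_layers):
            nb = nb0 if l == 0 else h.take(units.edge_src)
            ctx = self._attention_step(
                f"atom{l}", h, nb, units.edge_tgt, n_atoms, training, rng,
                record=record_attention,
            )
            h = self._gru(f"atom{l}", h, self._dropout(ctx, training, rng))
        # supernode readout on the star graph; atom rows stay fixed
        s = segment_mean(h, units.atom_frag, units.n_frags)
        for t in range(self.cfg.mol_layers):
            ctx = self._attention_step(
                f"mol{t}", s, h, units.atom_frag, units.n_frags, training, rng,
                record=record_attention,
            )
            s = self._gru(f"mol{t}", s, self._dropout(ctx, training, rng))
        y_pair = segment_sum(s, units.frag_pair, units.n_pairs)
        y_mol = segment_mean(y_pair, pair_mol, n_mols)
        return (y_mol @ p["head/W"] + p["head/b"]).reshape(-1)

    def predict_batch(self, units_list: list, training=False, rng=None) -> Tensor:
        merged = _merge_units(units_list)
        pair_mol = np.concatenate(
            [np.full(u.n_pairs, i, dtype=np.intp) for i, u in enumerate(units_list)]
        )
        return self.forward_units(
            merged, pair_mol, len(units_list), training=training, rng=rng
        )

    # -- single-molecule entry points -------------------------------------

    def forward(self, g: MolecularGraph) -> float:
        """Deterministic (evaluation-mode) prediction via the fragment path."""
        units = compile_molecule(g, null_fragment=False)
        self.stats["pair_enumerations"] += units.m
        pair_mol = np.zeros(units.n_pairs, dtype=np.intp)
        return float(self.forward_units(units, pair_mol, 1).data[0])

    def null_fragment_forward(self, g: MolecularGraph) -> float:
        """Whole-molecule ablation path: one pass, no fragmentation."""
        units = compile_molecule(g, null_fragment=True)
        pair_mol = np.zeros(units.n_pairs, dtype=np.intp)
        return float(self.forward_units(units, pair_mol, 1).data[0])

    # -- spec-level single-fragment operations -----------------------------
    # These expose the network's stages on one fragment at a time; the
    # batched pass above composes exactly these computations.

    def init_embeddings(self, frag: MolecularGraph) -> AtomStateSet:
        """Project raw atom features (40-d) to the F-wide initial states."""
        if frag.atom_features.shape[1] != self.feature_cfg.atom_width:
            raise ConfigError(
                f"atom feature width {frag.atom_features.shape[1]} does not match "
                f"configured width {self.feature_cfg.atom_width}"
            )
        h = (
            Tensor(frag.atom_features.astype(self.dtype)) @ self.params["target_init/W"]
            + self.params["target_init/b"]
        )
        return AtomStateSet(states=h.data, layer=0)

    def atom_attention_layer(
        self, states: AtomStateSet, frag: MolecularGraph, layer: int
    ) -> np.ndarray:
        """Context matrix C (N x F) of one atom-level attention layer."""
        src, tgt, edge_x = _fragment_arrays(frag)
        h = Tensor(states.states.astype(self.dtype))
        if layer == 0:
            nb = (
                Tensor(edge_x.astype(self.dtype)) @ self.params["neighbor_init/W"]
                + self.params["neighbor_init/b"]
            )
        else:
            nb = h.take(src)
        ctx = self._attention_step(
            f"atom{layer}", h, nb, tgt, frag.n_atoms, training=False, rng=None
        )
        return ctx.data

    def gru_update(self, prev: AtomStateSet, context: np.ndarray) -> AtomStateSet:
        if prev.states.shape != np.asarray(context).shape:
            raise ValueError(
                f"shape mismatch: states {prev.states.shape} vs context {np.shape(context)}"
            )
        layer = min(prev.layer, self.cfg.atom_layers - 1)
        out = self._gru(f"atom{layer}", Tensor(prev.states), Tensor(context))
        return AtomStateSet(states=out.data, layer=prev.layer + 1)

    def build_supernode_graph(self, final_states: AtomStateSet) -> SupernodeGraph:
        """Star graph whose supernode starts at the mean atom state."""
        if final_states.states.shape[0] == 0:
            raise ValueError("cannot build a supernode graph for an empty fragment")
        super_state = final_states.states.mean(axis=0, keepdims=True)
        return SupernodeGraph(node_states=np.vstack([super_state, final_states.states]))

    def readout_fragment(self, sg: SupernodeGraph) -> FragmentEmbedding:
        """Run the molecule-level attention+GRU steps; supernode is sole target."""
        s = Tensor(sg.node_states[:1])
        atoms = Tensor(sg.node_states[1:])
        n = sg.node_states.shape[0] - 1
        tgt = np.zeros(n, dtype=np.intp)
        for t in range(self.cfg.mol_layers):
            ctx = self._attention_step(f"mol{t}", s, atoms, tgt, 1, training=False, rng=None)
            s = self._gru(f"mol{t}", s, ctx)
        return FragmentEmbedding(vector=s.data[0])

    @staticmethod
    def fuse_pair(y1: FragmentEmbedding, y2: FragmentEmbedding) -> MoleculeEmbedding:
        if y1.vector.shape != y2.vector.shape:
            raise ValueError("fragment embedding widths differ")
        return MoleculeEmbedding(vector=y1.vector + y2.vector)

    @staticmethod
    def average_pairs(embeddings: list) -> MoleculeEmbedding:
        if not embeddings:
            raise ValueError("cannot average an empty list of pair embeddings")
        return MoleculeEmbedding(vector=np.mean([e.vector for e in embeddings], axis=0))

    def predict_head(self, y: MoleculeEmbedding) -> float:
        out = Tensor(y.vector.reshape(1, -1)) @ self.params["head/W"] + self.params["head/b"]
        return float(out.data[0, 0])

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "config": {
                "hidden_width": self.cfg.hidden_width,
                "atom_layers": self.cfg.atom_layers,
                "mol_layers": self.cfg.mol_layers,
                "dropout_rate": self.cfg.dropout_rate,
                "leaky_slope": self.cfg.leaky_slope,
                "seed": self.cfg.seed,
            },
            "feature_digest": self.feature_cfg.digest(),
            "params": {k: v.data.tolist() for k, v in self.params.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(
        cls, path, feature_cfg: FeatureConfig = DEFAULT_FEATURES, dtype=np.float32
    ) -> "MolFraNetwork":
        with open(path) as fh:
            payload = json.load(fh)
        if payload["feature_digest"] != feature_cfg.digest():
            raise CheckpointMismatchError(
                "checkpoint featurization digest does not match the current FeatureConfig"
            )
        net = cls(ModelConfig(**payload["config"]), feature_cfg, dtype=dtype)
        for k, v in payload["params"].items():
            net.params[k].data = np.asarray(v, dtype=net.dtype)
        return net

    def get_flat_params(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_flat_params(self, values: dict) -> None:
        for k, v in values.items():
            self.params[k].data = v.copy()
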