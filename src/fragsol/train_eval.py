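"""Dataset splitting, the training loop, and regression metrics.

Training minimizes batch-mean MSE with Adam (decoupled L2 weight decay added
to the raw gradient), evaluates validation RMSE after every epoch, keeps the
best-validation parameters, and stops early once the validation metric has
not improved for ``patience`` consecutive epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from ._autodiff import Tensor
from .chem_io import InvalidSMILESError, MoleculeRecord, smiles_to_graph
from .molfra_model import MolFraNetwork, compile_molecule


class ConfigError(ValueError):
    pass


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class SplitSpec:
    mode: str = "random"  # "random" | "scaffold"
    ratios: tuple = (0.8, 0.1, 0.1)
    seed: int = 0

    def validate(self):
        if self.mode not in ("random", "scaffold"):
            raise ConfigError(f"unknown split mode {self.mode!r}")
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise ConfigError("ratios must be three positive fractions")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ConfigError("ratios must sum to 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings; defaults follow the reference training recipe."""

    epochs: int = 300
    batch_size: int = 256
    lr: float = 0.0025
    weight_decay: float = 0.005
    patience: int = 40
    seed: int = 0

    def validate(self):
        if min(self.epochs, self.batch_size, self.patience) < 1 or self.lr <= 0:
            raise ConfigError("epochs, batch_size, patience and lr must be positive")
        if self.patience > self.epochs:
            raise ConfigError("patience must not exceed epochs")


@dataclass(frozen=True)
class MetricsResult:
    mae: float
    rmse: float
    n: int


def evaluate(preds: Sequence[float], labels: Sequence[float]) -> MetricsResult:
    """MAE and RMSE of a prediction set against its labels."""
    preds = np.asarray(preds, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if preds.shape != labels.shape or preds.ndim != 1 or preds.size == 0:
        raise ValueError(
            f"predictions and labels must be equal-length non-empty 1-d arrays; "
            f"got {preds.shape} vs {labels.shape}"
        )
    err = preds - labels
    return MetricsResult(
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        n=int(preds.size),
    )


# ---------------------------------------------------------------------------
# splitting


def _split_sizes(n: int, ratios) -> tuple:
    n_val = int(math.floor(ratios[1] * n))
    n_test = int(math.floor(ratios[2] * n))
    return n - n_val - n_test, n_val, n_test


def random_split(records: Sequence, spec: SplitSpec) -> tuple:
    """Seeded shuffle, then contiguous train/val/test slices.

    Validation and test sizes are the floors of their ratios; the remainder
    goes to train.
    """
    spec.validate()
    if spec.mode != "random":
        raise ConfigError("random_split requires mode='random'")
    n = len(records)
    if n < 3:
        raise ConfigError("need at least 3 records to split")
    n_train, n_val, n_test = _split_sizes(n, spec.ratios)
    perm = np.random.default_rng(spec.seed).permutation(n)
    records = list(records)
    train = [records[i] for i in perm[:n_train]]
    val = [records[i] for i in perm[n_train : n_train + n_val]]
    test = [records[i] for i in perm[n_train + n_val :]]
    return train, val, test


def bemis_murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko framework SMILES ('' for acyclic molecules)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSMILESError(f"invalid SMILES: {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def scaffold_split(records: Sequence, spec: SplitSpec) -> tuple:
    """Deterministic whole-group assignment by Bemis-Murcko scaffold.

    Molecules sharing a scaffold always land in the same partition.  The
    acyclic (empty-scaffold) group goes to train first; remaining groups are
    placed largest-first into whichever partition is furthest below its
    target count (ties resolved train > val > test).
    """
    spec.validate()
    if spec.mode != "scaffold":
        raise ConfigError("scaffold_split requires mode='scaffold'")
    records = list(records)
    n = len(records)
    groups: dict = {}
    for idx, rec in enumerate(records):
        groups.setdefault(bemis_murcko_scaffold(rec.smiles), []).append(idx)

    targets = [r * n for r in spec.ratios]
    parts = [[], [], []]

    def assign(indices):
        deficits = [targets[k] - len(parts[k]) for k in range(3)]
        parts[int(np.argmax(deficits))].extend(indices)

    ordered = sorted(
        ((s, idxs) for s, idxs in groups.items() if s != ""),
        key=lambda kv: (-len(kv[1]), kv[0]),
    )
    if "" in groups:
        parts[0].extend(groups[""])
    for _, idxs in ordered:
        assign(idxs)
    return tuple([records[i] for i in sorted(part)] for part in parts)


# ---------------------------------------------------------------------------
# training


def prepare_units(
    records: Sequence[MoleculeRecord], feature_cfg, null_fragment: bool = False
) -> tuple:
    """Featurize, fragment and flatten records once before training."""
    units, labels = [], []
    for rec in records:
        g = smiles_to_graph(rec.smiles, feature_cfg)
        units.append(compile_molecule(g, null_fragment=null_fragment))
        labels.append(rec.logS)
    return units, np.asarray(labels, dtype=np.float64)


class _Adam:
    def __init__(self, params: dict, lr: float, weight_decay: float):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _predict_units(net: MolFraNetwork, units, chunk: int = 512) -> np.ndarray:
    out = []
    for lo in range(0, len(units), chunk):
        out.append(net.predict_batch(units[lo : lo + chunk]).data)
    return np.concatenate(out)


def train(
    net: MolFraNetwork,
    train_records: Sequence[MoleculeRecord],
    val_records: Sequence[MoleculeRecord],
    tc: TrainConfig,
    null_fragment: bool = False,
    val_metric: Optional[Callable[[MolFraNetwork], float]] = None,
    log: Optional[Callable[[str], None]] = None,
) -> tuple:
    """Fit the network; returns ``(best_params, history)``.

    ``best_params`` are the parameters of the epoch with the lowest
    validation RMSE (not the last epoch).  ``history`` holds one dict per
    epoch: train MSE, validation MAE/RMSE and a best-so-far flag.
    ``val_metric`` optionally replaces the monitored quantity (it receives
    the live network and must return a float to minimize).
    """
    tc.validate()
    if not len(train_records) or not len(val_records):
        raise ConfigError("train and validation sets must be non-empty")
    train_units, train_y = prepare_units(train_records, net.feature_cfg, null_fragment)
    val_units, val_y = prepare_units(val_records, net.feature_cfg, null_fragment)

    rng = np.random.default_rng(tc.seed)
    opt = _Adam(net.params, tc.lr, tc.weight_decay)
    history = []
    best = {"rmse": math.inf, "epoch": -1, "params": net.get_flat_params()}

    for epoch in range(1, tc.epochs + 1):
        order = rng.permutation(len(train_units))
        mse_accum, n_seen = 0.0, 0
        for lo in range(0, len(order), tc.batch_size):
            idx = order[lo : lo + tc.batch_size]
            net.zero_grad()
            preds = net.predict_batch([train_units[i] for i in idx], training=True, rng=rng)
            err = preds - Tensor(train_y[idx].astype(preds.data.dtype))
            loss = (err * err).mean()
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            mse_accum += float(loss.data) * len(idx)
            n_seen += len(idx)

        val_preds = _predict_units(net, val_units)
        val_metrics = evaluate(val_preds, val_y)
        monitored = val_metric(net) if val_metric is not None else val_metrics.rmse
        improved = monitored < best["rmse"]
        if improved:
            best = {"rmse": monitored, "epoch": epoch, "params": net.get_flat_params()}
        history.append(
            {
                "epoch": epoch,
                "train_mse": mse_accum / n_seen,
                "val_mae": val_metrics.mae,
                "val_rmse": val_metrics.rmse,
                "monitored": monitored,
                "best": improved,
            }
        )
        if log is not None:
            log(
                f"epoch {epoch:4d}  train_mse {mse_accum / n_seen:.5f}  "
                f"val_mae {val_metrics.mae:.4f}  val_rmse {val_metrics.rmse:.4f}"
                f"{'  *' if improved else ''}"
            )
        if epoch - best["epoch"] >= tc.patience:
            break

    net.set_flat_params(best["params"])
    return best["params"], history


def predict_records(net: MolFraNetwork, records, null_fragment: bool = False) -> np.ndarray:
    units, _ = prepare_units(records, net.feature_cfg, null_fragment)
    return _predict_units(net, units)
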