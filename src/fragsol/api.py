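"""Model/Results front end tying cleaning, splitting, training and metrics together.

``FragmentSolubilityModel`` is constructed from data (records, a DataFrame,
or a CSV path); ``fit()`` runs the full pipeline and returns a
``FragmentSolubilityResults`` with the trained network, training history,
held-out metrics, a ``summary()`` table and ``predict()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import chem_io
from .chem_io import DEFAULT_FEATURES, FeatureConfig, MoleculeRecord
from .molfra_model import ModelConfig, MolFraNetwork
from .train_eval import (
    MetricsResult,
    SplitSpec,
    TrainConfig,
    evaluate,
    predict_records,
    random_split,
    scaffold_split,
    train,
)


class FragmentSolubilityModel:
    """Fragment-pair attention regression of aqueous solubility (logS).

    Parameters
    ----------
    records : sequence of MoleculeRecord
        SMILES + logS data; cleaned (missing/duplicate removal) before
        splitting unless ``clean=False``.
    split : SplitSpec
        Random or Bemis-Murcko scaffold split with (train, val, test) ratios.
    model_config, train_config
        Architecture and optimizer settings.
    null_fragment : bool
        Run the whole-molecule ablation path instead of fragment pairs.
    """

    def __init__(
        self,
        records: Sequence[MoleculeRecord],
        split: SplitSpec = SplitSpec(),
        model_config: ModelConfig = ModelConfig(),
        train_config: TrainConfig = TrainConfig(),
        null_fragment: bool = False,
        feature_config: FeatureConfig = DEFAULT_FEATURES,
        clean: bool = True,
    ):
        self.raw_records = list(records)
        self.records = chem_io.clean_dataset(self.raw_records) if clean else list(records)
        self.split = split
        self.model_config = model_config
        self.train_config = train_config
        self.null_fragment = null_fragment
        self.feature_config = feature_config

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, smiles_column: str = "smiles", label_column: str = "logS", **kw
    ) -> "FragmentSolubilityModel":
        records = [
            MoleculeRecord(smiles=str(r[smiles_column]), logS=float(r[label_column]))
            for _, r in df.iterrows()
        ]
        return cls(records, **kw)

    @classmethod
    def from_csv(
        cls, path, smiles_column: str = "smiles", label_column: str = "logS", sep: str = ",", **kw
    ) -> "FragmentSolubilityModel":
        records = chem_io.load_dataset(
            path, smiles_column=smiles_column, label_column=label_column, sep=sep
        )
        return cls(records, **kw)

    def fit(self, log=None) -> "FragmentSolubilityResults":
        splitter = random_split if self.split.mode == "random" else scaffold_split
        train_set, val_set, test_set = splitter(self.records, self.split)
        net = MolFraNetwork(self.model_config, self.feature_config)
        _, history = train(
            net,
            train_set,
            val_set,
            self.train_config,
            null_fragment=self.null_fragment,
            log=log,
        )
        test_metrics = None
        if test_set:
            preds = predict_records(net, test_set, self.null_fragment)
            test_metrics = evaluate(preds, [r.logS for r in test_set])
        return FragmentSolubilityResults(
            model=self,
            network=net,
            history=history,
            train_set=train_set,
            val_set=val_set,
            test_set=test_set,
            test_metrics=test_metrics,
        )


@dataclass
class FragmentSolubilityResults:
    """Fitted-model container: parameters, history, held-out metrics."""

    model: FragmentSolubilityModel
    network: MolFraNetwork
    history: list
    train_set: list
    val_set: list
    test_set: list
    test_metrics: Optional[MetricsResult]

    @property
    def best_epoch(self) -> int:
        for h in reversed(self.history):
            if h["best"]:
                return h["epoch"]
        return self.history[-1]["epoch"] if self.history else 0

    def predict(self, smiles) -> np.ndarray:
        """Predict logS for one SMILES or a sequence of SMILES."""
        single = isinstance(smiles, str)
        smiles_list = [smiles] if single else list(smiles)
        records = [MoleculeRecord(smiles=s, logS=float("nan")) for s in smiles_list]
        preds = predict_records(self.network, records, self.model.null_fragment)
        return float(preds[0]) if single else preds

    def predict_dataframe(self, smiles: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame({"smiles": list(smiles), "logS_pred": self.predict(list(smiles))})

    def summary(self) -> str:
        m = self.model
        lines = [
            "Fragment-pair attention solubility model",
            "=" * 46,
            f"records (after cleaning)   {len(m.records)}",
            f"split                      {m.split.mode} {m.split.ratios} (seed {m.split.seed})",
            f"train / val / test         {len(self.train_set)} / {len(self.val_set)} / {len(self.test_set)}",
            f"mode                       {'null-fragment (whole molecule)' if m.null_fragment else 'fragment pairs'}",
            f"hidden width F             {m.model_config.hidden_width}",
            f"atom / mol layers          {m.model_config.atom_layers} / {m.model_config.mol_layers}",
            f"parameters                 {self.network.n_parameters}",
            f"epochs run                 {len(self.history)} (best: {self.best_epoch})",
        ]
        if self.history:
            best = min(self.history, key=lambda h: h["val_rmse"])
            lines.append(f"best val MAE / RMSE        {best['val_mae']:.4f} / {best['val_rmse']:.4f}")
        if self.test_metrics is not None:
            lines.append(
                f"test MAE / RMSE (n={self.test_metrics.n})  "
                f"{self.test_metrics.mae:.4f} / {self.test_metrics.rmse:.4f}"
            )
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training-curve plot (train MSE and validation RMSE per epoch)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = [h["epoch"] for h in self.history]
        ax.plot(epochs, [h["train_mse"] for h in self.history], label="train MSE")
        ax.plot(epochs, [h["val_rmse"] for h in self.history], label="val RMSE")
        ax.axvline(self.best_epoch, color="grey", ls="--", lw=0.8, label="best epoch")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss / error")
        ax.legend()
        return ax

    def save_checkpoint(self, path) -> None:
        self.network.save(path)
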