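# fragsol

Fragment-pair graph-attention regression of aqueous solubility (logS) from
SMILES.

Aqueous solubility — logS, the log₁₀ molar concentration of a compound
dissolved in water — is one of the gating physicochemical properties in
early drug discovery: a candidate that cannot dissolve cannot be absorbed.
`fragsol` predicts logS directly from a molecule's SMILES string with a
graph neural network that looks at the molecule *in pieces*: every acyclic
single bond is broken in turn, each break yields a pair of connected
fragments, both fragments are embedded by a shared atom-level
attention + GRU network with a supernode readout, the pair embeddings are
summed, and the molecule's representation is the mean over all m pairs,

  ŷᵢ = y¹ᵢ + y²ᵢ,   ŷ = (1/m) Σᵢ₌₁..ₘ ŷᵢ,   logS ≈ wᵀŷ + b,

with per-layer attention aggregation εₜᵢ = leakyrelu(s·[W aₜ, W aᵢ]),
αₜᵢ = softmaxᵢ(εₜᵢ), Cₜ = elu(Σᵢ αₜᵢ W aᵢ) and GRU state updates
aₜˡ = GRU(aₜˡ⁻¹, Cₜˡ). Molecules with no breakable bond (benzene, single
atoms) go through the identical network as a whole; that whole-molecule
path is also exposed as the "null-fragment" ablation so the value of
fragment pairing can be measured. Model fitting minimizes MSE with Adam,
early-stops on validation RMSE, and reports MAE/RMSE on a random or
Bemis–Murcko scaffold split.

The network, its gradients and the optimizer are implemented on NumPy with
a small reverse-mode autodiff engine; RDKit handles all chemistry (parsing,
canonicalization, scaffolds, atom/bond properties). A seeded synthetic
SMILES generator with an exactly linear structure→logS law makes the whole
pipeline testable offline. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

```python
from fragsol import (FragmentSolubilityModel, ModelConfig, SplitSpec,
                     SynthConfig, TrainConfig, make_dataset)

# 400 synthetic molecules, logS = 0.5 - 0.45·#C + 0.8·(#N+#O) - 1.2·#rings + noise
recs = make_dataset(SynthConfig(n_molecules=400, noise_sigma=0.1, seed=7))

model = FragmentSolubilityModel(
    recs,
    split=SplitSpec(seed=7),                      # random 8:1:1
    model_config=ModelConfig(hidden_width=32, seed=7),
    train_config=TrainConfig(seed=7),             # Adam, lr 2.5e-3, patience 40
)
res = model.fit()
print(res.summary())
for smi in ["CCO", "CCCCCCCC", "Cc1ccccc1"]:
    print(f"{smi:>10}  predicted logS = {res.predict(smi):+.3f}")
```

prints

```
Fragment-pair attention solubility model
==============================================
records (after cleaning)   235
split                      random (0.8, 0.1, 0.1) (seed 7)
train / val / test         189 / 23 / 23
mode                       fragment pairs
hidden width F             32
atom / mol layers          3 / 2
parameters                 39617
epochs run                 300 (best: 274)
best val MAE / RMSE        0.1999 / 0.2687
test MAE / RMSE (n=23)  0.2317 / 0.2948

       CCO  predicted logS = +0.481
  CCCCCCCC  predicted logS = -2.950
 Cc1ccccc1  predicted logS = -4.311
```

The 400 generated rows contain deliberate duplicates; cleaning keeps 235
unique structures. Held-out MAE 0.23 against label noise σ = 0.1 means the
network recovered the underlying linear law through the full
fragmentation/attention path (a predict-the-mean baseline scores MAE ≈ 1.9
on this split). The spot predictions follow the law's chemistry: ethanol's
polar oxygen keeps it soluble (+0.48), octane's eight carbons push it to
−2.95, and toluene's aromatic ring costs a further penalty (−4.31).

Real datasets load the same way from CSV:

```python
model = FragmentSolubilityModel.from_csv("delaney.csv")   # smiles,logS columns
res = model.fit()
```

## Command line

```sh
fragsol synth --n 400 --seed 7 --sigma 0.1 --out data.csv
fragsol train --data data.csv --out-dir run --seed 7 -v
fragsol predict --ckpt run/checkpoint.json --in smiles.txt
fragsol fragment "CC(=O)Oc1ccccc1C(=O)O"   # aspirin: m = 5 pairs, as JSON
fragsol eval --pred preds.csv --truth data.csv
```

`fragsol train` writes the resolved run configuration (with seed and
package version), a JSON checkpoint, the per-epoch history and the test
metrics into the run directory; `--null-fragment` switches to the
whole-molecule ablation.

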