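"""Training loop, data splitting, cross-validation and regression metrics.

Splitting modes mirror the evaluation protocols of the drug-response study:

* ``mixed`` — drug/cell-line *pairs* are split 8:1:1 into train/validation/test.
* ``drug_blind`` — 10% of drugs (and all their pairs) form the test set; the
  remaining drugs are split 8:1 into training and validation drugs, so no
  test drug is ever seen in training (the cold-start drug setting).
* ``cell_blind`` — likewise on cell lines: 10% of cell lines are held out for
  testing and the rest are split 8:1 into training and validation cells.

Five-fold cross-validation fixes ten equal pieces of the pair set and rotates
two pieces per fold as validation and test.  Metrics are Pearson and Spearman
correlation, R^2 and RMSE; cross-validation spread is the population
(divisor-n) standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from ._autograd import Tensor
from . import nn
from .core_data import Dataset, standardize_omics, apply_standardization
from .network import (FeatureTensors, GraphBatch, NeRDNetwork, NetworkSpec,
                      cne_pretrain, mse_loss)


# ------------------------------------------------------------------- metrics

@dataclass
class MetricsReport:
    cc_p: float
    cc_s: float
    r2: float
    rmse: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {"cc_p": self.cc_p, "cc_s": self.cc_s, "r2": self.r2,
                "rmse": self.rmse, "n": self.n}


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """Pearson/Spearman correlation, R^2 = 1 - SS_res/SS_tot, RMSE."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(y_true) == 0:
        raise ValueError("y_true is constant; correlation undefined")
    cc_p = float(sps.pearsonr(y_true, y_pred).statistic)
    cc_s = float(sps.spearmanr(y_true, y_pred).statistic)  # average ranks on ties
    ss_res = float(np.sum((y_pred - y_true) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = math.sqrt(ss_res / y_true.size)
    return MetricsReport(cc_p=cc_p, cc_s=cc_s, r2=r2, rmse=rmse, n=int(y_true.size))


@dataclass
class CVResult:
    folds: list[MetricsReport]

    def mean(self) -> dict[str, float]:
        return {k: float(np.mean([f.as_dict()[k] for f in self.folds]))
                for k in ("cc_p", "cc_s", "r2", "rmse")}

    def std(self) -> dict[str, float]:
        # population standard deviation (divisor n), the STDEVP convention
        return {k: float(np.std([f.as_dict()[k] for f in self.folds]))
                for k in ("cc_p", "cc_s", "r2", "rmse")}


# -------------------------------------------------------------------- splits

@dataclass
class SplitSpec:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    mode: str
    seed: int

    def __post_init__(self):
        self.train_idx = np.asarray(self.train_idx, dtype=np.intp)
        self.val_idx = np.asarray(self.val_idx, dtype=np.intp)
        self.test_idx = np.asarray(self.test_idx, dtype=np.intp)
        sets = [set(self.train_idx), set(self.val_idx), set(self.test_idx)]
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ValueError("split partitions must be pairwise disjoint")

    def as_dict(self) -> dict:
        return {"mode": self.mode, "seed": self.seed,
                "train": self.train_idx.tolist(), "val": self.val_idx.tolist(),
                "test": self.test_idx.tolist()}


def _entity_split(entities: list[str], rng: np.random.Generator,
                  fracs: tuple[float, float, float]) -> tuple[list, list, list]:
    order = list(rng.permutation(len(entities)))
    n = len(entities)
    n_test = max(1, round(fracs[2] * n))
    n_val = max(1, round(fracs[1] * n))
    if n_test + n_val >= n:
        raise ValueError(f"too few entities ({n}) for a blind split")
    test = [entities[i] for i in order[:n_test]]
    val = [entities[i] for i in order[n_test:n_test + n_val]]
    train = [entities[i] for i in order[n_test + n_val:]]
    return train, val, test


def make_split(dataset: Dataset, mode: str = "mixed",
               ratios: tuple[int, int, int] = (8, 1, 1), seed: int = 0) -> SplitSpec:
    """Split response indices into train/validation/test partitions."""
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be three positive numbers")
    total = sum(ratios)
    fracs = tuple(r / total for r in ratios)
    rng = np.random.default_rng(seed)
    n = len(dataset.responses)

    if mode == "mixed":
        order = rng.permutation(n)
        n_train = int(math.floor(fracs[0] * n))
        n_val = int(math.floor(fracs[1] * n))
        train = order[:n_train]
        val = order[n_train:n_train + n_val]
        test = order[n_train + n_val:]
        if min(len(train), len(val), len(test)) == 0:
            raise ValueError("too few pairs for a mixed split")
        return SplitSpec(train, val, test, mode, seed)

    if mode in ("drug_blind", "cell_blind"):
        key = "drug_id" if mode == "drug_blind" else "cell_id"
        entities = sorted({getattr(r, key) for r in dataset.responses})
        if len(entities) < 3:
            raise ValueError(f"{mode} needs at least 3 entities")
        train_e, val_e, test_e = _entity_split(entities, rng, fracs)
        groups = {"train": set(train_e), "val": set(val_e), "test": set(test_e)}
        parts = {name: [] for name in groups}
        for i, r in enumerate(dataset.responses):
            ent = getattr(r, key)
            for name, members in groups.items():
                if ent in members:
                    parts[name].append(i)
        return SplitSpec(parts["train"], parts["val"], parts["test"], mode, seed)

    raise ValueError(f"unknown split mode {mode!r}")


def five_fold_cv(dataset: Dataset, seed: int = 0) -> list[SplitSpec]:
    """Fix ten equal pieces of the pair set; fold k takes pieces (2k, 2k+1)
    as validation and test and the remaining eight as training."""
    n = len(dataset.responses)
    if n < 10:
        raise ValueError("need at least 10 pairs for five-fold cross-validation")
    rng = np.random.default_rng(seed)
    pieces = np.array_split(rng.permutation(n), 10)
    folds = []
    for k in range(5):
        val = pieces[2 * k]
        test = pieces[2 * k + 1]
        train = np.concatenate([p for j, p in enumerate(pieces)
                                if j not in (2 * k, 2 * k + 1)])
        folds.append(SplitSpec(train, val, test, "mixed_cv", seed))
    return folds


def entity_blind_split_from_test_group(dataset: Dataset, axis: str,
                                       test_entities: list[str], seed: int = 0
                                       ) -> SplitSpec:
    """Blind split with a prescribed test group (used by similarity binning);
    remaining entities are split 8:1 into train/validation."""
    key = "drug_id" if axis == "drug" else "cell_id"
    rng = np.random.default_rng(seed)
    all_entities = sorted({getattr(r, key) for r in dataset.responses})
    rest = [e for e in all_entities if e not in set(test_entities)]
    order = rng.permutation(len(rest))
    n_val = max(1, round(len(rest) / 9.0))
    val_e = {rest[i] for i in order[:n_val]}
    train_e = {rest[i] for i in order[n_val:]}
    parts = {"train": [], "val": [], "test": []}
    test_set = set(test_entities)
    for i, r in enumerate(dataset.responses):
        ent = getattr(r, key)
        if ent in test_set:
            parts["test"].append(i)
        elif ent in val_e:
            parts["val"].append(i)
        else:
            parts["train"].append(i)
    mode = f"{axis}_blind"
    return SplitSpec(parts["train"], parts["val"], parts["test"], mode, seed)


# ---------------------------------------------------------------- similarity

def mean_entity_similarity(dataset: Dataset, axis: str) -> dict[str, float]:
    """Mean similarity of each entity to all others.

    Drugs: Tanimoto similarity on substructure fingerprints.  Cells: Pearson
    correlation on the concatenated standardized omics blocks.
    """
    if axis == "drug":
        ids = dataset.drug_ids
        fps = []
        for d in ids:
            rec = dataset.drugs[d]
            if rec.fingerprint is None:
                raise ValueError(f"drug {d} has no fingerprint")
            fps.append(rec.fingerprint.bits.astype(float))
        X = np.stack(fps)
        inter = X @ X.T
        pop = X.sum(axis=1)
        union = pop[:, None] + pop[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(union > 0, inter / union, 1.0)
    elif axis == "cell":
        ids = dataset.cell_ids
        blocks = []
        for c in ids:
            rec = dataset.cells[c]
            blocks.append(np.concatenate([rec.mirna, rec.cnv]))
        X = np.stack(blocks)
        X = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise ValueError("constant omics profile; correlation undefined")
        sim = (X @ X.T) / np.outer(norms, norms)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 entities")
    mean_sim = (sim.sum(axis=1) - np.diag(sim)) / (n - 1)
    return dict(zip(ids, mean_sim.tolist()))


def similarity_bins(dataset: Dataset, axis: str, n_bins: int = 5) -> list[list[str]]:
    """Order entities by mean similarity to the rest and cut them into
    near-equal groups, lowest similarity first (ties broken by id order)."""
    scores = mean_entity_similarity(dataset, axis)
    if len(scores) < n_bins:
        raise ValueError(f"need at least {n_bins} entities on axis {axis!r}")
    ordered = sorted(scores, key=lambda e: (scores[e], e))
    return [list(group) for group in np.array_split(np.array(ordered), n_bins)]


# ------------------------------------------------------------------ training

@dataclass
class TrainingConfig:
    network: NetworkSpec = field(default_factory=NetworkSpec)
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int | None = 256
    cne_pretrain_epochs: int = 20
    cne_lr: float = 1e-3
    finetune_cne: bool = True
    dtype: str = "float32"


def build_features(dataset: Dataset, train_idx: np.ndarray,
                   channels: tuple[str, ...]) -> tuple[FeatureTensors, dict, dict]:
    """Assemble entity-level feature arrays; omics standardized with the
    statistics of cells that appear in the training pairs only."""
    drug_ids = dataset.drug_ids
    cell_ids = dataset.cell_ids
    drug_index = {d: i for i, d in enumerate(drug_ids)}
    cell_index = {c: i for i, c in enumerate(cell_ids)}

    train_cells = sorted({dataset.responses[i].cell_id for i in np.asarray(train_idx)})
    train_rows = np.array([cell_index[c] for c in train_cells], dtype=np.intp)

    fingerprints = graphs = mirna = cnv = None
    if "mfe" in channels:
        fingerprints = np.stack([dataset.drugs[d].fingerprint.bits for d in drug_ids]
                                ).astype(np.float32)
    if "dse" in channels:
        from .featurize import smiles_to_graph
        gs = []
        for d in drug_ids:
            rec = dataset.drugs[d]
            if rec.graph is None:
                rec.graph = smiles_to_graph(rec.smiles, d)
            gs.append(rec.graph)
        graphs = GraphBatch.from_graphs(gs)
    if "mee" in channels:
        raw = np.stack([dataset.cells[c].mirna for c in cell_ids])
        mirna, _ = standardize_omics(raw, train_rows)
        mirna = mirna.astype(np.float32)
    if "cne" in channels:
        raw = np.stack([dataset.cells[c].cnv for c in cell_ids])
        cnv, _ = standardize_omics(raw, train_rows)
        cnv = cnv.astype(np.float32)
    return FeatureTensors(fingerprints, graphs, mirna, cnv), drug_index, cell_index


class TrainedModel:
    """A trained network plus the feature tensors and index maps it needs."""

    def __init__(self, network: NeRDNetwork, features: FeatureTensors,
                 drug_index: dict, cell_index: dict, config: TrainingConfig,
                 split: SplitSpec, history: list[dict], best_epoch: int):
        self.network = network
        self.features = features
        self.drug_index = drug_index
        self.cell_index = cell_index
        self.config = config
        self.split = split
        self.history = history
        self.best_epoch = best_epoch

    def predict_indices(self, drug_rows: np.ndarray, cell_rows: np.ndarray,
                        return_stages: bool = False):
        self.network.eval()
        out = self.network(self.features, drug_rows, cell_rows,
                           return_stages=return_stages)
        if return_stages:
            pred, stages = out
            return pred.numpy().astype(float), stages
        return out.numpy().astype(float)

    def predict_pairs(self, drug_ids: list[str], cell_ids: list[str]) -> np.ndarray:
        drows = np.array([self.drug_index[d] for d in drug_ids], dtype=np.intp)
        crows = np.array([self.cell_index[c] for c in cell_ids], dtype=np.intp)
        return self.predict_indices(drows, crows)

    def predict_responses(self, dataset: Dataset, idx: np.ndarray) -> np.ndarray:
        records = [dataset.responses[i] for i in np.asarray(idx)]
        return self.predict_pairs([r.drug_id for r in records],
                                  [r.cell_id for r in records])

    def evaluate(self, dataset: Dataset, idx: np.ndarray) -> MetricsReport:
        idx = np.asarray(idx)
        y_true = np.array([dataset.responses[i].label for i in idx], dtype=float)
        y_pred = self.predict_responses(dataset, idx)
        return compute_metrics(y_true, y_pred)


def _pair_arrays(dataset: Dataset, idx: np.ndarray, drug_index: dict,
                 cell_index: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    records = [dataset.responses[i] for i in np.asarray(idx)]
    if any(r.label is None for r in records):
        raise ValueError("responses carry no labels; run preprocess_responses first")
    drows = np.array([drug_index[r.drug_id] for r in records], dtype=np.intp)
    crows = np.array([cell_index[r.cell_id] for r in records], dtype=np.intp)
    labels = np.array([r.label for r in records], dtype=float)
    return drows, crows, labels


def train_model(dataset: Dataset, split: SplitSpec, config: TrainingConfig | None = None,
                seed: int = 0) -> TrainedModel:
    """Train the network on the split's training pairs, minimizing the mean
    squared error of normalized labels; the checkpoint with the best
    validation RMSE is returned."""
    config = config or TrainingConfig()
    if len(split.train_idx) == 0:
        raise ValueError("empty training partition")
    spec = config.network
    features, drug_index, cell_index = build_features(dataset, split.train_idx,
                                                      spec.channels)
    mirna_dim = features.mirna.shape[1] if features.mirna is not None else 1
    cnv_dim = features.cnv.shape[1] if features.cnv is not None else 1
    net = NeRDNetwork(spec, mirna_dim, cnv_dim, seed=seed)

    train_d, train_c, train_y = _pair_arrays(dataset, split.train_idx,
                                             drug_index, cell_index)
    has_val = len(split.val_idx) > 0
    if has_val:
        val_d, val_c, val_y = _pair_arrays(dataset, split.val_idx,
                                           drug_index, cell_index)

    if net.cne is not None and config.cne_pretrain_epochs > 0:
        train_cell_rows = np.unique(train_c)
        cne_pretrain(net.cne, features.cnv[train_cell_rows],
                     epochs=config.cne_pretrain_epochs, lr=config.cne_lr,
                     seed=seed + 1)

    params = net.parameters()
    if net.cne is not None and not config.finetune_cne:
        frozen = set(id(p) for p in net.cne.encoder.parameters())
        params = [p for p in params if id(p) not in frozen]
    # decoder parameters take no part in the supervised phase
    if net.cne is not None:
        dec = set(id(p) for p in net.cne.decoder.parameters())
        params = [p for p in params if id(p) not in dec]
    opt = nn.Adam(params, lr=config.lr)
    nn.set_dropout_rng(net, np.random.default_rng(seed + 2))
    shuffle_rng = np.random.default_rng(seed + 3)

    n_train = len(train_y)
    bs = n_train if config.batch_size is None else min(config.batch_size, n_train)
    history: list[dict] = []
    best = {"rmse": np.inf, "state": None, "epoch": -1}
    for epoch in range(config.epochs):
        net.train()
        order = shuffle_rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, bs):
            rows = order[start:start + bs]
            if len(rows) < 2:
                continue  # batch standardization needs >= 2 samples
            pred = net(features, train_d[rows], train_c[rows])
            loss = mse_loss(pred, train_y[rows].astype(pred.dtype))
            value = float(loss.item())
            if not np.isfinite(value):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            losses.append(value)
            opt.zero_grad()
            loss.backward()
            opt.step()
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if has_val:
            net.eval()
            val_pred = net(features, val_d, val_c).numpy()
            val_rmse = float(np.sqrt(np.mean((val_pred - val_y) ** 2)))
            entry["val_rmse"] = val_rmse
            if val_rmse < best["rmse"]:
                best = {"rmse": val_rmse, "state": net.state_dict(), "epoch": epoch}
        history.append(entry)

    if has_val and best["state"] is not None:
        net.load_state_dict(best["state"])
    net.eval()
    return TrainedModel(net, features, drug_index, cell_index, config, split,
                        history, best["epoch"])


def data_reduction_experiment(dataset: Dataset, split: SplitSpec,
                              fractions: tuple[float, ...] = (0.5, 0.25, 0.125, 0.0625),
                              config: TrainingConfig | None = None,
                              seed: int = 0) -> dict[float, MetricsReport]:
    """Retrain on uniformly subsampled training pairs (validation and test
    untouched) and evaluate on the fixed test partition."""
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out: dict[float, MetricsReport] = {}
    for frac in fractions:
        n_sub = int(math.floor(frac * len(split.train_idx)))
        if n_sub < 10:
            raise ValueError(f"fraction {frac} leaves fewer than 10 training pairs")
        if frac == 1.0:
            sub_train = split.train_idx
        else:
            sub_train = rng.choice(split.train_idx, size=n_sub, replace=False)
        sub_split = SplitSpec(sub_train, split.val_idx, split.test_idx,
                              split.mode, split.seed)
        model = train_model(dataset, sub_split, config, seed=seed)
        out[frac] = model.evaluate(dataset, split.test_idx)
    return out


def save_checkpoint(model: TrainedModel, run_dir) -> None:
    """Serialize parameters plus a spec manifest (dims, seeds, split) so the
    checkpoint is self-describing and reloadable against the same dataset."""
    import json
    from pathlib import Path

    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    np.savez(run_dir / "checkpoint.npz", **model.network.state_dict())
    spec = model.config.network
    meta = {
        "channels": list(spec.channels),
        "mirna_dim": (model.features.mirna.shape[1]
                      if model.features.mirna is not None else 1),
        "cnv_dim": (model.features.cnv.shape[1]
                    if model.features.cnv is not None else 1),
        "fusion_hidden": list(spec.fusion.hidden),
        "dropout": spec.fusion.dropout,
        "split": model.split.as_dict(),
        "best_epoch": model.best_epoch,
        "history": model.history,
    }
    with open(run_dir / "checkpoint_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_checkpoint(dataset: Dataset, run_dir,
                    config: TrainingConfig | None = None) -> TrainedModel:
    """Rebuild a TrainedModel from a checkpoint directory and its dataset."""
    import json
    from dataclasses import replace as _replace
    from pathlib import Path

    from .network import FusionSpec

    run_dir = Path(run_dir)
    with open(run_dir / "checkpoint_meta.json") as fh:
        meta = json.load(fh)
    config = config or TrainingConfig()
    spec = _replace(config.network, channels=tuple(meta["channels"]),
                    fusion=FusionSpec(hidden=tuple(meta["fusion_hidden"]),
                                      dropout=meta["dropout"]))
    config = _replace(config, network=spec)
    split = SplitSpec(np.array(meta["split"]["train"]), np.array(meta["split"]["val"]),
                      np.array(meta["split"]["test"]), meta["split"]["mode"],
                      meta["split"]["seed"])
    features, drug_index, cell_index = build_features(dataset, split.train_idx,
                                                      spec.channels)
    net = NeRDNetwork(spec, meta["mirna_dim"], meta["cnv_dim"])
    state = dict(np.load(run_dir / "checkpoint.npz"))
    net.load_state_dict(state)
    net.eval()
    return TrainedModel(net, features, drug_index, cell_index, config, split,
                        meta["history"], meta["best_epoch"])


def run_cv(dataset: Dataset, config: TrainingConfig | None = None,
           seed: int = 0) -> CVResult:
    """Five-fold cross-validation on the mixed split."""
    folds = five_fold_cv(dataset, seed=seed)
    reports = []
    for k, split in enumerate(folds):
        model = train_model(dataset, split, config, seed=seed + k)
        reports.append(model.evaluate(dataset, split.test_idx))
    return CVResult(reports)
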