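"""Channel attribution: ablation grid, exact 4-channel Shapley values, and
stage-wise embedding extraction.

The four input channels (DSE, MFE, mEE, CNE) define a cooperative game: the
value of a channel subset S is the test performance of a model trained with
exactly those channels, minus the value of the empty coalition (a constant
mean-label predictor), so v(empty) = 0.  For RMSE, where smaller is better,
the value is the *improvement* over the mean predictor, rmse(empty) - rmse(S),
keeping every game higher-is-better.  With only four channels the Shapley
value is computed exactly by enumerating all 4! orderings; the weighted-subset
closed form is also provided as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import chain, combinations, permutations
from math import factorial

import numpy as np

from .core_data import Dataset
from .network import CHANNELS
from .train_eval import (MetricsReport, SplitSpec, TrainedModel, TrainingConfig,
                         train_model)

METRICS = ("cc_p", "cc_s", "r2", "rmse")


def all_channel_subsets(channels: tuple[str, ...] = CHANNELS) -> list[frozenset]:
    """All 2^n subsets, the empty coalition included."""
    return [frozenset(s) for s in chain.from_iterable(
        combinations(channels, k) for k in range(len(channels) + 1))]


def mean_baseline_metrics(dataset: Dataset, split: SplitSpec) -> MetricsReport:
    """The empty-coalition predictor: the constant mean of the training labels.

    A constant prediction has no defined correlation; both correlation entries
    are reported as 0 (no association), R^2 and RMSE are computed as usual.
    """
    train_y = np.array([dataset.responses[i].label for i in split.train_idx])
    test_y = np.array([dataset.responses[i].label for i in split.test_idx])
    pred = np.full_like(test_y, train_y.mean())
    ss_res = float(np.sum((pred - test_y) ** 2))
    ss_tot = float(np.sum((test_y - test_y.mean()) ** 2))
    return MetricsReport(cc_p=0.0, cc_s=0.0, r2=1.0 - ss_res / ss_tot,
                         rmse=float(np.sqrt(ss_res / test_y.size)), n=test_y.size)


def ablation_grid(dataset: Dataset, split: SplitSpec,
                  subsets: list[frozenset] | None = None,
                  config: TrainingConfig | None = None, seed: int = 0
                  ) -> dict[frozenset, MetricsReport]:
    """Train one model per channel subset (common split and seed) and report
    test metrics.  The empty subset maps to the mean-label baseline."""
    config = config or TrainingConfig()
    subsets = subsets if subsets is not None else all_channel_subsets(
        config.network.channels)
    out: dict[frozenset, MetricsReport] = {}
    for subset in subsets:
        unknown = set(subset) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channel name(s): {sorted(unknown)}")
        if len(subset) == 0:
            out[subset] = mean_baseline_metrics(dataset, split)
            continue
        sub_config = replace(config, network=replace(
            config.network, channels=tuple(c for c in CHANNELS if c in subset)))
        model = train_model(dataset, split, sub_config, seed=seed)
        out[subset] = model.evaluate(dataset, split.test_idx)
    return out


# ------------------------------------------------------------------- Shapley

@dataclass
class ChannelGame:
    """Higher-is-better coalition values with v(empty) = 0."""
    channels: tuple[str, ...]
    v: dict[frozenset, float]

    def __post_init__(self):
        for subset in all_channel_subsets(self.channels):
            if subset not in self.v:
                raise ValueError(f"missing value for subset {set(subset) or '{}'}")

    @classmethod
    def from_metrics(cls, metric: str, grid: dict[frozenset, MetricsReport],
                     channels: tuple[str, ...] = CHANNELS) -> "ChannelGame":
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}")
        empty = frozenset()
        if empty not in grid:
            raise ValueError("grid must include the empty coalition")
        base = grid[empty].as_dict()[metric]
        v: dict[frozenset, float] = {}
        for subset, report in grid.items():
            value = report.as_dict()[metric]
            # RMSE is recast as improvement over the baseline so larger = better
            v[subset] = (base - value) if metric == "rmse" else (value - base)
        return cls(channels, v)


def shapley_values(game: ChannelGame) -> dict[str, float]:
    """Exact Shapley values by enumeration over all n! channel orderings."""
    n = len(game.channels)
    phi = {c: 0.0 for c in game.channels}
    for order in permutations(game.channels):
        acc: frozenset = frozenset()
        for channel in order:
            with_c = acc | {channel}
            phi[channel] += game.v[with_c] - game.v[acc]
            acc = with_c
    n_fact = factorial(n)
    return {c: phi[c] / n_fact for c in game.channels}


def shapley_values_closed_form(game: ChannelGame) -> dict[str, float]:
    """The weighted-subset formula sum_S |S|!(n-|S|-1)!/n! [v(S+i) - v(S)];
    equal to the permutation enumeration, kept as an independent check."""
    n = len(game.channels)
    phi = {}
    for channel in game.channels:
        others = [c for c in game.channels if c != channel]
        total = 0.0
        for k in range(len(others) + 1):
            weight = factorial(k) * factorial(n - k - 1) / factorial(n)
            for subset in combinations(others, k):
                s = frozenset(subset)
                total += weight * (game.v[s | {channel}] - game.v[s])
        phi[channel] = total
    return phi


@dataclass
class ChannelAttribution:
    """Shapley values and percentage shares, per metric."""
    phi: dict[str, dict[str, float]]     # metric -> channel -> Shapley value
    shares: dict[str, dict[str, float]]  # metric -> channel -> percent of total

    def efficiency_gap(self, games: dict[str, ChannelGame]) -> dict[str, float]:
        gaps = {}
        for metric, game in games.items():
            full = frozenset(game.channels)
            gaps[metric] = abs(sum(self.phi[metric].values()) - game.v[full])
        return gaps


def shapley_channels(games: dict[str, ChannelGame]) -> ChannelAttribution:
    """Shapley attribution for each metric's game, with percent shares
    normalized within metric (each row sums to 100)."""
    phi: dict[str, dict[str, float]] = {}
    shares: dict[str, dict[str, float]] = {}
    for metric, game in games.items():
        values = shapley_values(game)
        phi[metric] = values
        total = sum(values.values())
        if total == 0:
            raise ValueError(f"total contribution is zero for metric {metric!r}")
        shares[metric] = {c: 100.0 * v / total for c, v in values.items()}
    return ChannelAttribution(phi=phi, shares=shares)


def channel_attribution(dataset: Dataset, split: SplitSpec,
                        config: TrainingConfig | None = None, seed: int = 0,
                        metrics: tuple[str, ...] = METRICS
                        ) -> tuple[ChannelAttribution, dict[frozenset, MetricsReport]]:
    """Full pipeline: 16-subset ablation grid -> per-metric games -> Shapley."""
    grid = ablation_grid(dataset, split, None, config, seed)
    games = {m: ChannelGame.from_metrics(m, grid) for m in metrics}
    return shapley_channels(games), grid


# --------------------------------------------------------- stage embeddings

def stage_embeddings(model: TrainedModel, dataset: Dataset, idx: np.ndarray,
                     n_sample: int = 1000, seed: int = 0) -> dict:
    """Embeddings of sampled pairs at three stages: the initial feature
    concatenation, the post-extractor concatenation, and the last fusion
    hidden layer; IC50 labels are attached for coloring 2-D projections."""
    idx = np.asarray(idx)
    if n_sample > idx.size:
        raise ValueError(f"n_sample {n_sample} exceeds available pairs {idx.size}")
    rng = np.random.default_rng(seed)
    sample = rng.choice(idx, size=n_sample, replace=False)
    records = [dataset.responses[i] for i in sample]
    drows = np.array([model.drug_index[r.drug_id] for r in records], dtype=np.intp)
    crows = np.array([model.cell_index[r.cell_id] for r in records], dtype=np.intp)

    feats = model.features
    blocks, manifest = [], {}
    if feats.fingerprints is not None:
        blocks.append(feats.fingerprints[drows])
        manifest["fingerprint"] = feats.fingerprints.shape[1]
    if feats.graphs is not None:
        flat = feats.graphs.node_features[drows].reshape(len(drows), -1)
        blocks.append(flat)
        manifest["graph_block"] = flat.shape[1]
    if feats.mirna is not None:
        blocks.append(feats.mirna[crows])
        manifest["mirna"] = feats.mirna.shape[1]
    if feats.cnv is not None:
        blocks.append(feats.cnv[crows])
        manifest["cnv"] = feats.cnv.shape[1]
    initial = np.concatenate(blocks, axis=1)

    _, stages = model.predict_indices(drows, crows, return_stages=True)
    labels = np.array([r.label for r in records], dtype=float)
    return {
        "pair_idx": sample,
        "labels": labels,
        "initial": initial,
        "extractor_concat": stages["extractor_concat"],
        "fusion_hidden": stages["fusion_hidden"],
        "manifest": {"initial_blocks": manifest,
                     "initial_width": initial.shape[1],
                     "extractor_width": stages["extractor_concat"].shape[1],
                     "fusion_hidden_width": stages["fusion_hidden"].shape[1]},
    }


def project_2d(X: np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D t-SNE projection (plumbing around scikit-learn)."""
    from sklearn.manifold import TSNE

    perplexity = min(30.0, max(2.0, X.shape[0] / 4.0))
    return TSNE(n_components=2, random_state=seed,
                perplexity=perplexity, init="pca").fit_transform(X)
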