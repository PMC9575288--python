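"""Loading, cleaning and normalization of drug-response and omics data.

The response target is an IC50 concentration: the pipeline drops non-positive
entries, takes the natural logarithm, removes box-plot outliers computed
jointly over all responses (fences at Q1 - k*IQR and Q3 + k*IQR with
interpolated type-7 quartiles), and min-max scales the surviving log values
to [0, 1].  The scaling is invertible, so predicted labels map back to
concentrations exactly.  Omics blocks are z-scored per feature with
training-set statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


# --------------------------------------------------------------------- types

@dataclass
class ResponseRecord:
    drug_id: str
    cell_id: str
    ic50_raw: float
    label: float | None = None  # set after the log + min-max transform

    def __post_init__(self):
        self.ic50_raw = float(self.ic50_raw)


@dataclass
class CellLineRecord:
    cell_id: str
    mirna: np.ndarray
    cnv: np.ndarray
    mirna_standardized: bool = False
    cnv_standardized: bool = False


@dataclass
class Dataset:
    """Drugs, cell lines and the sparse response panel tying them together."""

    drugs: dict = field(default_factory=dict)      # drug_id -> DrugRecord
    cells: dict[str, CellLineRecord] = field(default_factory=dict)
    responses: list[ResponseRecord] = field(default_factory=list)
    label_bounds: tuple[float, float] | None = None  # (log_min, log_max)

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.responses:
            if r.drug_id not in self.drugs:
                raise ValueError(f"response references unknown drug {r.drug_id!r}")
            if r.cell_id not in self.cells:
                raise ValueError(f"response references unknown cell line {r.cell_id!r}")
            pair = (r.drug_id, r.cell_id)
            if pair in seen:
                raise ValueError(f"duplicate response pair {pair}")
            seen.add(pair)
        if self.label_bounds is not None and not self.label_bounds[0] < self.label_bounds[1]:
            raise ValueError("label bounds must satisfy log_min < log_max")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.drugs.keys())

    @property
    def cell_ids(self) -> list[str]:
        return list(self.cells.keys())


# ------------------------------------------------------------------- loading

def load_response_table(path: str | Path, orientation: str = "long") -> list[ResponseRecord]:
    """Read a sparse response table.

    ``long`` orientation expects columns (drug_id, cell_id, ic50); ``matrix``
    orientation expects drug rows x cell columns with blanks for missing
    entries.  Missing entries are skipped, never imputed.
    """
    path = Path(path)
    if orientation == "long":
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] < 3:
            raise ValueError(f"{path}: long format needs >= 3 columns")
        records: list[ResponseRecord] = []
        seen: set[tuple[str, str]] = set()
        for i, row in enumerate(df.itertuples(index=False)):
            drug_id, cell_id, raw = str(row[0]), str(row[1]), row[2]
            if pd.isna(raw):
                continue
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise ValueError(f"{path}: non-numeric IC50 {raw!r} at row {i}") from None
            pair = (drug_id, cell_id)
            if pair in seen:
                raise ValueError(f"{path}: duplicate response pair {pair}")
            seen.add(pair)
            records.append(ResponseRecord(drug_id, cell_id, value))
        return records
    if orientation == "matrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        records = []
        for drug_id, row in df.iterrows():
            for cell_id, raw in row.items():
                if pd.isna(raw):
                    continue
                try:
                    value = float(raw)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric IC50 {raw!r} at ({drug_id}, {cell_id})"
                    ) from None
                records.append(ResponseRecord(str(drug_id), str(cell_id), value))
        return records
    raise ValueError(f"unknown orientation {orientation!r}")


def load_omics_table(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read an omics matrix: header of feature names, first column cell_id."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    matrix = df.to_numpy(dtype=float)
    if not np.isfinite(matrix).all():
        raise ValueError(f"{path}: omics matrix contains non-finite values")
    return [str(i) for i in df.index], [str(c) for c in df.columns], matrix


def load_manifest(path: str | Path) -> Dataset:
    """Assemble a Dataset from a YAML manifest naming all component files."""
    from . import featurize  # deferred: rdkit import is slow

    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    base = path.parent

    def resolve(key: str) -> Path:
        p = base / manifest[key]
        if not p.exists():
            raise FileNotFoundError(f"manifest entry {key!r} points to missing file {p}")
        return p

    drug_df = pd.read_csv(resolve("drugs"), sep=None, engine="python")
    drugs = {}
    for row in drug_df.itertuples(index=False):
        drug_id, smiles = str(row[0]), str(row[1])
        try:
            record = featurize.DrugRecord(drug_id=drug_id, smiles=smiles)
            record.graph = featurize.smiles_to_graph(smiles)
        except ValueError:
            continue  # unparseable SMILES: drop the drug
        drugs[drug_id] = record

    if "fingerprints" in manifest:
        fps = featurize.load_fingerprint_table(resolve("fingerprints"))
        for drug_id, fp in fps.items():
            if drug_id in drugs:
                drugs[drug_id].fingerprint = fp
    for record in drugs.values():
        if record.fingerprint is None:
            record.fingerprint = featurize.compute_fingerprint(record.smiles)

    mirna_ids, _, mirna = load_omics_table(resolve("mirna"))
    cnv_ids, _, cnv = load_omics_table(resolve("cnv"))
    common = [c for c in mirna_ids if c in set(cnv_ids)]
    cnv_pos = {c: i for i, c in enumerate(cnv_ids)}
    mirna_pos = {c: i for i, c in enumerate(mirna_ids)}
    cells = {
        c: CellLineRecord(c, mirna[mirna_pos[c]].copy(), cnv[cnv_pos[c]].copy())
        for c in common
    }

    responses = load_response_table(
        resolve("responses"), orientation=manifest.get("response_orientation", "long"))
    responses = [r for r in responses if r.drug_id in drugs and r.cell_id in cells]

    ds = Dataset(drugs=drugs, cells=cells, responses=responses)
    ds.validate()
    return ds


# ---------------------------------------------------------------- transforms

def log_transform(values) -> np.ndarray:
    """Natural logarithm; rejects non-positive inputs listing their indices."""
    values = np.asarray(values, dtype=float)
    bad = np.where(~(values > 0))[0]
    if bad.size:
        raise ValueError(f"non-positive values at indices {bad.tolist()[:20]}")
    return np.log(values)


def iqr_outlier_mask(values, k: float = 1.5) -> np.ndarray:
    """Box-plot outlier mask over *all* supplied values jointly.

    True marks values below Q1 - k*IQR or above Q3 + k*IQR, with quartiles
    from linear interpolation of the order statistics (type 7).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values to estimate quartiles")
    if not np.isfinite(values).all():
        raise ValueError("NaN or infinite values present")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


def normalize_labels(log_values, bounds: tuple[float, float] | None = None
                     ) -> tuple[np.ndarray, tuple[float, float]]:
    """Min-max scale log responses to [0, 1].

    When ``bounds`` is given (training-set bounds at inference) values are
    scaled with them and may fall outside [0, 1]; they are reported as-is.
    """
    log_values = np.asarray(log_values, dtype=float)
    if bounds is None:
        bounds = (float(log_values.min()), float(log_values.max()))
    lo, hi = bounds
    if not hi > lo:
        raise ValueError(f"degenerate label bounds ({lo}, {hi})")
    return (log_values - lo) / (hi - lo), bounds


def invert_labels(labels, bounds: tuple[float, float]) -> np.ndarray:
    lo, hi = bounds
    if not hi > lo:
        raise ValueError(f"degenerate label bounds ({lo}, {hi})")
    return np.asarray(labels, dtype=float) * (hi - lo) + lo


@dataclass
class PreprocessReport:
    """Bookkeeping of the response cleaning pipeline.

    Conservation holds exactly: n_in = n_retained + n_outliers + n_nonpositive.
    """
    n_in: int
    n_nonpositive: int
    n_outliers: int
    n_retained: int
    bounds: tuple[float, float]


def preprocess_responses(records: list[ResponseRecord], k: float = 1.5,
                         train_index: np.ndarray | None = None
                         ) -> tuple[list[ResponseRecord], PreprocessReport]:
    """Drop non-positive IC50s, log-transform, remove joint IQR outliers and
    attach min-max normalized labels.

    ``train_index`` (indices into the *retained* record list) restricts the
    min-max bounds to the training portion; by default all retained records
    define the bounds.
    """
    n_in = len(records)
    positive = [r for r in records if r.ic50_raw > 0]
    n_nonpositive = n_in - len(positive)
    logs = log_transform([r.ic50_raw for r in positive])
    mask = iqr_outlier_mask(logs, k=k)
    retained = [r for r, m in zip(positive, mask) if not m]
    logs = logs[~mask]
    n_outliers = int(mask.sum())
    if train_index is not None:
        _, bounds = normalize_labels(logs[np.asarray(train_index)])
        labels, _ = normalize_labels(logs, bounds)
    else:
        labels, bounds = normalize_labels(logs)
    for r, lab in zip(retained, labels):
        r.label = float(lab)
    report = PreprocessReport(
        n_in=n_in, n_nonpositive=n_nonpositive, n_outliers=n_outliers,
        n_retained=len(retained), bounds=bounds)
    return retained, report


def standardize_omics(matrix, train_rows) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Z-score each feature column with statistics of the training rows.

    Population (divisor-n) standard deviation; features constant over the
    training rows are mapped to zero everywhere and their sd recorded as 0.
    Returns the standardized matrix and the stats for reuse at inference.
    """
    matrix = np.asarray(matrix, dtype=float)
    train_rows = np.asarray(train_rows, dtype=np.intp)
    if train_rows.size == 0:
        raise ValueError("train_rows must be non-empty")
    mu = matrix[train_rows].mean(axis=0)
    sd = matrix[train_rows].std(axis=0)  # ddof=0
    stats = {"mean": mu, "sd": sd}
    return apply_standardization(matrix, stats), stats


def apply_standardization(matrix, stats: dict[str, np.ndarray]) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    mu, sd = stats["mean"], stats["sd"]
    if matrix.shape[1] != mu.shape[0]:
        raise ValueError(
            f"feature count mismatch: matrix has {matrix.shape[1]}, stats expect {mu.shape[0]}")
    out = np.zeros_like(matrix)
    nz = sd > 0
    out[:, nz] = (matrix[:, nz] - mu[nz]) / sd[nz]
    return out
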