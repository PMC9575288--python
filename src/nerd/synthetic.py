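"""Self-contained synthetic datasets with the structure the method assumes.

The generator emulates the statistical shape of a large drug-repurposing
response panel: a sparse heavy-tailed IC50 matrix over drugs x cell lines,
parseable small-molecule SMILES, and correlated omics blocks where the copy
number matrix carries a planted low-rank latent structure that also drives
part of the miRNA block.

The planted response surface is

    log IC50(d, c) = alpha * z_d + beta * z_c + gamma * z_d * z_c + eps,

with z_d a standardized linear score of the drug's substructure fingerprint,
z_c a standardized linear score of the cell's latent factors (the factors
shared with the copy-number block by default, or the miRNA-private factors in
the ``mirna_private`` variant, where copy number then carries no response
signal), and eps ~ Normal(0, noise_sd).  One percent of the observed entries
is multiplied by 50 to plant box-plot outliers with known identities.  All
generating weights are returned for oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

from .core_data import CellLineRecord, Dataset, ResponseRecord
from .featurize import DrugRecord, compute_fingerprint, smiles_to_graph

ALPHA, BETA, GAMMA = 0.5, 0.5, 0.15  # response-surface coefficients (log scale)
OUTLIER_FRACTION = 0.01
OUTLIER_MULTIPLIER = 50.0


@dataclass
class SyntheticScenario:
    n_drugs: int = 60
    n_cells: int = 40
    mirna_dim: int = 200
    cnv_dim: int = 2000
    label_density: float = 0.45
    noise_sd: float = 0.05
    latent_rank: int = 5
    seed: int = 0
    cell_signal: str = "shared"  # or "mirna_private"

    def __post_init__(self):
        if self.n_drugs < 2 or self.n_cells < 2:
            raise ValueError("need at least 2 drugs and 2 cells")
        if not 0 < self.label_density <= 1:
            raise ValueError("label_density must be in (0, 1]")
        if self.latent_rank >= min(self.mirna_dim, self.cnv_dim):
            raise ValueError("latent_rank must be smaller than both omics widths")
        if self.cell_signal not in ("shared", "mirna_private"):
            raise ValueError(f"unknown cell_signal {self.cell_signal!r}")


# fragment grammar: pieces that stay valid under plain concatenation
_MID_FRAGMENTS = [
    "C", "CC", "CCC", "CCCC", "O", "N", "C(C)", "C(=O)", "C(=O)N", "C(=O)O",
    "c1ccccc1", "c1ccncc1", "c1ccsc1", "c1ccoc1", "C1CCCCC1", "C1CCNCC1",
    "C1CCOCC1", "C(F)(F)", "S", "C(Cl)",
]
_TERMINAL_FRAGMENTS = ["", "C", "O", "N", "Cl", "Br", "F", "C#N", "C(=O)O", "C(F)(F)F"]

MIN_HEAVY_ATOMS, MAX_HEAVY_ATOMS = 3, 30


def gen_drugs(n: int, seed: int = 0) -> list[DrugRecord]:
    """Drugs assembled from a small fragment grammar; every SMILES parses and
    has 3-30 heavy atoms.  Fingerprints and graphs are computed eagerly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[DrugRecord] = []
    seen: set[str] = set()
    while len(records) < n:
        n_mid = int(rng.integers(1, 5))
        body = "".join(rng.choice(_MID_FRAGMENTS) for _ in range(n_mid))
        smiles = body + str(rng.choice(_TERMINAL_FRAGMENTS))
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        if not MIN_HEAVY_ATOMS <= mol.GetNumAtoms() <= MAX_HEAVY_ATOMS:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen and len(seen) < 4 * n:
            continue  # prefer distinct molecules; give up if the space is tight
        seen.add(canonical)
        drug_id = f"D{len(records):04d}"
        records.append(DrugRecord(
            drug_id=drug_id, smiles=smiles,
            fingerprint=compute_fingerprint(smiles, drug_id),
            graph=smiles_to_graph(smiles, drug_id)))
    return records


@dataclass
class CellFactors:
    shared: np.ndarray        # (m, r) latents driving cnv and part of mirna
    mirna_private: np.ndarray  # (m, r) latents driving mirna only
    cnv_noiseless: np.ndarray  # the rank-r component of the cnv block


def gen_cells(m: int, mirna_dim: int, cnv_dim: int, latent_rank: int,
              seed: int = 0) -> tuple[list[CellLineRecord], CellFactors]:
    """Correlated omics: cnv = shared latents x loadings + noise; mirna mixes
    the shared latents with miRNA-private factors."""
    if latent_rank >= min(mirna_dim, cnv_dim):
        raise ValueError("latent_rank must be smaller than both omics widths")
    rng = np.random.default_rng(seed)
    r = latent_rank
    shared = rng.normal(size=(m, r))
    private = rng.normal(size=(m, r))
    b_cnv = rng.normal(size=(r, cnv_dim)) / np.sqrt(r)
    cnv_clean = shared @ b_cnv
    cnv = cnv_clean + 0.1 * rng.normal(size=(m, cnv_dim))
    b_mir_shared = rng.normal(size=(r, mirna_dim)) / np.sqrt(r)
    b_mir_private = rng.normal(size=(r, mirna_dim)) / np.sqrt(r)
    mirna = (0.6 * shared @ b_mir_shared + 0.8 * private @ b_mir_private
             + 0.1 * rng.normal(size=(m, mirna_dim)))
    cells = [CellLineRecord(f"CL{i:04d}", mirna[i].copy(), cnv[i].copy())
             for i in range(m)]
    return cells, CellFactors(shared, private, cnv_clean)


@dataclass
class GroundTruth:
    """Everything the generator knows, returned for oracle checks."""
    w_fp: np.ndarray
    w_lat: np.ndarray
    drug_score: np.ndarray   # standardized z_d per drug
    cell_score: np.ndarray   # standardized z_c per cell
    log_clean: np.ndarray    # noiseless log response surface (drugs x cells)
    observed: np.ndarray     # boolean mask (drugs x cells)
    outlier_pairs: set[tuple[str, str]] = field(default_factory=set)
    factors: CellFactors | None = None


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd < 1e-12:
        raise ValueError("degenerate planted score (no variance)")
    return (v - v.mean()) / sd


def gen_responses(drugs: list[DrugRecord], cells: list[CellLineRecord],
                  scenario: SyntheticScenario, factors: CellFactors
                  ) -> tuple[Dataset, GroundTruth]:
    """Sparse response panel with the planted log-linear surface and 1% of the
    observed entries multiplied by 50 as planted box-plot outliers."""
    rng = np.random.default_rng(scenario.seed + 1000)
    fp = np.stack([d.fingerprint.bits for d in drugs]).astype(float)
    w_fp = rng.normal(size=fp.shape[1])
    z_d = _standardize(fp @ w_fp)
    latent = (factors.shared if scenario.cell_signal == "shared"
              else factors.mirna_private)
    w_lat = rng.normal(size=latent.shape[1])
    z_c = _standardize(latent @ w_lat)

    D, C = len(drugs), len(cells)
    eps = rng.normal(scale=scenario.noise_sd, size=(D, C))
    log_clean = (ALPHA * z_d[:, None] + BETA * z_c[None, :]
                 + GAMMA * np.outer(z_d, z_c))
    log_ic50 = log_clean + eps
    observed = rng.random((D, C)) < scenario.label_density

    obs_flat = np.flatnonzero(observed.ravel())
    n_out = max(1, round(OUTLIER_FRACTION * obs_flat.size))
    out_flat = rng.choice(obs_flat, size=n_out, replace=False)
    out_mask = np.zeros(D * C, dtype=bool)
    out_mask[out_flat] = True
    out_mask = out_mask.reshape(D, C)
    log_ic50 = log_ic50 + np.log(OUTLIER_MULTIPLIER) * out_mask

    responses = []
    outlier_pairs = set()
    for i in range(D):
        for j in range(C):
            if observed[i, j]:
                responses.append(ResponseRecord(
                    drugs[i].drug_id, cells[j].cell_id, float(np.exp(log_ic50[i, j]))))
                if out_mask[i, j]:
                    outlier_pairs.add((drugs[i].drug_id, cells[j].cell_id))

    ds = Dataset(drugs={d.drug_id: d for d in drugs},
                 cells={c.cell_id: c for c in cells},
                 responses=responses)
    ds.validate()
    truth = GroundTruth(w_fp=w_fp, w_lat=w_lat, drug_score=z_d, cell_score=z_c,
                        log_clean=log_clean, observed=observed,
                        outlier_pairs=outlier_pairs, factors=factors)
    return ds, truth


def generate_scenario(scenario: SyntheticScenario | None = None
                      ) -> tuple[Dataset, GroundTruth]:
    """Full pipeline: drugs, cells, responses (labels not yet normalized;
    run :func:`nerd.core_data.preprocess_responses` on ``dataset.responses``)."""
    scenario = scenario or SyntheticScenario()
    drugs = gen_drugs(scenario.n_drugs, seed=scenario.seed)
    cells, factors = gen_cells(scenario.n_cells, scenario.mirna_dim,
                               scenario.cnv_dim, scenario.latent_rank,
                               seed=scenario.seed + 500)
    return gen_responses(drugs, cells, scenario, factors)


def write_scenario(dataset: Dataset, out_dir: str | Path,
                   scenario: SyntheticScenario | None = None) -> Path:
    """Write the dataset in the exact file formats the readers consume and
    return the manifest path, so loading back exercises the real parsers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    drug_ids = dataset.drug_ids
    pd.DataFrame({"drug_id": drug_ids,
                  "smiles": [dataset.drugs[d].smiles for d in drug_ids]
                  }).to_csv(out_dir / "drugs.csv", index=False)
    fp = pd.DataFrame(
        np.stack([dataset.drugs[d].fingerprint.bits for d in drug_ids]),
        index=pd.Index(drug_ids, name="drug_id"),
        columns=[f"bit{i}" for i in range(dataset.drugs[drug_ids[0]].fingerprint.bits.size)])
    fp.to_csv(out_dir / "fingerprints.csv")

    cell_ids = dataset.cell_ids
    for name, attr in (("mirna", "mirna"), ("cnv", "cnv")):
        mat = np.stack([getattr(dataset.cells[c], attr) for c in cell_ids])
        pd.DataFrame(mat, index=pd.Index(cell_ids, name="cell_id"),
                     columns=[f"{name}_{i}" for i in range(mat.shape[1])]
                     ).to_csv(out_dir / f"{name}.csv")

    pd.DataFrame({
        "drug_id": [r.drug_id for r in dataset.responses],
        "cell_id": [r.cell_id for r in dataset.responses],
        "ic50": [r.ic50_raw for r in dataset.responses],
    }).to_csv(out_dir / "responses.csv", index=False)

    manifest = {
        "drugs": "drugs.csv", "fingerprints": "fingerprints.csv",
        "mirna": "mirna.csv", "cnv": "cnv.csv", "responses": "responses.csv",
        "response_orientation": "long",
    }
    if scenario is not None:
        manifest["scenario"] = {k: getattr(scenario, k) for k in (
            "n_drugs", "n_cells", "mirna_dim", "cnv_dim", "label_density",
            "noise_sd", "latent_rank", "seed", "cell_signal")}
    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh)
    return path
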