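"""Synthetic data generators with planted ground truth.

Every input consumed by the analysis modules can be produced here from a
seeded configuration, so each stage's recovery can be asserted against a
known answer: which blend components dominate the tumor matrisome, which
single-cell clusters carry which identity, how strongly each cell line
attaches to each substrate, and what the true cell-type census of a
culture is.

Randomness
----------
Each generator derives its own ``numpy.random.Generator`` from
``np.random.SeedSequence(seed)``.  Generators never share stream state,
so the same seed reproduces the same table regardless of call order.

Noise models (documented choices)
---------------------------------
* Protein intensities are lognormal per gene per group; fold changes act
  on the median.  This is the standard noise model for label-free
  quantification data.
* Single-cell counts are negative binomial with a shared dispersion,
  sampled as a gamma-Poisson mixture — the standard scRNA-seq assumption.
* Marker booleans are corrupted by independent Bernoulli flips at rates
  (1 - sensitivity) for true positives and (1 - specificity) for true
  negatives.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .reference import core_genes, load_matrisome_reference

# ---------------------------------------------------------------------------
# proteomics

#: the nine-component tumor-mimetic ECM blend: collagen VI, fibronectin,
#: tenascin C, perlecan, collagen XII, TGFBI, lumican, periostin, laminin
DEFAULT_PLANTED = (
    "COL6A1", "FN1", "TNC", "HSPG2", "COL12A1",
    "TGFBI", "LUM", "POSTN", "LAMA4",
)

COAG_GENES = ("FGA", "FGB", "FGG")


@dataclass(frozen=True)
class ProteomicsSimConfig:
    """Paired tumor / adjacent-normal LFQ simulation.

    The planted components receive a ``tumor_fold`` median enrichment in
    the tumor group; background core-matrisome genes sit below the
    planted baseline (log-uniform over [0.3, 1.0] x ``base_scale``) so
    that the planted set dominates the tumor core matrisome while every
    core gene remains above the 0.1 %LFQ retention floor.  Coagulation
    genes (fibrinogen chains) are simulated as highly abundant — a few
    percent of total intensity, as seen in tumor lysates — so that the
    coagulation-exclusion step has something meaningful to remove.
    """

    seed: int = 0
    n_core: int = 36
    n_other: int = 200
    n_coag: int = 3
    n_samples_per_group: int = 5
    planted_components: tuple[str, ...] = DEFAULT_PLANTED
    tumor_fold: float = 4.0
    cv: float = 0.3
    base_scale: float = 1e6
    coag_rel_abundance: float = 5.0
    coag_tumor_fold: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples_per_group <= 0:
            raise ValueError("n_samples_per_group must be positive")
        if min(self.n_core, self.n_other, self.n_coag) < 0:
            raise ValueError("gene counts must be >= 0")
        if self.cv <= 0:
            raise ValueError("cv must be > 0")
        if self.n_core < len(self.planted_components):
            raise ValueError("n_core must cover the planted components")
        if self.n_coag > len(COAG_GENES):
            raise ValueError(f"at most {len(COAG_GENES)} coagulation genes available")
        available = core_genes()
        missing = [g for g in self.planted_components if g not in available]
        if missing:
            raise ValueError(f"planted gene(s) not in core list: {missing}")
        if self.n_core > len(available):
            raise ValueError(
                f"n_core={self.n_core} exceeds the {len(available)} core genes "
                "in the packaged reference"
            )


def lognormal_sigma(cv: float) -> float:
    """Log-scale SD of a lognormal with the given coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv))


def draw_lognormal(rng: np.random.Generator, median: float, cv: float, size=None):
    """Lognormal intensities parameterized by median and CV.

    Mean is ``median * exp(sigma^2 / 2)`` with ``sigma`` from
    :func:`lognormal_sigma`; useful as the analytic moment in
    Monte-Carlo checks.
    """
    sigma = lognormal_sigma(cv)
    return median * np.exp(sigma * rng.standard_normal(size))


def gen_proteomics(config: ProteomicsSimConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a long-format protein quantification table.

    Returns ``(records, truth)`` where ``records`` has columns
    ``protein_id, gene, sample, group, intensity`` for
    ``n_samples_per_group`` tumor and normal samples, and ``truth``
    carries the planted component list, per-gene group medians and
    expected fold changes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    planted = list(config.planted_components)
    background = [g for g in core_genes() if g not in planted]
    core = planted + background[: config.n_core - len(planted)]
    other = [f"OTHG{i:04d}" for i in range(config.n_other)]
    coag = list(COAG_GENES[: config.n_coag])

    medians_normal: dict[str, float] = {}
    folds: dict[str, float] = {}
    for g in core:
        if g in planted:
            medians_normal[g] = config.base_scale
            folds[g] = config.tumor_fold
        else:
            medians_normal[g] = config.base_scale * _loguniform(rng, 0.3, 1.0)
            folds[g] = 1.0
    for g in other:
        medians_normal[g] = config.base_scale * _loguniform(rng, 0.02, 2.0)
        folds[g] = 1.0
    for g in coag:
        medians_normal[g] = config.base_scale * config.coag_rel_abundance
        folds[g] = config.coag_tumor_fold

    genes = core + other + coag
    n = config.n_samples_per_group
    samples = [(f"T{i + 1}", "tumor") for i in range(n)] + [
        (f"N{i + 1}", "normal") for i in range(n)
    ]
    rows = []
    for gene in genes:
        for sample, group in samples:
            median = medians_normal[gene] * (folds[gene] if group == "tumor" else 1.0)
            intensity = float(draw_lognormal(rng, median, config.cv))
            rows.append((f"P_{gene}", gene, sample, group, intensity))
    records = pd.DataFrame(
        rows, columns=["protein_id", "gene", "sample", "group", "intensity"]
    )
    truth = {
        "planted_components": planted,
        "core_genes": core,
        "coag_genes": coag,
        "median_normal": medians_normal,
        "fold_change": folds,
        "cv": config.cv,
        "sigma": lognormal_sigma(config.cv),
    }
    return records, truth


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size))


# ---------------------------------------------------------------------------
# single-cell counts

IDENTITY_MARKERS: dict[str, tuple[str, ...]] = {
    "Epithelial": ("AQP1", "AQP2", "EPCAM"),
    "Endothelial": ("PLVAP", "PECAM1", "CD34"),
    "Fibroblast": ("PDGFRB", "PDGFRA"),
    "Immune": ("PTPRC",),
    "Tumor": ("CXCR4", "VIM", "KRT18", "PAX8", "PAX2", "CA9", "MME"),
}

CAF_MARKERS = ("ACTA2", "IGFBP7", "TAGLN", "MYL9", "MYLK", "REN")

DEFAULT_ECM_GENES = (
    "COL6A1", "COL6A2", "COL6A3", "FN1", "LUM",
    "COL12A1", "HSPG2", "TNC", "POSTN", "TGFBI",
)

SC_IDENTITIES = frozenset(
    {"Epithelial", "Endothelial", "Fibroblast", "CAF-Fibroblast", "Immune", "Tumor"}
)


@dataclass(frozen=True)
class ClusterSpec:
    cluster_id: str
    identity: str
    multiplier: float = 4.0

    def __post_init__(self) -> None:
        if self.identity not in SC_IDENTITIES:
            raise ValueError(f"unknown identity {self.identity!r}")
        if self.multiplier < 1:
            raise ValueError("marker multiplier must be >= 1")


def default_cluster_plan(multiplier: float = 4.0) -> tuple[ClusterSpec, ...]:
    """One cluster per identity, including a CAF fibroblast subcluster."""
    return (
        ClusterSpec("c_epi", "Epithelial", multiplier),
        ClusterSpec("c_endo", "Endothelial", multiplier),
        ClusterSpec("c_fib", "Fibroblast", multiplier),
        ClusterSpec("c_caf", "CAF-Fibroblast", multiplier),
        ClusterSpec("c_imm", "Immune", multiplier),
        ClusterSpec("c_tum", "Tumor", multiplier),
    )


@dataclass(frozen=True)
class ScSimConfig:
    """Negative-binomial gene x cell count simulation with planted clusters.

    ``ecm_load`` maps cluster ids to a multiplier applied to the ECM
    gene panel, emulating matrix-producing populations; CAF fibroblast
    clusters additionally elevate the CAF marker set (ACTA2, IGFBP7,
    TAGLN, MYL9, MYLK, REN).
    """

    seed: int = 0
    n_cells_per_cluster: int = 300
    cluster_plan: tuple[ClusterSpec, ...] = field(default_factory=default_cluster_plan)
    ecm_load: tuple[tuple[str, float], ...] = ()
    ecm_genes: tuple[str, ...] = DEFAULT_ECM_GENES
    gene_boost: tuple[tuple[str, str, float], ...] = ()
    nb_dispersion: float = 2.0
    library_size_mean: float = 5000.0
    n_filler_genes: int = 300

    def __post_init__(self) -> None:
        if not self.cluster_plan:
            raise ValueError("cluster plan is empty")
        if self.n_cells_per_cluster <= 0:
            raise ValueError("n_cells_per_cluster must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        ids = [c.cluster_id for c in self.cluster_plan]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cluster ids")
        for cid, mult in self.ecm_load:
            if cid not in ids:
                raise ValueError(f"ecm_load references unknown cluster {cid!r}")
            if mult < 1:
                raise ValueError("ECM multipliers must be >= 1")
        for cid, _, mult in self.gene_boost:
            if cid not in ids:
                raise ValueError(f"gene_boost references unknown cluster {cid!r}")
            if mult < 1:
                raise ValueError("gene boosts must be >= 1")


def _sc_gene_list(config: ScSimConfig) -> list[str]:
    genes: list[str] = []
    for panel in IDENTITY_MARKERS.values():
        genes.extend(panel)
    genes.extend(CAF_MARKERS)
    genes.extend(g for g in config.ecm_genes if g not in genes)
    genes.extend(f"FILL{i:04d}" for i in range(config.n_filler_genes))
    return genes


def gen_counts(config: ScSimConfig) -> tuple[ad.AnnData, dict]:
    """Generate a cells x genes integer count matrix as an AnnData.

    Marker genes of each cluster's planted identity are elevated by that
    cluster's multiplier; CAF fibroblast clusters elevate fibroblast
    markers plus the CAF panel; clusters listed in ``ecm_load`` elevate
    the ECM gene panel.  ``adata.obs["cluster"]`` holds labels; the
    returned truth dict maps cluster id to planted identity.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genes = _sc_gene_list(config)
    n_genes = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}

    # panel/CAF/ECM genes get a detectable baseline (markers of real cell
    # types are expressed, not borderline); filler genes span a wider range
    n_signal = n_genes - config.n_filler_genes
    base = np.concatenate(
        [
            _loguniform(rng, 0.5, 3.0, size=n_signal),
            _loguniform(rng, 0.1, 3.0, size=config.n_filler_genes),
        ]
    )

    ecm_load = dict(config.ecm_load)
    blocks, labels = [], []
    for spec in config.cluster_plan:
        mu = base.copy()
        identity = "Fibroblast" if spec.identity == "CAF-Fibroblast" else spec.identity
        for g in IDENTITY_MARKERS[identity]:
            mu[gene_idx[g]] *= spec.multiplier
        if spec.identity == "CAF-Fibroblast":
            for g in CAF_MARKERS:
                mu[gene_idx[g]] *= spec.multiplier
        for g in config.ecm_genes:
            mu[gene_idx[g]] *= ecm_load.get(spec.cluster_id, 1.0)
        for cid, g, mult in config.gene_boost:
            if cid == spec.cluster_id:
                mu[gene_idx[g]] *= mult
        # equalize expected library size across clusters, mirroring the
        # per-cell depth normalization the analysis applies; multipliers
        # therefore act on a cluster's expression *composition*
        mu *= config.library_size_mean / mu.sum()
        theta = config.nb_dispersion
        lam = rng.gamma(theta, mu / theta, size=(config.n_cells_per_cluster, n_genes))
        blocks.append(rng.poisson(lam))
        labels.extend([spec.cluster_id] * config.n_cells_per_cluster)

    X = sparse.csr_matrix(np.vstack(blocks).astype(np.int64))
    obs = pd.DataFrame(
        {"cluster": pd.Categorical(labels)},
        index=[f"cell{i:05d}" for i in range(X.shape[0])],
    )
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    adata = ad.AnnData(X=X, obs=obs, var=var)
    truth = {
        "identity": {c.cluster_id: c.identity for c in config.cluster_plan},
        "multiplier": {c.cluster_id: c.multiplier for c in config.cluster_plan},
        "ecm_load": ecm_load,
        "ecm_genes": list(config.ecm_genes),
    }
    return adata, truth


def write_counts(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write genes x cells Matrix Market + genes.tsv/cells.tsv + labels.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sparse.csr_matrix(adata.X)
    spio.mmwrite(outdir / "matrix.mtx", X.T.astype(np.int64))
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "cells.tsv", index=False, header=False)
    if "cluster" in adata.obs:
        adata.obs[["cluster"]].rename_axis("cell").to_csv(outdir / "labels.csv")


def read_counts(outdir: str | Path) -> ad.AnnData:
    """Read a directory written by :func:`write_counts` back into AnnData."""
    outdir = Path(outdir)
    X = sparse.csr_matrix(spio.mmread(outdir / "matrix.mtx")).T
    genes = pd.read_csv(outdir / "genes.tsv", header=None)[0].tolist()
    cells = pd.read_csv(outdir / "cells.tsv", header=None)[0].tolist()
    adata = ad.AnnData(
        X=X.astype(np.int64),
        obs=pd.DataFrame(index=cells),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    labels = outdir / "labels.csv"
    if labels.exists():
        lab = pd.read_csv(labels, index_col="cell")
        adata.obs["cluster"] = pd.Categorical(lab.loc[adata.obs_names, "cluster"])
    return adata


# ---------------------------------------------------------------------------
# attachment assay

def gen_attachment(
    prob_matrix: pd.DataFrame,
    n_seeded: int = 2000,
    seed: int = 0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Binomial attachment counts per (cell line, substrate, replicate).

    ``prob_matrix`` is cell lines (rows) x substrates (columns) of
    attachment probabilities; each replicate draws
    ``Binomial(n_seeded, p)`` attached cells.
    """
    probs = prob_matrix.to_numpy(dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("attachment probabilities must lie in [0, 1]")
    if n_seeded < 0:
        raise ValueError("n_seeded must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for line in prob_matrix.index:
        for substrate in prob_matrix.columns:
            p = float(prob_matrix.loc[line, substrate])
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (line, substrate, rep, int(rng.binomial(n_seeded, p)), n_seeded)
                )
    return pd.DataFrame(
        rows, columns=["cell_line", "substrate", "replicate", "attached", "seeded"]
    )


# ---------------------------------------------------------------------------
# cultured-cell marker tables

#: noise-free marker templates per true cell type (the staining-panel
#: definitions used by the census classifier). Immune CXCR4 is drawn
#: "+/-" — positive with probability 0.5 — since the phenotype allows
#: either state.
TYPE_TEMPLATES: dict[str, dict[str, bool | None]] = {
    "Fibroblast": {
        "PDGFRAB": True, "CD45": False, "CD34": False,
        "VIM": True, "CK18": False, "PAX28": False, "CXCR4": False,
    },
    "Endothelial": {
        "PDGFRAB": False, "CD45": False, "CD34": True,
        "VIM": False, "CK18": False, "PAX28": False, "CXCR4": False,
    },
    "Immune": {
        "PDGFRAB": False, "CD45": True, "CD34": False,
        "VIM": False, "CK18": False, "PAX28": False, "CXCR4": None,
    },
    "Tumor": {
        "PDGFRAB": False, "CD45": False, "CD34": False,
        "VIM": True, "CK18": True, "PAX28": True, "CXCR4": True,
    },
    "Other": {
        "PDGFRAB": False, "CD45": False, "CD34": False,
        "VIM": False, "CK18": False, "PAX28": False, "CXCR4": False,
    },
}

CENSUS_MARKERS = ("PDGFRAB", "CD45", "CD34", "VIM", "CK18", "PAX28", "CXCR4")


@dataclass(frozen=True)
class CensusSimConfig:
    """Dissociated-tumor cell suspension simulation.

    Default proportions reflect a tumor-cell-dominant suspension with a
    small fibroblast compartment (~7% of cells), with marker booleans
    corrupted at the stated sensitivity/specificity.  ``edu_prob`` plants
    a per-type proliferation probability for the EDU marker.
    """

    seed: int = 0
    n_cells: int = 1000
    true_type_proportions: tuple[tuple[str, float], ...] = (
        ("Tumor", 0.55),
        ("Immune", 0.20),
        ("Endothelial", 0.10),
        ("Fibroblast", 0.07),
        ("Other", 0.08),
    )
    marker_sensitivity: float = 0.95
    marker_specificity: float = 0.95
    edu_prob: tuple[tuple[str, float], ...] = ()
    condition: str = "input"

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        props = dict(self.true_type_proportions)
        unknown = set(props) - set(TYPE_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown cell type(s) in proportions: {sorted(unknown)}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("type proportions must sum to 1")
        for p in (self.marker_sensitivity, self.marker_specificity):
            if not 0.0 <= p <= 1.0:
                raise ValueError("sensitivity/specificity must lie in [0, 1]")


def _allocate_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation: counts sum to n, composition exact."""
    raw = {t: n * p for t, p in proportions.items()}
    counts = {t: int(math.floor(v)) for t, v in raw.items()}
    short = n - sum(counts.values())
    for t in sorted(raw, key=lambda t: raw[t] - counts[t], reverse=True)[:short]:
        counts[t] += 1
    return counts


def gen_culture_cells(config: CensusSimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a per-cell marker table plus true labels.

    Type counts follow the configured proportions exactly (largest
    remainder), so at sensitivity = specificity = 1 the census equals
    the configured composition with no sampling error.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    props = dict(config.true_type_proportions)
    counts = _allocate_counts(config.n_cells, props)
    edu_prob = dict(config.edu_prob)

    types: list[str] = []
    for t, c in counts.items():
        types.extend([t] * c)
    rng.shuffle(types)

    rows = []
    for i, t in enumerate(types):
        template = TYPE_TEMPLATES[t]
        markers: dict[str, bool] = {}
        for m in CENSUS_MARKERS:
            truth = template[m]
            if truth is None:
                truth = bool(rng.random() < 0.5)
            if truth:
                observed = rng.random() < config.marker_sensitivity
            else:
                observed = rng.random() >= config.marker_specificity
            markers[m] = bool(observed)
        row = {"cell_id": f"cell{i:05d}", "condition": config.condition, **markers}
        if edu_prob:
            row["EDU"] = bool(rng.random() < edu_prob.get(t, 0.0))
        rows.append(row)
    table = pd.DataFrame(rows)
    labels = pd.Series(types, index=table["cell_id"].to_numpy(), name="true_type")
    return table, labels


# ---------------------------------------------------------------------------
# 3D structures

def gen_structures(
    n: int,
    live_prob: float = 0.8,
    diameter_lognormal_params: tuple[float, float] = (math.log(30.0), 0.4),
    seed: int = 0,
    condition: str = "dome",
) -> pd.DataFrame:
    """Hoechst-positive 3D structures with complementary live/dead stains.

    Each structure is live (calcein+/EthD2-) with probability
    ``live_prob`` and dead (calcein-/EthD2+) otherwise; diameters in um
    are lognormal with the given (mean log, SD log).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= live_prob <= 1.0:
        raise ValueError("live_prob must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mu, sigma = diameter_lognormal_params
    live = rng.random(n) < live_prob
    diameters = np.exp(mu + sigma * rng.standard_normal(n))
    return pd.DataFrame(
        {
            "structure_id": [f"s{i:05d}" for i in range(n)],
            "condition": condition,
            "hoechst_pos": True,
            "calcein_pos": live,
            "ethd2_pos": ~live,
            "diameter": diameters,
        }
    )


# ---------------------------------------------------------------------------
# plumbing: CSV / JSON round-trips

def write_proteomics(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_proteomics(path: str | Path) -> pd.DataFrame:
    records = pd.read_csv(path)
    records["gene"] = records["gene"].str.upper()
    return records


def write_cells(table: pd.DataFrame, path: str | Path) -> None:
    """Cells CSV with marker columns encoded 1/0/NA."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype == bool or col in CENSUS_MARKERS or col == "EDU":
            out[col] = out[col].map({True: 1, False: 0})
    out.to_csv(path, index=False, na_rep="NA")


def read_cells(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, na_values=["NA"])
    for col in table.columns:
        if col in CENSUS_MARKERS or col == "EDU":
            table[col] = table[col].map({1: True, 0: False, 1.0: True, 0.0: False})
    return table


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
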