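"""Differential matrisome composition and ECM blend formulation.

Pipeline: annotate protein quantification records against the matrisome
reference, exclude coagulation components (GO:0050817), convert
intensities to percent-of-total label-free quantification (%LFQ),
renormalize abundant core-matrisome proteins (> 0.1 %LFQ) to percent of
core matrisome, and select components at or above the third abundance
quartile to formulate a tumor-mimetic ECM blend at a stated total
protein concentration (2 ug/mL by default).

Differential abundance between tumor and adjacent-normal samples uses
Welch's t-test on log2 intensities with Benjamini-Hochberg correction,
honoring the stated significance gates (p < 0.05, FDR < 1%).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import COAGULATION_GO, load_matrisome_reference
from .stats import bh_qvalues, welch_t


@dataclass(frozen=True)
class ThresholdConfig:
    """The analysis thresholds, with their conventional defaults.

    ``core_abundance_cut_pct`` is the %LFQ floor (percent of total
    sample intensity, tumor group) below which a core-matrisome protein
    is dropped before renormalization; ``quartile_pct`` is the abundance
    percentile at or above which renormalized components enter the
    blend.
    """

    p_cut: float = 0.05
    fdr_cut: float = 0.01
    core_abundance_cut_pct: float = 0.1
    quartile_pct: float = 75.0
    coag_go: str = COAGULATION_GO
    group_summary: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        if not 0 < self.p_cut < 1 or not 0 < self.fdr_cut < 1:
            raise ValueError("p_cut and fdr_cut must lie in (0, 1)")
        if self.core_abundance_cut_pct <= 0:
            raise ValueError("core abundance cut must be > 0")
        if not 0 < self.quartile_pct < 100:
            raise ValueError("quartile_pct must lie in (0, 100)")
        if self.group_summary not in ("mean", "median"):
            raise ValueError("group_summary must be 'mean' or 'median'")


@dataclass(frozen=True)
class BlendRecipe:
    """A named ECM blend: fractional composition and mass concentrations.

    ``components`` maps gene symbol to blend fraction (sums to 1);
    ``coverage`` is the fraction of total core-matrisome %LFQ captured
    by the selected components before renormalization.
    """

    components: tuple[tuple[str, float], ...]
    total_conc: float = 2.0
    coverage: float = 1.0

    @property
    def fractions(self) -> dict[str, float]:
        return dict(self.components)

    @property
    def mass_conc(self) -> dict[str, float]:
        return {g: f * self.total_conc for g, f in self.components}

    def to_dict(self) -> dict:
        return {
            "total_conc_ug_per_ml": self.total_conc,
            "coverage": self.coverage,
            "components": [
                {"gene": g, "fraction": f, "ug_per_ml": f * self.total_conc}
                for g, f in self.components
            ],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "BlendRecipe":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            components=tuple((c["gene"], c["fraction"]) for c in d["components"]),
            total_conc=d["total_conc_ug_per_ml"],
            coverage=d["coverage"],
        )


# ---------------------------------------------------------------------------
# annotation and exclusion

def annotate_matrisome(
    records: pd.DataFrame, reference: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Tag each record with matrisome division, category and GO terms.

    Genes absent from the reference are labeled non-matrisome.  No
    records are created or dropped.
    """
    if reference is None:
        reference = load_matrisome_reference()
    if reference.index.duplicated().any():
        raise ValueError("duplicate gene in matrisome reference")
    out = records.copy()
    out["gene"] = out["gene"].str.upper()
    out["division"] = out["gene"].map(reference["division"]).fillna("non-matrisome")
    out["category"] = out["gene"].map(reference["category"]).fillna("none")
    go = out["gene"].map(reference["go_terms"])
    out["go_terms"] = [s if isinstance(s, frozenset) else frozenset() for s in go]
    return out


def exclude_coagulation(
    annotated: pd.DataFrame, config: ThresholdConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split annotated records into (retained, coagulation-excluded)."""
    config = config or ThresholdConfig()
    if "go_terms" not in annotated:
        raise ValueError("records must be annotated before coagulation exclusion")
    is_coag = annotated["go_terms"].map(lambda s: config.coag_go in s)
    return annotated[~is_coag].copy(), annotated[is_coag].copy()


# ---------------------------------------------------------------------------
# %LFQ

def pct_lfq(records: pd.DataFrame, group_summary: str = "mean") -> pd.DataFrame:
    """Per-gene, per-group percent of total sample intensity.

    Within each sample, a gene's %LFQ is 100 * intensity / sample total;
    the group value is the mean (or median) across that group's samples.
    Returns a DataFrame indexed by gene with columns ``pct_lfq_tumor``
    and ``pct_lfq_normal``.
    """
    wide = records.pivot_table(
        index="gene", columns="sample", values="intensity", aggfunc="sum"
    ).fillna(0.0)
    totals = wide.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"sample(s) with non-positive total intensity: {bad}")
    pct = 100.0 * wide / totals

    groups = records.drop_duplicates("sample").set_index("sample")["group"]
    out = {}
    for group in ("tumor", "normal"):
        cols = groups.index[groups == group]
        if len(cols) == 0:
            continue
        block = pct[cols]
        out[f"pct_lfq_{group}"] = (
            block.mean(axis=1) if group_summary == "mean" else block.median(axis=1)
        )
    return pd.DataFrame(out)


def per_sample_pct(records: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample %LFQ matrix (columns each sum to 100)."""
    wide = records.pivot_table(
        index="gene", columns="sample", values="intensity", aggfunc="sum"
    ).fillna(0.0)
    return 100.0 * wide / wide.sum(axis=0)


# ---------------------------------------------------------------------------
# differential abundance

def differential_abundance(
    records: pd.DataFrame, config: ThresholdConfig | None = None
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal differential abundance.

    log2 fold change of group mean intensities; Welch's t-test on log2
    intensities; BH q-values over the tested genes.  Zero intensities
    are treated as missing for the log transform, and a gene missing in
    more than half of either group's samples is excluded from testing
    (p and q reported as NaN).  Flags significance at both the p-value
    and FDR gates.
    """
    config = config or ThresholdConfig()
    samples = records.drop_duplicates("sample").set_index("sample")["group"]
    for group in ("tumor", "normal"):
        if (samples == group).sum() < 2:
            raise ValueError(f"need >= 2 samples in group {group!r}")

    wide = records.pivot_table(
        index="gene", columns="sample", values="intensity", aggfunc="sum"
    )
    t_cols = samples.index[samples == "tumor"]
    n_cols = samples.index[samples == "normal"]

    rows = []
    for gene, row in wide.iterrows():
        x = row[t_cols].to_numpy(dtype=float)
        y = row[n_cols].to_numpy(dtype=float)
        x_mean, y_mean = np.nanmean(x), np.nanmean(y)
        if np.nansum(x) == 0 or np.nansum(y) == 0:
            rows.append((gene, np.nan, np.nan))  # undefined fold change
            continue
        log2fc = float(np.log2(x_mean / y_mean))
        lx = np.log2(x[x > 0])
        ly = np.log2(y[y > 0])
        if lx.size < max(2, len(x) / 2) or ly.size < max(2, len(y) / 2):
            rows.append((gene, log2fc, np.nan))
            continue
        _, p = welch_t(lx, ly)
        rows.append((gene, log2fc, p))

    out = pd.DataFrame(rows, columns=["gene", "log2fc", "p_value"]).set_index("gene")
    out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
    out["significant_p"] = out["p_value"] < config.p_cut
    out["significant_fdr"] = out["q_value"] < config.fdr_cut
    return out


# ---------------------------------------------------------------------------
# abundance gating and renormalization

def dda_abundance_gate(pct: pd.Series, z_offset: float = 0.0) -> list[str]:
    """Retain the most abundant genes via a normal fit to log abundance.

    Fits a normal distribution to log10(%LFQ) and keeps genes strictly
    above ``mean + z_offset * sd``.  With the default offset of 0 this
    keeps everything above the fitted mean of the log-abundance
    distribution.
    """
    pct = pct.dropna()
    if (pct <= 0).any():
        raise ValueError("abundance percentages must be > 0")
    if len(pct) < 3:
        raise ValueError("need at least 3 genes to fit an abundance distribution")
    logs = np.log10(pct.to_numpy(dtype=float))
    cut = logs.mean() + z_offset * logs.std(ddof=0)
    kept = pct.index[logs > cut].tolist()
    if not kept:
        warnings.warn("abundance gate retained no genes (degenerate distribution)")
    return kept


def renormalize_core(
    pct: pd.DataFrame,
    annotations: pd.DataFrame,
    config: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Renormalize abundant core-matrisome proteins to percent of core.

    Keeps core-matrisome genes whose tumor %LFQ exceeds the abundance
    floor and renormalizes their tumor %LFQ to sum to 100.  Returns the
    composition table with ``core_pct`` set for retained genes.
    """
    config = config or ThresholdConfig()
    division = annotations.drop_duplicates("gene").set_index("gene")["division"]
    comp = pct.copy()
    comp["division"] = comp.index.map(division).fillna("non-matrisome")
    is_core = comp["division"] == "core matrisome"
    retained = is_core & (comp["pct_lfq_tumor"] > config.core_abundance_cut_pct)
    if not retained.any():
        raise ValueError("no core-matrisome gene passes the abundance floor")
    core_total = comp.loc[retained, "pct_lfq_tumor"].sum()
    comp["core_pct"] = np.nan
    comp.loc[retained, "core_pct"] = 100.0 * comp.loc[retained, "pct_lfq_tumor"] / core_total
    return comp


# ---------------------------------------------------------------------------
# blend selection and formulation

def select_blend(
    composition: pd.DataFrame, config: ThresholdConfig | None = None
) -> list[str]:
    """Select blend components at or above the abundance quartile.

    The third quartile of retained ``core_pct`` values is computed with
    linear interpolation (type-7); genes at or above it are selected,
    ties included.  Requires at least 4 retained core genes.
    """
    config = config or ThresholdConfig()
    core = composition["core_pct"].dropna()
    if len(core) < 4:
        raise ValueError("need >= 4 retained core genes for quartile selection")
    q3 = float(np.percentile(core.to_numpy(dtype=float), config.quartile_pct))
    selected = core[core >= q3]
    return selected.sort_values(ascending=False).index.tolist()


def formulate_blend(
    selected: list[str], composition: pd.DataFrame, total_conc: float = 2.0
) -> BlendRecipe:
    """Turn selected components into a mass recipe at ``total_conc`` ug/mL.

    Blend fractions are the selected genes' core percentages
    renormalized over the selected set; coverage is the share of total
    core-matrisome abundance the selection captures.
    """
    if not selected:
        raise ValueError("selected component list is empty")
    if total_conc <= 0:
        raise ValueError("total_conc must be > 0")
    core = composition.loc[selected, "core_pct"]
    if core.isna().any():
        missing = core.index[core.isna()].tolist()
        raise ValueError(f"selected gene(s) lack core_pct: {missing}")
    coverage = float(core.sum() / 100.0)
    fractions = core / core.sum()
    components = tuple(
        (g, float(f)) for g, f in fractions.sort_values(ascending=False).items()
    )
    return BlendRecipe(components=components, total_conc=total_conc, coverage=coverage)


def build_blend(
    records: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    config: ThresholdConfig | None = None,
    total_conc: float = 2.0,
) -> tuple[BlendRecipe, pd.DataFrame]:
    """End-to-end: quantification records -> (blend recipe, composition).

    Annotate, exclude coagulation, compute %LFQ, renormalize the core
    matrisome and select/formulate the blend.
    """
    config = config or ThresholdConfig()
    annotated = annotate_matrisome(records, reference)
    retained, _ = exclude_coagulation(annotated, config)
    pct = pct_lfq(retained, group_summary=config.group_summary)
    composition = renormalize_core(pct, retained, config)
    selected = select_blend(composition, config)
    recipe = formulate_blend(selected, composition, total_conc=total_conc)
    return recipe, composition


# ---------------------------------------------------------------------------
# tissue-staining consistency filter

STAIN_PATTERNS = frozenset({"interstitial-only", "mixed", "absent", "other"})


def protein_atlas_filter(
    candidates: list[str], staining: pd.DataFrame
) -> tuple[list[str], pd.DataFrame]:
    """Filter blend candidates by tissue staining pattern criteria.

    A candidate is removed if, where evidence exists, it violates any of:
    A — staining in tumors, when present, is interstitial-only;
    B — staining in normal kidney, when present, is interstitial-only;
    C — no staining in the glomeruli of normal kidney.
    Unknown fields never remove a candidate.  Returns ``(kept, removed)``
    where ``removed`` lists the failed criterion letters per gene.
    """
    stain = staining.set_index("gene") if "gene" in staining else staining
    for col in ("tumor_pattern", "normal_pattern"):
        if col in stain:
            bad = set(stain[col].dropna()) - STAIN_PATTERNS
            if bad:
                raise ValueError(f"unknown staining pattern(s): {sorted(bad)}")
    kept, removed = [], []
    for gene in candidates:
        if gene not in stain.index:
            kept.append(gene)
            continue
        row = stain.loc[gene]
        reasons = []
        tp = row.get("tumor_pattern")
        if pd.notna(tp) and tp not in ("interstitial-only", "absent"):
            reasons.append("A")
        np_ = row.get("normal_pattern")
        if pd.notna(np_) and np_ not in ("interstitial-only", "absent"):
            reasons.append("B")
        glom = row.get("glomerular_staining")
        if pd.notna(glom) and bool(glom):
            reasons.append("C")
        if reasons:
            removed.append((gene, "".join(reasons)))
        else:
            kept.append(gene)
    removed_df = pd.DataFrame(removed, columns=["gene", "failed_criteria"])
    return kept, removed_df
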