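"""Rule-based immunophenotype census of cultured and dissociated cells.

Cells carry boolean marker states (missing allowed, tracked distinctly
from negative) and are classified by a fixed-precedence rule table into
{Fibroblast, Endothelial, Immune, Tumor, Other}:

* Fibroblast: PDGFRa/b+, CD45-, VIM+ and negative for the remaining
  carcinoma markers (CK18, PAX2/8, CXCR4).
* Endothelial: CD34+, CD45- and negative for all carcinoma markers.
* Immune: CD45+ with CK18- and PAX2/8-; CXCR4 may be either state and
  VIM is unconstrained by default (immune cells are frequently VIM+) —
  ``strict_immune`` adds VIM- to the exclusion.
* Tumor: PDGFRa/b-, CD45-, CD34- and positive for any two of the
  carcinoma markers CK18, VIM, PAX2/8, CXCR4.
* Anything else: Other.  Cells with every decision marker missing are
  "Unscorable" and reported separately.

The module also summarizes per-condition composition, Pareto-scales the
type x condition matrix, clusters conditions against the tumor input,
and computes joint marker fractions (e.g. VIM/CXCR4), EdU-positive
fractions and the live/dead census of 3D structures with the > 40 um
necrotic-risk flag.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .stats import student_t, welch_t

CELL_TYPES = ("Fibroblast", "Endothelial", "Immune", "Tumor", "Other")
DECISION_MARKERS = ("PDGFRAB", "CD45", "CD34", "VIM", "CK18", "PAX28", "CXCR4")
CARCINOMA_MARKERS = ("CK18", "VIM", "PAX28", "CXCR4")


def classify_cell(markers: dict, strict_immune: bool = False) -> str:
    """Classify one cell from its marker states.

    ``markers`` maps marker name to True/False/None (missing).  A rule
    only fires when every marker it references has a definite value
    satisfying it; missing never counts as negative.  Rules are
    evaluated in fixed order Fibroblast -> Endothelial -> Immune ->
    Tumor -> Other; the first match wins.  A cell with every decision
    marker missing is "Unscorable".
    """
    state = {m: markers.get(m) for m in DECISION_MARKERS}
    if all(v is None for v in state.values()):
        return "Unscorable"

    def pos(m: str) -> bool:
        return state[m] is True

    def neg(m: str) -> bool:
        return state[m] is False

    if (
        pos("PDGFRAB") and neg("CD45") and pos("VIM")
        and neg("CK18") and neg("PAX28") and neg("CXCR4")
    ):
        return "Fibroblast"
    if pos("CD34") and neg("CD45") and all(neg(m) for m in CARCINOMA_MARKERS):
        return "Endothelial"
    if (
        pos("CD45") and neg("CK18") and neg("PAX28")
        and (neg("VIM") if strict_immune else True)
    ):
        return "Immune"
    if (
        neg("PDGFRAB") and neg("CD45") and neg("CD34")
        and sum(pos(m) for m in CARCINOMA_MARKERS) >= 2
    ):
        return "Tumor"
    return "Other"


def classify_cells(records: pd.DataFrame, strict_immune: bool = False) -> pd.Series:
    """Vector version of :func:`classify_cell` over a cells table."""
    cols = [m for m in DECISION_MARKERS if m in records.columns]
    if not cols:
        raise ValueError("no decision-marker columns present")
    labels = []
    for _, row in records.iterrows():
        markers = {
            m: (None if pd.isna(row[m]) else bool(row[m])) for m in cols
        }
        labels.append(classify_cell(markers, strict_immune=strict_immune))
    index = (
        records["cell_id"].to_numpy() if "cell_id" in records else records.index
    )
    return pd.Series(labels, index=index, name="cell_type")


def census(records: pd.DataFrame, strict_immune: bool = False) -> pd.DataFrame:
    """Per-condition cell-type composition.

    Returns one row per condition with counts and fractions per type
    plus the scorable denominator ``n`` and the count of unscorable
    cells (excluded from the denominator).  Fractions sum to 1 per
    condition.
    """
    if "condition" not in records:
        records = records.assign(condition="all")
    out = []
    for condition, block in records.groupby("condition"):
        labels = classify_cells(block, strict_immune=strict_immune)
        n_unscorable = int((labels == "Unscorable").sum())
        scorable = labels[labels != "Unscorable"]
        if scorable.empty:
            raise ValueError(f"no scorable cells in condition {condition!r}")
        n = len(scorable)
        counts = scorable.value_counts()
        row: dict = {"condition": condition, "n": n, "n_unscorable": n_unscorable}
        for t in CELL_TYPES:
            c = int(counts.get(t, 0))
            row[f"count_{t}"] = c
            row[f"frac_{t}"] = c / n
        out.append(row)
    return pd.DataFrame(out).set_index("condition")


def census_matrix(result: pd.DataFrame) -> pd.DataFrame:
    """Cell types (rows) x conditions (columns) fraction matrix."""
    mat = result[[f"frac_{t}" for t in CELL_TYPES]].T
    mat.index = list(CELL_TYPES)
    return mat


# ---------------------------------------------------------------------------
# composition clustering

def pareto_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pareto row scaling: (x - row mean) / sqrt(row SD), sample SD.

    Zero-variance rows map to zeros.  After scaling every row has mean 0
    and SD sqrt(original SD).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns to scale")
    X = matrix.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    # guard against floating-point residue on numerically constant rows
    zero = sd <= 1e-12 * (np.abs(mean) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(~zero, (X - mean) / np.sqrt(sd), 0.0)
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def cluster_conditions(
    scaled: pd.DataFrame, input_label: str = "input"
) -> tuple[np.ndarray, list[str], str | None]:
    """Agglomerative clustering of conditions (columns).

    Euclidean distance, average linkage.  Returns ``(linkage_matrix,
    condition_order, nearest)`` where ``nearest`` is the condition at
    the smallest distance to ``input_label`` (None when the label is
    absent).
    """
    if scaled.shape[1] < 2:
        raise ValueError("need at least 2 conditions to cluster")
    conditions = list(scaled.columns)
    X = scaled.to_numpy(dtype=float).T
    Z = linkage(X, method="average", metric="euclidean")
    nearest = None
    if input_label in conditions:
        D = squareform(pdist(X, metric="euclidean"))
        i = conditions.index(input_label)
        d = D[i].copy()
        d[i] = np.inf
        nearest = conditions[int(np.argmin(d))]
    return Z, conditions, nearest


# ---------------------------------------------------------------------------
# marker fractions

def round_half_up_pct(fraction: float) -> int:
    """Display rounding of a fraction to integer percent, half away up."""
    return int(Decimal(str(fraction * 100)).quantize(0, rounding=ROUND_HALF_UP))


def joint_marker_fractions(
    records: pd.DataFrame, primary_marker: str, secondary_marker: str
) -> dict[str, float | None]:
    """Joint and conditional fractions for a two-marker co-stain.

    Over cells with both markers scored: the primary-positive marginal,
    the secondary-positive conditional within primary-positive cells,
    and the two joint fractions (primary+/secondary+ and
    primary+/secondary-).  The joint fractions factor exactly as
    marginal x conditional.  Fractions are carried at full precision;
    round only at display (:func:`round_half_up_pct`).
    """
    for m in (primary_marker, secondary_marker):
        if m not in records.columns:
            raise ValueError(f"marker column {m!r} missing")
    scored = records.dropna(subset=[primary_marker, secondary_marker])
    if scored.empty:
        raise ValueError("no cell has both markers scored")
    p = scored[primary_marker].astype(bool)
    s = scored[secondary_marker].astype(bool)
    p_primary = float(p.mean())
    if p.sum() == 0:
        conditional = None
        joint_pos = 0.0
        joint_neg = 0.0
    else:
        conditional = float(s[p].mean())
        joint_pos = p_primary * conditional
        joint_neg = p_primary * (1.0 - conditional)
    return {
        "p_primary": p_primary,
        "p_secondary_given_primary": conditional,
        "p_joint_pos": joint_pos,
        "p_primary_only": joint_neg,
        "n": int(len(scored)),
    }


def edu_fraction(
    records: pd.DataFrame, within_type: str, strict_immune: bool = False
) -> float:
    """Fraction of EdU-positive cells among cells classified as a type."""
    if "EDU" not in records.columns:
        raise ValueError("no EDU column in records")
    labels = classify_cells(records, strict_immune=strict_immune)
    mask = (labels == within_type).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"no cells of type {within_type!r}")
    edu = records["EDU"].to_numpy()[mask]
    edu = np.array([bool(v) for v in edu if not pd.isna(v)])
    if edu.size == 0:
        raise ValueError(f"no scored EDU values among {within_type!r} cells")
    return float(edu.mean())


# ---------------------------------------------------------------------------
# 3D structure census

def structure_census(
    structures: pd.DataFrame,
    necrotic_diameter_cut: float = 40.0,
    equal_var: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Live/dead census of Hoechst-positive 3D structures per condition.

    A structure is live when calcein+/EthD2-, dead when EthD2-only;
    structures positive for both stains are a distinct "mixed" category
    and ones negative for both are excluded with a warning count.  The
    necrotic-risk flag marks structures strictly larger than the
    diameter cut (40 um by default).  When a ``replicate`` column is
    present, conditions are compared pairwise by a two-sample t-test on
    per-replicate structure counts.

    Returns ``(summary, pairwise_tests)``.
    """
    if not structures["hoechst_pos"].all():
        raise ValueError("non-Hoechst-positive structure in input")
    df = structures.copy()
    calcein = df["calcein_pos"].astype(bool)
    ethd2 = df["ethd2_pos"].astype(bool)
    df["status"] = np.select(
        [calcein & ~ethd2, ethd2 & ~calcein, calcein & ethd2],
        ["live", "dead", "mixed"],
        default="excluded",
    )
    df["necrotic_flag"] = df["diameter"] > necrotic_diameter_cut

    rows = []
    for condition, block in df.groupby("condition"):
        counted = block[block["status"] != "excluded"]
        n = len(counted)
        rows.append(
            {
                "condition": condition,
                "n_structures": n,
                "live_fraction": (counted["status"] == "live").mean() if n else np.nan,
                "dead_fraction": (counted["status"] == "dead").mean() if n else np.nan,
                "mixed_fraction": (counted["status"] == "mixed").mean() if n else np.nan,
                "n_excluded": int((block["status"] == "excluded").sum()),
                "n_necrotic_flagged": int(block["necrotic_flag"].sum()),
            }
        )
    summary = pd.DataFrame(rows).set_index("condition")

    tests = []
    if "replicate" in df.columns:
        per_rep = (
            df[df["status"] != "excluded"]
            .groupby(["condition", "replicate"], observed=True)
            .size()
        )
        for a, b in combinations(summary.index, 2):
            x = per_rep.loc[a].to_numpy(dtype=float)
            y = per_rep.loc[b].to_numpy(dtype=float)
            if len(x) >= 2 and len(y) >= 2:
                t, p = student_t(x, y) if equal_var else welch_t(x, y)
                tests.append((a, b, t, p))
    pairwise = pd.DataFrame(tests, columns=["condition_a", "condition_b", "t", "p_value"])
    return summary, pairwise
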