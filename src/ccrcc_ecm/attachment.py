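"""Attachment-assay quantification.

Counts of attached cells per (cell line, substrate, replicate) are
compared against a reference substrate — the uncoated "None" wells for
single-component screens, or the complete blend "All" for
leave-one-out dropout analysis.  The exported metric is the log2 fold
change of mean attached counts with a continuity constant of 0.5 added
to both means so zero-count conditions stay finite, plus a two-sample
test across replicates.

"Student's t-test" is implemented as Welch's unequal-variance test by
default (a safer choice with n = 3 replicates); the classic
pooled-variance form is available via ``equal_var=True``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrisome import BlendRecipe
from .stats import student_t, welch_t

CONTINUITY = 0.5


def two_sample_test(x, y, equal_var: bool = False) -> tuple[float, float]:
    """Two-sample t-test across replicate values: ``(t, p)``, two-sided."""
    return student_t(x, y) if equal_var else welch_t(x, y)


def _log2fc(mean_x: float, mean_ref: float, c: float = CONTINUITY) -> float:
    return float(np.log2((mean_x + c) / (mean_ref + c)))


def relative_attachment(
    records: pd.DataFrame,
    reference_substrate: str = "None",
    continuity: float = CONTINUITY,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Log2 fold change of attachment versus a reference substrate.

    One row per (cell line, substrate) with ``log2fc``, ``p_value`` and
    replicate count ``n``; reference rows are identically zero.  Raises
    if any cell line lacks the reference substrate.
    """
    out = []
    for line, block in records.groupby("cell_line"):
        ref = block.loc[block["substrate"] == reference_substrate, "attached"]
        if ref.empty:
            raise ValueError(f"cell line {line!r} lacks reference {reference_substrate!r}")
        ref_vals = ref.to_numpy(dtype=float)
        for substrate, sub in block.groupby("substrate"):
            vals = sub["attached"].to_numpy(dtype=float)
            if len(vals) == 0:
                raise ValueError(f"no replicates for ({line}, {substrate})")
            if substrate == reference_substrate:
                lfc, p = 0.0, 1.0
            else:
                lfc = _log2fc(vals.mean(), ref_vals.mean(), continuity)
                if len(vals) >= 2 and len(ref_vals) >= 2:
                    _, p = two_sample_test(vals, ref_vals, equal_var=equal_var)
                else:
                    p = np.nan
            out.append((line, substrate, lfc, p, len(vals)))
    return pd.DataFrame(
        out, columns=["cell_line", "substrate", "log2fc", "p_value", "n"]
    )


def attachment_matrix(relative: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long relative-attachment table to lines x substrates."""
    return relative.pivot(index="cell_line", columns="substrate", values="log2fc")


def dropout_analysis(
    records: pd.DataFrame,
    recipe: BlendRecipe | None = None,
    all_substrate: str = "All",
    minus_prefix: str = "All-minus-",
    continuity: float = CONTINUITY,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Leave-one-out blend dropout effects relative to the full blend.

    For every ``All-minus-<component>`` condition, reports the log2 fold
    change of attachment against the complete blend, a replicate-level
    test, and — when a recipe is supplied — the removed component's
    percentage of the blend.
    """
    has_all = (records["substrate"] == all_substrate).any()
    if not has_all:
        raise ValueError(f"no {all_substrate!r} condition in records")
    dropouts = sorted(
        s for s in records["substrate"].unique() if s.startswith(minus_prefix)
    )
    if not dropouts:
        raise ValueError(f"no {minus_prefix}* condition in records")
    fractions = recipe.fractions if recipe is not None else {}

    out = []
    for line, block in records.groupby("cell_line"):
        ref = block.loc[block["substrate"] == all_substrate, "attached"]
        if ref.empty:
            raise ValueError(f"cell line {line!r} lacks {all_substrate!r}")
        ref_vals = ref.to_numpy(dtype=float)
        for substrate in dropouts:
            vals = block.loc[block["substrate"] == substrate, "attached"].to_numpy(
                dtype=float
            )
            if len(vals) == 0:
                continue
            component = substrate[len(minus_prefix):]
            lfc = _log2fc(vals.mean(), ref_vals.mean(), continuity)
            if len(vals) >= 2 and len(ref_vals) >= 2:
                _, p = two_sample_test(vals, ref_vals, equal_var=equal_var)
            else:
                p = np.nan
            blend_pct = 100.0 * fractions[component] if component in fractions else np.nan
            out.append((line, component, lfc, p, len(vals), blend_pct))
    return pd.DataFrame(
        out,
        columns=["cell_line", "component", "delta_log2", "p_value", "n", "blend_pct"],
    )
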