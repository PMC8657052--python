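"""Packaged reference tables: matrisome annotation and gene-symbol aliases.

The matrisome reference is a small curated table mapping gene symbols to
their matrisome division ("core matrisome", "matrisome-associated",
"non-matrisome") and category (glycoprotein, collagen, proteoglycan,
ECM-affiliated, regulator, secreted factor), together with a set of GO
terms.  Core matrisome membership is restricted to glycoproteins,
collagens and proteoglycans, the structural classes that make up the
kidney cortex matrisome.  The fibrinogen chains (FGA/FGB/FGG) carry the
coagulation term GO:0050817 so that the coagulation-exclusion step of
the composition pipeline can identify them.

The alias table maps common protein/CD names used in staining panels to
HGNC gene symbols (CD31 -> PECAM1, CD45 -> PTPRC, CD10 -> MME,
CK18 -> KRT18).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

#: matrisome categories that constitute the core (structural) matrisome
CORE_CATEGORIES = frozenset({"glycoprotein", "collagen", "proteoglycan"})

#: GO term used to flag coagulation components for exclusion
COAGULATION_GO = "GO:0050817"


def _data_path(name: str):
    return resources.files("ccrcc_ecm").joinpath("data", name)


@lru_cache(maxsize=None)
def load_matrisome_reference() -> pd.DataFrame:
    """Load the packaged matrisome reference table.

    Returns a DataFrame indexed by uppercase gene symbol with columns
    ``division``, ``category`` and ``go_terms`` (a frozenset of GO ids).
    """
    with resources.as_file(_data_path("matrisome_reference.csv")) as path:
        ref = pd.read_csv(path)
    ref["gene"] = ref["gene"].str.upper()
    if ref["gene"].duplicated().any():
        dupes = ref.loc[ref["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate reference gene(s): {dupes}")
    ref["go_terms"] = ref["go_terms"].fillna("").map(
        lambda s: frozenset(t for t in s.split(";") if t)
    )
    return ref.set_index("gene")


@lru_cache(maxsize=None)
def load_gene_aliases() -> dict[str, str]:
    """Mapping of common staining-panel names to HGNC symbols."""
    with resources.as_file(_data_path("gene_aliases.csv")) as path:
        table = pd.read_csv(path)
    return {a.upper(): g.upper() for a, g in zip(table["alias"], table["gene"])}


def canonical_gene(symbol: str) -> str:
    """Uppercase a gene symbol and resolve panel aliases (CD31 -> PECAM1...)."""
    sym = str(symbol).upper()
    return load_gene_aliases().get(sym, sym)


def core_genes(include_coagulation: bool = False) -> list[str]:
    """Core-matrisome gene symbols from the packaged reference.

    Coagulation-flagged entries (GO:0050817) are omitted unless
    ``include_coagulation`` is set; they are excluded from composition
    analysis anyway, so most callers want them out of the way.
    """
    ref = load_matrisome_reference()
    core = ref[ref["division"] == "core matrisome"]
    if not include_coagulation:
        core = core[~core["go_terms"].map(lambda s: COAGULATION_GO in s)]
    return core.index.tolist()
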