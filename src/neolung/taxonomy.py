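"""Cell-type taxonomy for the neonatal lung.

A fixed map from cell-type label to lineage. The default taxonomy has 40
types split across the four lung lineages (epithelial, endothelial,
mesenchymal, immune); smaller taxonomies can be built for fast tests with
:func:`make_taxonomy`.
"""

from __future__ import annotations

LINEAGES = ("epithelial", "endothelial", "mesenchymal", "immune")

# 13 epithelial, 5 endothelial, 6 mesenchymal, 16 immune = 40 types.
DEFAULT_TAXONOMY: dict[str, str] = {
    # epithelial (airway + alveolar)
    "AT1": "epithelial",
    "AT2": "epithelial",
    "Immature AT2": "epithelial",
    "Transitional AT2": "epithelial",
    "Basal": "epithelial",
    "Secretory": "epithelial",
    "Multiciliated": "epithelial",
    "Goblet": "epithelial",
    "Deuterosomal": "epithelial",
    "PNEC": "epithelial",
    "Submucosal gland": "epithelial",
    "Tip": "epithelial",
    "Stalk": "epithelial",
    # endothelial
    "Capillary": "endothelial",
    "aCap": "endothelial",
    "Arterial EC": "endothelial",
    "Venous EC": "endothelial",
    "Lymphatic EC": "endothelial",
    # mesenchymal
    "Alveolar fibroblast": "mesenchymal",
    "Adventitial fibroblast": "mesenchymal",
    "Myofibroblast": "mesenchymal",
    "Airway smooth muscle": "mesenchymal",
    "Vascular smooth muscle": "mesenchymal",
    "Pericyte": "mesenchymal",
    # immune
    "Alveolar macrophage": "immune",
    "Interstitial macrophage": "immune",
    "Monocyte": "immune",
    "cDC1": "immune",
    "cDC2": "immune",
    "pDC": "immune",
    "Mast": "immune",
    "Neutrophil": "immune",
    "Eosinophil": "immune",
    "B cell": "immune",
    "Plasma": "immune",
    "CD4 T": "immune",
    "CD8 T": "immune",
    "Treg": "immune",
    "NK": "immune",
    "ILC": "immune",
}


def make_taxonomy(n_types: int = 40) -> dict[str, str]:
    """Return a cell-type -> lineage map with ``n_types`` types.

    For ``n_types == 40`` this is the full default taxonomy. Smaller values
    take types round-robin across lineages so every lineage stays
    represented (down to ``n_types = 4``).
    """
    if n_types < 4:
        raise ValueError("taxonomy needs at least one type per lineage (n_types >= 4)")
    if n_types == len(DEFAULT_TAXONOMY):
        return dict(DEFAULT_TAXONOMY)
    by_lineage: dict[str, list[str]] = {lin: [] for lin in LINEAGES}
    for ct, lin in DEFAULT_TAXONOMY.items():
        by_lineage[lin].append(ct)
    out: dict[str, str] = {}
    i = 0
    while len(out) < n_types:
        lin = LINEAGES[i % len(LINEAGES)]
        pool = by_lineage[lin]
        k = i // len(LINEAGES)
        if k < len(pool):
            out[pool[k]] = lin
        i += 1
        if i > 4 * len(DEFAULT_TAXONOMY):  # n_types beyond the catalogue
            raise ValueError(f"cannot build taxonomy with {n_types} types")
    return out


def lineage_of(cell_type: str, taxonomy: dict[str, str] | None = None) -> str:
    tax = DEFAULT_TAXONOMY if taxonomy is None else taxonomy
    try:
        return tax[cell_type]
    except KeyError:
        raise KeyError(f"unknown cell type {cell_type!r}") from None
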