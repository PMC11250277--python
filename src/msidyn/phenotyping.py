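"""Marker-colocalization phenotyping and neighborhood immune counting.

Tumor cells are identified by pan-cytokeratin positivity and split into
MSH6-proficient/deficient by the MSH6 channel; immune cells are gated with the
precedence CD20 (B cell) > FoxP3 (Treg) > CD8 (cytotoxic T) > CD4 (helper T).
Neighborhood analysis counts, per tumor MSH6 class, the immune cells of each
subtype whose center lies within a radius R (default 100 um) of at least one
tumor cell of that class; each immune cell is counted at most once per class
per tile.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .segmentation import CellRecord

__all__ = [
    "derive_thresholds",
    "phenotype_cells",
    "neighborhood_counts",
    "TUMOR_CLASSES",
    "IMMUNE_CLASSES",
]

TUMOR_CLASSES = ("tumor_MSH6_proficient", "tumor_MSH6_deficient")
IMMUNE_CLASSES = ("b_cell", "treg", "cytotoxic_t", "helper_t")

# gating precedence: epithelial first, then immune lineage markers
_IMMUNE_GATES = (
    ("CD20", "b_cell"),
    ("FOXP3", "treg"),
    ("CD8", "cytotoxic_t"),
    ("CD4", "helper_t"),
)


def derive_thresholds(cells: list[CellRecord], channels: list[str]) -> dict[str, float]:
    """Per-channel positivity thresholds from the per-cell mean intensities.

    Uses Otsu's bimodal split of the per-cell distribution; falls back to the
    midpoint of the range when the distribution is degenerate.
    """
    from skimage.filters import threshold_otsu

    out: dict[str, float] = {}
    for chan in channels:
        vals = np.array([c.channel_means.get(chan, 0.0) for c in cells], dtype=float)
        if len(vals) == 0:
            out[chan] = np.inf
        elif np.ptp(vals) == 0:
            out[chan] = vals[0] + 0.5  # uniform: nothing is positive
        else:
            try:
                out[chan] = float(threshold_otsu(vals))
            except ValueError:
                out[chan] = float(vals.min() + 0.5 * np.ptp(vals))
    return out


def phenotype_cells(
    cells: list[CellRecord],
    thresholds: dict[str, float] | None = None,
) -> list[CellRecord]:
    """Attach phenotype labels in place and return the cells.

    ``thresholds`` maps channel name to a positivity cutoff on the per-cell
    mean intensity; when omitted, thresholds are derived from the cell
    population with :func:`derive_thresholds`. Requires a pan-CK channel
    (named ``panCK``); MSH6 and the immune markers are used when present.
    """
    if not cells:
        return cells
    channels = list(cells[0].channel_means)
    if "panCK" not in channels:
        raise KeyError("phenotyping requires a 'panCK' channel")
    if thresholds is None:
        thresholds = derive_thresholds(cells, channels)

    def positive(cell: CellRecord, chan: str) -> bool:
        if chan not in cell.channel_means or chan not in thresholds:
            return False
        return cell.channel_means[chan] >= thresholds[chan]

    for cell in cells:
        if positive(cell, "panCK"):
            if positive(cell, "MSH6"):
                cell.phenotype = "tumor_MSH6_proficient"
            else:
                cell.phenotype = "tumor_MSH6_deficient"
            continue
        for chan, label in _IMMUNE_GATES:
            if positive(cell, chan):
                cell.phenotype = label
                break
        else:
            cell.phenotype = "unclassified"
    return cells


def neighborhood_counts(
    cells: list[CellRecord],
    radius_um: float = 100.0,
) -> dict[str, dict[str, int]]:
    """Immune-cell counts within ``radius_um`` of each tumor MSH6 class.

    Distances are center-to-center in micrometers; the radius boundary is
    inclusive. An immune cell within range of several tumor cells of the same
    class is counted once for that class. Returns
    ``{tumor_class: {immune_class: count}}`` (zero-filled when empty).
    """
    report = {tc: {ic: 0 for ic in IMMUNE_CLASSES} for tc in TUMOR_CLASSES}
    if not cells:
        return report
    pos = np.array([c.center_um for c in cells], dtype=float)
    labels = np.array([c.phenotype or "unclassified" for c in cells])
    for tc in TUMOR_CLASSES:
        tumor_pos = pos[labels == tc]
        if len(tumor_pos) == 0:
            continue
        tree = cKDTree(tumor_pos)
        for ic in IMMUNE_CLASSES:
            immune_pos = pos[labels == ic]
            if len(immune_pos) == 0:
                continue
            dists, _ = tree.query(immune_pos, k=1)
            report[tc][ic] = int((dists <= radius_um).sum())
    return report
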