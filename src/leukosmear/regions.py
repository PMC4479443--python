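"""Identification of nuclei, cells and overlapped aggregates from masks.

Segmented regions are described by shape (circularity, eccentricity),
color (mean L*) and spatial relations (containment proportion) and run
through threshold rules: a near-circular region of plausible size is a
nucleus; an oversized or irregular region of up-to-double plausible size is
an overlapped aggregate routed to the separation stage; anything else is
rejected.  A cell is accepted when it contains at least one nucleus at a
containment proportion of at least 95% and that nucleus is darker (lower
mean L*) than the cell's cytoplasm; a cell matching two or more nuclei is
flagged overlapped.

The shape thresholds mirror rules induced from small sets of regular vs
irregular example regions; ``induce_shape_thresholds`` re-derives them from
such examples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .features import chain_perimeter

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "CellRecord",
    "IdentificationRules",
    "compute_region_descriptors",
    "containment_proportion",
    "identify_nuclei",
    "identify_cells",
    "induce_shape_thresholds",
]


@dataclass
class Region:
    """One connected region with its shape and color descriptors."""

    instance_id: int
    mask: np.ndarray  # full-frame boolean mask
    area: float
    perimeter: float
    centroid: tuple[float, float]
    circularity: float
    eccentricity: float
    mean_L: float
    bbox: tuple[int, int, int, int]


@dataclass
class CellRecord:
    """A matched cell with its nucleus and derived cytoplasm."""

    cell: Region
    nucleus: Region | None
    cytoplasm_mask: np.ndarray | None
    containment: float
    flag: str  # ok | overlapped | unmatched
    extra_nuclei: list[Region] = field(default_factory=list)


@dataclass(frozen=True)
class IdentificationRules:
    """Threshold rules for the nucleus/cell decision trees."""

    min_area: float = 50.0
    max_area: float = 6000.0
    circ_max: float = 1.5
    ecc_max: float = 0.95
    containment_min: float = 0.95


def compute_region_descriptors(
    mask: np.ndarray, intensity: np.ndarray | None = None
) -> list[Region]:
    """Connected-component analysis (8-connectivity) with descriptors.

    ``mask`` may be binary (components are labeled here) or already
    instance-labeled.  ``intensity`` (usually the L* plane) feeds the
    mean-color descriptor; without it mean_L is NaN.
    """
    mask = np.asarray(mask)
    if mask.dtype == bool or mask.max() <= 1:
        labeled = measure.label(mask.astype(bool), connectivity=2)
    else:
        labeled = mask.astype(np.int64)
    regions: list[Region] = []
    for prop in measure.regionprops(labeled):
        inst = np.zeros(labeled.shape, dtype=bool)
        inst[labeled == prop.label] = True
        perim = chain_perimeter(inst)
        area = float(prop.area)
        regions.append(
            Region(
                instance_id=int(prop.label),
                mask=inst,
                area=area,
                perimeter=perim,
                centroid=tuple(float(c) for c in prop.centroid),
                circularity=float(perim**2 / (4.0 * np.pi * area)),
                eccentricity=float(prop.eccentricity),
                mean_L=float(np.mean(intensity[inst])) if intensity is not None else float("nan"),
                bbox=tuple(int(v) for v in prop.bbox),
            )
        )
    return regions


def containment_proportion(inner: Region, outer: Region) -> float:
    """|inner ∩ outer| / |inner|.

    Raises
    ------
    ValueError : if the inner region is empty.
    """
    inner_n = inner.mask.sum()
    if inner_n == 0:
        raise ValueError("containment undefined for an empty inner region")
    return float(np.logical_and(inner.mask, outer.mask).sum() / inner_n)


def identify_nuclei(
    regions: list[Region], rules: IdentificationRules = IdentificationRules()
) -> dict[str, list[Region]]:
    """Partition nucleus-mask regions into nucleus / overlapped / reject.

    A region is a nucleus when its area lies within [min_area, max_area] and
    both circularity <= circ_max and eccentricity <= ecc_max hold.  A region
    failing the shape or size ceiling but no larger than 2 x max_area (an
    aggregate of at most ~two nuclei) is flagged overlapped.  Everything
    else — specks below min_area or implausibly large blobs — is rejected.
    Every region receives exactly one label.
    """
    out: dict[str, list[Region]] = {"nucleus": [], "overlapped": [], "reject": []}
    for region in regions:
        if region.area < rules.min_area or region.area > 2.0 * rules.max_area:
            out["reject"].append(region)
        elif (
            region.area <= rules.max_area
            and region.circularity <= rules.circ_max
            and region.eccentricity <= rules.ecc_max
        ):
            out["nucleus"].append(region)
        else:
            out["overlapped"].append(region)
    return out


def identify_cells(
    cell_regions: list[Region],
    nuclei: list[Region],
    rules: IdentificationRules = IdentificationRules(),
) -> tuple[list[CellRecord], list[Region]]:
    """Match cell-mask regions with their nuclei.

    A cell is accepted when it contains >= 1 nucleus with containment >= the
    95% threshold AND the nucleus is darker than the cell's cytoplasm (lower
    mean L*).  Cells matching >= 2 nuclei are flagged overlapped (routed to
    the separation stage).  Matching is injective for ok records: each
    nucleus belongs to at most one cell (the one containing it).  Nuclei
    contained by no cell are returned separately (logged as unmatched).
    """
    records: list[CellRecord] = []
    matched: set[int] = set()
    for cell in cell_regions:
        inside: list[tuple[Region, float]] = []
        for nuc in nuclei:
            c = containment_proportion(nuc, cell)
            if c >= rules.containment_min:
                cyto = cell.mask & ~nuc.mask
                if cyto.any() and not np.isnan(nuc.mean_L):
                    # darker relation on the cytoplasm ring
                    cyto_L = _masked_mean_L(cell, nuc)
                    if not (nuc.mean_L < cyto_L):
                        continue
                inside.append((nuc, c))
        if not inside:
            continue
        inside.sort(key=lambda t: -t[1])
        if len(inside) == 1:
            nuc, c = inside[0]
            records.append(
                CellRecord(
                    cell=cell,
                    nucleus=nuc,
                    cytoplasm_mask=cell.mask & ~nuc.mask,
                    containment=c,
                    flag="ok",
                )
            )
            matched.add(id(nuc))
        else:
            nuc, c = inside[0]
            records.append(
                CellRecord(
                    cell=cell,
                    nucleus=nuc,
                    cytoplasm_mask=None,
                    containment=c,
                    flag="overlapped",
                    extra_nuclei=[n for n, _ in inside[1:]],
                )
            )
            for n, _ in inside:
                matched.add(id(n))
    unmatched = [n for n in nuclei if id(n) not in matched]
    for n in unmatched:
        logger.warning("nucleus %d has no containing cell (unmatched)", n.instance_id)
    return records, unmatched


def _masked_mean_L(cell: Region, nucleus: Region) -> float:
    """Mean L* of the cytoplasm ring, recovered from the regions' stored means."""
    n_cell = cell.mask.sum()
    n_nuc = np.logical_and(cell.mask, nucleus.mask).sum()
    if n_cell - n_nuc <= 0:
        return float("inf")
    # mean over cell = weighted mean over nucleus part and cytoplasm ring
    return (cell.mean_L * n_cell - nucleus.mean_L * n_nuc) / (n_cell - n_nuc)


def induce_shape_thresholds(
    regular: list[Region], irregular: list[Region], slack: float = 0.5
) -> IdentificationRules:
    """Re-derive the shape rule thresholds from labeled example regions.

    Given regular (single nucleus/cell) and irregular (overlapped aggregate)
    examples, each threshold is placed the fraction ``slack`` of the way from
    the extreme regular value toward the nearest irregular value — the same
    single-split rule induction a decision-stump learner performs on these
    descriptors.
    """
    if not regular or not irregular:
        raise ValueError("need at least one example of each shape class")

    def _between(lo: float, hi: float) -> float:
        return lo + slack * (hi - lo) if hi > lo else lo

    reg_area = max(r.area for r in regular)
    irr_area = min(i.area for i in irregular)
    reg_circ = max(r.circularity for r in regular)
    irr_circ = min(i.circularity for i in irregular)
    reg_ecc = max(r.eccentricity for r in regular)
    return IdentificationRules(
        min_area=min(r.area for r in regular) * 0.5,
        max_area=_between(reg_area, irr_area),
        circ_max=_between(reg_circ, irr_circ),
        ecc_max=min(1.0, reg_ecc + 0.05),
    )
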