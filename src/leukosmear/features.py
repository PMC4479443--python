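"""The 67-feature morphometric description of a leukocyte.

Each identified cell is described by 67 named features: 14 morphologic
(computed for the nucleus and for the whole cell; only the area is kept for
the cytoplasm), 5 statistical and 5 gray-level co-occurrence (GLCM) texture
statistics (computed per region over the R, G, B and gray channels), the
first 10 eigenvalues of the region crop per channel (nucleus and cell), and
3 nucleus/cell size ratios.  Images are deliberately NOT normalized before
extraction: absolute size and color are discriminative between leukemia
subtypes.

The flat feature table expands the per-region / per-channel blocks into one
column per (feature, region, channel) combination; ``flat_feature_names()``
is the single source of truth for that schema.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "MORPHOLOGIC_NAMES",
    "STATISTICAL_NAMES",
    "TEXTURE_NAMES",
    "RATIO_NAMES",
    "flat_feature_names",
    "morphological_features",
    "statistical_features",
    "glcm_features",
    "eigen_features",
    "size_ratio_features",
    "extract_feature_vector",
]

MORPHOLOGIC_NAMES = [
    "area",
    "perimeter",
    "circularity",
    "width",
    "length",
    "elongation",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "extent",
    "equivalent_diameter",
    "euler_number",
    "convex_area",
    "solidity",
]
STATISTICAL_NAMES = ["mode", "mean", "std", "variance", "sum"]
TEXTURE_NAMES = ["homogeneity", "contrast", "correlation", "energy", "entropy"]
EIGEN_CHANNELS = ["R", "G", "B", "gray"]
RATIO_NAMES = ["n_cyto_area", "n_cell_area", "n_cell_perimeter"]

#: The canonical 67 feature names, in table order: 14 morphologic,
#: 5 statistical, 5 texture, 40 eigen (10 per channel), 3 size ratios.
FEATURE_NAMES = (
    MORPHOLOGIC_NAMES
    + STATISTICAL_NAMES
    + TEXTURE_NAMES
    + [f"eigen_{ch}_{i}" for ch in EIGEN_CHANNELS for i in range(1, 11)]
    + RATIO_NAMES
)

STAT_REGIONS = ["nucleus", "cytoplasm", "cell"]
EIGEN_REGIONS = ["nucleus", "cell"]
CHANNELS = ["R", "G", "B", "gray"]


def flat_feature_names() -> list[str]:
    """Ordered column names of the expanded flat feature table.

    Morphology for nucleus and cell; area only for the cytoplasm; statistical
    and GLCM blocks per region x channel; eigen blocks per region x channel;
    the three size ratios.  232 columns total.
    """
    names: list[str] = []
    for region in ("nucleus", "cell"):
        names += [f"{region}_{n}" for n in MORPHOLOGIC_NAMES]
    names.append("cytoplasm_area")
    for block in (STATISTICAL_NAMES, TEXTURE_NAMES):
        for region in STAT_REGIONS:
            for ch in CHANNELS:
                names += [f"{region}_{ch}_{n}" for n in block]
    for region in EIGEN_REGIONS:
        for ch in CHANNELS:
            names += [f"{region}_{ch}_eigen_{i}" for i in range(1, 11)]
    names += RATIO_NAMES
    return names


# ---------------------------------------------------------------------------
# morphology


def _ordered_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered outer-boundary pixel chain of a connected region (Moore tracing).

    Returns an (n, 2) array of (row, col) pixel coordinates tracing the outer
    border counter-clockwise; the chain is closed implicitly (last adjacent to
    first).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no boundary")
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    # start at the top-most, then left-most foreground pixel
    start = (rows.min(), cols[rows == rows.min()].min())
    # Moore neighborhood in clockwise order starting from W
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
    boundary = [start]
    # backtrack starts to the W of the start pixel (which is background)
    prev_dir = 0
    cur = start
    while True:
        found = False
        for k in range(8):
            d = (prev_dir + k) % 8
            ny, nx = cur[0] + nbrs[d][0], cur[1] + nbrs[d][1]
            if padded[ny, nx]:
                # next scan starts just past the direction pointing back at cur
                prev_dir = (d + 5) % 8
                cur = (ny, nx)
                found = True
                break
        if not found:  # isolated pixel
            break
        if cur == start and len(boundary) > 1:
            break
        boundary.append(cur)
        if len(boundary) > 4 * padded.size:  # safety net; cannot happen on valid masks
            raise RuntimeError("boundary tracing failed to terminate")
    return np.array(boundary) - 1  # undo padding offset


def chain_perimeter(mask: np.ndarray) -> float:
    """Boundary-chain perimeter: distance between adjoining border pixels.

    Steps between 4-adjacent border pixels count 1, diagonal steps sqrt(2).
    A single-pixel region is assigned perimeter 1 by convention (warned).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 1:
        warnings.warn("single-pixel region: perimeter set to 1 by convention")
        return 1.0
    b = _ordered_boundary(mask)
    diffs = np.diff(np.vstack([b, b[:1]]), axis=0)
    return float(np.sqrt((diffs**2).sum(axis=1)).sum())


def morphological_features(mask: np.ndarray) -> dict[str, float]:
    """The 14 morphologic features of a binary region mask.

    Width/length come from the axis-aligned bounding box (length is the
    larger side); major/minor axis and eccentricity from the second-moment
    ellipse; Euler number with 8-connected objects.
    """
    from skimage import measure

    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum())
    if area == 0:
        raise ValueError("empty region")
    perimeter = chain_perimeter(mask)
    if area == 1:
        warnings.warn("single-pixel region: circularity is a convention value")
    circularity = perimeter**2 / (4.0 * np.pi * area)
    rows, cols = np.nonzero(mask)
    h = float(rows.max() - rows.min() + 1)
    w = float(cols.max() - cols.min() + 1)
    length, width = max(h, w), min(h, w)
    props = measure.regionprops(mask.astype(np.uint8))[0]
    return {
        "area": area,
        "perimeter": perimeter,
        "circularity": float(circularity),
        "width": width,
        "length": length,
        "elongation": length / width,
        "major_axis_length": float(props.axis_major_length),
        "minor_axis_length": float(props.axis_minor_length),
        "eccentricity": float(props.eccentricity),
        "extent": area / (width * length),
        "equivalent_diameter": float(np.sqrt(4.0 * area / np.pi)),
        "euler_number": float(measure.euler_number(mask, connectivity=2)),
        "convex_area": float(props.area_convex),
        "solidity": float(props.solidity),
    }


# ---------------------------------------------------------------------------
# statistics and GLCM texture


def statistical_features(values: np.ndarray) -> dict[str, float]:
    """Mode, mean, SD, variance (population, 1/n) and sum of region pixels.

    The mode breaks ties to the smallest value.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("empty region")
    uniq, counts = np.unique(values, return_counts=True)
    mode = float(uniq[np.argmax(counts)])  # argmax takes the first = smallest on ties
    var = float(values.var())
    return {
        "mode": mode,
        "mean": float(values.mean()),
        "std": float(np.sqrt(var)),
        "variance": var,
        "sum": float(values.sum()),
    }


def glcm_features(plane: np.ndarray, mask: np.ndarray, levels: int = 32) -> dict[str, float]:
    """Five GLCM statistics of the region at offset (0, 1).

    The co-occurrence matrix counts horizontally adjacent pixel pairs that
    both fall inside the region, quantized to ``levels`` gray levels over
    [0, 255]; it is symmetrized and normalized.  Energy is the sum of squared
    matrix elements; entropy is -sum p log2 p over nonzero entries.  A
    constant region yields contrast 0, homogeneity 1, energy 1, entropy 0;
    correlation is 0 by convention when either marginal has zero variance.

    Raises
    ------
    ValueError : if the region contains no valid horizontal pixel pair.
    """
    plane = np.asarray(plane, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    q = np.clip((plane * levels / 256.0).astype(np.int64), 0, levels - 1)
    pair_ok = mask[:, :-1] & mask[:, 1:]
    if not pair_ok.any():
        raise ValueError("no in-region horizontal pixel pairs for the GLCM")
    i = q[:, :-1][pair_ok]
    j = q[:, 1:][pair_ok]
    glcm = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(glcm, (i, j), 1.0)
    glcm = glcm + glcm.T  # symmetric
    p = glcm / glcm.sum()

    ii, jj = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    homogeneity = float((p / (1.0 + np.abs(ii - jj))).sum())
    contrast = float((p * (ii - jj) ** 2).sum())
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    var_i = float((p * (ii - mu_i) ** 2).sum())
    var_j = float((p * (jj - mu_j) ** 2).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0
    else:
        correlation = float((p * (ii - mu_i) * (jj - mu_j)).sum() / np.sqrt(var_i * var_j))
    energy = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {
        "homogeneity": homogeneity,
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "entropy": entropy,
    }


# ---------------------------------------------------------------------------
# eigen features


def eigen_features(crop: np.ndarray, n: int = 10) -> np.ndarray:
    """First ``n`` eigenvalues of the column-covariance of a region crop.

    The crop's rows are treated as observations and its columns as variables;
    the eigenvalues of the resulting covariance matrix are sorted descending
    and the first ``n`` returned (zero-padded when the rank is lower).
    Eigenvalues are clipped at zero to absorb numerical round-off.
    """
    crop = np.asarray(crop, dtype=np.float64)
    if crop.ndim != 2:
        raise ValueError("expected a 2-D single-channel crop")
    if crop.shape[0] < 2:
        warnings.warn("degenerate crop with < 2 rows: eigen features zero-padded")
        return np.zeros(n)
    cov = np.cov(crop, rowvar=False)
    cov = np.atleast_2d(cov)
    vals = np.linalg.eigvalsh(cov)[::-1]
    vals = np.clip(vals, 0.0, None)
    out = np.zeros(n)
    out[: min(n, vals.size)] = vals[:n]
    return out


def region_crop(plane: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Bounding-box crop of a channel with out-of-region pixels filled.

    Out-of-region pixels are replaced by the region's mean intensity so the
    eigen decomposition does not leak background structure.
    """
    rows, cols = np.nonzero(mask)
    sl = (slice(rows.min(), rows.max() + 1), slice(cols.min(), cols.max() + 1))
    crop = np.asarray(plane, dtype=np.float64)[sl].copy()
    m = np.asarray(mask, dtype=bool)[sl]
    crop[~m] = crop[m].mean()
    return crop


# ---------------------------------------------------------------------------
# size ratios and assembly


@dataclass
class RatioResult:
    values: dict[str, float]
    flags: list[str]


def size_ratio_features(
    nucleus_mask: np.ndarray, cell_mask: np.ndarray
) -> tuple[dict[str, float], list[str]]:
    """Nucleus/cytoplasm area, nucleus/cell area and nucleus/cell perimeter ratios.

    A cell with no cytoplasm (nucleus == cell) has an undefined
    nucleus/cytoplasm ratio, reported as NaN with an explanatory flag.
    """
    n_area = float(np.sum(nucleus_mask))
    c_area = float(np.sum(cell_mask))
    if n_area == 0 or c_area == 0:
        raise ValueError("empty nucleus or cell region")
    cyto_area = c_area - n_area
    flags: list[str] = []
    if cyto_area <= 0:
        n_cyto = float("nan")
        flags.append("zero-cytoplasm-area")
    else:
        n_cyto = n_area / cyto_area
    n_perim = chain_perimeter(nucleus_mask)
    c_perim = chain_perimeter(cell_mask)
    return (
        {
            "n_cyto_area": n_cyto,
            "n_cell_area": n_area / c_area,
            "n_cell_perimeter": n_perim / c_perim,
        },
        flags,
    )


def _channels(rgb: np.ndarray) -> dict[str, np.ndarray]:
    rgb = np.asarray(rgb, dtype=np.float64)
    gray = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]  # ITU-R 601 luma
    return {"R": rgb[..., 0], "G": rgb[..., 1], "B": rgb[..., 2], "gray": gray}


def extract_feature_vector(
    nucleus_mask: np.ndarray, cell_mask: np.ndarray, rgb: np.ndarray
) -> pd.Series:
    """Assemble the full flat feature vector for one cell.

    Morphology for nucleus and cell, cytoplasm area only, statistical and
    GLCM blocks for nucleus / cytoplasm / cell over R, G, B and gray, eigen
    blocks for the nucleus and cell crops, and the three size ratios.  The
    raster is used as-is (no normalization).  Returns a Series indexed by
    ``flat_feature_names()``.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    cyto_mask = cell_mask & ~nucleus_mask
    out: dict[str, float] = {}
    for region, mask in (("nucleus", nucleus_mask), ("cell", cell_mask)):
        for name, val in morphological_features(mask).items():
            out[f"{region}_{name}"] = val
    out["cytoplasm_area"] = float(cyto_mask.sum())

    chans = _channels(rgb)
    masks = {"nucleus": nucleus_mask, "cytoplasm": cyto_mask, "cell": cell_mask}
    for region in STAT_REGIONS:
        mask = masks[region]
        for ch in CHANNELS:
            plane = chans[ch]
            stats = statistical_features(plane[mask])
            for name, val in stats.items():
                out[f"{region}_{ch}_{name}"] = val
    for region in STAT_REGIONS:
        mask = masks[region]
        for ch in CHANNELS:
            glcm = glcm_features(chans[ch], mask)
            for name, val in glcm.items():
                out[f"{region}_{ch}_{name}"] = val
    for region in EIGEN_REGIONS:
        mask = masks[region]
        for ch in CHANNELS:
            vals = eigen_features(region_crop(chans[ch], mask))
            for i, v in enumerate(vals, start=1):
                out[f"{region}_{ch}_eigen_{i}"] = float(v)
    ratios, flags = size_ratio_features(nucleus_mask, cell_mask)
    out.update(ratios)
    if flags:
        logger.warning("feature extraction flags: %s", flags)
    return pd.Series(out, index=flat_feature_names(), dtype=np.float64)
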