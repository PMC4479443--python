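"""Synthetic Wright-stained bone-marrow smear generator with ground truth.

No public accession of stained marrow-smear micrographs with per-pixel truth
exists for this pipeline, so every downstream stage is exercised on rendered
smears: purple/blue leukocyte nuclei strictly darker than their cytoplasm,
orange/rose erythrocytes, a pale textured background, per-image affine stain
shifts and additive sensor noise, and configurable cell overlap.  Cells are
randomly rotated ellipses with low-order radial boundary jitter; nuclei are
smaller offset ellipses rendered wholly inside their cell.  The five FAB
subtypes (L1, L2 lymphoblastic; M2, M3, M5 myeloblastic) differ only in
parameterized statistics (nucleus/cell size ratio, chroma, texture grain) —
no cytological realism is attempted.

Two further generators emulate the measurement side: a labeled 67-feature
table with controllable class separation, and a multi-sample patient cohort
for the diagnosis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as _skdraw

from .features import FEATURE_NAMES, flat_feature_names

__all__ = [
    "SmearSpec",
    "GroundTruth",
    "PlacementError",
    "SUBTYPES",
    "FAMILY_OF",
    "generate_smear",
    "generate_feature_dataset",
    "generate_patient_set",
]

SUBTYPES = ("L1", "L2", "M2", "M3", "M5")
FAMILY_OF = {"L1": "ALL", "L2": "ALL", "M2": "AML", "M3": "AML", "M5": "AML"}

# base render colors (sRGB); nuclei are darker and bluer than cytoplasm,
# erythrocytes orange/rose, background pale and near-neutral
_COL_BACKGROUND = np.array([236.0, 232.0, 230.0])
_COL_ERYTHROCYTE = np.array([238.0, 165.0, 140.0])
_COL_CYTOPLASM = np.array([176.0, 178.0, 216.0])
_COL_NUCLEUS = np.array([96.0, 66.0, 148.0])

# class-conditional rendering statistics: nucleus/cell radius ratio,
# nucleus chroma shift (RGB), nucleus texture grain SD (8-bit units)
_SUBTYPE_RENDER = {
    "L1": {"n_ratio": 0.80, "chroma": np.array([0.0, 0.0, 0.0]), "grain": 2.0},
    "L2": {"n_ratio": 0.68, "chroma": np.array([8.0, -4.0, 6.0]), "grain": 3.0},
    "M2": {"n_ratio": 0.58, "chroma": np.array([-6.0, 4.0, -8.0]), "grain": 5.0},
    "M3": {"n_ratio": 0.52, "chroma": np.array([10.0, 6.0, -6.0]), "grain": 7.0},
    "M5": {"n_ratio": 0.46, "chroma": np.array([-4.0, -6.0, 10.0]), "grain": 4.0},
}


class PlacementError(RuntimeError):
    """Raised when the requested cell counts cannot be placed within the retry budget."""


@dataclass(frozen=True)
class SmearSpec:
    """Rendering conditions for one synthetic smear."""

    image_size: int = 256
    n_leukocytes: int = 3
    n_erythrocytes: int = 12
    overlap_fraction: float = 0.0
    stain_shift: tuple[float, float, float] | None = None  # None: drawn per image
    noise_sd: float = 4.0
    seed: int = 0
    subtypes: tuple[str, ...] | None = None  # per-leukocyte; None: drawn uniformly

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if min(self.image_size, self.n_leukocytes, self.n_erythrocytes) < 0:
            raise ValueError("counts and sizes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.subtypes is not None:
            unknown = set(self.subtypes) - set(SUBTYPES)
            if unknown:
                raise ValueError(f"unknown subtypes: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Instance-level truth for one rendered smear.

    Instance labels are positive and contiguous from 1; every nucleus
    instance lies wholly inside its cell instance of the same label.
    """

    nucleus_mask: np.ndarray  # int instance labels, 0 = background
    cell_mask: np.ndarray
    class_label: dict[int, str] = field(default_factory=dict)
    overlap_pairs: list[tuple[int, int]] = field(default_factory=list)


def _jittered_ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
    jitter: np.ndarray,
) -> np.ndarray:
    """Rasterize a rotated ellipse whose radius is modulated by low-order harmonics."""
    theta = np.deg2rad(np.arange(0.0, 360.0, 1.0))
    a, b = axes
    rel = theta - angle
    r = a * b / np.sqrt((b * np.cos(rel)) ** 2 + (a * np.sin(rel)) ** 2)
    mod = np.ones_like(theta)
    for k, (amp, ph) in enumerate(jitter, start=2):
        mod += amp * np.cos(k * theta + ph)
    r = r * np.clip(mod, 0.75, 1.25)
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    rr, cc = _skdraw.polygon(rows, cols, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _draw_jitter(rng: np.random.Generator, n_harmonics: int = 3, amp: float = 0.035) -> np.ndarray:
    amps = rng.uniform(0.0, amp, size=n_harmonics)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harmonics)
    return np.column_stack([amps, phases])


def _place_overlapping(
    shape: tuple[int, int],
    partner_mask: np.ndarray,
    partner_center: np.ndarray,
    radius: float,
    partner_radius: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Translate a new cell toward a partner until masks intersect by 10-30%.

    Returns (cell mask, center, direction away from partner) or None when no
    admissible placement is found.
    """
    direction = rng.uniform(0.0, 2.0 * np.pi)
    u = np.array([np.sin(direction), np.cos(direction)])
    angle = rng.uniform(0.0, np.pi)
    ecc = rng.uniform(0.85, 1.0)
    axes = (radius, radius * ecc)
    jit = _draw_jitter(rng)
    for s in np.linspace(0.98, 0.55, 24):
        center = partner_center + u * (radius + partner_radius) * s
        if not (0 <= center[0] < shape[0] and 0 <= center[1] < shape[1]):
            continue
        mask = _jittered_ellipse_mask(shape, tuple(center), axes, angle, jit)
        inter = np.logical_and(mask, partner_mask).sum()
        smaller = min(mask.sum(), partner_mask.sum())
        if smaller == 0:
            continue
        frac = inter / smaller
        if 0.10 <= frac <= 0.30:
            return mask, center, u
        if frac > 0.30:
            break
    return None


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float, sigma: float) -> np.ndarray:
    raw = rng.normal(0.0, 1.0, size=shape)
    sm = ndimage.gaussian_filter(raw, sigma=sigma)
    s = sm.std()
    return sm * (sd / s) if s > 0 else sm


def generate_smear(spec: SmearSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic smear and its ground truth.

    Leukocytes are placed with a retry budget; the requested
    ``overlap_fraction`` of them is translated against an already placed
    leukocyte until the masks intersect by 10-30% of the smaller area (the
    concave waist the separation stage needs).  Erythrocytes never intrude on
    leukocytes.  Output is deterministic for a fixed spec (the seed drives
    every random draw).

    Raises
    ------
    PlacementError : when the cell counts cannot be placed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    shape = (n, n)
    cell_mask = np.zeros(shape, dtype=np.int32)
    nucleus_mask = np.zeros(shape, dtype=np.int32)
    class_label: dict[int, str] = {}
    overlap_pairs: list[tuple[int, int]] = []

    if spec.subtypes is not None and len(spec.subtypes) not in (0, spec.n_leukocytes):
        if len(spec.subtypes) == 1:
            subtypes = [spec.subtypes[0]] * spec.n_leukocytes
        else:
            raise ValueError("subtypes must be length 1 or n_leukocytes")
    elif spec.subtypes is not None:
        subtypes = list(spec.subtypes)
    else:
        subtypes = [SUBTYPES[i] for i in rng.integers(0, len(SUBTYPES), size=spec.n_leukocytes)]

    n_overlap = int(round(spec.overlap_fraction * spec.n_leukocytes))
    # overlapping cells are placed last so partners already exist
    centers: list[np.ndarray] = []
    radii: list[float] = []
    masks: list[np.ndarray] = []
    away: list[np.ndarray | None] = []

    budget = 300
    for i in range(spec.n_leukocytes):
        radius = rng.uniform(16.0, 24.0) * min(1.0, n / 256.0 + 0.35)
        wants_overlap = i >= spec.n_leukocytes - n_overlap and i > 0
        placed = False
        for _ in range(budget):
            if wants_overlap:
                j = int(rng.integers(0, len(masks)))
                res = _place_overlapping(shape, masks[j], centers[j], radius, radii[j], rng)
                if res is None:
                    continue
                mask, center, u = res
                # reject if it also collides with any non-partner cell
                others = [m for t, m in enumerate(masks) if t != j]
                if any(np.logical_and(mask, m).any() for m in others):
                    continue
                overlap_pairs.append((j + 1, i + 1))
                masks.append(mask)
                centers.append(center)
                radii.append(radius)
                away.append(u)
                placed = True
                break
            else:
                margin = radius * 1.15
                center = rng.uniform(margin, n - margin, size=2)
                angle = rng.uniform(0.0, np.pi)
                ecc = rng.uniform(0.85, 1.0)
                mask = _jittered_ellipse_mask(shape, tuple(center), (radius, radius * ecc), angle, _draw_jitter(rng))
                if any(np.logical_and(mask, m).any() for m in masks):
                    continue
                masks.append(mask)
                centers.append(center)
                radii.append(radius)
                away.append(None)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place leukocyte {i + 1}/{spec.n_leukocytes} within {budget} retries"
            )

    # nuclei: offset ellipses wholly inside the cell, pushed away from overlap
    nucleus_masks: list[np.ndarray] = []
    for i, (mask, center, radius) in enumerate(zip(masks, centers, radii)):
        sub = subtypes[i]
        ratio = _SUBTYPE_RENDER[sub]["n_ratio"] * rng.uniform(0.92, 1.08)
        n_radius_base = radius * min(ratio, 0.85)
        placed = False
        for attempt in range(budget):
            n_radius = n_radius_base * (0.97 ** attempt)  # shrink only as a fallback
            if away[i] is not None:
                off_dir = -away[i] + rng.normal(0.0, 0.2, size=2)
                off_dir = off_dir / np.linalg.norm(off_dir)
                off = off_dir * (radius - n_radius) * rng.uniform(0.4, 0.7)
            else:
                phi = rng.uniform(0.0, 2.0 * np.pi)
                off_dir = np.array([np.sin(phi), np.cos(phi)])
                off = off_dir * rng.uniform(0.0, (radius - n_radius) * 0.5) * (0.9**attempt)
            ncenter = center + off
            nangle = rng.uniform(0.0, np.pi)
            necc = rng.uniform(0.85, 1.0)
            nmask = _jittered_ellipse_mask(
                shape, tuple(ncenter), (n_radius, n_radius * necc), nangle, _draw_jitter(rng, amp=0.02)
            )
            if not nmask.any():
                continue
            if np.logical_and(nmask, ~mask).any():  # must sit wholly inside its cell
                continue
            # must not be occluded by any other (later-painted) cell
            if any(np.logical_and(nmask, m).any() for t, m in enumerate(masks) if t != i):
                continue
            nucleus_masks.append(nmask)
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place nucleus inside leukocyte {i + 1}")

    # erythrocytes: avoid leukocytes entirely, may crowd each other
    leuko_union = np.zeros(shape, dtype=bool)
    for m in masks:
        leuko_union |= ndimage.binary_dilation(m, iterations=2)
    ery_masks: list[np.ndarray] = []
    for _ in range(spec.n_erythrocytes):
        placed = False
        for _ in range(budget):
            radius = rng.uniform(8.0, 12.0)
            center = rng.uniform(radius, n - radius, size=2)
            angle = rng.uniform(0.0, np.pi)
            mask = _jittered_ellipse_mask(
                shape, tuple(center), (radius, radius * rng.uniform(0.8, 1.0)), angle, _draw_jitter(rng)
            )
            if np.logical_and(mask, leuko_union).any():
                continue
            ery_masks.append(mask)
            placed = True
            break
        if not placed:
            raise PlacementError("could not place erythrocyte without touching a leukocyte")

    # ---- render ----
    img = np.empty(shape + (3,), dtype=np.float64)
    img[...] = _COL_BACKGROUND
    # background mottle (heterogeneous staining texture)
    img += _smooth_noise(rng, shape, sd=2.5, sigma=12.0)[..., None]
    for mask in ery_masks:
        img[mask] = _COL_ERYTHROCYTE + rng.normal(0.0, 4.0, size=3)
    # paint cells in instance order; later instances overwrite the lens
    for i, (mask, nmask) in enumerate(zip(masks, nucleus_masks)):
        sub = subtypes[i]
        render = _SUBTYPE_RENDER[sub]
        cyto_col = _COL_CYTOPLASM + rng.normal(0.0, 3.0, size=3)
        nuc_col = _COL_NUCLEUS + render["chroma"] + rng.normal(0.0, 3.0, size=3)
        img[mask] = cyto_col
        grain = _smooth_noise(rng, shape, sd=render["grain"], sigma=1.2)
        img[nmask] = nuc_col
        img[..., 0][nmask] += grain[nmask]
        img[..., 1][nmask] += grain[nmask]
        img[..., 2][nmask] += grain[nmask]
        cell_mask[mask] = i + 1
        nucleus_mask[nmask] = i + 1

    # per-image affine stain transform: channel gains + hue/brightness shift
    if spec.stain_shift is None:
        shift = rng.uniform(-8.0, 8.0, size=3)
    else:
        shift = np.asarray(spec.stain_shift, dtype=np.float64)
    gain = rng.uniform(0.97, 1.03, size=3)
    img = img * gain + shift
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        nucleus_mask=nucleus_mask,
        cell_mask=cell_mask,
        class_label={i + 1: subtypes[i] for i in range(spec.n_leukocytes)},
        overlap_pairs=overlap_pairs,
    )
    return img, truth


# ---------------------------------------------------------------------------
# labeled feature tables


def _base_feature_stats(names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Plausible per-column base means and SDs, fixed across calls."""
    base_rng = np.random.default_rng(20150624)
    means = np.empty(len(names))
    sds = np.empty(len(names))
    for i, name in enumerate(names):
        short = name.rsplit("_", 1)[-1] if not name.split("_")[-1].isdigit() else "eigen"
        if "eigen" in name:
            k = int(name.rsplit("_", 1)[-1]) if name.rsplit("_", 1)[-1].isdigit() else 1
            means[i] = 120.0 / k
        elif "area" in short or short == "sum":
            means[i] = base_rng.uniform(400.0, 1200.0)
        elif short in ("perimeter", "width", "length", "major", "minor"):
            means[i] = base_rng.uniform(20.0, 120.0)
        elif short in ("mode", "mean"):
            means[i] = base_rng.uniform(60.0, 200.0)
        elif short in ("std", "variance", "contrast", "entropy"):
            means[i] = base_rng.uniform(2.0, 40.0)
        else:
            means[i] = base_rng.uniform(0.3, 1.5)
        sds[i] = 0.08 * abs(means[i]) + 0.5
    return means, sds


def generate_feature_dataset(
    n_per_class: int,
    class_separation: float,
    seed: int,
    classes: tuple[str, ...] = ("L1", "L2"),
    expanded: bool = False,
    signal_region: str | None = None,
) -> pd.DataFrame:
    """Draw a labeled feature table from class-conditional Gaussians.

    Columns follow the canonical 67-feature schema (or, with
    ``expanded=True``, the flat per-region/per-channel schema).  Class means
    are placed hierarchically: each class mean is the sum of an orthonormal
    subtype direction and (for FAB subtypes) its family's shared direction,
    scaled so that two subtypes of the same family sit ``class_separation``
    pooled SDs apart and subtypes of different families sqrt(2) times
    farther — families are morphologically more distinct than subtypes
    within a family.  ``class_separation=0`` makes the classes
    exchangeable.  With ``signal_region`` the separation is confined to
    columns of that region prefix (requires the expanded schema), leaving
    all other columns pure noise.

    Raises
    ------
    ValueError : on negative separation, ``n_per_class < 2`` or an unusable
        signal region.
    """
    if class_separation < 0:
        raise ValueError("class_separation must be non-negative")
    if n_per_class < 2:
        raise ValueError("n_per_class must be at least 2")
    names = flat_feature_names() if expanded else list(FEATURE_NAMES)
    if signal_region is not None:
        if not expanded:
            raise ValueError("signal_region requires the expanded schema")
        signal_cols = np.array([n.startswith(f"{signal_region}_") for n in names])
        if not signal_cols.any():
            raise ValueError(f"no columns for region {signal_region!r}")
    else:
        signal_cols = np.ones(len(names), dtype=bool)

    means, sds = _base_feature_stats(names)
    d = int(signal_cols.sum())
    families = sorted({FAMILY_OF[c] for c in classes if c in FAMILY_OF})
    dir_rng = np.random.default_rng(8421)
    raw = dir_rng.normal(size=(d, len(classes) + len(families)))
    q, _ = np.linalg.qr(raw)
    scale = class_separation / np.sqrt(2.0)
    fam_dir = {f: q[:, len(classes) + i] for i, f in enumerate(families)}
    deltas = np.empty((len(classes), d))
    for c, cls in enumerate(classes):
        delta = q[:, c].copy()
        if cls in FAMILY_OF:
            delta += fam_dir[FAMILY_OF[cls]]
        deltas[c] = scale * delta

    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    for c, cls in enumerate(classes):
        z = rng.normal(size=(n_per_class, len(names)))
        z[:, signal_cols] += deltas[c]
        rows.append(means + sds * z)
        labels += [cls] * n_per_class
    table = pd.DataFrame(np.vstack(rows), columns=names)
    table["label"] = labels
    return table


def generate_patient_set(
    n_patients: int,
    samples_per_patient: int,
    subtypes: tuple[str, ...] | None = None,
    seed: int = 0,
    class_separation: float = 3.0,
    expanded: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a patient manifest and per-sample feature rows.

    Each patient carries one ground-truth subtype (hence family); all of the
    patient's samples are drawn from that subtype's feature distribution.
    ``subtypes`` assigns one subtype per patient (cycled from the FAB roster
    when omitted).  Returns ``(manifest, features)``: the manifest has one
    row per sample with patient/sample ids and truth labels; the feature
    table is indexed by sample id.

    Raises
    ------
    ValueError : if ``samples_per_patient < 1``.
    """
    if samples_per_patient < 1:
        raise ValueError("samples_per_patient must be at least 1")
    if subtypes is None:
        subtypes = tuple(SUBTYPES[i % len(SUBTYPES)] for i in range(n_patients))
    if len(subtypes) != n_patients:
        raise ValueError("need one subtype per patient")
    unknown = set(subtypes) - set(SUBTYPES)
    if unknown:
        raise ValueError(f"unknown subtypes: {sorted(unknown)}")

    pool = generate_feature_dataset(
        n_per_class=max(samples_per_patient * max(1, n_patients), 2),
        class_separation=class_separation,
        seed=seed,
        classes=tuple(SUBTYPES),
        expanded=expanded,
    )
    feature_cols = [c for c in pool.columns if c != "label"]
    manifest_rows = []
    feature_rows = []
    cursors = {s: 0 for s in SUBTYPES}
    for p in range(n_patients):
        sub = subtypes[p]
        cls_rows = pool[pool["label"] == sub]
        for s in range(samples_per_patient):
            sample_id = f"P{p + 1:03d}_S{s + 1:03d}"
            manifest_rows.append(
                {
                    "patient_id": f"P{p + 1:03d}",
                    "sample_id": sample_id,
                    "family": FAMILY_OF[sub],
                    "subtype": sub,
                }
            )
            feature_rows.append(cls_rows.iloc[cursors[sub]][feature_cols].rename(sample_id))
            cursors[sub] += 1
    manifest = pd.DataFrame(manifest_rows)
    features = pd.DataFrame(feature_rows)
    features.index.name = "sample_id"
    return manifest, features
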