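"""CIE L*a*b* color model and channel-intensity grouping.

Wright-stained marrow smears show leukocyte nuclei in dark purple, cytoplasm
in blue/rose and erythrocytes in orange tones.  In CIE L*a*b* the luminosity
plane L* isolates the dark nucleus while b* (blue-yellow opponent axis) pulls
the purple/blue leukocyte apart from orange erythrocytes and the pale
background.  Pixels of a chosen plane are grouped by k-means on their scalar
intensity (k = 2 or 3) and per-group mean / variance / standard deviation are
kept as the color observations for the downstream Markov-random-field
segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "LabImage",
    "ChannelGroups",
    "rgb_to_lab",
    "lab_to_rgb",
    "cluster_channel",
    "select_foreground_group",
]


@dataclass(frozen=True)
class LabImage:
    """Per-pixel CIE L*a*b* planes of an sRGB image (D65 white point).

    L* is in [0, 100]; a* and b* are signed opponent axes (green-red and
    blue-yellow respectively).
    """

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if not (self.L.shape == self.a.shape == self.b.shape):
            raise ValueError("L*, a*, b* planes must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape


@dataclass
class ChannelGroups:
    """k-means grouping of one channel plane with per-group statistics."""

    k: int
    assignments: np.ndarray  # per-pixel group index, same shape as the plane
    means: np.ndarray  # (k,)
    variances: np.ndarray  # (k,) population variances
    stds: np.ndarray  # (k,)
    foreground_group: int | None = field(default=None)

    def statistics(self, group: int) -> tuple[float, float, float]:
        return float(self.means[group]), float(self.variances[group]), float(self.stds[group])


# sRGB -> XYZ (linear, D65 primaries) and the D65 reference white
_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_D65 = np.array([0.95047, 1.0, 1.08883])
_LAB_DELTA = 6.0 / 29.0


def rgb_to_lab(rgb: np.ndarray) -> LabImage:
    """Convert an 8-bit/channel sRGB raster to CIE L*a*b*.

    The chain is sRGB gamma expansion -> linear RGB -> XYZ (D65 white) ->
    L*a*b*, applied per pixel; the reference white maps to exactly
    (100, 0, 0).

    Parameters
    ----------
    rgb : (H, W, 3) uint8 or float array. Floats are interpreted on [0, 1].

    Raises
    ------
    ValueError : if the input does not carry exactly three channels.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {rgb.shape}")
    if np.issubdtype(rgb.dtype, np.integer):
        rgb = rgb.astype(np.float64) / 255.0
    else:
        rgb = rgb.astype(np.float64)
    linear = np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
    xyz = linear @ _RGB2XYZ.T
    t = xyz / _D65
    f = np.where(t > _LAB_DELTA**3, np.cbrt(t), t / (3.0 * _LAB_DELTA**2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return LabImage(L=L, a=a, b=b)


def lab_to_rgb(lab: LabImage) -> np.ndarray:
    """Inverse transform (auxiliary; used by the synthetic smear renderer).

    Returns an (H, W, 3) uint8 sRGB raster; out-of-gamut values are clipped.
    """
    stack = np.dstack([lab.L, lab.a, lab.b])
    rgb = _skcolor.lab2rgb(stack)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def cluster_channel(
    plane: np.ndarray,
    k: int = 2,
    seed: int = 0,
    restarts: int = 10,
    max_fit_pixels: int = 20000,
) -> ChannelGroups:
    """Group a channel plane into ``k`` intensity clusters by k-means.

    Scalar k-means with ``restarts`` random initializations; on large planes
    the centroids are fit on a random subsample (``max_fit_pixels``) and all
    pixels are then assigned to the nearest centroid, which for scalar data
    leaves the assignment rule exact.  Per-group mean, population variance and
    standard deviation are computed from the full assignment.

    Raises
    ------
    ValueError : if ``k < 2`` or the plane has fewer distinct values than k.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.size == 0:
        raise ValueError("empty channel plane")
    if k < 2:
        raise ValueError("k must be at least 2")
    values = plane.reshape(-1, 1)
    if np.unique(values).size < k:
        raise ValueError(f"degenerate plane: fewer than k={k} distinct intensity values")

    rng = np.random.default_rng(seed)
    if values.shape[0] > max_fit_pixels:
        fit_idx = rng.choice(values.shape[0], size=max_fit_pixels, replace=False)
        fit_values = values[fit_idx]
        # guard: the subsample must still expose k distinct values
        if np.unique(fit_values).size < k:
            fit_values = values
    else:
        fit_values = values
    km = KMeans(n_clusters=k, n_init=restarts, random_state=int(seed) % (2**31))
    km.fit(fit_values)

    # sort groups by ascending mean so group indices are deterministic
    order = np.argsort(km.cluster_centers_.ravel())
    centers = km.cluster_centers_.ravel()[order]
    # nearest-centroid assignment of every pixel
    assignments = np.argmin(np.abs(values - centers[None, :]), axis=1).reshape(plane.shape)

    means = np.empty(k)
    variances = np.empty(k)
    for g in range(k):
        members = plane[assignments == g]
        if members.size == 0:
            means[g] = centers[g]
            variances[g] = 0.0
        else:
            means[g] = members.mean()
            variances[g] = members.var()  # population convention
    return ChannelGroups(
        k=k,
        assignments=assignments,
        means=means,
        variances=variances,
        stds=np.sqrt(variances),
    )


def select_foreground_group(groups: ChannelGroups, mode: str) -> int:
    """Pick the cluster that represents the nucleus or the whole cell.

    ``mode='nucleus'`` expects groups built on L* and returns the darkest
    group (minimum mean L*); ``mode='cell'`` expects groups on b* and returns
    the most blue/purple group (minimum mean b*).  Ties break to the lowest
    group index.
    """
    if mode not in ("nucleus", "cell"):
        raise ValueError(f"mode must be 'nucleus' or 'cell', got {mode!r}")
    idx = int(np.argmin(groups.means))  # argmin takes the first (lowest) index on ties
    if np.sum(groups.means == groups.means[idx]) > 1:
        logger.warning("tie in group means; breaking to lowest group index %d", idx)
    groups.foreground_group = idx
    return idx
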