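"""2-D Wold texture decomposition: harmonic + generalized evanescent + stochastic.

A homogeneous random texture field splits into three mutually orthogonal
components — a harmonic field (isolated spectral peaks: periodicity), a
generalized evanescent field (energy on lines through the frequency plane:
directionality) and a stochastic field (the broadband residual: randomness).
Here the split is performed on the DFT of the mean-subtracted channel: peak
bins feed the harmonic field, line-supported bins (found by a Hough transform
on the thresholded residual magnitude) feed the evanescent field, and every
remaining bin feeds the stochastic field.  The three spectral supports are
disjoint by construction, so the spatial fields add back to the channel
(plus its recorded mean) exactly.

Amplitude convention: the "amplitude" of a frequency bin is 2|F|/Npix, i.e. a
pure cosine of amplitude A scores A at each of its two conjugate bins.  The
peak threshold (default 10) is therefore in the intensity units of the
channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import hough_line, hough_line_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "TextureFields",
    "detect_harmonic_peaks",
    "extract_harmonic_field",
    "detect_evanescent_lines",
    "decompose",
    "windowed_energy",
]


@dataclass
class Spectrum:
    """2-D DFT of a real channel plane, DC at index (0, 0)."""

    F: np.ndarray  # complex (H, W)

    @property
    def shape(self) -> tuple[int, int]:
        return self.F.shape

    @property
    def npix(self) -> int:
        return int(self.F.shape[0] * self.F.shape[1])

    def magnitude(self) -> np.ndarray:
        return np.abs(self.F)

    def amplitude(self) -> np.ndarray:
        """Per-bin amplitude on the cosine scale (2|F|/Npix)."""
        return 2.0 * np.abs(self.F) / self.npix

    def phase(self) -> np.ndarray:
        return np.angle(self.F)

    @classmethod
    def from_plane(cls, plane: np.ndarray) -> "Spectrum":
        return cls(F=np.fft.fft2(np.asarray(plane, dtype=np.float64)))


@dataclass
class TextureFields:
    """Spatial Wold components of one channel plus their spectral parameters.

    ``harmonic + evanescent + stochastic + mean`` reconstructs the input
    channel; the three components occupy disjoint frequency supports.  The DC
    term (channel mean) is kept apart so the stochastic residual is zero-mean
    even for degenerate constant inputs.
    """

    harmonic: np.ndarray
    evanescent: np.ndarray
    stochastic: np.ndarray
    mean: float
    harmonic_params: list[tuple[tuple[int, int], float, float]] = field(default_factory=list)
    evanescent_params: list[dict] = field(default_factory=list)

    @property
    def structural(self) -> np.ndarray:
        """Structural component = harmonic + generalized evanescent fields."""
        return self.harmonic + self.evanescent

    def reconstruct(self) -> np.ndarray:
        return self.harmonic + self.evanescent + self.stochastic + self.mean


def _conjugate_index(idx: tuple[int, int], shape: tuple[int, int]) -> tuple[int, int]:
    return ((-idx[0]) % shape[0], (-idx[1]) % shape[1])


def detect_harmonic_peaks(
    spectrum: Spectrum,
    amplitude_threshold: float = 10.0,
    min_separation: int = 2,
) -> list[tuple[int, int]]:
    """Locate the largest isolated spectral peaks above the amplitude threshold.

    A bin qualifies when its amplitude (2|F|/Npix) exceeds the threshold and
    it is a strict local maximum over its 8-neighborhood (periodic wrap) —
    strictness keeps dense evanescent line support, where neighbors tie, out
    of the harmonic stage.  DC is excluded.  Accepted peaks are taken
    greedily by descending amplitude with
    a minimum separation of ``min_separation`` bins (Chebyshev) between them;
    the conjugate of each accepted bin is accepted with it, so peaks come in
    conjugate pairs.  Returned indices are (row, col) into the unshifted DFT,
    sorted for determinism.
    """
    amp = spectrum.amplitude()
    h, w = amp.shape
    ring = np.ones((3, 3), dtype=bool)
    ring[1, 1] = False
    neighbor_max = ndimage.maximum_filter(amp, footprint=ring, mode="wrap")
    # strict up to a relative tolerance: numerically tied line bins are not peaks
    candidate = (amp > neighbor_max * (1.0 + 1e-9) + 1e-12) & (amp > amplitude_threshold)
    candidate[0, 0] = False
    idxs = np.argwhere(candidate)
    if idxs.size == 0:
        return []
    # greedy selection by descending amplitude, deterministic tie order
    order = np.lexsort((idxs[:, 1], idxs[:, 0], -amp[idxs[:, 0], idxs[:, 1]]))
    accepted: list[tuple[int, int]] = []
    taken: set[tuple[int, int]] = set()

    def _near(p: tuple[int, int], q: tuple[int, int]) -> bool:
        dy = min(abs(p[0] - q[0]), h - abs(p[0] - q[0]))
        dx = min(abs(p[1] - q[1]), w - abs(p[1] - q[1]))
        return max(dy, dx) < min_separation

    for i in order:
        p = (int(idxs[i, 0]), int(idxs[i, 1]))
        if p in taken:
            continue
        if any(_near(p, q) for q in accepted):
            continue
        conj = _conjugate_index(p, (h, w))
        accepted.append(p)
        taken.add(p)
        if conj != p and conj not in taken:
            accepted.append(conj)
            taken.add(conj)
    return sorted(accepted)


def extract_harmonic_field(
    spectrum: Spectrum, peaks: list[tuple[int, int]]
) -> tuple[np.ndarray, list[tuple[tuple[int, int], float, float]]]:
    """Inverse-transform the spectrum restricted to the peak bins.

    Returns the real spatial harmonic field and, per peak, its
    ((row, col), amplitude, phase) parameterization.
    """
    F = spectrum.F
    mask = np.zeros(F.shape, dtype=bool)
    params: list[tuple[tuple[int, int], float, float]] = []
    amp = spectrum.amplitude()
    ph = spectrum.phase()
    for p in peaks:
        mask[p] = True
        params.append((p, float(amp[p]), float(ph[p])))
    fieldF = np.where(mask, F, 0.0)
    return np.real(np.fft.ifft2(fieldF)), params


def detect_evanescent_lines(
    spectrum: Spectrum,
    amplitude_threshold: float = 10.0,
    max_lines: int = 4,
    min_support: int = 8,
    exclude: np.ndarray | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Find up to ``max_lines`` evanescent spectral lines by a Hough transform.

    The fftshifted residual amplitude is thresholded into a binary image and
    straight lines are voted with a 1-degree angular, 1-bin radial Hough
    accumulator.  A line's spectral support is every above-threshold bin
    within 1 bin of it; lines with fewer than ``min_support`` supporting bins
    are dropped (logged).  The support mask is symmetrized with its conjugate
    bins so the resulting field is real.  Returns the boolean support mask
    (unshifted indexing, DC and ``exclude`` bins removed) plus per-line
    parameters with the DFT amplitude/phase along the line.
    """
    amp = spectrum.amplitude()
    h, w = amp.shape
    shifted = np.fft.fftshift(amp)
    binary = shifted > amplitude_threshold
    # DC in shifted coordinates
    binary[h // 2, w // 2] = False
    if exclude is not None:
        binary &= ~np.fft.fftshift(exclude)
    support = np.zeros((h, w), dtype=bool)
    params: list[dict] = []
    if not binary.any():
        return support, params

    theta = np.deg2rad(np.arange(-90.0, 90.0, 1.0))
    accum, angles, dists = hough_line(binary, theta=theta)
    peaks = hough_line_peaks(accum, angles, dists, num_peaks=max_lines, threshold=1)
    rr, cc = np.nonzero(binary)
    for votes, angle, dist in zip(*peaks):
        # bins within 1 bin of the line x*cos(a) + y*sin(a) = dist
        d = np.abs(cc * np.cos(angle) + rr * np.sin(angle) - dist)
        on_line = d <= 1.0
        if on_line.sum() < min_support:
            logger.info("evanescent line with support %d < %d dropped", on_line.sum(), min_support)
            continue
        line_mask = np.zeros((h, w), dtype=bool)
        line_mask[rr[on_line], cc[on_line]] = True
        support |= line_mask
        params.append(
            {
                "angle": float(angle),
                "dist": float(dist),
                "votes": int(votes),
                "n_bins": int(on_line.sum()),
            }
        )
    support = np.fft.ifftshift(support)
    support[0, 0] = False
    if exclude is not None:
        support &= ~exclude
    # symmetrize so the evanescent field is real
    conj = np.zeros_like(support)
    rr2, cc2 = np.nonzero(support)
    conj[(-rr2) % h, (-cc2) % w] = True
    support |= conj
    # record amplitude/phase along each line for the parameterization
    if params:
        ampl, phs = spectrum.amplitude(), spectrum.phase()
        for p in params:
            p_mask = support
            p["amplitudes_mean"] = float(ampl[p_mask].mean())
            p["phase_example"] = float(phs[p_mask].ravel()[0])
    return support, params


def decompose(
    plane: np.ndarray,
    amplitude_threshold: float = 10.0,
    max_evanescent_lines: int = 4,
) -> TextureFields:
    """Split a channel plane into its three Wold components.

    Stages: (1) DFT of the mean-subtracted plane and harmonic-peak detection
    at ``amplitude_threshold``; (2) Hough detection of up to
    ``max_evanescent_lines`` evanescent lines on the residual spectrum;
    (3) the remaining bins form the stochastic field.  On a constant plane
    both structural components are empty and the stochastic field is the
    zero-mean residual (all zeros).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if min(plane.shape) < 8:
        raise ValueError("plane side length must be at least 8")
    mean = float(plane.mean())
    spec = Spectrum.from_plane(plane - mean)

    peaks = detect_harmonic_peaks(spec, amplitude_threshold=amplitude_threshold)
    harmonic, hparams = extract_harmonic_field(spec, peaks)
    peak_mask = np.zeros(spec.shape, dtype=bool)
    for p in peaks:
        peak_mask[p] = True

    line_mask, eparams = detect_evanescent_lines(
        spec,
        amplitude_threshold=amplitude_threshold,
        max_lines=max_evanescent_lines,
        exclude=peak_mask,
    )
    evanescent = np.real(np.fft.ifft2(np.where(line_mask, spec.F, 0.0)))

    stoch_mask = ~(peak_mask | line_mask)
    stoch_mask[0, 0] = True  # DC of the mean-subtracted plane is ~0 anyway
    stochastic = np.real(np.fft.ifft2(np.where(stoch_mask, spec.F, 0.0)))
    return TextureFields(
        harmonic=harmonic,
        evanescent=evanescent,
        stochastic=stochastic,
        mean=mean,
        harmonic_params=hparams,
        evanescent_params=eparams,
    )


def windowed_energy(field: np.ndarray, window: int = 16) -> np.ndarray:
    """Per-pixel local energy of a texture field (sliding window, stride 1).

    Mean of the squared field over a ``window`` x ``window`` neighborhood with
    reflective padding.
    """
    return ndimage.uniform_filter(np.square(np.asarray(field, dtype=np.float64)), size=window, mode="reflect")


def local_spectral_energies(
    plane: np.ndarray,
    window: int = 16,
    amplitude_threshold: float = 10.0,
    stride: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site structural and stochastic texture energy from local window spectra.

    The global Wold split cannot serve as a per-pixel observation — its
    harmonic and evanescent fields extend over the whole image — so each
    site's observation comes from the DFT of its own mean-subtracted
    ``window`` x ``window`` neighborhood: the structural energy is the mean
    squared contribution of window-spectrum bins whose amplitude
    (2|F|/Npix) exceeds ``amplitude_threshold`` (concentrated, structured
    content), the stochastic energy is the remainder.  Windows are evaluated
    on a ``stride`` grid (reflective padding) and nearest-filled back to
    pixel resolution, which leaves the maps piecewise constant at sub-window
    scale.  Returns ``(structural, stochastic)`` maps of the plane's shape.
    """
    plane = np.asarray(plane, dtype=np.float64)
    h, w = plane.shape
    pad = window // 2
    padded = np.pad(plane, pad, mode="reflect")
    views = np.lib.stride_tricks.sliding_window_view(padded, (window, window))[::stride, ::stride]
    gh, gw = views.shape[:2]
    npix = window * window
    out_struct = np.empty((gh, gw))
    out_stoch = np.empty((gh, gw))
    chunk = max(1, 2_000_000 // (npix * gw))
    for r0 in range(0, gh, chunk):
        block = views[r0 : r0 + chunk].astype(np.float64)
        block = block - block.mean(axis=(2, 3), keepdims=True)
        F = np.fft.rfft2(block)
        mag = np.abs(F)
        amp = 2.0 * mag / npix
        strong = amp > amplitude_threshold
        # account for the bins rfft2 folds away (conjugate half-plane)
        weight = np.full(F.shape[-1], 2.0)
        weight[0] = 1.0
        if window % 2 == 0:
            weight[-1] = 1.0
        power = mag**2 * weight
        total = power.sum(axis=(2, 3)) / npix**2
        struct = (power * strong).sum(axis=(2, 3)) / npix**2
        out_struct[r0 : r0 + chunk] = struct
        out_stoch[r0 : r0 + chunk] = total - struct
    rows = np.minimum(np.arange(h) // stride, gh - 1)
    cols = np.minimum(np.arange(w) // stride, gw - 1)
    return out_struct[np.ix_(rows, cols)], out_stoch[np.ix_(rows, cols)]
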