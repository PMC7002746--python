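"""Colour deconvolution for hematoxylin–DAB (H-DAB) brightfield immunohistochemistry.

Brightfield chromogens absorb light, so the natural working space is optical
density, ``OD = -log10(I / I0)``, in which stain contributions combine linearly
(Beer–Lambert).  Each stain is characterised by a unit vector of per-channel
optical densities; a 3x3 matrix whose rows are the hematoxylin, DAB and
residual vectors unmixes an OD pixel into per-stain amounts.  The default
vectors are the Ruifrok–Johnston H-DAB set; alternatively the pair of vectors
can be estimated from the image itself by plane/percentile (Macenko-style)
estimation, mirroring the automatic stain estimation that slide-analysis
platforms run as preprocessing.

All OD values use log base 10 and an 8-bit white point ``I0 = 255`` unless
stated otherwise.  Intensities are clamped to >= 1 before the logarithm so
optical densities are always finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "I0_DEFAULT",
    "RGBImage",
    "ODImage",
    "StainMatrix",
    "ConcentrationMaps",
    "StainEstimationError",
    "rgb_to_od",
    "od_to_rgb",
    "default_hdab_matrix",
    "estimate_stain_vectors",
    "deconvolve",
    "composite",
    "read_rgb",
    "write_rgb",
    "write_concentration_tiff",
]

I0_DEFAULT = 255.0

#: Ruifrok–Johnston H-DAB optical-density vectors (R, G, B), un-normalised.
RUIFROK_HEMATOXYLIN = (0.65, 0.70, 0.29)
RUIFROK_DAB = (0.27, 0.57, 0.78)


class StainEstimationError(RuntimeError):
    """Raised when an image contains too little stained tissue to estimate vectors."""


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit-range RGB brightfield image with known physical pixel size."""

    pixels: np.ndarray  #: (H, W, 3) array, values in [0, 255]
    pixel_size_um: float = 0.5  #: edge length of one pixel, micrometres

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) RGB array")
        if not np.all(np.isfinite(px)):
            raise ValueError("RGB image contains non-finite pixel values")
        if px.min() < 0.0 or px.max() > 255.0:
            raise ValueError("RGB intensities must lie in [0, 255]")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def as_uint8(self) -> np.ndarray:
        return np.clip(np.round(self.pixels), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class ODImage:
    """Per-pixel, per-channel optical densities of a brightfield image."""

    od: np.ndarray  #: (H, W, 3) non-negative optical densities
    i0: float = I0_DEFAULT  #: white-point intensity
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        od = np.asarray(self.od, dtype=np.float64)
        if od.ndim != 3 or od.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) OD array")
        if not np.all(np.isfinite(od)):
            raise ValueError("OD image contains non-finite values")
        if od.min() < 0.0:
            raise ValueError("optical densities must be non-negative")
        if not (self.i0 > 0 and self.pixel_size_um > 0):
            raise ValueError("i0 and pixel_size_um must be positive")
        object.__setattr__(self, "od", od)

    @property
    def shape(self) -> tuple[int, int]:
        return self.od.shape[:2]


@dataclass(frozen=True)
class StainMatrix:
    """Rows are unit OD-space vectors for hematoxylin, DAB and the residual channel.

    The residual row is the normalised cross product of the first two rows, so
    it is orthogonal to both; the matrix is therefore always invertible when
    the two stain vectors are not collinear.
    """

    vectors: np.ndarray  #: (3, 3) array, row order (hematoxylin, DAB, residual)

    def __post_init__(self) -> None:
        m = np.asarray(self.vectors, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("stain matrix rows must have unit Euclidean norm")
        if abs(np.dot(m[2], m[0])) > 1e-9 or abs(np.dot(m[2], m[1])) > 1e-9:
            raise ValueError("residual row must be orthogonal to both stain rows")
        if not np.isfinite(np.linalg.cond(m)):
            raise ValueError("stain matrix is singular")
        object.__setattr__(self, "vectors", m)

    @classmethod
    def from_stain_pair(cls, hematoxylin, dab) -> "StainMatrix":
        """Build a full matrix from two stain vectors, completing the residual row."""
        h = np.asarray(hematoxylin, dtype=np.float64)
        d = np.asarray(dab, dtype=np.float64)
        h = h / np.linalg.norm(h)
        d = d / np.linalg.norm(d)
        r = np.cross(h, d)
        nr = np.linalg.norm(r)
        if nr < 1e-12:
            raise ValueError("stain vectors are collinear; residual undefined")
        return cls(np.vstack([h, d, r / nr]))

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.vectors[0]

    @property
    def dab(self) -> np.ndarray:
        return self.vectors[1]

    @property
    def residual(self) -> np.ndarray:
        return self.vectors[2]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"rows": ["hematoxylin", "dab", "residual"],
                        "vectors": self.vectors.tolist()}, indent=2)
        )

    @classmethod
    def from_json(cls, path) -> "StainMatrix":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["vectors"], dtype=np.float64))


@dataclass(frozen=True)
class ConcentrationMaps:
    """Per-pixel stain amounts (OD units along each stain vector) after unmixing."""

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray
    stain_matrix: StainMatrix
    pixel_size_um: float = 0.5
    reconstruction_error: float = 0.0  #: max |M^T c - od| after clamping

    @property
    def shape(self) -> tuple[int, int]:
        return self.hematoxylin.shape


def rgb_to_od(image: RGBImage, i0: float = I0_DEFAULT) -> ODImage:
    """Convert an RGB image to optical density, ``od = -log10(max(I, 1) / i0)``.

    Intensities are clamped to >= 1 before the log so the result is finite;
    with the default 8-bit white point this caps the representable OD at
    ``log10(255) ~ 2.41`` per channel.
    """
    if not i0 > 0:
        raise ValueError("i0 must be positive")
    od = -np.log10(np.maximum(image.pixels, 1.0) / i0)
    return ODImage(np.maximum(od, 0.0), i0=i0, pixel_size_um=image.pixel_size_um)


def od_to_rgb(od_image: ODImage, quantize: bool = True) -> RGBImage:
    """Invert the Beer–Lambert transform, ``I = i0 * 10**(-od)``, clamped to [0, 255].

    With ``quantize=True`` intensities are rounded to whole 8-bit levels, so the
    round trip through :func:`rgb_to_od` is the identity up to +-1 level.
    """
    intensities = np.clip(od_image.i0 * np.power(10.0, -od_image.od), 0.0, 255.0)
    if quantize:
        intensities = np.round(intensities)
    return RGBImage(intensities, pixel_size_um=od_image.pixel_size_um)


def default_hdab_matrix() -> StainMatrix:
    """The normalised Ruifrok–Johnston H-DAB stain matrix with residual completed."""
    return StainMatrix.from_stain_pair(RUIFROK_HEMATOXYLIN, RUIFROK_DAB)


def _angle_to_vector(phi: np.ndarray | float, basis: np.ndarray) -> np.ndarray:
    v = np.cos(phi) * basis[0] + np.sin(phi) * basis[1]
    if v.sum() < 0:  # stain vectors live in the non-negative orthant
        v = -v
    return v / np.linalg.norm(v)


def estimate_stain_vectors(
    od_image: ODImage,
    beta: float = 0.15,
    alpha: float = 1.0,
    min_pixels: int = 100,
) -> StainMatrix:
    """Estimate the H-DAB stain pair from the image's own OD point cloud.

    Plane/percentile (Macenko-style) estimation: pixels with total OD below
    ``beta`` are discarded as unstained; the remainder are projected onto the
    plane of the two leading principal directions of the OD cloud; the
    ``alpha``-th and ``(100 - alpha)``-th percentile extreme angles within that
    plane are taken as the two stain vectors.  Hematoxylin (a blue counterstain
    that absorbs mostly red/green) is the vector with the smaller blue-minus-red
    OD component; DAB (brown, absorbing mostly blue) is the other.  The residual
    row is completed as the normalised cross product.

    Raises
    ------
    StainEstimationError
        If fewer than ``min_pixels`` pixels exceed the OD floor, estimation is
        refused and the caller should fall back to :func:`default_hdab_matrix`.
    """
    if not 0 < alpha < 50:
        raise ValueError("alpha must be a percentile in (0, 50)")
    flat = od_image.od.reshape(-1, 3)
    stained = flat[flat.sum(axis=1) >= beta]
    if stained.shape[0] < min_pixels:
        raise StainEstimationError(
            f"only {stained.shape[0]} pixels above OD {beta}; "
            f"need >= {min_pixels} to estimate stain vectors"
        )
    # Leading plane of the (uncentred) OD cloud.
    _, _, vt = np.linalg.svd(stained, full_matrices=False)
    basis = vt[:2]
    for k in range(2):  # orient the basis toward the data
        if (stained @ basis[k]).sum() < 0:
            basis[k] = -basis[k]
    proj = stained @ basis.T
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    phi_lo = np.percentile(phi, alpha)
    phi_hi = np.percentile(phi, 100.0 - alpha)
    v1 = _angle_to_vector(phi_lo, basis)
    v2 = _angle_to_vector(phi_hi, basis)
    if np.linalg.norm(np.cross(v1, v2)) < 1e-6:
        raise StainEstimationError("estimated stain vectors are collinear; "
                                   "image lacks two distinct hues")
    # blue - red discriminates the blue counterstain from the brown chromogen
    if (v1[2] - v1[0]) <= (v2[2] - v2[0]):
        hematoxylin, dab = v1, v2
    else:
        hematoxylin, dab = v2, v1
    return StainMatrix.from_stain_pair(hematoxylin, dab)


def deconvolve(od_image: ODImage, m: StainMatrix) -> ConcentrationMaps:
    """Unmix an OD image into per-stain amounts by solving ``M^T c = od`` per pixel.

    Negative solutions (possible under noise) are clamped to zero after
    solving; the worst-case reconstruction residual of the clamped solution is
    reported on the result.
    """
    inv = np.linalg.inv(m.vectors.T)  # StainMatrix guarantees invertibility
    conc = od_image.od @ inv.T
    conc = np.maximum(conc, 0.0)
    recon = conc @ m.vectors
    err = float(np.abs(recon - od_image.od).max()) if conc.size else 0.0
    return ConcentrationMaps(
        hematoxylin=conc[..., 0],
        dab=conc[..., 1],
        residual=conc[..., 2],
        stain_matrix=m,
        pixel_size_um=od_image.pixel_size_um,
        reconstruction_error=err,
    )


def composite(
    hematoxylin: np.ndarray,
    dab: np.ndarray,
    m: StainMatrix,
    residual: np.ndarray | None = None,
    i0: float = I0_DEFAULT,
    pixel_size_um: float = 0.5,
) -> ODImage:
    """Forward-model an OD image from per-stain amount maps (inverse of deconvolve)."""
    h = np.asarray(hematoxylin, dtype=np.float64)
    d = np.asarray(dab, dtype=np.float64)
    r = np.zeros_like(h) if residual is None else np.asarray(residual, dtype=np.float64)
    conc = np.stack([h, d, r], axis=-1)
    od = conc @ m.vectors
    return ODImage(np.maximum(od, 0.0), i0=i0, pixel_size_um=pixel_size_um)


def read_rgb(path, pixel_size_um: float = 0.5) -> RGBImage:
    """Read an 8-bit RGB TIFF or PNG; an alpha channel, if present, is dropped."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return RGBImage(arr.astype(np.float64), pixel_size_um=pixel_size_um)


def write_rgb(path, image: RGBImage) -> None:
    iio.imwrite(path, image.as_uint8())


def write_concentration_tiff(path, channel: np.ndarray) -> None:
    """Write one stain-amount map as a single-channel 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(channel, dtype=np.float32))
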