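"""Spectral indices for bloom detection and assembly of the model input stack.

Works on 8-band remote-sensing reflectance (Rrs, sr^-1) frames at the GOCI
band centers 412/443/490/555/660/680/745/865 nm.  Two indices separate bloom
water from clear water:

* the red-tide index ``RI = (Rrs555 - Rrs443) / (Rrs490 - Rrs443)`` — a
  blue-green band-ratio statistic that is elevated over bloom water, and
* ``NDVI = (Rrs865 - Rrs660) / (Rrs865 + Rrs660)`` — over open water both
  classes are negative, with clear seawater more negative than bloom water.

The network consumes a 7-channel stack per frame: the six visible bands
(412–680 nm) plus NDVI; the 745/865 nm bands enter only through NDVI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical band centers (nm), in storage order.
BAND_CENTERS: tuple[int, ...] = (412, 443, 490, 555, 660, 680, 745, 865)

#: Channel layout of the model input: six visible bands then NDVI.
FEATURE_CHANNELS: tuple = (412, 443, 490, 555, 660, 680, "NDVI")

#: Default guard against near-zero index denominators (sr^-1).
DEFAULT_DENOM_EPS = 1e-9


@dataclass
class SceneFrame:
    """One timestamped H x W x 8 reflectance raster.

    `valid` marks usable pixels (False = cloud / missing); it defaults to all
    valid and propagates into every derived product.
    """

    rrs: np.ndarray
    band_centers: tuple[int, ...] = BAND_CENTERS
    timestamp: str = ""
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.rrs = np.asarray(self.rrs, dtype=np.float64)
        if self.rrs.ndim != 3 or self.rrs.shape[2] != len(self.band_centers):
            raise ValueError(
                f"rrs must be H x W x {len(self.band_centers)}, got {self.rrs.shape}")
        if tuple(self.band_centers) != BAND_CENTERS:
            raise ValueError(f"band centers must be {BAND_CENTERS} in order")
        if self.valid is None:
            self.valid = np.ones(self.rrs.shape[:2], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.rrs.shape[:2]:
                raise ValueError("valid mask shape must match raster")

    def band(self, center: int) -> np.ndarray:
        """Return the H x W slice for a band center, or raise naming the band."""
        try:
            i = self.band_centers.index(center)
        except ValueError:
            raise KeyError(f"frame is missing the {center} nm band") from None
        return self.rrs[:, :, i]


@dataclass
class IndexMap:
    """A per-pixel spectral index with a validity mask."""

    values: np.ndarray
    valid: np.ndarray
    kind: str  # "RI" or "NDVI"

    def __post_init__(self):
        if self.kind not in ("RI", "NDVI"):
            raise ValueError(f"kind must be RI or NDVI, got {self.kind!r}")


@dataclass
class FeatureStack:
    """H x W x 7 model input: visible bands 412–680 nm followed by NDVI."""

    features: np.ndarray
    valid: np.ndarray
    channel_names: tuple = FEATURE_CHANNELS

    def __post_init__(self):
        if self.features.shape[2] != 7:
            raise ValueError(f"expected 7 channels, got {self.features.shape[2]}")


def _ratio_index(num: np.ndarray, den: np.ndarray, base_valid: np.ndarray,
                 eps: float) -> tuple[np.ndarray, np.ndarray]:
    valid = base_valid & (np.abs(den) > eps) & np.isfinite(num) & np.isfinite(den)
    values = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=values, where=valid)
    return values, valid


def compute_ri(frame: SceneFrame, eps: float = DEFAULT_DENOM_EPS) -> IndexMap:
    """Red-tide index (Rrs555 - Rrs443) / (Rrs490 - Rrs443).

    Pixels whose denominator magnitude falls below `eps` are marked invalid
    rather than producing infinities.
    """
    num = frame.band(555) - frame.band(443)
    den = frame.band(490) - frame.band(443)
    values, valid = _ratio_index(num, den, frame.valid, eps)
    return IndexMap(values=values, valid=valid, kind="RI")


def compute_ndvi(frame: SceneFrame, eps: float = DEFAULT_DENOM_EPS) -> IndexMap:
    """Normalized difference of the NIR (865 nm) and red (660 nm) bands.

    Bounded in [-1, 1] for nonnegative reflectances; zero-sum pixels invalid.
    """
    nir, red = frame.band(865), frame.band(660)
    values, valid = _ratio_index(nir - red, nir + red, frame.valid, eps)
    return IndexMap(values=values, valid=valid, kind="NDVI")


def build_feature_stack(frame: SceneFrame, eps: float = DEFAULT_DENOM_EPS) -> FeatureStack:
    """Assemble the 7-channel network input for one frame.

    Channels 1–6 are Rrs at 412/443/490/555/660/680 nm; channel 7 is NDVI.
    A pixel invalid in the frame or in the NDVI denominator is invalid in the
    stack (its feature values are zero-filled and excluded downstream).
    """
    ndvi = compute_ndvi(frame, eps=eps)
    vis = np.stack([frame.band(c) for c in FEATURE_CHANNELS[:6]], axis=2)
    features = np.concatenate([vis, ndvi.values[:, :, None]], axis=2)
    valid = frame.valid & ndvi.valid
    features = np.where(valid[:, :, None], features, 0.0)
    return FeatureStack(features=features, valid=valid)


# ---------------------------------------------------------------------------
# Raster I/O (plain TIFF / NetCDF; georeferencing is out of scope)
# ---------------------------------------------------------------------------

def write_frame_geotiff(frame: SceneFrame, path) -> None:
    """Write a frame as an 8-band float32 TIFF (band order = BAND_CENTERS)."""
    import tifffile

    tifffile.imwrite(str(path), frame.rrs.astype(np.float32).transpose(2, 0, 1),
                     metadata={"band_centers_nm": list(frame.band_centers),
                               "timestamp": frame.timestamp})


def read_frame_geotiff(path, timestamp: str = "") -> SceneFrame:
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.ndim != 3 or arr.shape[0] != 8:
        raise ValueError(f"expected an 8-band raster, got shape {arr.shape}")
    return SceneFrame(rrs=arr.transpose(1, 2, 0), timestamp=timestamp)


def write_index_geotiff(index: IndexMap, path) -> None:
    """Single-band TIFF of an index map; invalid pixels written as NaN."""
    import tifffile

    out = np.where(index.valid, index.values, np.nan).astype(np.float32)
    tifffile.imwrite(str(path), out, metadata={"kind": index.kind})
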