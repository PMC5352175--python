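"""Three-material decomposition of dual-energy CT volumes.

A voxel acquired at two tube voltages is a point ``P = (HU_low, HU_high)``
in the two-energy attenuation plane.  Unenhanced tissue lies on the
piecewise-linear locus through the fixed attenuation points of air, fat and
soft tissue; iodinated contrast displaces the point along the iodine
direction ``(iodine_slope, 1)`` (iodine attenuates more strongly at the low
tube voltage, so the slope exceeds 1).  Decomposition shifts each voxel back
along that direction onto the locus: the signed travel distance, expressed
in high-kVp HU, is the iodine-attributable enhancement, and the landing
point defines the virtual-non-contrast (VNC) value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionMismatchError, InvalidConfigError

#: Default mixing weight of the low-kVp channel in the weighted-average image
#: (60% of the information from the low-kVp acquisition).
DEFAULT_WEIGHT_LOW = 0.6

#: Tolerance (HU) within which the air basis point must sit at (-1000, -1000).
AIR_TOLERANCE_HU = 50.0


@dataclass(frozen=True)
class MaterialBasis:
    """Fixed two-energy attenuation points of the basis materials.

    Attributes
    ----------
    air_pair, fat_pair, soft_pair
        ``(HU_low, HU_high)`` of pure air, fat and soft tissue.
    iodine_slope
        Low-kVp enhancement per unit of high-kVp enhancement for pure
        iodine; must exceed 1.
    iodine_unit_hu_high
        High-kVp enhancement (HU) produced by one unit of iodine
        concentration.
    """

    air_pair: tuple[float, float] = (-1000.0, -1000.0)
    fat_pair: tuple[float, float] = (-100.0, -80.0)
    soft_pair: tuple[float, float] = (60.0, 50.0)
    iodine_slope: float = 2.0
    iodine_unit_hu_high: float = 30.0

    def __post_init__(self) -> None:
        ax, ay = self.air_pair
        if abs(ax + 1000.0) > AIR_TOLERANCE_HU or abs(ay + 1000.0) > AIR_TOLERANCE_HU:
            raise InvalidConfigError(
                f"air basis point {self.air_pair} must lie within "
                f"{AIR_TOLERANCE_HU} HU of (-1000, -1000)"
            )
        if not self.iodine_slope > 1.0:
            raise InvalidConfigError(
                f"iodine_slope must exceed 1 (got {self.iodine_slope})"
            )
        a, f, s = map(np.asarray, (self.air_pair, self.fat_pair, self.soft_pair))
        u, v = f - a, s - a
        cross = u[0] * v[1] - u[1] * v[0]
        if abs(float(cross)) < 1e-9:
            raise InvalidConfigError(
                "air, fat and soft-tissue points are collinear in the "
                "two-energy plane"
            )

    @property
    def locus_points(self) -> np.ndarray:
        """Vertices of the unenhanced-tissue polyline, shape (3, 2)."""
        return np.array([self.air_pair, self.fat_pair, self.soft_pair], dtype=float)

    @property
    def iodine_direction(self) -> np.ndarray:
        """Displacement in (HU_low, HU_high) per HU of high-kVp enhancement."""
        return np.array([self.iodine_slope, 1.0])

    def to_dict(self) -> dict:
        return {
            "air_pair": list(self.air_pair),
            "fat_pair": list(self.fat_pair),
            "soft_pair": list(self.soft_pair),
            "iodine_slope": self.iodine_slope,
            "iodine_unit_hu_high": self.iodine_unit_hu_high,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialBasis":
        return cls(
            air_pair=tuple(d["air_pair"]),
            fat_pair=tuple(d["fat_pair"]),
            soft_pair=tuple(d["soft_pair"]),
            iodine_slope=float(d["iodine_slope"]),
            iodine_unit_hu_high=float(d["iodine_unit_hu_high"]),
        )


@dataclass
class DualEnergyVolume:
    """Paired low/high-kVp attenuation volumes with voxel spacing in mm."""

    low_kv: np.ndarray
    high_kv: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kvp_pair: tuple[int, int] = (80, 140)

    def __post_init__(self) -> None:
        self.low_kv = np.asarray(self.low_kv, dtype=float)
        self.high_kv = np.asarray(self.high_kv, dtype=float)
        if self.low_kv.shape != self.high_kv.shape:
            raise DimensionMismatchError(
                f"low/high channel shapes differ: "
                f"{self.low_kv.shape} vs {self.high_kv.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise InvalidConfigError(f"spacing must be positive, got {self.spacing}")


@dataclass
class DerivedChannels:
    """Channels derived from a dual-energy volume.

    ``weighted_average`` mixes the two acquisitions (approximately a 120-kVp
    image), ``vnc`` estimates unenhanced attenuation, and ``iodine`` holds
    the iodine-attributable enhancement in high-kVp HU.
    """

    weighted_average: np.ndarray
    vnc: np.ndarray
    iodine: np.ndarray
    spacing: tuple[float, float, float]
    qc: dict = field(default_factory=dict)


def weighted_average(
    volume: DualEnergyVolume, weight_low: float = DEFAULT_WEIGHT_LOW
) -> np.ndarray:
    """Voxelwise mix ``weight_low * low + (1 - weight_low) * high``."""
    if not 0.0 <= weight_low <= 1.0:
        raise InvalidConfigError(f"weight_low must be in [0, 1], got {weight_low}")
    return weight_low * volume.low_kv + (1.0 - weight_low) * volume.high_kv


def _project_onto_locus(
    low: np.ndarray, high: np.ndarray, basis: MaterialBasis
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Shift points along the iodine direction onto the tissue locus.

    Returns ``(q_low, q_high, iodine_hu, outside)`` where ``q`` is the
    landing point, ``iodine_hu`` the signed travel in high-kVp HU, and
    ``outside`` flags voxels whose intersection parameter fell outside every
    segment, so the nearest segment's line was extrapolated.
    """
    pts = basis.locus_points
    slope = basis.iodine_slope

    best_x = np.full(low.shape, np.nan)
    best_s = np.zeros(low.shape)
    best_seg = np.full(low.shape, -1, dtype=int)
    has_valid = np.zeros(low.shape, dtype=bool)

    # Exact intersection: P - x*(slope, 1) = A + s*(B - A), solved per segment.
    for k in range(2):
        a, b = pts[k], pts[k + 1]
        dl, dh = b[0] - a[0], b[1] - a[1]
        det = dl - slope * dh
        s = ((low - a[0]) - slope * (high - a[1])) / det
        x = (high - a[1]) - s * dh
        valid = (s >= -1e-9) & (s <= 1.0 + 1e-9)
        better = valid & (~has_valid | (np.abs(x) < np.abs(best_x)))
        best_x = np.where(better, x, best_x)
        best_s = np.where(better, s, best_s)
        best_seg = np.where(better, k, best_seg)
        has_valid |= valid

    outside = ~has_valid
    if np.any(outside):
        # Nearest-segment fallback: the segment line closest to the voxel is
        # extrapolated (s outside [0, 1]).  This keeps the iodine estimate
        # linear — hence unbiased under symmetric noise — for voxels beyond
        # the locus endpoints, e.g. tissue denser than the soft-tissue point.
        d = basis.iodine_direction
        dd = float(d @ d)
        best_d2 = np.full(low.shape, np.inf)
        for k in range(2):
            a, b = pts[k], pts[k + 1]
            dl, dh = b[0] - a[0], b[1] - a[1]
            det = dl - slope * dh
            s = ((low - a[0]) - slope * (high - a[1])) / det
            s_cl = np.clip(s, 0.0, 1.0)
            ql, qh = a[0] + s_cl * dl, a[1] + s_cl * dh
            x_cl = ((low - ql) * d[0] + (high - qh) * d[1]) / dd
            rl = low - ql - x_cl * d[0]
            rh = high - qh - x_cl * d[1]
            d2 = rl * rl + rh * rh
            x = (high - a[1]) - s * dh
            better = outside & (d2 < best_d2)
            best_d2 = np.where(better, d2, best_d2)
            best_x = np.where(better, x, best_x)
            best_s = np.where(better, s, best_s)
            best_seg = np.where(better, k, best_seg)

    seg = np.clip(best_seg, 0, 1)
    a = pts[seg]
    b = pts[seg + 1]
    q_low = a[..., 0] + best_s * (b[..., 0] - a[..., 0])
    q_high = a[..., 1] + best_s * (b[..., 1] - a[..., 1])
    return q_low, q_high, best_x, outside


def decompose_three_material(
    volume: DualEnergyVolume,
    basis: MaterialBasis | None = None,
    weight_low: float = DEFAULT_WEIGHT_LOW,
    clip_iodine: bool = False,
) -> DerivedChannels:
    """Decompose a dual-energy volume into weighted-average, VNC and iodine.

    The iodine channel is the signed displacement along the iodine direction
    expressed as high-kVp enhancement (HU); the VNC channel is the weighted
    average of the landing point on the air-fat-soft-tissue locus.  Negative
    iodine values (noise below the locus) are retained unless
    ``clip_iodine`` is set.  Voxels whose projection falls beyond the locus
    endpoints are projected onto the nearest segment's extension and
    counted in the QC summary.
    """
    basis = basis or MaterialBasis()
    q_low, q_high, iodine, outside = _project_onto_locus(
        volume.low_kv, volume.high_kv, basis
    )
    if clip_iodine:
        iodine = np.maximum(iodine, 0.0)
    vnc = weight_low * q_low + (1.0 - weight_low) * q_high
    wavg = weighted_average(volume, weight_low)
    qc = {
        "n_voxels": int(volume.low_kv.size),
        "n_outside_locus": int(np.count_nonzero(outside)),
        "iodine_range_hu": [float(np.min(iodine)), float(np.max(iodine))],
        "vnc_range_hu": [float(np.min(vnc)), float(np.max(vnc))],
        "clip_iodine": bool(clip_iodine),
        "weight_low": float(weight_low),
    }
    return DerivedChannels(
        weighted_average=wavg, vnc=vnc, iodine=iodine,
        spacing=volume.spacing, qc=qc,
    )


def iodine_hu_to_concentration(iodine_hu: np.ndarray, basis: MaterialBasis) -> np.ndarray:
    """Convert high-kVp iodine enhancement (HU) to concentration units."""
    return np.asarray(iodine_hu, dtype=float) / basis.iodine_unit_hu_high
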