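"""Synthetic dual-energy phantoms and per-grade feature tables.

Two generators make every downstream stage testable without scanner data:

* ``simulate_nodule_phantom`` builds a spherical part-solid lung nodule
  (solid core, ground-glass shell) on a lung-attenuation background, plants
  a known iodine-concentration map, and renders the two energy channels
  through the same linear forward model that the decomposition inverts —
  so planted iodine and unenhanced attenuation are exact ground truth.
* ``simulate_feature_table`` draws per-tumor radiomics feature vectors from
  per-grade Gaussian distributions.  Its defaults are the published
  per-grade means/SDs and the 19/65/7 grade prevalence of the reference
  cohort of 91 early-stage lung adenocarcinomas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import DEFAULT_WEIGHT_LOW, DualEnergyVolume, MaterialBasis
from .errors import InvalidCompositionError, InvalidConfigError
from .features import RoiMask

FRACTION_TOL = 1e-6


def forward_attenuation(
    fractions: tuple[float, float, float],
    iodine_concentration: float,
    basis: MaterialBasis | None = None,
) -> tuple[float, float]:
    """Two-energy attenuation of a voxel with known composition.

    ``fractions`` are the (air, fat, soft-tissue) volume fractions; the
    voxel's attenuation is their convex combination of the basis points
    plus the iodine displacement ``c * (unit * slope, unit)``.
    """
    basis = basis or MaterialBasis()
    f = np.asarray(fractions, dtype=float)
    if f.shape != (3,):
        raise InvalidCompositionError(f"expected 3 material fractions, got {f.shape}")
    if np.any(f < -FRACTION_TOL):
        raise InvalidCompositionError(f"fractions must be nonnegative: {fractions}")
    if abs(float(f.sum()) - 1.0) > FRACTION_TOL:
        raise InvalidCompositionError(
            f"fractions must sum to 1 (got {float(f.sum()):.9f})"
        )
    if iodine_concentration < 0:
        raise InvalidCompositionError("iodine concentration must be nonnegative")
    pts = basis.locus_points
    low = float(f @ pts[:, 0]) + iodine_concentration * basis.iodine_unit_hu_high * basis.iodine_slope
    high = float(f @ pts[:, 1]) + iodine_concentration * basis.iodine_unit_hu_high
    return low, high


def locus_fractions_for_vnc(
    vnc_hu: np.ndarray,
    basis: MaterialBasis | None = None,
    weight_low: float = DEFAULT_WEIGHT_LOW,
) -> np.ndarray:
    """Material fractions of the locus point whose weighted average is ``vnc_hu``.

    The weighted-average HU increases monotonically along the
    air -> fat -> soft-tissue polyline, so each attainable VNC value maps to
    a unique two-material mixture of adjacent basis materials.  Returns an
    array of (air, fat, soft) fractions with shape ``vnc_hu.shape + (3,)``.
    """
    basis = basis or MaterialBasis()
    v = np.asarray(vnc_hu, dtype=float)
    pts = basis.locus_points
    wa = weight_low * pts[:, 0] + (1.0 - weight_low) * pts[:, 1]
    if np.any(v < wa[0] - 1e-9) or np.any(v > wa[2] + 1e-9):
        raise InvalidConfigError(
            f"VNC target outside attainable locus range [{wa[0]:.1f}, {wa[2]:.1f}] HU"
        )
    out = np.zeros(v.shape + (3,))
    on_first = v <= wa[1]
    s1 = (np.clip(v, wa[0], wa[1]) - wa[0]) / (wa[1] - wa[0])
    s2 = (np.clip(v, wa[1], wa[2]) - wa[1]) / (wa[2] - wa[1])
    out[..., 0] = np.where(on_first, 1.0 - s1, 0.0)
    out[..., 1] = np.where(on_first, s1, 1.0 - s2)
    out[..., 2] = np.where(on_first, 0.0, s2)
    return out


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, composition and noise of a synthetic nodule phantom.

    The nodule is a sphere of ``nodule_radius`` mm with a solid core of
    radius ``r * (1 - ggo_fraction)**(1/3)`` (so the ground-glass shell
    holds exactly ``ggo_fraction`` of the nodule volume).  HU values are
    unenhanced (VNC) targets; iodine is added on top via
    ``iodine_map_spec = {"kind": "uniform"|"radial"|"none",
    "amplitude": <concentration units>}``.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    nodule_radius: float = 12.0
    ggo_fraction: float = 0.5
    solid_hu: float = 40.0
    ggo_hu: float = -600.0
    background_hu: float = -870.0
    iodine_map_spec: dict = field(
        default_factory=lambda: {"kind": "uniform", "amplitude": 1.0}
    )
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise InvalidConfigError(f"spacing must be positive: {self.spacing}")
        if self.nodule_radius <= 0:
            raise InvalidConfigError(
                f"nodule_radius must be positive, got {self.nodule_radius}"
            )
        if not 0.0 <= self.ggo_fraction <= 1.0:
            raise InvalidConfigError(
                f"ggo_fraction must be in [0, 1], got {self.ggo_fraction}"
            )
        if self.noise_sd < 0:
            raise InvalidConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _iodine_concentration_map(
    spec: dict, rho: np.ndarray, radius: float, inside: np.ndarray
) -> np.ndarray:
    kind = spec.get("kind", "uniform")
    amp = float(spec.get("amplitude", 0.0))
    if kind == "none" or amp == 0.0:
        return np.zeros(rho.shape)
    if kind == "uniform":
        conc = np.full(rho.shape, amp)
    elif kind == "radial":
        # Perfusion-like profile, peaking at the nodule centre.
        conc = amp * np.clip(1.0 - rho / radius, 0.0, 1.0)
    else:
        raise InvalidConfigError(f"unknown iodine map kind {kind!r}")
    return np.where(inside, conc, 0.0)


def simulate_nodule_phantom(
    config: PhantomConfig | None = None,
    basis: MaterialBasis | None = None,
) -> tuple[DualEnergyVolume, RoiMask, np.ndarray, np.ndarray]:
    """Render a dual-energy nodule phantom with known ground truth.

    Returns ``(volume, mask, gt_iodine_hu, gt_vnc_hu)``: the noisy
    dual-energy volume, the nodule mask, and the noiseless planted iodine
    enhancement (high-kVp HU) and unenhanced attenuation per voxel.
    """
    config = config or PhantomConfig()
    basis = basis or MaterialBasis()

    shape = tuple(config.grid_shape)
    spacing = tuple(float(s) for s in config.spacing)
    center = [(n - 1) / 2.0 * d for n, d in zip(shape, spacing)]
    half_extent = [(n - 1) / 2.0 * d for n, d in zip(shape, spacing)]
    if config.nodule_radius > min(half_extent):
        raise InvalidConfigError(
            f"nodule radius {config.nodule_radius} mm does not fit inside the "
            f"grid (half extents {half_extent} mm)"
        )

    axes = [
        np.arange(n) * d - c for n, d, c in zip(shape, spacing, center)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    rho = np.sqrt(xx**2 + yy**2 + zz**2)

    r = config.nodule_radius
    r_core = r * (1.0 - config.ggo_fraction) ** (1.0 / 3.0)
    inside = rho <= r
    core = rho <= r_core

    vnc = np.full(shape, config.background_hu)
    vnc[inside] = config.ggo_hu
    vnc[core] = config.solid_hu

    conc = _iodine_concentration_map(config.iodine_map_spec, rho, r, inside)

    fractions = locus_fractions_for_vnc(vnc, basis)
    pts = basis.locus_points
    low = fractions @ pts[:, 0] + conc * basis.iodine_unit_hu_high * basis.iodine_slope
    high = fractions @ pts[:, 1] + conc * basis.iodine_unit_hu_high

    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        low = low + rng.normal(0.0, config.noise_sd, shape)
        high = high + rng.normal(0.0, config.noise_sd, shape)

    volume = DualEnergyVolume(low_kv=low, high_kv=high, spacing=spacing)
    mask = RoiMask(mask=inside, spacing=spacing)
    gt_iodine_hu = conc * basis.iodine_unit_hu_high
    return volume, mask, gt_iodine_hu, vnc.astype(float)


# ---------------------------------------------------------------------------
# Per-grade feature-table simulation
# ---------------------------------------------------------------------------

#: Grade prevalence of the reference cohort (91 tumors).
DEFAULT_N_PER_GRADE = (19, 65, 7)

#: Per-grade (mean, SD) of each quantitative feature in the reference cohort
#: of early-stage lung adenocarcinomas, by tumor grade 1/2/3.  Feature names
#: follow the channel-prefix convention: no prefix = non-contrast (VNC)
#: channel, ``i-`` = iodine map, ``g-`` = gradient channel.
DEFAULT_GRADE_FEATURE_STATS: dict[str, tuple[tuple[float, float], ...]] = {
    "SUVmax": ((0.44, 0.46), (3.1, 2.67), (5.44, 3.84)),
    "Size in lung setting (mm)": ((15.58, 7.76), (25.15, 11.59), (22.57, 9.54)),
    "Size in mediastinal setting (mm)": ((2.68, 6.90), (13.57, 13.11), (19.86, 11.19)),
    "Volume (cm3)": ((2.20, 2.91), (6.88, 10.28), (7.14, 9.80)),
    "Density": ((0.41, 0.17), (0.72, 0.21), (0.82, 0.21)),
    "i-Density": ((1.17, 0.02), (1.03, 0.39), (0.83, 0.55)),
    "g-Density": ((1.88, 0.17), (1.54, 0.22), (1.43, 0.20)),
    "Mass (g)": ((0.83, 1.12), (5.23, 7.37), (6.31, 8.64)),
    "i-Mass (g)": ((2.10, 2.58), (5.38, 7.90), (7.07, 10.77)),
    "g-Mass (g)": ((3.79, 5.53), (9.39, 17.20), (10.22, 13.24)),
    "Skewness": ((0.41, 0.66), (-0.67, 1.01), (-1.17, 0.48)),
    "i-Skewness": ((1.19, 1.48), (0.29, 0.71), (-0.20, 0.40)),
    "g-Skewness": ((-0.31, 0.60), (0.52, 0.79), (0.98, 0.83)),
    "Kurtosis": ((3.37, 1.83), (4.04, 4.43), (3.36, 2.05)),
    "i-Kurtosis": ((8.17, 8.36), (4.13, 2.88), (2.88, 1.70)),
    "g-Kurtosis": ((3.15, 1.71), (3.77, 2.60), (3.85, 1.83)),
    "75th percentile (HU)": ((-496.0, 192.0), (-175.0, 210.0), (43.3, 133.0)),
    "i-75th percentile (HU)": ((66.1, 25.1), (75.7, 33.7), (50.0, 27.1)),
    "g-75th percentile (HU)": ((734.0, 119.0), (471.0, 205.0), (379.0, 218.0)),
    "97.5th percentile (HU)": ((-329.0, 171.0), (-49.3, 151.0), (67.8, 45.5)),
    "i-97.5th percentile (HU)": ((135.7, 25.2), (134.0, 58.5), (76.0, 61.5)),
    "g-97.5th percentile (HU)": ((838.0, 55.9), (687.0, 182.0), (780.0, 103.0)),
    "Uniformity": ((0.0046, 0.0034), (0.0028, 0.0019), (0.0020, 0.0031)),
    "i-Uniformity": ((0.0134, 0.0046), (0.0071, 0.0047), (0.0061, 0.0046)),
    "g-Uniformity": ((0.0057, 0.0039), (0.0031, 0.0017), (0.0031, 0.0018)),
    "Entropy": ((8.26, 0.91), (8.85, 1.26), (7.99, 2.71)),
    "i-Entropy": ((6.64, 0.49), (6.38, 2.39), (5.13, 3.42)),
    "g-Entropy": ((7.95, 0.99), (8.78, 0.68), (8.86, 0.83)),
    "g-Intensity-variability": ((7.42, 3.84), (7.97, 4.28), (9.00, 2.41)),
    "g-Size-zone-variability": ((8.97, 8.18), (15.7, 12.5), (18.4, 13.9)),
}


@dataclass
class TableSimConfig:
    """Configuration of the per-grade Gaussian feature-table simulator.

    ``feature_means``/``feature_sds`` are (3, F) arrays ordered by grade
    1/2/3; ``correlation`` is an optional (F, F) within-grade correlation
    matrix shared across grades (features are independent by default — the
    reference cohort publishes no covariances).
    """

    feature_names: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    n_per_grade: tuple[int, int, int] = DEFAULT_N_PER_GRADE
    correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        nf = len(self.feature_names)
        if self.feature_means.shape != (3, nf) or self.feature_sds.shape != (3, nf):
            raise InvalidConfigError(
                f"feature_means/sds must have shape (3, {nf}); got "
                f"{self.feature_means.shape} and {self.feature_sds.shape}"
            )
        if np.any(self.feature_sds < 0):
            raise InvalidConfigError("feature SDs must be nonnegative")
        if any(n < 0 for n in self.n_per_grade):
            raise InvalidConfigError(f"n_per_grade must be >= 0: {self.n_per_grade}")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape != (nf, nf) or not np.allclose(c, c.T, atol=1e-10):
                raise InvalidConfigError("correlation must be a symmetric (F, F) matrix")
            if np.min(np.linalg.eigvalsh(c)) < -1e-8:
                raise InvalidConfigError("correlation matrix is not positive semi-definite")
            self.correlation = c

    @classmethod
    def from_reference_cohort(
        cls,
        features: list[str] | None = None,
        n_per_grade: tuple[int, int, int] = DEFAULT_N_PER_GRADE,
        correlation: np.ndarray | None = None,
        seed: int = 0,
    ) -> "TableSimConfig":
        """Defaults taken from the reference cohort's per-grade statistics."""
        names = list(features) if features is not None else list(DEFAULT_GRADE_FEATURE_STATS)
        unknown = [n for n in names if n not in DEFAULT_GRADE_FEATURE_STATS]
        if unknown:
            raise InvalidConfigError(f"no reference statistics for features {unknown}")
        means = np.array([[DEFAULT_GRADE_FEATURE_STATS[n][g][0] for n in names] for g in range(3)])
        sds = np.array([[DEFAULT_GRADE_FEATURE_STATS[n][g][1] for n in names] for g in range(3)])
        return cls(
            feature_names=names, feature_means=means, feature_sds=sds,
            n_per_grade=n_per_grade, correlation=correlation, seed=seed,
        )


def simulate_feature_table(config: TableSimConfig | None = None) -> pd.DataFrame:
    """Draw a per-tumor feature table with known per-grade distributions.

    Returns a DataFrame with columns ``tumor_id, patient_id, grade`` followed
    by the configured features; exactly ``n_per_grade[g-1]`` rows carry grade
    ``g``.  Deterministic given ``config.seed``.
    """
    config = config or TableSimConfig.from_reference_cohort()
    rng = np.random.default_rng(config.seed)
    nf = len(config.feature_names)

    factor = None
    if config.correlation is not None:
        w, u = np.linalg.eigh(config.correlation)
        factor = u @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    rows = []
    grades = []
    for g_idx, n in enumerate(config.n_per_grade):
        z = rng.standard_normal((n, nf))
        if factor is not None:
            z = z @ factor.T
        x = config.feature_means[g_idx] + config.feature_sds[g_idx] * z
        rows.append(x)
        grades.extend([g_idx + 1] * n)

    x_all = np.vstack(rows) if rows else np.empty((0, nf))
    n_total = x_all.shape[0]
    df = pd.DataFrame(x_all, columns=config.feature_names)
    df.insert(0, "grade", np.asarray(grades, dtype=int))
    df.insert(0, "patient_id", [f"P{i + 1:03d}" for i in range(n_total)])
    df.insert(0, "tumor_id", [f"T{i + 1:03d}" for i in range(n_total)])
    return df
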