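"""24-2 visual-field grid geometry and the anatomical spatial prior.

The 24-2 test pattern of standard automated perimetry samples differential
light sensitivity (DLS) on a 6-degree grid covering the central visual
field: 54 points, of which the two falling on the physiological blind spot
are excluded, leaving M = 52 analysis locations.

Spatial correlation between locations is anatomical rather than purely
geometric: retinal nerve-fibre bundles sweep arcuate paths into the optic
nerve head (ONH), so two locations threaded by the same bundle co-vary even
when they are not close on the grid, while the horizontal raphe prevents
any correlation between the superior and inferior hemifields.  The prior
correlation between locations p and q is modelled with a product
squared-exponential kernel in Euclidean grid distance d_pq (degrees) and
absolute fibre entry-angle difference theta_pq (degrees),

    Psi_pq = exp(-d_pq^2 / (2 sigma_d^2) - theta_pq^2 / (2 sigma_theta^2))

for same-hemifield pairs and Psi_pq = 0 across the midline.  Slope and
intercept priors are multivariate normal with covariances a*Psi and b*Psi.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VFLocation",
    "VisualFieldGrid",
    "SpatialPrior",
    "build_grid",
    "spatial_correlation",
    "build_spatial_prior",
    "grid_242_coordinates",
    "synthetic_fibre_angle",
]

# Blind spot of the right eye sits ~15 deg temporal to fixation; the two
# 24-2 points at (15, +-3) are excluded from analysis.
BLIND_SPOT_XY = ((15, 3), (15, -3))
GRID_SPACING_DEG = 6.0
ONH_X_DEG = 15.0  # optic nerve head position on the horizontal meridian

# Row layout of the 24-2 pattern (right-eye orientation, x>0 temporal):
# the two central rows extend one extra step nasally (x = -27).
_ROWS = {
    21: range(-9, 10, 6),
    15: range(-15, 16, 6),
    9: range(-21, 22, 6),
    3: range(-27, 22, 6),
}


def grid_242_coordinates(include_blind_spot: bool = False) -> list[tuple[int, int]]:
    """Ordered (x, y) coordinates of the 24-2 pattern, right-eye orientation.

    Row-major from the superior edge down, x ascending; 54 points with the
    blind spot, 52 without.
    """
    coords: list[tuple[int, int]] = []
    for y in sorted(_ROWS, reverse=True):
        coords.extend((x, y) for x in _ROWS[y])
    for y in sorted(_ROWS):
        coords.extend((x, -y) for x in _ROWS[y])
    if not include_blind_spot:
        coords = [c for c in coords if c not in BLIND_SPOT_XY]
    return coords


def synthetic_fibre_angle(x_deg: float, y_deg: float) -> float:
    """Approximate nerve-fibre entry angle into the ONH, degrees.

    Synthetic stand-in for a measured entry-angle map: the angle of the
    straight path from the ONH (at (+15, 0) in right-eye field coordinates)
    to the location, with a mild arcuate correction for paths that would
    cross the papillomacular axis.  Convention: 0 deg = temporal ONH pole,
    positive = superior field, range (-180, 180].
    """
    psi = math.degrees(math.atan2(y_deg, x_deg - ONH_X_DEG))
    # fibres cannot cross the fovea: paths through the central 5 degrees
    # are bent around it, pushing the entry point poleward
    if 0.0 < x_deg < ONH_X_DEG and abs(y_deg) <= 5.0:
        bend = 15.0 * (1.0 - abs(y_deg) / 5.0)
        psi += math.copysign(bend, y_deg)
    return psi


@dataclass(frozen=True)
class VFLocation:
    """One analysed 24-2 test location."""

    index: int
    x_deg: float
    y_deg: float
    hemifield: str  # "superior" | "inferior"
    fibre_angle_deg: float

    def __post_init__(self) -> None:
        expected = "superior" if self.y_deg > 0 else "inferior"
        if self.hemifield != expected:
            raise ValueError(
                f"location {self.index}: hemifield {self.hemifield!r} "
                f"inconsistent with y={self.y_deg}"
            )


@dataclass(frozen=True)
class VisualFieldGrid:
    """The ordered analysis locations and their 4-neighbour adjacency."""

    locations: tuple[VFLocation, ...]
    eye_side: str = "right"
    adjacency: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        m = len(self.locations)
        adj = np.zeros((m, m), dtype=bool)
        for i in range(m):
            for j in range(i + 1, m):
                p, q = self.locations[i], self.locations[j]
                d = math.hypot(p.x_deg - q.x_deg, p.y_deg - q.y_deg)
                if abs(d - GRID_SPACING_DEG) < 1e-9:
                    adj[i, j] = adj[j, i] = True
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def hemifields(self) -> np.ndarray:
        return np.array([loc.hemifield for loc in self.locations])

    def coordinates(self) -> np.ndarray:
        return np.array([(l.x_deg, l.y_deg) for l in self.locations])

    def fibre_angles(self) -> np.ndarray:
        return np.array([l.fibre_angle_deg for l in self.locations])


def load_fibre_angle_map(path=None) -> dict[tuple[float, float], float]:
    """Read the per-location fibre-angle table (right-eye coordinates).

    CSV columns: x_deg, y_deg, fibre_angle_deg.  The packaged default is a
    synthetic approximation (see :func:`synthetic_fibre_angle`).
    """
    if path is None:
        ref = importlib.resources.files("answers.data").joinpath(
            "fibre_angles_24_2_synthetic.csv"
        )
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"x_deg", "y_deg", "fibre_angle_deg"}
    if not required.issubset(df.columns):
        raise ValueError(f"fibre-angle map needs columns {sorted(required)}")
    return {
        (float(r.x_deg), float(r.y_deg)): float(r.fibre_angle_deg)
        for r in df.itertuples()
    }


def build_grid(eye_side: str = "right", fibre_angle_map=None) -> VisualFieldGrid:
    """Construct the 52-location analysis grid for one eye.

    Coordinates are stored in the eye's own field-of-view convention; the
    left eye is the mirror image of the right (x negated), with fibre
    angles looked up on the right-eye map after mirroring.

    Parameters
    ----------
    eye_side : {"right", "left"}
    fibre_angle_map : optional mapping (x_deg, y_deg) -> angle in right-eye
        coordinates; defaults to the packaged synthetic table.
    """
    if eye_side not in ("right", "left"):
        raise ValueError(f"eye_side must be 'right' or 'left', got {eye_side!r}")
    if fibre_angle_map is None:
        fibre_angle_map = load_fibre_angle_map()
    locations = []
    for idx, (x, y) in enumerate(grid_242_coordinates()):
        key = (float(x), float(y))
        if key not in fibre_angle_map:
            raise KeyError(
                f"fibre-angle map has no entry for 24-2 location {key}"
            )
        angle = fibre_angle_map[key]
        x_eye = -x if eye_side == "left" else x
        locations.append(
            VFLocation(
                index=idx,
                x_deg=float(x_eye),
                y_deg=float(y),
                hemifield="superior" if y > 0 else "inferior",
                fibre_angle_deg=angle,
            )
        )
    return VisualFieldGrid(locations=tuple(locations), eye_side=eye_side)


# ---------------------------------------------------------------------------
# Spatial prior
# ---------------------------------------------------------------------------

def spatial_correlation(
    p: VFLocation,
    q: VFLocation,
    sigma_d: float,
    sigma_theta: float,
    kernel: str = "squared_exponential",
) -> float:
    """Prior correlation between two locations, in [0, 1].

    Zero across the horizontal midline (the nerve-fibre raphe); otherwise a
    kernel in grid distance and fibre entry-angle difference.
    """
    if sigma_d <= 0 or sigma_theta <= 0:
        raise ValueError("sigma_d and sigma_theta must be positive")
    if p.index == q.index:
        return 1.0
    if p.hemifield != q.hemifield:
        return 0.0
    d = math.hypot(p.x_deg - q.x_deg, p.y_deg - q.y_deg)
    theta = abs(p.fibre_angle_deg - q.fibre_angle_deg)
    if kernel == "squared_exponential":
        return math.exp(-(d * d) / (2 * sigma_d**2) - (theta * theta) / (2 * sigma_theta**2))
    if kernel == "exponential":
        return math.exp(-d / sigma_d - theta / sigma_theta)
    raise ValueError(f"unknown kernel {kernel!r}")


@dataclass(frozen=True)
class SpatialPrior:
    """Multivariate-normal priors over per-location slopes and intercepts.

    psi is the unscaled correlation matrix; the slope prior is
    N(mu_slope * 1, a * psi) and the intercept prior N(mu_intercept * 1,
    b * psi).  Defaults make both priors weakly informative: prior SDs of
    10 dB/year and 10 dB (a = b = 100) and an intercept mean in the middle
    of the 0-35 dB measurement range.
    """

    psi: np.ndarray
    a: float = 100.0
    b: float = 100.0
    mu_slope: float = 0.0
    mu_intercept: float = 17.5
    sigma_d: float = 6.0
    sigma_theta: float = 15.0
    jitter: float = 1e-8

    @property
    def n_locations(self) -> int:
        return self.psi.shape[0]

    @property
    def slope_cov(self) -> np.ndarray:
        return self.a * self.psi

    @property
    def intercept_cov(self) -> np.ndarray:
        return self.b * self.psi

    def diagonalized(self) -> "SpatialPrior":
        """Prior with off-diagonal correlation removed (spatial term off)."""
        return SpatialPrior(
            psi=np.eye(self.n_locations),
            a=self.a,
            b=self.b,
            mu_slope=self.mu_slope,
            mu_intercept=self.mu_intercept,
            sigma_d=self.sigma_d,
            sigma_theta=self.sigma_theta,
            jitter=self.jitter,
        )


def build_spatial_prior(
    grid: VisualFieldGrid,
    sigma_d: float = 6.0,
    sigma_theta: float = 15.0,
    slope_sd: float = 10.0,
    intercept_sd: float = 10.0,
    mu_slope: float = 0.0,
    mu_intercept: float = 17.5,
    kernel: str = "squared_exponential",
    jitter: float = 1e-8,
) -> SpatialPrior:
    """Assemble the spatial prior for a grid.

    sigma_d defaults to the 6-degree spacing between neighbouring points;
    sigma_theta to 15 degrees of fibre entry-angle difference.  The scale
    factors are slope_sd**2 and intercept_sd**2 so that the marginal prior
    SD at every location equals the requested values (psi has unit
    diagonal).  A small diagonal jitter guards positive definiteness: the
    kernel over an irregular angle map is not guaranteed PSD.
    """
    m = grid.n_locations
    psi = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            c = spatial_correlation(
                grid.locations[i], grid.locations[j], sigma_d, sigma_theta, kernel
            )
            psi[i, j] = psi[j, i] = c
    eigmin = float(np.linalg.eigvalsh(psi).min())
    psi_j = psi + jitter * np.eye(m)
    if np.linalg.eigvalsh(psi_j).min() <= 0:
        raise np.linalg.LinAlgError(
            f"spatial correlation matrix not PSD after jitter "
            f"(min eigenvalue {eigmin:.3e}, cond {np.linalg.cond(psi):.3e})"
        )
    return SpatialPrior(
        psi=psi_j,
        a=slope_sd**2,
        b=intercept_sd**2,
        mu_slope=mu_slope,
        mu_intercept=mu_intercept,
        sigma_d=sigma_d,
        sigma_theta=sigma_theta,
        jitter=jitter,
    )
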