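"""MIRD-style cell geometry: nested spheres, 9-cell grid, gold configurations.

The model is a concentric-sphere cell (nucleus radius 5 um, cell radius
12.5 um) at the centre of a planar 3x3 grid of touching cells immersed in
a 200 uL cube of culture medium.  Gold is represented either as a single
equivalent sphere at the cell centre (``central_sphere``) or as a thin
shell around the nucleus (``nucleus_shell``); both mimic a fixed number
of nanoparticles by volume equivalence.  In the ``nucleus_shell`` mode
six contiguous 10 nm water scoring shells cover 0-60 nm outside the gold
surface; they exist at identical radii whether the shell material is
gold or water so dose-enhancement ratios compare like with like.

All lengths are micrometres internally; densities g/cm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

WATER_DENSITY = 1.0     # g/cm3
GOLD_DENSITY = 19.3     # g/cm3

N_SCORING_SHELLS = 6
SCORING_SHELL_THICKNESS_UM = 0.010  # 10 nm


def equivalent_gold_sphere_radius(count: float, np_diameter_nm: float) -> float:
    """Radius (um) of a single sphere holding the gold volume of ``count``
    nanoparticles of the given diameter (nm)."""
    if count <= 0 or np_diameter_nm <= 0:
        raise ValueError("count and diameter must be > 0")
    return count ** (1.0 / 3.0) * (np_diameter_nm / 2.0) * 1e-3


def gold_shell_thickness(count: float, np_diameter_nm: float,
                         inner_radius_um: float, exact: bool = False) -> float:
    """Thickness (nm) of a shell of inner radius ``inner_radius_um`` whose
    volume equals the total nanoparticle gold volume.

    The default thin-shell formula ``t = V / (4 pi r^2)`` is adequate when
    t << r; ``exact=True`` solves ``(r+t)^3 - r^3 = 3V/(4 pi)`` instead.
    """
    if count == 0:
        return 0.0
    if count < 0 or np_diameter_nm <= 0 or inner_radius_um <= 0:
        raise ValueError("inputs must be positive (count may be 0)")
    v_nm3 = count * (math.pi / 6.0) * np_diameter_nm ** 3
    r_nm = inner_radius_um * 1e3
    if not exact:
        return v_nm3 / (4.0 * math.pi * r_nm ** 2)
    return (r_nm ** 3 + 3.0 * v_nm3 / (4.0 * math.pi)) ** (1.0 / 3.0) - r_nm


@dataclass(frozen=True)
class GoldConfig:
    """Gold arrangement in the cell: none, central sphere, or nucleus shell."""

    mode: str = "none"                      # none | central_sphere | nucleus_shell
    count: float | None = None              # number of nanoparticles
    np_diameter_nm: float | None = None
    sphere_radius_um: float | None = None   # central_sphere mode
    shell_thickness_nm: float | None = None  # nucleus_shell mode

    def __post_init__(self) -> None:
        if self.mode not in ("none", "central_sphere", "nucleus_shell"):
            raise ValueError(f"unknown gold mode {self.mode!r}")

    @classmethod
    def from_nanoparticles(cls, mode: str, count: float, np_diameter_nm: float,
                           nucleus_radius_um: float = 5.0) -> "GoldConfig":
        """Derive the solid's dimensions from the nanoparticle inventory."""
        if mode == "central_sphere":
            r = equivalent_gold_sphere_radius(count, np_diameter_nm)
            return cls(mode, count, np_diameter_nm, sphere_radius_um=r)
        if mode == "nucleus_shell":
            t = gold_shell_thickness(count, np_diameter_nm, nucleus_radius_um)
            return cls(mode, count, np_diameter_nm, shell_thickness_nm=t)
        return cls("none")


@dataclass(frozen=True)
class CellModel:
    """The 9-cell model: central emitting cell, neighbours, medium, gold.

    ``gold_material`` lets the gold region be filled with water at the same
    radii (the "without gold" arm of dose-enhancement pairs).
    ``scoring_shells`` adds the six nanometric shells outside the gold shell
    (implied by ``nucleus_shell`` mode).
    """

    nucleus_radius_um: float = 5.0
    cell_radius_um: float = 12.5
    medium_volume_uL: float = 200.0
    gold: GoldConfig = field(default_factory=GoldConfig)
    gold_material: str = "gold"             # "gold" | "water" (null arm)
    grid: tuple[int, int] = (3, 3)
    scoring_shells: bool | None = None      # None -> auto from gold mode

    def __post_init__(self) -> None:
        if not 0 < self.nucleus_radius_um < self.cell_radius_um:
            raise ValueError("need 0 < nucleus radius < cell radius")
        if self.medium_volume_uL <= 0:
            raise ValueError("medium volume must be > 0")
        if self.gold.mode == "central_sphere":
            if not self.gold.sphere_radius_um or \
                    self.gold.sphere_radius_um >= self.nucleus_radius_um:
                raise ValueError("central gold sphere must fit in the nucleus")
        if self.gold.mode == "nucleus_shell" and not self.gold.shell_thickness_nm:
            raise ValueError("nucleus_shell mode needs a shell thickness")
        object.__setattr__(
            self, "scoring_shells",
            self.gold.mode == "nucleus_shell" if self.scoring_shells is None
            else self.scoring_shells)
        if self.scoring_shells and self.gold.mode != "nucleus_shell":
            raise ValueError("scoring shells require nucleus_shell gold mode")

    # -------------------------------------------------------------- layout
    @property
    def medium_half_side_um(self) -> float:
        # 1 uL = 1e9 um^3
        return (self.medium_volume_uL * 1e9) ** (1.0 / 3.0) / 2.0

    @property
    def neighbor_centers(self) -> np.ndarray:
        """Centres of the non-central cells of the touching planar grid."""
        cached = self.__dict__.get("_neighbor_centers")
        if cached is not None:
            return cached
        nx, ny = self.grid
        pitch = 2.0 * self.cell_radius_um
        offs = [(i - (nx - 1) / 2, j - (ny - 1) / 2)
                for i in range(nx) for j in range(ny)]
        pts = [(pitch * a, pitch * b, 0.0) for a, b in offs if (a, b) != (0, 0)]
        arr = np.asarray(pts, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "_neighbor_centers", arr)
        return arr

    def shell_radii(self) -> list[tuple[str, float]]:
        """Ordered (region, outer radius um) for the central concentric family."""
        cached = self.__dict__.get("_shell_radii")
        if cached is not None:
            return cached
        out: list[tuple[str, float]] = []
        r_n = self.nucleus_radius_um
        if self.gold.mode == "central_sphere":
            out.append(("gold", self.gold.sphere_radius_um))
        out.append(("nucleus", r_n))
        r = r_n
        if self.gold.mode == "nucleus_shell":
            r += self.gold.shell_thickness_nm * 1e-3
            out.append(("gold", r))
        if self.scoring_shells:
            for i in range(1, N_SCORING_SHELLS + 1):
                r += SCORING_SHELL_THICKNESS_UM
                out.append((f"shell_{i}", r))
        if r >= self.cell_radius_um:
            raise ValueError("scoring shells extend beyond the cytoplasm")
        out.append(("cytoplasm", self.cell_radius_um))
        object.__setattr__(self, "_shell_radii", out)
        object.__setattr__(self, "_radii_list", [x for _, x in out])
        object.__setattr__(self, "_names_arr", [n for n, _ in out])
        return out

    @property
    def region_names(self) -> list[str]:
        return [name for name, _ in self.shell_radii()] + ["neighbor", "medium"]

    #: regions aggregated as the whole central cell
    @property
    def cell_regions(self) -> list[str]:
        return [name for name, _ in self.shell_radii()]

    def material_of(self, region: str) -> str:
        if region == "gold":
            return self.gold_material
        return "water"

    def density_of(self, region: str) -> float:
        return GOLD_DENSITY if self.material_of(region) == "gold" else WATER_DENSITY

    # -------------------------------------------------------------- volumes
    def region_volume_um3(self, region: str) -> float:
        radii = self.shell_radii()
        names = [n for n, _ in radii]
        sphere = lambda r: 4.0 / 3.0 * math.pi * r ** 3
        if region in names:
            i = names.index(region)
            outer = radii[i][1]
            inner = radii[i - 1][1] if i > 0 else 0.0
            return sphere(outer) - sphere(inner)
        if region == "cell":
            return sphere(self.cell_radius_um)
        if region == "neighbor":
            return len(self.neighbor_centers) * sphere(self.cell_radius_um)
        if region == "medium":
            n_cells = 1 + len(self.neighbor_centers)
            return self.medium_volume_uL * 1e9 - n_cells * sphere(self.cell_radius_um)
        raise KeyError(f"unknown region {region!r}; "
                       f"valid: {self.region_names + ['cell']}")

    def region_mass_kg(self, region: str) -> float:
        """Mass of a region: volume x material density."""
        if region in ("cell", "nucleus", "cytoplasm", "neighbor", "medium") \
                or region.startswith("shell_"):
            rho = WATER_DENSITY
            if region == "cell" and self.gold.mode != "none" \
                    and self.gold_material == "gold":
                # water cell volume plus the excess mass of the gold region
                v_au = self.region_volume_um3("gold")
                return (self.region_volume_um3("cell") * WATER_DENSITY
                        + v_au * (GOLD_DENSITY - WATER_DENSITY)) * 1e-15
        elif region == "gold":
            rho = self.density_of("gold")
        else:
            raise KeyError(f"unknown region {region!r}")
        # um^3 x g/cm^3 -> kg:  1 um^3 = 1e-12 cm^3;  g -> kg: 1e-3
        return self.region_volume_um3(region) * rho * 1e-15

    # -------------------------------------------------------------- sampling
    def sample_point(self, region: str, rng: np.random.Generator,
                     n: int = 1) -> np.ndarray:
        """Uniform points in a region's volume, shape (n, 3), um."""
        radii = self.shell_radii()
        names = [n_ for n_, _ in radii]
        if region in names:
            i = names.index(region)
            outer = radii[i][1]
            inner = radii[i - 1][1] if i > 0 else 0.0
        elif region == "cell":
            inner, outer = 0.0, self.cell_radius_um
        elif region == "medium":
            return self._sample_medium(rng, n)
        else:
            raise KeyError(f"cannot sample region {region!r}")
        if outer <= inner and outer == inner:
            raise ValueError(f"region {region!r} has zero volume")
        u = rng.random(n)
        r = (inner ** 3 + u * (outer ** 3 - inner ** 3)) ** (1.0 / 3.0)
        return r[:, None] * _isotropic(rng, n)

    def _sample_medium(self, rng: np.random.Generator, n: int) -> np.ndarray:
        half = self.medium_half_side_um
        pts = np.empty((n, 3))
        got = 0
        centers = np.vstack([[0.0, 0.0, 0.0], self.neighbor_centers])
        while got < n:
            cand = rng.uniform(-half, half, size=(2 * (n - got) + 16, 3))
            d2 = ((cand[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            ok = cand[(d2 > self.cell_radius_um ** 2).all(axis=1)]
            take = min(len(ok), n - got)
            pts[got:got + take] = ok[:take]
            got += take
        return pts

    # -------------------------------------------------------------- tracing
    def locate(self, point) -> str:
        """Region id containing a point (boundary points go outward)."""
        self.shell_radii()
        x, y, z = float(point[0]), float(point[1]), float(point[2])
        r2 = x * x + y * y + z * z
        names = self.__dict__["_names_arr"]
        for i, rad in enumerate(self.__dict__["_radii_list"]):
            if r2 < rad * rad:
                return names[i]
        rc2 = self.cell_radius_um ** 2
        for cx, cy, cz in self.neighbor_centers:
            dx, dy, dz = x - cx, y - cy, z - cz
            if dx * dx + dy * dy + dz * dz < rc2:
                return "neighbor"
        half = self.medium_half_side_um
        if abs(x) < half and abs(y) < half and abs(z) < half:
            return "medium"
        return "outside"

    def segment_path(self, origin: np.ndarray, direction: np.ndarray,
                     max_length: float) -> list[tuple[str, float]]:
        """Trace a ray into ordered ``(region, chord length um)`` segments.

        Segments are contiguous from the origin; their lengths sum to
        ``max_length`` unless the ray leaves the medium cube first.
        """
        self.shell_radii()
        ox, oy, oz = float(origin[0]), float(origin[1]), float(origin[2])
        dx, dy, dz = float(direction[0]), float(direction[1]), float(direction[2])
        norm2 = dx * dx + dy * dy + dz * dz
        if abs(norm2 - 1.0) > 2e-9:
            raise ValueError("direction must be a unit vector")

        ts: list[float] = []
        b = ox * dx + oy * dy + oz * dz
        c0 = ox * ox + oy * oy + oz * oz
        for radius in self.__dict__["_radii_list"]:
            disc = b * b - (c0 - radius * radius)
            if disc > 0:
                sq = math.sqrt(disc)
                t = -b - sq
                if 1e-12 < t < max_length:
                    ts.append(t)
                t = -b + sq
                if 1e-12 < t < max_length:
                    ts.append(t)
        # neighbour spheres matter only if the ray can leave the central cell
        rc = self.cell_radius_um
        if math.sqrt(c0) + max_length > rc:
            rc2 = rc * rc
            for cx, cy, cz in self.neighbor_centers:
                px, py, pz = ox - cx, oy - cy, oz - cz
                bb = px * dx + py * dy + pz * dz
                disc = bb * bb - (px * px + py * py + pz * pz - rc2)
                if disc > 0:
                    sq = math.sqrt(disc)
                    t = -bb - sq
                    if 1e-12 < t < max_length:
                        ts.append(t)
                    t = -bb + sq
                    if 1e-12 < t < max_length:
                        ts.append(t)
        # medium cube exit
        half = self.medium_half_side_um
        t_exit = max_length
        for o, d in ((ox, dx), (oy, dy), (oz, dz)):
            if d != 0.0:
                t = ((half if d > 0 else -half) - o) / d
                if 1e-12 < t < t_exit:
                    t_exit = t
        ts = sorted({t for t in ts if t < t_exit} | {t_exit})

        segments: list[tuple[str, float]] = []
        t_prev = 0.0
        last = None
        for t in ts:
            tm = (t_prev + t) / 2.0
            region = self.locate((ox + dx * tm, oy + dy * tm, oz + dz * tm))
            length = t - t_prev
            if last == region:
                segments[-1] = (region, segments[-1][1] + length)
            elif length > 0:
                segments.append((region, length))
                last = region
            t_prev = t
        return segments

    # -------------------------------------------------------------- variants
    def without_gold(self) -> "CellModel":
        """Same radii with the gold region filled with water."""
        return replace(self, gold_material="water")

    def describe(self) -> "pd.DataFrame":  # noqa: F821 - forward ref
        """Derived quantities (volumes, masses) as a tidy table."""
        import pandas as pd

        rows = []
        for region in self.cell_regions + ["cell", "neighbor", "medium"]:
            rows.append({
                "region": region,
                "material": self.material_of(region) if region not in
                ("cell", "neighbor", "medium") else "water",
                "volume_um3": self.region_volume_um3(region),
                "mass_kg": self.region_mass_kg(region),
            })
        return pd.DataFrame(rows)


def _isotropic(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """n isotropic unit vectors, shape (n, 3)."""
    mu = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    s = np.sqrt(1.0 - mu * mu)
    return np.stack([s * np.cos(phi), s * np.sin(phi), mu], axis=1)


def standard_gold_shell_model(count: float = 2.83e8, np_diameter_nm: float = 4.0,
                           gold_material: str = "gold") -> CellModel:
    """The nucleus-shell irradiation setup: 30 nm gold shell + scoring shells."""
    return CellModel(gold=GoldConfig.from_nanoparticles(
        "nucleus_shell", count, np_diameter_nm), gold_material=gold_material)


def standard_central_sphere_model(count: float = 2.83e8,
                               np_diameter_nm: float = 4.0) -> CellModel:
    """The central-sphere irradiation setup: 1.3 um equivalent gold sphere."""
    return CellModel(gold=GoldConfig.from_nanoparticles(
        "central_sphere", count, np_diameter_nm))
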