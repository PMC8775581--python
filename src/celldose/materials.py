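"""Material physics data: stopping powers, photon attenuation, relaxation.

Tables are bundled CSVs on log grids (see ``scripts/make_fixtures.py`` for
their provenance) and interpolated log-log.  Each material carries, besides
the tables, the simplified atomic-relaxation data used on photoelectric
absorption: the absorption-edge energies, fluorescence yields and mean
fluorescence line energies, plus the fractions into which the remaining
binding energy is split as an Auger electron burst.

The CSDA range and its inverse are precomputed on a fine log grid at load
time so electron stepping is two table lookups per segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

#: energy below which residual electron energy is deposited on the spot
RANGE_FLOOR_KEV = 0.1


@dataclass(frozen=True)
class Edge:
    """One absorption edge: threshold, fluorescence yield and line energy."""

    energy_keV: float
    fluorescence_yield: float
    fluorescence_energy_keV: float


# simplified relaxation data; gold M/L/K, water O-K treated as local deposit
RELAXATION = {
    "gold": [Edge(80.7, 0.96, 68.8), Edge(11.92, 0.35, 9.7), Edge(2.21, 0.03, 2.1)],
    "water": [],
}

#: binding energy split into an Auger burst (fractions of remaining energy).
#: A gold M-vacancy relaxes predominantly by a single M-N,N Auger electron
#: (the N-shell bindings are only ~80 eV, so it carries nearly the full
#: 2.2 keV), followed by a soft N-shell cascade.
AUGER_BURST_FRACTIONS = (0.92, 0.04, 0.04)


class MaterialTable:
    """Interpolable electron/photon data for one material."""

    def __init__(self, name: str, density_g_cm3: float,
                 e_grid_keV: np.ndarray, stopping_keV_per_um: np.ndarray,
                 p_grid_keV: np.ndarray, mu_pe_per_um: np.ndarray,
                 mu_compton_per_um: np.ndarray):
        if np.any(stopping_keV_per_um <= 0) or np.any(mu_pe_per_um < 0):
            raise ValueError(f"{name}: non-positive table values")
        self.name = name
        self.density_g_cm3 = density_g_cm3
        self.edges = RELAXATION.get(name, [])
        self._log_e = np.log(e_grid_keV)
        self._log_s = np.log(stopping_keV_per_um)
        self._log_p = np.log(p_grid_keV)
        with np.errstate(divide="ignore"):
            self._log_mu_pe = np.log(mu_pe_per_um)
            self._log_mu_c = np.log(mu_compton_per_um)
            self._log_mu_t = np.log(mu_pe_per_um + mu_compton_per_um)
        self.e_min, self.e_max = float(e_grid_keV[0]), float(e_grid_keV[-1])
        self.p_min, self.p_max = float(p_grid_keV[0]), float(p_grid_keV[-1])
        self._build_range_table()

    # ------------------------------------------------------------ electrons
    def stopping(self, energy_keV: float) -> float:
        """Collision stopping power, keV/um (log-log interpolated)."""
        return float(np.exp(np.interp(np.log(energy_keV),
                                      self._log_e, self._log_s)))

    def _build_range_table(self) -> None:
        g = np.logspace(np.log10(RANGE_FLOOR_KEV), np.log10(self.e_max), 4000)
        s = np.exp(np.interp(np.log(g), self._log_e, self._log_s))
        inv = 1.0 / s
        dr = np.diff(g) * (inv[1:] + inv[:-1]) / 2.0
        r = np.concatenate([[0.0], np.cumsum(dr)])
        self._range_e = g
        self._range_r = r

    def csda_range(self, energy_keV: float,
                   cutoff_keV: float = RANGE_FLOOR_KEV) -> float:
        """CSDA range (um) from ``cutoff_keV`` up to ``energy_keV``."""
        if not (self.e_min <= energy_keV <= self.e_max):
            raise ValueError(
                f"{energy_keV} keV outside {self.name} table "
                f"[{self.e_min}, {self.e_max}] keV")
        r_e = float(np.interp(energy_keV, self._range_e, self._range_r))
        if cutoff_keV <= RANGE_FLOOR_KEV:
            return r_e
        return r_e - float(np.interp(cutoff_keV, self._range_e, self._range_r))

    def energy_at_range(self, range_um: float) -> float:
        """Inverse of ``csda_range``: energy whose residual range is given."""
        return float(np.interp(range_um, self._range_r, self._range_e))

    # -------------------------------------------------------------- photons
    def mu_total(self, energy_keV: float) -> float:
        return float(np.exp(np.interp(np.log(energy_keV),
                                      self._log_p, self._log_mu_t)))

    def mu_photoelectric(self, energy_keV: float) -> float:
        return float(np.exp(np.interp(np.log(energy_keV),
                                      self._log_p, self._log_mu_pe)))

    def mu_compton(self, energy_keV: float) -> float:
        return float(np.exp(np.interp(np.log(energy_keV),
                                      self._log_p, self._log_mu_c)))

    def binding_edge(self, photon_keV: float) -> Edge | None:
        """Deepest accessible edge for a photon, or None (outer shells only)."""
        for edge in self.edges:  # listed deepest first
            if photon_keV >= edge.energy_keV:
                return edge
        return None


def _read_csv(path: Path) -> dict[str, np.ndarray]:
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    return {k: df[k].to_numpy() for k in df.columns}


def load_material(name: str, directory: str | Path | None = None) -> MaterialTable:
    """Load a bundled (or external) material table pair by name."""
    if directory is None:
        with resources.as_file(resources.files("celldose.data")
                               / f"{name}_electrons.csv") as p:
            return load_material(name, p.parent)
    directory = Path(directory)
    e = _read_csv(directory / f"{name}_electrons.csv")
    p = _read_csv(directory / f"{name}_photons.csv")
    density = _density_from_header(directory / f"{name}_electrons.csv")
    return MaterialTable(name, density,
                         e["energy_keV"], e["stopping_keV_per_um"],
                         p["energy_keV"], p["mu_pe_per_um"],
                         p["mu_compton_per_um"])


def _density_from_header(path: Path) -> float:
    with open(path) as fh:
        for line in fh:
            if line.startswith("# density_g_cm3:"):
                return float(line.split(":")[1])
            if not line.startswith("#"):
                break
    raise ValueError(f"{path}: missing '# density_g_cm3:' header")


_CACHE: dict[str, MaterialTable] = {}


def builtin(name: str) -> MaterialTable:
    """Cached access to the bundled water/gold tables."""
    if name not in _CACHE:
        _CACHE[name] = load_material(name)
    return _CACHE[name]


def csda_range(energy_keV: float, material: MaterialTable,
               cutoff_keV: float = RANGE_FLOOR_KEV) -> float:
    """Module-level convenience wrapper for ``MaterialTable.csda_range``."""
    return material.csda_range(energy_keV, cutoff_keV)
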