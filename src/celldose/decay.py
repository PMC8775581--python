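"""Per-decay emission inventory of a radionuclide and its sampling.

A radionuclide's source term is described by a continuous beta spectrum
(sampled event-by-event by inverse-CDF) plus a list of discrete lines:
the full Auger/Coster-Kronig electron list and single average-energy
lines for internal-conversion electrons, X-rays and gammas.  The bundled
Lu-177 inventory (``celldose/data``) carries a 3-branch allowed-shape
beta spectrum with mean energy ~133 keV, physical half-life 6.647 d and
a 2.5 keV average X-ray line.

File format
-----------
``<nuclide>_emissions.csv`` starts with a comment header block::

    # id: Lu-177
    # half_life_days: 6.647
    # beta_file: lu177_beta.csv
    component,energy_keV,yield

followed by one row per discrete line, ``component`` one of
``auger, ic, xray, gamma``.  The companion beta file is a two-column
table ``energy_keV,density_per_keV`` normalised to unit integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

COMPONENTS = ("beta", "auger", "ic", "xray", "gamma")
ELECTRON_COMPONENTS = ("beta", "auger", "ic")
PHOTON_COMPONENTS = ("xray", "gamma")

#: minimum fixture energy, keV; lower-energy emissions are deposited locally
#: by transport anyway and are disallowed in the data files
ENERGY_FLOOR_KEV = 0.1


@dataclass(frozen=True)
class EmissionLine:
    """One discrete emission: ``yield_per_decay`` emissions of ``energy_keV``."""

    component: str
    energy_keV: float
    yield_per_decay: float

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(
                f"unknown component {self.component!r}; valid: {COMPONENTS}")
        if not self.energy_keV >= ENERGY_FLOOR_KEV:
            raise ValueError(
                f"line energy {self.energy_keV} keV below the "
                f"{ENERGY_FLOOR_KEV} keV fixture floor")
        if self.yield_per_decay < 0:
            raise ValueError("yield must be >= 0")


class BetaSpectrum:
    """Tabulated beta energy distribution (density per keV, unit integral)."""

    def __init__(self, energy_keV: np.ndarray, density_per_keV: np.ndarray):
        energy_keV = np.asarray(energy_keV, dtype=float)
        density_per_keV = np.asarray(density_per_keV, dtype=float)
        if energy_keV.ndim != 1 or energy_keV.shape != density_per_keV.shape:
            raise ValueError("energy and density must be matching 1-d arrays")
        if np.any(np.diff(energy_keV) <= 0):
            raise ValueError("beta energy grid must be strictly increasing")
        if np.any(density_per_keV < 0):
            raise ValueError("beta density must be non-negative")
        integral = np.trapezoid(density_per_keV, energy_keV)
        if abs(integral - 1.0) > 1e-6:
            raise ValueError(
                f"beta density not normalised: integral = {integral!r}")
        self.energy_keV = energy_keV
        self.density_per_keV = density_per_keV
        # trapezoid CDF for inverse-CDF sampling
        cdf = np.concatenate(
            [[0.0], np.cumsum(np.diff(energy_keV)
                              * (density_per_keV[1:] + density_per_keV[:-1]) / 2)])
        self._cdf = cdf / cdf[-1]

    @property
    def mean_energy_keV(self) -> float:
        return float(np.trapezoid(self.energy_keV * self.density_per_keV,
                                  self.energy_keV))

    def cdf(self, energy_keV: np.ndarray) -> np.ndarray:
        """Cumulative distribution at the given energies."""
        return np.interp(energy_keV, self.energy_keV, self._cdf)

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Draw ``n`` beta energies by inverse-CDF interpolation."""
        u = rng.random(n)
        return np.interp(u, self._cdf, self.energy_keV)


@dataclass
class EmissionSpectrum:
    """Full per-decay radiation inventory of a radionuclide."""

    nuclide: str
    half_life_days: float
    beta: BetaSpectrum | None
    lines: list[EmissionLine] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.half_life_days > 0:
            raise ValueError("physical half-life must be > 0")

    def lines_of(self, component: str) -> list[EmissionLine]:
        return [l for l in self.lines if l.component == component]

    @property
    def components(self) -> list[str]:
        present = [c for c in COMPONENTS if self.lines_of(c)]
        if self.beta is not None:
            present.insert(0, "beta")
        return present


def _parse_header(path: Path) -> tuple[dict, int]:
    meta, n = {}, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
    return meta, n


def load_emission_spectrum(path: str | Path) -> EmissionSpectrum:
    """Load and validate an emission inventory from its CSV file pair.

    Raises
    ------
    ValueError
        Naming the offending row for malformed lines; quoting the computed
        integral for a non-normalised beta density.
    FileNotFoundError
        If the emission file or its beta companion is missing.
    """
    path = Path(path)
    meta, nskip = _parse_header(path)
    if "half_life_days" not in meta:
        raise ValueError(f"{path}: missing '# half_life_days:' header")

    lines: list[EmissionLine] = []
    with open(path) as fh:
        rows = [l.strip() for l in fh]
    body = [r for r in rows[nskip:] if r]
    if not body or body[0] != "component,energy_keV,yield":
        raise ValueError(f"{path}: expected header 'component,energy_keV,yield'")
    for i, row in enumerate(body[1:], start=2 + nskip):
        parts = row.split(",")
        if len(parts) != 3:
            raise ValueError(f"{path} row {i}: expected 3 fields, got {row!r}")
        try:
            lines.append(EmissionLine(parts[0].strip(),
                                      float(parts[1]), float(parts[2])))
        except ValueError as err:
            raise ValueError(f"{path} row {i}: {err}") from None

    beta = None
    if "beta_file" in meta:
        e, d = _load_beta(path.parent / meta["beta_file"])
        beta = BetaSpectrum(e, d)
    return EmissionSpectrum(meta.get("id", path.stem), float(meta["half_life_days"]),
                            beta, lines)


def _load_beta(path: Path) -> tuple[np.ndarray, np.ndarray]:
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    return df["energy_keV"].to_numpy(), df["density_per_keV"].to_numpy()


def lu177() -> EmissionSpectrum:
    """The bundled Lu-177 fixture."""
    with resources.as_file(resources.files("celldose.data")
                           / "lu177_emissions.csv") as p:
        return load_emission_spectrum(p)


def mean_energy_per_decay(spectrum: EmissionSpectrum,
                          component: str = "all") -> float:
    """Yield-weighted energy per decay (keV) of one component or ``"all"``.

    For the beta spectrum this is the first moment of the tabulated density
    (one beta per decay); for discrete components the sum of yield x energy.
    """
    if component == "all":
        return sum(mean_energy_per_decay(spectrum, c)
                   for c in spectrum.components)
    if component == "beta":
        if spectrum.beta is None:
            raise ValueError("spectrum has no beta component")
        return spectrum.beta.mean_energy_keV
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}; "
                         f"valid: {COMPONENTS + ('all',)}")
    lines = spectrum.lines_of(component)
    if not lines:
        raise ValueError(f"component {component!r} not present in spectrum")
    return sum(l.energy_keV * l.yield_per_decay for l in lines)


def sample_decay(spectrum: EmissionSpectrum, rng: np.random.Generator,
                 components: tuple[str, ...] | None = None,
                 ) -> list[tuple[str, float]]:
    """Sample the emissions of one decay as ``[(component, energy_keV), ...]``.

    Each discrete line emits ``floor(yield)`` particles plus one more with
    probability ``yield - floor(yield)``; the beta energy is drawn by
    inverse-CDF from the tabulated spectrum.  Restricting ``components``
    samples only those (used for per-component transport runs).
    """
    wanted = components or tuple(spectrum.components)
    out: list[tuple[str, float]] = []
    if "beta" in wanted and spectrum.beta is not None:
        out.append(("beta", float(spectrum.beta.sample(rng, 1)[0])))
    for line in spectrum.lines:
        if line.component not in wanted:
            continue
        k = int(line.yield_per_decay)
        if rng.random() < line.yield_per_decay - k:
            k += 1
        out.extend((line.component, line.energy_keV) for _ in range(k))
    return out
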