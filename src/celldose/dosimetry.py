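"""Cellular dosimetry: S-values, cumulated activity and localization scenarios.

The MIRD-style chain is: a tally of energy per simulated decay becomes an
S-value (Gy per decay) by dividing by the target mass; the cumulated
(time-integrated) activity of a compartment over an interval is

    A_tilde = (T_p / ln 2) * A_0 * (1 - exp(-ln 2 * dt / T_p))

(the familiar ``1.44 T_p A_0 (1 - e^(-0.693 dt/T_p))`` with the exact
mean-life constant); and a localization scenario -- which fractions of the
initial activity sit in the nucleus, cytoplasm or culture medium, for how
long -- combines the two into a per-cell absorbed dose.

The per-cell share of the activity of an internalized compartment follows
one of two conventions (the assay protocol supports both readings):

``volume_share``
    per-cell activity = fraction * A0 * (V_cell / V_medium), the literal
    "200 uL of medium and a cell diameter of 25 um" reading (default);
``per_seeded_cell``
    per-cell activity = fraction * A0 / N_cells with the assay seeding
    density (50,000 clonogenic, 20,000 MTT).

Dose from activity decaying in the medium is evaluated with a uniform-bath
(charged-particle-equilibrium) S-value: electrons are absorbed locally in
the 200 uL bath; photon energy is weighted by an energy-absorption factor
over the bath's mean chord.  An analog Monte Carlo estimate of the
medium-to-cell S-value is hopeless at desk scale (geometric efficiency
~4e-8) and the equilibrium value is exact in the limit that ranges are
small against the bath size, which holds here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay import EmissionSpectrum, mean_energy_per_decay, lu177
from .geometry import CellModel
from .materials import builtin
from .transport import (KEV_TO_J, MEC2, Tally, TransportConfig, run_histories,
                        _kahn_compton)

LN2 = math.log(2.0)
DAY_S = 86400.0
HOUR_S = 3600.0

#: assay decay durations (assay protocol): internalized compartments decay
#: for the assay length plus the 4 h incubation; medium terms for 4 h only
ASSAY_DURATIONS_S = {
    "clonogenic": {"internal": 14 * DAY_S + 4 * HOUR_S, "medium": 4 * HOUR_S,
                   "efflux": 14 * DAY_S},
    "mtt": {"internal": 72 * HOUR_S + 4 * HOUR_S, "medium": 4 * HOUR_S,
            "efflux": 72 * HOUR_S},
}

SEEDED_CELLS = {"clonogenic": 50_000, "mtt": 20_000}


@dataclass(frozen=True)
class SValue:
    """Absorbed dose to ``target`` per decay in ``source`` (Gy/decay)."""

    source: str
    target: str
    component: str
    gy_per_decay: float
    stderr: float = 0.0

    def __post_init__(self) -> None:
        if self.gy_per_decay < 0:
            raise ValueError("S-value must be >= 0")


@dataclass(frozen=True)
class ActivitySchedule:
    """Initial activity decaying physically for a fixed interval."""

    a0_Bq: float
    half_life_days: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.a0_Bq < 0 or self.half_life_days < 0 or self.duration_s < 0:
            raise ValueError("activity, half-life and duration must be >= 0")


def time_integrated_activity(schedule: ActivitySchedule) -> float:
    """Number of decays over the interval (cumulated activity, Eq. form
    ``1.44 T_p A_0 (1 - exp(-0.693 dt / T_p))`` with exact ln 2)."""
    tp_s = schedule.half_life_days * DAY_S
    if tp_s == 0.0:
        return 0.0
    return (tp_s / LN2) * schedule.a0_Bq * -math.expm1(
        -LN2 * schedule.duration_s / tp_s)


def per_cell_activity(a0_Bq: float, fraction: float, model: CellModel,
                      convention: str = "volume_share",
                      n_cells: int | None = None) -> float:
    """Share of a compartment's activity attributed to one cell (Bq)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if convention == "volume_share":
        v_cell = model.region_volume_um3("cell")           # um^3
        v_medium = model.medium_volume_uL * 1e9
        return fraction * a0_Bq * v_cell / v_medium
    if convention == "per_seeded_cell":
        if not n_cells:
            raise ValueError("per_seeded_cell convention needs n_cells")
        return fraction * a0_Bq / n_cells
    raise ValueError(f"unknown convention {convention!r}; "
                     "valid: volume_share, per_seeded_cell")


# ----------------------------------------------------------------- S-values
def s_value(source: str, target, component: str, model: CellModel,
            cfg: TransportConfig, n_histories: int,
            rng: np.random.Generator,
            spectrum: EmissionSpectrum | None = None,
            energy_keV: float | None = None,
            particle_kind: str | None = None,
            tally: Tally | None = None) -> SValue:
    """Monte Carlo S-value: energy per decay in ``target`` / target mass.

    ``target`` may be a region id or ``"cell"`` (the whole central cell).
    An existing ``tally`` (from a previous run with the same source) can be
    reused to extract further targets without re-simulating.
    """
    if tally is None:
        if n_histories < 1:
            raise ValueError("need n_histories >= 1")
        tally = run_histories(n_histories, source, component, model, cfg, rng,
                              spectrum=spectrum, energy_keV=energy_keV,
                              particle_kind=particle_kind)
    if target == "cell" and not any(r == "cell" for r, _ in tally._sum):
        regions = model.cell_regions  # tally without the aggregate
    else:
        regions = target
    mass = model.region_mass_kg(target)
    if mass <= 0.0:
        raise ValueError(f"target {target!r} has zero mass")
    to_gy = KEV_TO_J / mass
    return SValue(source, target if isinstance(target, str) else str(target),
                  component,
                  tally.mean_keV(regions, component) * to_gy,
                  tally.stderr_keV(regions, component) * to_gy)


def medium_s_value(model: CellModel,
                   spectrum: EmissionSpectrum | None = None,
                   target: str = "cell") -> SValue:
    """Uniform-bath equilibrium S-value for activity in the culture medium.

    Dose rate anywhere inside a large uniformly active bath equals the
    locally absorbed energy per decay over the bath mass.  Electrons
    (ranges <= ~2 mm) are fully absorbed; photon energy is weighted by
    ``1 - exp(-mu_en * mean chord)`` of the medium cube.
    """
    spectrum = spectrum or lu177()
    water = builtin("water")
    m_med = model.medium_volume_uL * 1e-6  # kg at water density
    e_dep = 0.0
    for comp in spectrum.components:
        e = mean_energy_per_decay(spectrum, comp)
        if comp in ("xray", "gamma"):
            for line in spectrum.lines_of(comp):
                mu_en = _mu_energy_absorption(water, line.energy_keV)
                side = 2.0 * model.medium_half_side_um
                chord = 2.0 * side / 3.0
                f_abs = -math.expm1(-mu_en * chord)
                e_dep += line.energy_keV * line.yield_per_decay * f_abs
        else:
            e_dep += e
    return SValue("medium", target, "all", e_dep * KEV_TO_J / m_med)


def _mu_energy_absorption(material, energy_keV: float) -> float:
    """Energy-absorption coefficient (1/um): photoelectric plus the
    electron-share of the Compton coefficient."""
    mu_pe = material.mu_photoelectric(energy_keV)
    mu_c = material.mu_compton(energy_keV)
    # mean fraction of photon energy to the recoil electron (Klein-Nishina),
    # by quick fixed-seed MC over the analytic sampler
    rng = np.random.default_rng(12345)
    frac = 1.0 - np.mean([_kahn_compton(energy_keV, rng)[0]
                          for _ in range(400)]) / energy_keV
    return mu_pe + mu_c * frac


# ---------------------------------------------------------------- scenarios
@dataclass(frozen=True)
class Scenario:
    """Compartment activity fractions and decay durations for one assay.

    ``entries`` hold the initial partition (fractions sum to 1);
    ``efflux_entries`` hold activity that relocates to the medium after
    the incubation and decays there for the assay remainder.
    """

    name: str
    assay: str
    entries: tuple[tuple[str, float, float], ...]  # (compartment, fraction, duration_s)
    efflux_entries: tuple[tuple[str, float, float], ...] = ()
    efflux: bool = False

    def __post_init__(self) -> None:
        if self.assay not in ASSAY_DURATIONS_S:
            raise ValueError(f"unknown assay {self.assay!r}")
        for compartment, fraction, duration in self.all_entries:
            if compartment not in ("nucleus", "cytoplasm", "medium"):
                raise ValueError(f"unknown compartment {compartment!r}")
            if fraction < 0 or duration < 0:
                raise ValueError("fractions and durations must be >= 0")
        total = sum(f for _, f, _ in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial fractions sum to {total}, expected 1")

    @property
    def all_entries(self):
        return self.entries + self.efflux_entries


PRESET_NAMES = ("1", "2", "1_efflux", "2_efflux", "cmo")


def scenario_preset(name: str, assay: str = "clonogenic",
                    internalized: float = 0.70) -> Scenario:
    """The five localization scenarios of the study.

    1: internalized fraction in the nucleus for the assay duration;
    2: same but in the cytoplasm; 1/2_efflux: internalized for the 4 h
    incubation only, then relocated to the medium for the assay remainder;
    cmo: culture medium only (the non-internalizing construct).
    The remainder (1 - internalized) always decays in the medium for the
    4 h incubation.
    """
    d = ASSAY_DURATIONS_S[assay]
    f, rest = internalized, 1.0 - internalized
    if name == "cmo":
        return Scenario("cmo", assay, (("medium", 1.0, d["medium"]),))
    compartment = {"1": "nucleus", "2": "cytoplasm"}[name.split("_")[0]]
    if name in ("1", "2"):
        return Scenario(name, assay,
                        ((compartment, f, d["internal"]),
                         ("medium", rest, d["medium"])))
    if name in ("1_efflux", "2_efflux"):
        return Scenario(name, assay,
                        ((compartment, f, d["medium"]),
                         ("medium", rest, d["medium"])),
                        efflux_entries=(("medium", f, d["efflux"]),),
                        efflux=True)
    raise ValueError(f"unknown scenario {name!r}; valid: {PRESET_NAMES}")


@dataclass
class AbsorbedDoseReport:
    """Per-cell absorbed dose for one scenario at one initial activity."""

    scenario: str
    assay: str
    a0_Bq: float
    dose_Gy: dict[str, float]          # target -> Gy (targets: cell, nucleus)
    stderr_Gy: dict[str, float]
    decays: dict[str, float]           # compartment -> cumulated decays
    convention: str = "volume_share"

    def to_frame(self) -> pd.DataFrame:
        rows = [{"scenario": self.scenario, "assay": self.assay,
                 "A0_MBq": self.a0_Bq / 1e6, "target": t,
                 "dose_Gy": d, "stderr_Gy": self.stderr_Gy.get(t, 0.0)}
                for t, d in self.dose_Gy.items()]
        return pd.DataFrame(rows)


def derive_compartment_fractions(uptake: pd.DataFrame) -> dict[str, float]:
    """Average internalized fraction over an uptake time course.

    Expects a column ``internalized_pct`` (percent of applied activity);
    the non-internalized remainder is assigned to the medium.
    """
    if len(uptake) == 0:
        raise ValueError("empty uptake series")
    internal = float(np.mean(uptake["internalized_pct"])) / 100.0
    internal = min(max(internal, 0.0), 1.0)
    return {"internalized": internal, "medium": 1.0 - internal}


def scenario_dose(scenario: Scenario, a0_Bq: float,
                  s_values: dict[tuple[str, str], SValue],
                  model: CellModel, half_life_days: float = 6.647,
                  convention: str = "volume_share",
                  n_cells: int | None = None) -> AbsorbedDoseReport:
    """Evaluate a scenario into per-cell absorbed dose.

    ``s_values`` maps ``(compartment, target)`` to an :class:`SValue`;
    every compartment appearing in the scenario must be covered for the
    targets ``cell`` and ``nucleus``.
    """
    targets = ("cell", "nucleus")
    if n_cells is None:
        n_cells = SEEDED_CELLS[scenario.assay]
    dose = {t: 0.0 for t in targets}
    var = {t: 0.0 for t in targets}
    decays: dict[str, float] = {}
    for compartment, fraction, duration in scenario.all_entries:
        if compartment == "medium":
            a_comp = fraction * a0_Bq
        else:
            a_comp = per_cell_activity(a0_Bq, fraction, model, convention,
                                       n_cells)
        n_decays = time_integrated_activity(
            ActivitySchedule(a_comp, half_life_days, duration))
        decays[compartment] = decays.get(compartment, 0.0) + n_decays
        for t in targets:
            key = (compartment, t)
            if key not in s_values:
                raise KeyError(
                    f"missing S-value for (source={compartment!r}, "
                    f"target={t!r})")
            sv = s_values[key]
            dose[t] += n_decays * sv.gy_per_decay
            var[t] += (n_decays * sv.stderr) ** 2
    return AbsorbedDoseReport(scenario.name, scenario.assay, a0_Bq, dose,
                              {t: math.sqrt(v) for t, v in var.items()},
                              decays, convention)


def dose_ratio(report_a: AbsorbedDoseReport, report_b: AbsorbedDoseReport,
               target: str = "cell") -> float:
    """Ratio of per-cell doses of two reports for the same target."""
    num, den = report_a.dose_Gy[target], report_b.dose_Gy[target]
    if den == 0.0:
        raise ZeroDivisionError("denominator report has zero dose")
    return num / den


def compute_scenario_s_values(model: CellModel, cfg: TransportConfig,
                              n_histories: int, rng: np.random.Generator,
                              spectrum: EmissionSpectrum | None = None,
                              ) -> dict[tuple[str, str], SValue]:
    """Full-spectrum S-values for the scenario compartments.

    Nucleus and cytoplasm sources by Monte Carlo (one run each, both
    targets extracted from the same tally); medium source analytically
    (uniform-bath equilibrium, identical for both targets).
    """
    spectrum = spectrum or lu177()
    out: dict[tuple[str, str], SValue] = {}
    for source in ("nucleus", "cytoplasm"):
        tally = run_histories(n_histories, source, "all", model, cfg, rng,
                              spectrum=spectrum)
        for target in ("cell", "nucleus"):
            out[(source, target)] = s_value(source, target, "all", model, cfg,
                                            0, rng, tally=tally)
    sv_med = medium_s_value(model, spectrum)
    for target in ("cell", "nucleus"):
        out[("medium", target)] = SValue("medium", target, "all",
                                         sv_med.gy_per_decay)
    return out
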