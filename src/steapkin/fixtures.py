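"""Named fixtures reproducing each in-study experiment's conditions.

Each fixture bundles the published concentrations, rate constants, phase
fractions, and observation windows of one experiment, together with a
citation string, and knows how to generate the corresponding synthetic
dataset.  Quantities the source never printed (extinction scale, exact
amplitude in AU, BLI off-rate, titration substrate series for the
FADH- saturation) are filled with realistic defaults and marked
``assumed`` in the fixture metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .kinetics import SequentialModel, TwoPopulationBindingModel
from .spectral import SpeciesLibrary, reference_library
from .synth import (
    BLISeries,
    ExperimentConditions,
    HyperbolicLaw,
    LinearLaw,
    NoiseModel,
    RapidScanDataset,
    TimeCourse,
    TitrationTable,
    generate_bli,
    generate_rapid_scan,
    generate_timecourse,
    generate_titration,
    log_time_grid,
)

__all__ = [
    "FIXTURES",
    "fixture",
    "rapid_scan",
    "timecourse",
    "titration",
    "bli",
    "two_population_model",
]


@dataclass(frozen=True)
class Fixture:
    """Conditions and published parameters of one experiment."""

    name: str
    kind: str  # rapid_scan | timecourse | titration | bli | oxidation
    citation: str
    params: dict[str, Any] = field(default_factory=dict)
    assumed: dict[str, Any] = field(default_factory=dict)


# Total A427 amplitude for ~1 uM heme at the placeholder extinction scale.
_A427_AMPLITUDE = 0.05
_A427_OFFSET = 0.06

FIXTURES: dict[str, Fixture] = {}


def _register(f: Fixture) -> Fixture:
    FIXTURES[f.name] = f
    return f


_register(Fixture(
    name="fig2A_fadh_steap1",
    kind="timecourse",
    citation="reduction of 1.1 uM STEAP1 by 4.5 uM FADH-, A427 followed 20 s",
    params={
        "enzyme_uM": 1.1, "substrate_uM": 4.5, "window_s": 20.0,
        "k_obs": (7.7, 0.67), "fractions": (0.60, 0.40),
        "direction": "rise", "wavelength_nm": 427.0,
        # saturation of the two phases with [FADH-]
        "titration_fast": HyperbolicLaw(vmax=12.0, km=4.7),
        "titration_slow": HyperbolicLaw(vmax=0.9, km=2.7),
    },
    assumed={"total_amplitude_AU": _A427_AMPLITUDE, "offset_AU": _A427_OFFSET,
             "titration_substrate_uM": "5 log-spaced points, 1-20 uM"},
))

_register(Fixture(
    name="fig2s1_L230G",
    kind="titration",
    citation="L230G STEAP1 reduced by FADH-: saturation of both phases",
    params={
        "titration_fast": HyperbolicLaw(vmax=2.0, km=3.6),
        "titration_slow": HyperbolicLaw(vmax=0.16, km=1.1),
    },
    assumed={"titration_substrate_uM": "5 log-spaced points, 1-20 uM"},
))

_register(Fixture(
    name="fig3A_b5r",
    kind="rapid_scan",
    citation="1.5 uM STEAP1 + 1.5 uM b5R mixed with 10 uM NADH, 20 s window;"
             " three sequential species",
    params={
        "enzyme_uM": 1.5, "substrate_uM": 10.0, "window_s": 20.0,
        "rates": (177.9, 0.13),
        "species": ("ferric_b5rox", "ferric_b5rred", "ferrous_b5rred"),
    },
    assumed={"t_min_s": 1e-3},
))

_register(Fixture(
    name="fig4s1_steap2_nadph",
    kind="rapid_scan",
    citation="STEAP2 + FAD reduced by NADPH; two species, k = 1.2e-3 s^-1",
    params={
        "enzyme_uM": 2.3, "substrate_uM": 60.0, "window_s": 3600.0,
        "rates": (1.2e-3,),
        "species": ("ferric_fadox", "ferrous_fadred"),
    },
    assumed={"t_min_s": 1.0},
))

_register(Fixture(
    name="fig2C_mixture",
    kind="rapid_scan",
    citation="1.1 uM STEAP2 + 0.9 uM STEAP1 + 2.2 uM FAD with 60 uM NADPH,"
             " 1 h; two species, k = 5.5e-4 s^-1",
    params={
        "enzyme_uM": 2.0, "substrate_uM": 60.0, "window_s": 3600.0,
        "rates": (5.5e-4,),
        "species": ("ferric_fadox", "ferrous_fadred"),
    },
    assumed={"t_min_s": 1.0},
))

_register(Fixture(
    name="fig4s1_steap2_fadh",
    kind="timecourse",
    citation="STEAP2 reduced by 4.5 uM FADH-: biphasic, 2.9 s^-1 (16%) and"
             " 6.9e-2 s^-1 (84%)",
    params={
        "enzyme_uM": 2.3, "substrate_uM": 4.5, "window_s": 120.0,
        "k_obs": (2.9, 6.9e-2), "fractions": (0.16, 0.84),
        "direction": "rise", "wavelength_nm": 427.0,
    },
    assumed={"total_amplitude_AU": _A427_AMPLITUDE, "offset_AU": _A427_OFFSET},
))

_register(Fixture(
    name="fig5_steap1_nta",
    kind="oxidation",
    citation="1.1 uM ferrous STEAP1 oxidized by Fe3+-NTA; two populations"
             " (85%/15%), kon/koff = 1.5e5/7.5 and 7.6e3/0.2",
    params={
        "enzyme_uM": 1.1, "substrate_uM": (25.0, 75.0, 125.0, 175.0),
        "window_s": 10.0, "fractions": (0.85, 0.15),
        "k_on": (1.5e5, 7.6e3), "k_off": (7.5, 0.2),
        "wavelength_nm": 427.0,
    },
    assumed={"total_amplitude_AU": _A427_AMPLITUDE, "offset_AU": 0.02,
             "window_s": "10 s (full-trace fit; only STEAP2 is"
                         " window-restricted)"},
))

_register(Fixture(
    name="fig5_steap2_nta",
    kind="oxidation",
    citation="1.1 uM ferrous STEAP2 oxidized by Fe3+-NTA; initial 2 s fitted"
             " biphasic; kon/koff = 1.1e4/2.2 and 3.5e3/0.3",
    params={
        "enzyme_uM": 1.1, "substrate_uM": (75.0, 125.0, 175.0),
        "window_s": 2.0, "fractions": (0.5, 0.5),
        "k_on": (1.1e4, 3.5e3), "k_off": (2.2, 0.3),
        "wavelength_nm": 427.0,
    },
    assumed={"total_amplitude_AU": _A427_AMPLITUDE / 2, "offset_AU": 0.02,
             "fractions": "equal split of the first-2-s amplitude"},
))

_register(Fixture(
    name="bli_b5r",
    kind="bli",
    citation="BLI of b5R binding immobilized STEAP1 at 20, 10, 5, 2.5, 1.3,"
             " 0.6 uM; dose-response K_D ~5.9 uM",
    params={
        "kd_uM": 5.9,
        "analyte_uM": (20.0, 10.0, 5.0, 2.5, 1.3, 0.6),
        "rmax": 1.0,
    },
    assumed={"k_off_s": 0.05, "req_noise_frac": 0.02},
))


def fixture(name: str) -> Fixture:
    try:
        return FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None


# --- spectral templates for the rapid-scan fixtures -------------------------

def _scan_library(fixture_name: str) -> SpeciesLibrary:
    """Composite species spectra (heme + flavin partner) per kinetic species."""
    ref = reference_library()
    grid = ref.grid_nm
    lib = SpeciesLibrary()

    def composite(name: str, parts: dict[str, float], state: str) -> None:
        eps = np.zeros_like(grid)
        for part, w in parts.items():
            eps = eps + w * ref[part].epsilon
        from .spectral import SpeciesSpectrum
        lib.add(SpeciesSpectrum(name=name, redox_state=state, grid_nm=grid,
                                epsilon=eps, meta={"composite_of": parts}))

    if fixture_name == "fig3A_b5r":
        # A: ferric STEAP1 + oxidized b5R; B: ferric + reduced b5R
        # (bleached 420-500 nm); C: ferrous + reduced b5R.
        composite("ferric_b5rox", {"ferric_heme": 1.0, "b5r_ox": 1.0}, "ferric")
        composite("ferric_b5rred", {"ferric_heme": 1.0, "b5r_red": 1.0}, "ferric")
        composite("ferrous_b5rred", {"ferrous_heme": 1.0, "b5r_red": 1.0},
                  "ferrous")
    else:
        composite("ferric_fadox", {"ferric_heme": 1.0, "fad_ox": 1.0}, "ferric")
        composite("ferrous_fadred", {"ferrous_heme": 1.0, "fadh_red": 1.0},
                  "ferrous")
    return lib


def rapid_scan(name: str, seed: int = 0,
               sigma_AU: float | None = None,
               dead_time_s: float | None = None,
               n_points: int = 400) -> RapidScanDataset:
    """Generate the rapid-scan dataset of a fixture."""
    f = fixture(name)
    if f.kind != "rapid_scan":
        raise ValueError(f"fixture {name!r} is not a rapid-scan fixture")
    p = f.params
    mech = SequentialModel(p["species"], p["rates"])
    cond = ExperimentConditions(
        enzyme_uM=p["enzyme_uM"], substrate_uM=p["substrate_uM"],
        dead_time_s=(1.5e-3 if dead_time_s is None else dead_time_s),
    )
    noise = NoiseModel(sigma_AU=0.002 if sigma_AU is None else sigma_AU,
                       seed=seed)
    t = log_time_grid(f.assumed["t_min_s"], p["window_s"], n_points)
    ds = generate_rapid_scan(mech, _scan_library(name), cond, noise, t)
    ds.provenance["fixture"] = name
    ds.provenance["citation"] = f.citation
    return ds


def timecourse(name: str, seed: int = 0, sigma_AU: float | None = None,
               n_points: int = 400) -> TimeCourse:
    """Generate the single-wavelength A427 time course of a fixture."""
    f = fixture(name)
    if f.kind != "timecourse":
        raise ValueError(f"fixture {name!r} is not a time-course fixture")
    p = f.params
    total = f.assumed["total_amplitude_AU"]
    phases = [(k, total * frac)
              for k, frac in zip(p["k_obs"], p["fractions"])]
    noise = NoiseModel(sigma_AU=0.002 if sigma_AU is None else sigma_AU,
                       seed=seed)
    t = log_time_grid(1e-3, p["window_s"], n_points)
    cond = ExperimentConditions(enzyme_uM=p["enzyme_uM"],
                                substrate_uM=p["substrate_uM"])
    tc = generate_timecourse(phases, f.assumed["offset_AU"], noise, t,
                             p["wavelength_nm"], p["direction"], cond)
    tc.provenance["fixture"] = name
    tc.provenance["citation"] = f.citation
    return tc


def two_population_model(name: str) -> TwoPopulationBindingModel:
    """Two-population binding model of a ferric-substrate oxidation fixture."""
    f = fixture(name)
    if f.kind != "oxidation":
        raise ValueError(f"fixture {name!r} is not an oxidation fixture")
    p = f.params
    return TwoPopulationBindingModel(p["fractions"], p["k_on"], p["k_off"])


def oxidation_timecourse(name: str, substrate_uM: float, seed: int = 0,
                         sigma_AU: float | None = None,
                         n_points: int = 1000) -> TimeCourse:
    """Decaying A427 trace of a ferrous enzyme oxidized by Fe3+ substrate.

    Single-wavelength stopped-flow shots are sampled on a linear time base
    (unlike the log-spaced rapid-scan grids).
    """
    f = fixture(name)
    if f.kind != "oxidation":
        raise ValueError(f"fixture {name!r} is not an oxidation fixture")
    p = f.params
    model = two_population_model(name)
    rates = model.observed_rates(substrate_uM)
    total = f.assumed["total_amplitude_AU"]
    phases = [(k, total * frac) for k, frac in zip(rates, model.fractions)]
    noise = NoiseModel(sigma_AU=0.002 if sigma_AU is None else sigma_AU,
                       seed=seed)
    t = np.linspace(2e-3, p["window_s"], n_points)
    cond = ExperimentConditions(enzyme_uM=p["enzyme_uM"],
                                substrate_uM=substrate_uM)
    tc = generate_timecourse(phases, f.assumed["offset_AU"], noise, t,
                             p["wavelength_nm"], "decay", cond)
    tc.provenance["fixture"] = name
    tc.provenance["substrate_uM"] = substrate_uM
    return tc


DEFAULT_TITRATION_SUBSTRATE_UM = tuple(np.geomspace(1.0, 20.0, 5))


def titration(name: str, phase: str = "fast", seed: int = 0,
              noise_frac: float = 0.0,
              substrate_uM: tuple[float, ...] | None = None) -> TitrationTable:
    """k_obs-vs-[S] table of a fixture.

    For FADH- saturation fixtures the law is hyperbolic (fast/slow phase);
    for Fe3+-NTA oxidation fixtures it is linear with the published
    kon/koff, evaluated at the published substrate series.
    """
    f = fixture(name)
    p = f.params
    if f.kind == "oxidation":
        i = 0 if phase == "fast" else 1
        law: HyperbolicLaw | LinearLaw = LinearLaw(p["k_on"][i], p["k_off"][i])
        s = substrate_uM if substrate_uM is not None else p["substrate_uM"]
    elif "titration_" + phase in p:
        law = p["titration_" + phase]
        s = substrate_uM if substrate_uM is not None \
            else DEFAULT_TITRATION_SUBSTRATE_UM
    else:
        raise ValueError(f"fixture {name!r} has no {phase!r} titration law")
    table = generate_titration(law, s, noise_frac, seed)
    table.provenance["fixture"] = name
    table.provenance["phase"] = phase
    return table


def bli(seed: int = 0, sigma: float = 0.0,
        req_noise_frac: float | None = None) -> BLISeries:
    """Synthetic BLI dose-response series of the b5R-STEAP1 experiment."""
    f = fixture("bli_b5r")
    p = f.params
    frac = f.assumed["req_noise_frac"] if req_noise_frac is None \
        else req_noise_frac
    series = generate_bli(p["kd_uM"], p["rmax"], p["analyte_uM"],
                          f.assumed["k_off_s"], NoiseModel(sigma, seed),
                          req_noise_frac=frac)
    series.provenance["fixture"] = "bli_b5r"
    series.provenance["citation"] = f.citation
    return series
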