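"""Synthetic stopped-flow / rapid-scan / titration / BLI data generators.

Every generator is a pure function of its parameters and seed: identical
inputs give bit-identical outputs, and the generating truth (rate constants,
amplitudes, K_D, ...) is recorded in the output's provenance dictionary so
that fits can be checked against it.

Photometric noise is additive Gaussian (default sigma 0.002 AU, a typical
diode-array noise floor); the instrument dead time shifts the recorded time
axis so that t = 0 is the end of the dead time, i.e. the mechanism has
already evolved for ``dead_time_s`` at the first recorded point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kinetics import SequentialModel, simulate_sequential
from .spectral import SpeciesLibrary

__all__ = [
    "ExperimentConditions",
    "NoiseModel",
    "RapidScanDataset",
    "TimeCourse",
    "TitrationTable",
    "BLISeries",
    "HyperbolicLaw",
    "LinearLaw",
    "generate_rapid_scan",
    "generate_timecourse",
    "generate_titration",
    "generate_bli",
    "log_time_grid",
]

DEFAULT_SIGMA_AU = 0.002
DEFAULT_DEAD_TIME_S = 1.5e-3


@dataclass(frozen=True)
class ExperimentConditions:
    """Mixing conditions of one stopped-flow shot."""

    enzyme_uM: float
    substrate_uM: float | tuple[float, ...] | None = None
    dead_time_s: float = DEFAULT_DEAD_TIME_S
    pathlength_cm: float = 1.0
    mix_ratio: float = 1.0  # syringe volume ratio, 1:1 unless stated

    def __post_init__(self) -> None:
        if self.enzyme_uM <= 0:
            raise ValueError("enzyme_uM must be > 0")
        if self.dead_time_s < 0:
            raise ValueError("dead_time_s must be >= 0")
        if self.pathlength_cm <= 0 or self.mix_ratio <= 0:
            raise ValueError("pathlength_cm and mix_ratio must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian photometric noise; the seed is recorded in all outputs."""

    sigma_AU: float = DEFAULT_SIGMA_AU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_AU < 0:
            raise ValueError("sigma_AU must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class RapidScanDataset:
    """Time x wavelength absorbance matrix with provenance."""

    time_s: np.ndarray
    grid_nm: np.ndarray
    absorbance: np.ndarray  # (n_times, n_wavelengths), AU
    conditions: ExperimentConditions | None = None
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        g = np.asarray(self.grid_nm, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != (t.size, g.size):
            raise ValueError("absorbance matrix shape mismatch")
        if np.any(~np.isfinite(a)):
            raise ValueError("absorbance matrix contains missing values")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "grid_nm", g)
        object.__setattr__(self, "absorbance", a)

    def trace(self, wavelength_nm: float) -> "TimeCourse":
        """Single-wavelength time course at the nearest grid point."""
        j = int(np.argmin(np.abs(self.grid_nm - wavelength_nm)))
        return TimeCourse(
            wavelength_nm=float(self.grid_nm[j]), time_s=self.time_s,
            absorbance=self.absorbance[:, j], conditions=self.conditions,
            provenance=dict(self.provenance),
        )


@dataclass(frozen=True)
class TimeCourse:
    """Single-wavelength absorbance trace."""

    wavelength_nm: float
    time_s: np.ndarray
    absorbance: np.ndarray
    conditions: ExperimentConditions | None = None
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("time and absorbance must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "absorbance", a)


@dataclass(frozen=True)
class TitrationTable:
    """k_obs versus substrate concentration."""

    substrate_uM: np.ndarray
    k_obs: np.ndarray  # s^-1
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_uM, dtype=float)
        k = np.asarray(self.k_obs, dtype=float)
        if s.ndim != 1 or k.shape != s.shape:
            raise ValueError("substrate and k_obs must be matching 1-D arrays")
        object.__setattr__(self, "substrate_uM", s)
        object.__setattr__(self, "k_obs", k)


@dataclass(frozen=True)
class BLISeries:
    """Bio-layer interferometry association/dissociation series."""

    analyte_uM: np.ndarray
    time_assoc_s: np.ndarray
    association: np.ndarray   # (n_times, n_analyte), response units
    time_dissoc_s: np.ndarray
    dissociation: np.ndarray
    req: np.ndarray           # equilibrium response per analyte conc
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.analyte_uM, dtype=float)
        if np.any(a <= 0):
            raise ValueError("analyte concentrations must be positive")
        if np.unique(a).size != a.size:
            raise ValueError("analyte concentrations must be unique")
        object.__setattr__(self, "analyte_uM", a)


def log_time_grid(t_min: float, t_max: float, n: int = 400) -> np.ndarray:
    """Log-spaced time grid resolving phases separated by >1000-fold."""
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    return np.geomspace(t_min, t_max, n)


# --- generators -------------------------------------------------------------

def generate_rapid_scan(mechanism: SequentialModel, library: SpeciesLibrary,
                        conditions: ExperimentConditions, noise: NoiseModel,
                        time_s: np.ndarray,
                        grid_nm: np.ndarray | None = None) -> RapidScanDataset:
    """Beer-Lambert rapid-scan matrix of a sequential mechanism plus noise.

    Recorded t = 0 is the end of the instrument dead time: concentrations
    are evaluated at t + dead_time_s after mixing.
    """
    missing = [n for n in mechanism.species_names if n not in library]
    if missing:
        raise KeyError(f"mechanism species not in library: {missing}")
    t = np.asarray(time_s, dtype=float)
    if t.size == 0 or t[0] < 0:
        raise ValueError("time grid must be nonempty and nonnegative")
    grid = library.grid_nm if grid_nm is None else np.asarray(grid_nm, float)
    traj = simulate_sequential(mechanism, conditions.enzyme_uM,
                               t + conditions.dead_time_s)
    E = library.epsilon_matrix(list(mechanism.species_names))  # (nl, ns)
    if grid_nm is not None:
        idx = [int(np.argmin(np.abs(library.grid_nm - lam))) for lam in grid]
        E = E[idx]
    A = (traj.concentrations / 1000.0 * conditions.pathlength_cm) @ E.T
    if noise.sigma_AU > 0:
        A = A + noise.rng().normal(0.0, noise.sigma_AU, size=A.shape)
    prov = {
        "generator": "generate_rapid_scan",
        "species": list(mechanism.species_names),
        "rates_per_s": list(mechanism.rates),
        "enzyme_uM": conditions.enzyme_uM,
        "dead_time_s": conditions.dead_time_s,
        "pathlength_cm": conditions.pathlength_cm,
        "sigma_AU": noise.sigma_AU,
        "seed": noise.seed,
    }
    return RapidScanDataset(t, grid, A, conditions, prov)


def generate_timecourse(phases: Sequence[tuple[float, float]], offset: float,
                        noise: NoiseModel, time_s: np.ndarray,
                        wavelength_nm: float, direction: str = "rise",
                        conditions: ExperimentConditions | None = None,
                        ) -> TimeCourse:
    """Multi-exponential single-wavelength trace.

    ``phases`` is a list of (k_obs s^-1, amplitude AU).  Rising traces
    (heme reduction followed at A427) use offset + sum a_i (1 - e^{-k t});
    decaying traces (heme oxidation) use offset + sum a_i e^{-k t}.
    """
    if not phases:
        raise ValueError("phase list must be nonempty")
    if direction not in ("rise", "decay"):
        raise ValueError("direction must be 'rise' or 'decay'")
    if any(k <= 0 for k, _ in phases):
        raise ValueError("all k_obs must be > 0")
    t = np.asarray(time_s, dtype=float)
    a = np.full_like(t, float(offset))
    for k, amp in phases:
        e = np.exp(-k * t)
        a += amp * (1.0 - e) if direction == "rise" else amp * e
    if noise.sigma_AU > 0:
        a = a + noise.rng().normal(0.0, noise.sigma_AU, size=a.shape)
    prov = {
        "generator": "generate_timecourse",
        "phases": [[float(k), float(amp)] for k, amp in phases],
        "offset": float(offset),
        "direction": direction,
        "sigma_AU": noise.sigma_AU,
        "seed": noise.seed,
    }
    return TimeCourse(float(wavelength_nm), t, a, conditions, prov)


@dataclass(frozen=True)
class HyperbolicLaw:
    """Saturation of k_obs with substrate: k_obs = Vmax [S] / (KM + [S])."""

    vmax: float  # s^-1
    km: float    # uM

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("vmax and km must be > 0")

    def k_obs(self, substrate_uM: np.ndarray) -> np.ndarray:
        s = np.asarray(substrate_uM, dtype=float)
        return self.vmax * s / (self.km + s)


@dataclass(frozen=True)
class LinearLaw:
    """Pseudo-first-order binding: k_obs = k_on [S] + k_off."""

    k_on: float   # M^-1 s^-1
    k_off: float  # s^-1

    def __post_init__(self) -> None:
        if self.k_on <= 0:
            raise ValueError("k_on must be > 0")
        if self.k_off < 0:
            raise ValueError("k_off must be >= 0")

    def k_obs(self, substrate_uM: np.ndarray) -> np.ndarray:
        s = np.asarray(substrate_uM, dtype=float)
        return self.k_on * s * 1e-6 + self.k_off


def generate_titration(law: HyperbolicLaw | LinearLaw,
                       substrate_uM: Sequence[float],
                       noise_frac: float = 0.0,
                       seed: int = 0) -> TitrationTable:
    """k_obs table from a rate law, with multiplicative noise (1 + frac*N)."""
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    s = np.asarray(substrate_uM, dtype=float)
    if np.any(s <= 0):
        raise ValueError("substrate concentrations must be positive")
    if s.size < 3:
        raise ValueError("need >= 3 substrate points for downstream fitting")
    k = law.k_obs(s)
    if noise_frac > 0:
        k = k * (1.0 + noise_frac * np.random.default_rng(seed).standard_normal(s.size))
    prov = {"generator": "generate_titration", "law": type(law).__name__,
            "truth": vars(law) if hasattr(law, "__dict__") else
            {f: getattr(law, f) for f in law.__dataclass_fields__},
            "noise_frac": noise_frac, "seed": seed}
    return TitrationTable(s, k, prov)


def generate_bli(true_kd_uM: float, rmax: float,
                 analyte_uM: Sequence[float], k_off_s: float,
                 noise: NoiseModel, seed: int | None = None,
                 req_noise_frac: float = 0.0,
                 t_assoc_s: float = 120.0, t_dissoc_s: float = 120.0,
                 n_points: int = 200) -> BLISeries:
    """Dose-response BLI series.

    Association R(t) = Req (1 - e^{-k_obs t}) with k_obs = k_on [A] + k_off
    and k_on = k_off / K_D; dissociation R(t) = Req e^{-k_off t};
    Req = Rmax [A] / (K_D + [A]).  ``req_noise_frac`` applies multiplicative
    Gaussian noise to each trace's Req; ``noise.sigma_AU`` adds pointwise
    noise to the traces.
    """
    if true_kd_uM <= 0:
        raise ValueError("K_D must be > 0")
    if rmax <= 0 or k_off_s <= 0:
        raise ValueError("rmax and k_off_s must be > 0")
    conc = np.asarray(analyte_uM, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("analyte concentrations must be positive")
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    k_on = k_off_s / true_kd_uM  # uM^-1 s^-1
    t_a = np.linspace(0.0, t_assoc_s, n_points)
    t_d = np.linspace(0.0, t_dissoc_s, n_points)
    req_true = rmax * conc / (true_kd_uM + conc)
    req = req_true.copy()
    if req_noise_frac > 0:
        req = req_true * (1.0 + req_noise_frac * rng.standard_normal(conc.size))
    assoc = np.empty((t_a.size, conc.size))
    dissoc = np.empty((t_d.size, conc.size))
    for j, (a, r) in enumerate(zip(conc, req)):
        k_obs = k_on * a + k_off_s
        assoc[:, j] = r * (1.0 - np.exp(-k_obs * t_a))
        dissoc[:, j] = r * np.exp(-k_off_s * t_d)
    if noise.sigma_AU > 0:
        assoc = assoc + rng.normal(0.0, noise.sigma_AU, size=assoc.shape)
        dissoc = dissoc + rng.normal(0.0, noise.sigma_AU, size=dissoc.shape)
    prov = {"generator": "generate_bli", "true_kd_uM": float(true_kd_uM),
            "rmax": float(rmax), "k_off_s": float(k_off_s),
            "req_noise_frac": req_noise_frac, "sigma": noise.sigma_AU,
            "seed": int(noise.seed if seed is None else seed)}
    return BLISeries(conc, t_a, assoc, t_d, dissoc, req, prov)
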