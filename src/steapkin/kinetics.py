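"""Forward integration of the kinetic mechanisms.

Three mechanisms cover the experiments analysed here:

* ``SequentialModel`` — irreversible first-order chain A -> B -> ... used for
  rapid-scan deconvolution (e.g. reduction of STEAP1 by b5R resolves three
  sequential species).  Solved in closed form (Bateman equations) unless two
  rate constants are nearly degenerate, in which case the chain generator is
  exponentiated numerically.
* ``TwoPopulationBindingModel`` — pseudo-first-order oxidation of ferrous
  heme by a ferric substrate in excess, with two enzyme populations each
  decaying at k_obs = k_on [S] + k_off (the model parameterized by the
  k_obs-vs-[S] linear fits).
* ``ShuttleChainModel`` — the full NADPH -> FAD -> heme -> Fe3+ electron
  shuttle with a diffusible reduced flavin, integrated as mass-action ODEs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

__all__ = [
    "SequentialModel",
    "TwoPopulationBindingModel",
    "ShuttleChainModel",
    "ConcentrationTrajectory",
    "simulate_sequential",
    "simulate_two_population_oxidation",
    "simulate_shuttle_chain",
    "PseudoFirstOrderWarning",
]

#: relative rate-constant gap below which the Bateman form is abandoned
DEGENERACY_RTOL = 1e-6


class PseudoFirstOrderWarning(UserWarning):
    """Substrate excess too small for the pseudo-first-order approximation."""


@dataclass(frozen=True)
class ConcentrationTrajectory:
    """Species concentrations (uM) on a time grid (s)."""

    time_s: np.ndarray
    concentrations: np.ndarray  # (n_times, n_species)
    species_names: tuple[str, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if c.shape != (t.size, len(self.species_names)):
            raise ValueError("concentration matrix shape mismatch")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "concentrations", c)

    def total(self) -> np.ndarray:
        """Per-time total concentration (uM)."""
        return self.concentrations.sum(axis=1)

    def species(self, name: str) -> np.ndarray:
        return self.concentrations[:, self.species_names.index(name)]


@dataclass(frozen=True)
class SequentialModel:
    """Irreversible first-order chain; n_species = n_rates + 1."""

    species_names: tuple[str, ...]
    rates: tuple[float, ...]  # s^-1, k1..k_{n-1}

    def __post_init__(self) -> None:
        names = tuple(self.species_names)
        rates = tuple(float(k) for k in self.rates)
        if len(names) != len(rates) + 1:
            raise ValueError("need n_species = n_rates + 1")
        if any(k <= 0 for k in rates):
            raise ValueError("all rates must be > 0")
        object.__setattr__(self, "species_names", names)
        object.__setattr__(self, "rates", rates)

    @property
    def n_species(self) -> int:
        return len(self.species_names)


def _chain_generator(rates: Sequence[float]) -> np.ndarray:
    """Rate matrix K of the chain: dc/dt = K c."""
    n = len(rates) + 1
    K = np.zeros((n, n))
    for i, k in enumerate(rates):
        K[i, i] -= k
        K[i + 1, i] += k
    return K


def bateman_fractions(rates: Sequence[float], time_s: np.ndarray) -> np.ndarray:
    """Fractional populations of a first-order chain starting as pure A.

    Uses the Bateman closed form when all effective decay constants
    (k_1..k_{n-1}, 0 for the terminal species) are mutually distinct by more
    than ``DEGENERACY_RTOL`` relative; otherwise falls back to the matrix
    exponential of the chain generator, which has no cancellation problem.
    Returns an (n_times, n_species) matrix whose rows sum to 1.
    """
    rates = [float(k) for k in rates]
    t = np.asarray(time_s, dtype=float)
    ks = np.array(rates + [0.0])  # decay constant per species
    n = ks.size
    scale = max(ks.max(), 1.0)
    degenerate = any(
        abs(ks[i] - ks[j]) <= DEGENERACY_RTOL * scale
        for i in range(n) for j in range(i + 1, n)
    )
    if degenerate:
        K = _chain_generator(rates)
        c0 = np.zeros(n)
        c0[0] = 1.0
        return np.array([expm(K * ti) @ c0 for ti in t])

    C = np.zeros((t.size, n))
    exps = np.exp(-np.outer(t, ks))  # (nt, n)
    for i in range(n):
        pref = np.prod(ks[:i]) if i else 1.0
        acc = np.zeros(t.size)
        for j in range(i + 1):
            denom = 1.0
            for l in range(i + 1):
                if l != j:
                    denom *= ks[l] - ks[j]
            acc += exps[:, j] / denom
        C[:, i] = pref * acc
    # clip tiny negative round-off
    return np.clip(C, 0.0, None)


def _check_time_grid(time_s: np.ndarray) -> np.ndarray:
    t = np.asarray(time_s, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be 1-D with >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if t[0] < 0:
        raise ValueError("time grid must start at t >= 0")
    return t


def simulate_sequential(model: SequentialModel, c0: float,
                        time_s: np.ndarray) -> ConcentrationTrajectory:
    """Integrate the chain from pure first species at concentration c0 (uM)."""
    if c0 <= 0:
        raise ValueError("c0 must be > 0")
    t = _check_time_grid(time_s)
    C = c0 * bateman_fractions(model.rates, t)
    return ConcentrationTrajectory(t, C, model.species_names)


@dataclass(frozen=True)
class TwoPopulationBindingModel:
    """Two enzyme populations, each oxidized pseudo-first-order by substrate.

    k_obs,i = k_on,i [S] + k_off,i with k_on in M^-1 s^-1 and [S] in uM.
    """

    fractions: tuple[float, float]
    k_on: tuple[float, float]   # M^-1 s^-1
    k_off: tuple[float, float]  # s^-1

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.fractions)
        kon = tuple(float(x) for x in self.k_on)
        koff = tuple(float(x) for x in self.k_off)
        if len(f) != 2 or len(kon) != 2 or len(koff) != 2:
            raise ValueError("model is defined by exactly two populations")
        if any(not 0.0 <= x <= 1.0 for x in f):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 within 1e-9")
        if any(x <= 0 for x in kon):
            raise ValueError("k_on must be > 0")
        if any(x < 0 for x in koff):
            raise ValueError("k_off must be >= 0")
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "k_on", kon)
        object.__setattr__(self, "k_off", koff)

    def observed_rates(self, substrate_uM: float) -> tuple[float, float]:
        """Per-population k_obs (s^-1) at a substrate concentration (uM)."""
        if substrate_uM < 0:
            raise ValueError("substrate concentration must be >= 0")
        s_M = substrate_uM * 1e-6
        return tuple(kon * s_M + koff
                     for kon, koff in zip(self.k_on, self.k_off))


def simulate_two_population_oxidation(model: TwoPopulationBindingModel,
                                      substrate_uM: float, e0: float,
                                      time_s: np.ndarray) -> np.ndarray:
    """Ferrous-heme concentration trace (uM) under substrate excess.

    ferrous(t) = e0 * sum_i f_i exp(-(k_on,i [S] + k_off,i) t); valid when
    [S] >> e0 (a warning is emitted below 10x excess).
    """
    if substrate_uM < 0:
        raise ValueError("substrate concentration must be >= 0")
    if e0 <= 0:
        raise ValueError("e0 must be > 0")
    t = _check_time_grid(time_s)
    if substrate_uM < 10.0 * e0:
        warnings.warn(
            f"substrate excess {substrate_uM / e0:.2f}x < 10x: "
            "pseudo-first-order approximation may be poor",
            PseudoFirstOrderWarning, stacklevel=2,
        )
    rates = model.observed_rates(substrate_uM)
    trace = np.zeros_like(t)
    for f, k in zip(model.fractions, rates):
        trace += f * np.exp(-k * t)
    return e0 * trace


@dataclass(frozen=True)
class ShuttleChainModel:
    """Diffusible-FAD electron shuttle from NADPH to a ferric substrate.

    NADPH reduces FAD bound at the oxidoreductase site (hydride transfer,
    k_hyd, effective first-order in NADPH gated by the oxidized-FAD
    fraction); the reduced flavin exchanges between a free pool and a
    heme-proximal bound pool (k_bind_steap1/k_bind_steap2 weighted by heme
    pool sizes, k_release); bound FADH- reduces ferric heme in two
    sequential one-electron steps at k_et (gated by the ferric fraction);
    ferrous heme reduces the ferric substrate at k_sub.  All pools in uM.
    """

    k_hyd: float = 1e-3        # s^-1, NADPH -> FADH- (rate-limiting in vivo)
    k_release: float = 1.0     # s^-1, bound FADH- -> free
    k_bind_steap1: float = 1.0  # s^-1, free FADH- -> STEAP1-bound
    k_bind_steap2: float = 1.0  # s^-1, free FADH- -> STEAP2-bound
    k_et: float = 10.0          # s^-1, per one-electron FADH- -> heme step
    k_sub: float = 0.0          # s^-1, ferrous heme -> Fe3+ substrate
    nadph_uM: float = 60.0
    fad_uM: float = 2.2
    steap1_heme_uM: float = 0.9
    steap2_heme_uM: float = 1.1
    fe3_uM: float = 0.0
    #: soft saturation constant for the substrate gate (uM)
    substrate_gate_uM: float = 1.0
    electrons_per_fadh: int = 2

    def __post_init__(self) -> None:
        rates = (self.k_hyd, self.k_release, self.k_bind_steap1,
                 self.k_bind_steap2, self.k_et, self.k_sub)
        pools = (self.nadph_uM, self.fad_uM, self.steap1_heme_uM,
                 self.steap2_heme_uM, self.fe3_uM)
        if any(k < 0 for k in rates):
            raise ValueError("all rate constants must be >= 0")
        if all(k == 0 for k in rates):
            raise ValueError("degenerate model: all rate constants are zero")
        if any(p < 0 for p in pools):
            raise ValueError("all pools must be >= 0")
        if self.steap1_heme_uM + self.steap2_heme_uM <= 0:
            raise ValueError("at least one heme pool must be > 0")
        if self.electrons_per_fadh not in (1, 2):
            raise ValueError("electrons_per_fadh must be 1 or 2")


SHUTTLE_SPECIES = ("nadph", "fad_ox", "fadh_free", "fadh_bound",
                   "fad_semi_bound", "heme_ferric", "heme_ferrous",
                   "fe3", "fe2")


def simulate_shuttle_chain(model: ShuttleChainModel,
                           time_s: np.ndarray) -> ConcentrationTrajectory:
    """Integrate the shuttle mechanism with a stiff-capable solver.

    Electron bookkeeping holds on every stored point: electrons residing on
    (heme_ferrous + Fe2+ + 2 x reduced-flavin pools + semiquinone) never
    exceed 2 x NADPH consumed.
    """
    t = _check_time_grid(time_s)
    m = model
    heme_total = m.steap1_heme_uM + m.steap2_heme_uM
    fad_total = m.fad_uM
    k_bind = (m.k_bind_steap1 * m.steap1_heme_uM
              + m.k_bind_steap2 * m.steap2_heme_uM) / heme_total
    two_step = m.electrons_per_fadh == 2

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        (nadph, fad_ox, fadh_free, fadh_bound, semi,
         ferric, ferrous, fe3, fe2) = y
        f_ox = fad_ox / fad_total if fad_total > 0 else 0.0
        f_ferric = max(ferric, 0.0) / heme_total
        v_hyd = m.k_hyd * max(nadph, 0.0) * f_ox
        v_bind = k_bind * max(fadh_free, 0.0)
        v_rel = m.k_release * max(fadh_bound, 0.0)
        v_et1 = m.k_et * max(fadh_bound, 0.0) * f_ferric
        if two_step:
            v_et2 = m.k_et * max(semi, 0.0) * f_ferric
        else:
            v_et2 = 0.0
        v_sub = (m.k_sub * max(ferrous, 0.0)
                 * max(fe3, 0.0) / (max(fe3, 0.0) + m.substrate_gate_uM)
                 if m.k_sub > 0 else 0.0)
        dy = np.empty(9)
        dy[0] = -v_hyd                              # NADPH
        dy[1] = -v_hyd + (v_et2 if two_step else v_et1)  # FAD_ox (regenerated)
        dy[2] = v_hyd - v_bind + v_rel              # FADH- free
        dy[3] = v_bind - v_rel - v_et1              # FADH- bound
        dy[4] = (v_et1 - v_et2) if two_step else 0.0  # semiquinone bound
        n_e = v_et1 + v_et2
        dy[5] = -n_e + v_sub                        # heme ferric
        dy[6] = n_e - v_sub                         # heme ferrous
        dy[7] = -v_sub                              # Fe3+
        dy[8] = v_sub                               # Fe2+
        return dy

    y0 = np.array([m.nadph_uM, m.fad_uM, 0.0, 0.0, 0.0,
                   heme_total, 0.0, m.fe3_uM, 0.0])
    sol = solve_ivp(rhs, (t[0], t[-1]), y0, t_eval=t, method="LSODA",
                    rtol=1e-8, atol=1e-12)
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"shuttle-chain integration failed: {sol.message}")
    C = np.clip(sol.y.T, 0.0, None)
    return ConcentrationTrajectory(t, C, SHUTTLE_SPECIES)


def electron_balance(traj: ConcentrationTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """(electrons held, electrons supplied) per time point, uM electrons.

    Held = ferrous + Fe2+ + 2 x (free + bound FADH-) + 1 x semiquinone;
    supplied = 2 x NADPH consumed.
    """
    c = {n: traj.species(n) for n in SHUTTLE_SPECIES}
    held = (c["heme_ferrous"] + c["fe2"]
            + 2.0 * (c["fadh_free"] + c["fadh_bound"]) + c["fad_semi_bound"])
    supplied = 2.0 * (c["nadph"][0] - c["nadph"])
    return held, supplied
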