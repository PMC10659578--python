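"""End-to-end reproduction checks of the published kinetic quantities.

Each check regenerates its synthetic dataset from the fixture conditions,
runs the corresponding fit, and compares the recovered quantity with the
published value at a stated tolerance.  ``reproduce_paper`` aggregates all
checks into a tidy report (one row per quantity, citing fixture and seeds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fixtures
from .deconvolution import deconvolve_sequential
from .fitting import compute_kd, fit_bli, fit_hyperbolic, fit_multiexponential

__all__ = [
    "CheckResult",
    "check_kd_arithmetic",
    "check_biphasic_recovery",
    "check_hyperbolic_self_consistency",
    "check_deconvolution_recovery",
    "check_mutant_vmax_ratio",
    "check_bli_recovery",
    "reproduce_paper",
]

#: Published kon/koff pairs (M^-1 s^-1, s^-1) and K_D (uM) for Fe3+-NTA.
TABLE1_NTA = (
    ("STEAP1 fast", 1.5e5, 7.5, 50.0),
    ("STEAP1 slow", 7.6e3, 0.2, 26.3),
    ("STEAP2 fast", 1.1e4, 2.2, 200.0),
    ("STEAP2 slow", 3.5e3, 0.3, 85.7),
)


@dataclass(frozen=True)
class CheckResult:
    target: str
    expected: float
    computed: float
    rel_dev: float
    tolerance: float
    passed: bool
    fixture: str
    seeds: str

    @staticmethod
    def build(target: str, expected: float, computed: float, tol: float,
              fixture_name: str, seeds: str) -> "CheckResult":
        rel = abs(computed - expected) / abs(expected) if expected else np.inf
        return CheckResult(target, expected, computed, rel, tol, rel <= tol,
                           fixture_name, seeds)


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return float(np.format_float_positional(
        x, precision=sig, unique=False, fractional=False, trim="k"))


def check_kd_arithmetic() -> list[CheckResult]:
    """K_D = k_off/k_on reproduces the four published values to 3 s.f."""
    out = []
    for label, kon, koff, kd_published in TABLE1_NTA:
        kd = compute_kd(kon, koff)
        out.append(CheckResult.build(
            f"K_D {label} (uM)", kd_published, _round_sig(kd, 3), 1e-9,
            "table1", "n/a"))
    return out


def check_biphasic_recovery(seed0: int = 0, n_seeds: int = 20,
                            ) -> list[CheckResult]:
    """Mean biphasic fit over noisy A427 rises recovers 7.7 s^-1 and 60%."""
    ks, fracs = [], []
    for seed in range(seed0, seed0 + n_seeds):
        tc = fixtures.timecourse("fig2A_fadh_steap1", seed=seed)
        fit = fit_multiexponential(tc, 2, direction="rise")
        ks.append(fit.phases[0].k_obs)
        fracs.append(fit.phases[0].fraction)
    seeds = f"{seed0}..{seed0 + n_seeds - 1}"
    return [
        CheckResult.build("fast-phase k_obs (s^-1)", 7.7,
                          float(np.mean(ks)), 0.05,
                          "fig2A_fadh_steap1", seeds),
        CheckResult("fast-phase fraction (%)", 60.0, float(np.mean(fracs)),
                    abs(float(np.mean(fracs)) - 60.0) / 60.0, 5.0 / 60.0,
                    abs(float(np.mean(fracs)) - 60.0) <= 5.0,
                    "fig2A_fadh_steap1", seeds),
    ]


WT_TITRATION_SUBSTRATE_UM = (1.0, 2.0, 5.0, 10.0, 20.0)


def check_hyperbolic_self_consistency() -> list[CheckResult]:
    """Noiseless saturation points refit to Vmax = 12 s^-1, KM = 4.7 uM."""
    table = fixtures.titration("fig2A_fadh_steap1", phase="fast",
                               substrate_uM=WT_TITRATION_SUBSTRATE_UM)
    fit = fit_hyperbolic(table)
    return [
        CheckResult.build("Vmax fast phase (s^-1)", 12.0, fit.vmax, 1e-6,
                          "fig2A_fadh_steap1", "noiseless"),
        CheckResult.build("KM fast phase (uM)", 4.7, fit.km, 1e-6,
                          "fig2A_fadh_steap1", "noiseless"),
    ]


def check_deconvolution_recovery(seed0: int = 0, n_seeds: int = 10,
                                 ) -> list[CheckResult]:
    """Global analysis recovers the slow interconversion rates.

    Three-species b5R -> STEAP1 reduction: mean recovered B -> C rate vs
    0.13 s^-1 over noisy replicates; two-species NADPH-driven STEAP2
    reduction: recovered rate vs 1.2e-3 s^-1.
    """
    slow = []
    for seed in range(seed0, seed0 + n_seeds):
        ds = fixtures.rapid_scan("fig3A_b5r", seed=seed)
        res = deconvolve_sequential(ds, 3, init_rates=(100.0, 1.0))
        slow.append(float(np.min(res.rates)))
    ds2 = fixtures.rapid_scan("fig4s1_steap2_nadph", seed=seed0)
    res2 = deconvolve_sequential(ds2, 2)
    return [
        CheckResult.build("B->C rate, b5R/STEAP1 (s^-1)", 0.13,
                          float(np.mean(slow)), 0.10, "fig3A_b5r",
                          f"{seed0}..{seed0 + n_seeds - 1}"),
        CheckResult.build("A->B rate, STEAP2/NADPH (s^-1)", 1.2e-3,
                          float(res2.rates[0]), 0.10, "fig4s1_steap2_nadph",
                          str(seed0)),
    ]


def check_mutant_vmax_ratio() -> list[CheckResult]:
    """Fast-phase Vmax of wild type exceeds L230G by at least 5-fold."""
    wt = fit_hyperbolic(fixtures.titration(
        "fig2A_fadh_steap1", "fast", substrate_uM=WT_TITRATION_SUBSTRATE_UM))
    mut = fit_hyperbolic(fixtures.titration(
        "fig2s1_L230G", "fast", substrate_uM=WT_TITRATION_SUBSTRATE_UM))
    ratio = wt.vmax / mut.vmax
    return [CheckResult("Vmax ratio WT/L230G", 5.0, float(ratio), 0.0, 0.0,
                        ratio >= 5.0, "fig2s1_L230G", "noiseless")]


def check_bli_recovery(seed0: int = 0, n_seeds: int = 20) -> list[CheckResult]:
    """Mean dose-response K_D over noisy BLI series vs 5.9 uM."""
    kds = []
    for seed in range(seed0, seed0 + n_seeds):
        series = fixtures.bli(seed=seed)
        kds.append(fit_bli(series).kd_uM)
    return [CheckResult.build("BLI K_D b5R-STEAP1 (uM)", 5.9,
                              float(np.mean(kds)), 0.10, "bli_b5r",
                              f"{seed0}..{seed0 + n_seeds - 1}")]


def reproduce_paper(seed: int = 0) -> pd.DataFrame:
    """Run every reproduction check; one row per published quantity."""
    rows: list[CheckResult] = []
    rows += check_kd_arithmetic()
    rows += check_biphasic_recovery(seed0=seed)
    rows += check_hyperbolic_self_consistency()
    rows += check_deconvolution_recovery(seed0=seed)
    rows += check_mutant_vmax_ratio()
    rows += check_bli_recovery(seed0=seed)
    return pd.DataFrame([vars(r) for r in rows])
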