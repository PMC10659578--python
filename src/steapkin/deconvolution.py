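"""Global analysis of rapid-scan matrices into sequential kinetic species.

A time x wavelength absorbance matrix A is modelled bilinearly as
A = C(t; k) S^T where C contains the Bateman populations of an
irreversible first-order chain and S the species spectra.  Rank estimation
uses the singular-value spectrum plus a lag-1 autocorrelation test on the
right singular vectors; rate fitting uses variable projection (nonlinear
search over log rate constants with spectra solved linearly, optionally
nonnegativity-constrained, at each iterate).

The scale/permutation ambiguity of bilinear fits is resolved by fixing the
concentration profiles to fractional populations (per-time sum of 1) and
ordering species by time of maximal population, so converged runs from
different starting rates return identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from .kinetics import bateman_fractions
from .synth import RapidScanDataset

__all__ = [
    "SVDDecomposition",
    "DeconvolutionResult",
    "IllConditionedWarning",
    "DegenerateDataWarning",
    "estimate_rank",
    "deconvolve_sequential",
    "reconstruct",
]


class IllConditionedWarning(UserWarning):
    """Fitted rates nearly equal or a species never populated."""


class DegenerateDataWarning(UserWarning):
    """Matrix carries no resolvable kinetic signal."""


@dataclass(frozen=True)
class SVDDecomposition:
    singular_values: np.ndarray  # descending
    left_vectors: np.ndarray     # (n_times, n_components), time profiles
    right_vectors: np.ndarray    # (n_wavelengths, n_components), spectra
    estimated_rank: int


@dataclass(frozen=True)
class DeconvolutionResult:
    n_species: int
    rates: np.ndarray               # s^-1, length n_species - 1
    species_spectra: np.ndarray     # (n_wavelengths, n_species), AU per unit fraction
    concentration_profiles: np.ndarray  # (n_times, n_species), fractions
    residual_norm: float            # Frobenius norm of A - C S^T
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.rates) <= 0):
            raise ValueError("all fitted rates must be positive")


def _lag1_autocorr(v: np.ndarray) -> float:
    x = v - v.mean()
    denom = x @ x
    if denom == 0:
        return 0.0
    return float((x[:-1] @ x[1:]) / denom)


def estimate_rank(dataset: RapidScanDataset, sv_threshold: float = 1e-3,
                  autocorr_threshold: float = 0.8) -> SVDDecomposition:
    """Number of spectrally distinct kinetic components in the matrix.

    A component counts toward the rank when its singular value exceeds
    ``sv_threshold`` x the largest singular value AND its right singular
    vector (a spectrum) has lag-1 autocorrelation above
    ``autocorr_threshold`` — signal spectra are smooth in wavelength,
    noise vectors are not.
    """
    A = dataset.absorbance
    if A.shape[0] < 3 or A.shape[1] < 3:
        raise ValueError("need >= 3 time points and >= 3 wavelengths")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    if s[0] == 0:
        warnings.warn("all-zero matrix: rank 0", DegenerateDataWarning,
                      stacklevel=2)
        return SVDDecomposition(s, U, Vt.T, 0)
    rank = 0
    for i in range(s.size):
        if s[i] > sv_threshold * s[0] and \
                _lag1_autocorr(Vt[i]) > autocorr_threshold:
            rank += 1
        else:
            break
    if rank <= 1:
        if np.allclose(A, A[0], rtol=0, atol=1e-12 * max(1.0, abs(A).max())):
            warnings.warn("static matrix (all rows equal): rank 1",
                          DegenerateDataWarning, stacklevel=2)
            rank = 1
        elif rank == 0:
            warnings.warn("no component passed the rank criteria: the matrix"
                          " looks like pure noise", DegenerateDataWarning,
                          stacklevel=2)
    return SVDDecomposition(s, U, Vt.T, rank)


def _solve_spectra(C: np.ndarray, A: np.ndarray,
                   nonneg: bool) -> np.ndarray:
    """Solve min ||A - C S^T||_F for S, per wavelength; (nl, ns)."""
    if not nonneg:
        S, *_ = np.linalg.lstsq(C, A, rcond=None)
        return S.T
    nl = A.shape[1]
    S = np.empty((nl, C.shape[1]))
    for j in range(nl):
        S[j], _ = nnls(C, A[:, j])
    return S


def deconvolve_sequential(dataset: RapidScanDataset, n_species: int,
                          init_rates="auto",
                          nonneg_spectra: bool = True) -> DeconvolutionResult:
    """Fit a sequential A -> B -> ... model to a rapid-scan matrix.

    Variable projection: ``least_squares`` runs over log rate constants; at
    each iterate the Bateman concentration matrix C(t; k) is formed (time
    axis offset by the recorded instrument dead time, so the chain starts
    at mixing) and the spectra S are solved linearly, by nonnegative least
    squares by default.  Species are ordered by time of maximal population;
    concentration profiles are fractional (rows sum to 1).
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    A = dataset.absorbance
    dead = float(dataset.provenance.get("dead_time_s", 0.0) or 0.0)
    t = dataset.time_s + dead

    def residual(log_k: np.ndarray) -> np.ndarray:
        C = bateman_fractions(np.exp(log_k), t)
        S = _solve_spectra(C, A, nonneg_spectra)
        return (A - C @ S.T).ravel()

    n_rates = n_species - 1
    if isinstance(init_rates, str) and init_rates == "auto":
        k_lo, k_hi = 1.0 / t[-1], 10.0 / t[0]
        base = np.geomspace(k_hi, k_lo, n_rates) if n_rates > 1 \
            else np.array([np.sqrt(k_lo * k_hi)])
        starts = [base, base * 10.0, base * 0.1]
    else:
        starts = [np.asarray(init_rates, dtype=float)]
        if starts[0].size != n_rates or np.any(starts[0] <= 0):
            raise ValueError("init_rates must be n_species - 1 positive rates")

    best = None
    for k0 in starts:
        try:
            res = least_squares(residual, x0=np.log(k0), method="lm",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=4000)
        except Exception:
            continue
        sse = float(res.cost * 2.0)
        if best is None or sse < best[0]:
            best = (sse, res, k0)
    if best is None:
        raise RuntimeError("deconvolution failed to converge from any start")
    sse, res, start_used = best

    rates = np.exp(res.x)
    # sequential chain: rates are already associated with ordered species;
    # enforce the temporal-ordering convention explicitly
    C = bateman_fractions(rates, t)
    S = _solve_spectra(C, A, nonneg_spectra)
    order = np.argsort([t[int(np.argmax(C[:, i]))] if C[:, i].max() > 0
                        else np.inf for i in range(n_species)], kind="stable")
    C, S = C[:, order], S[:, order]

    if n_rates > 1:
        r = np.sort(rates)[::-1]
        if np.any(np.abs(np.diff(r)) <= 0.01 * r[:-1]):
            warnings.warn("fitted rates within 1% of each other: the model"
                          " is ill-conditioned", IllConditionedWarning,
                          stacklevel=2)
    # spectrally indistinguishable adjacent species leave their rate
    # unidentifiable (e.g. static data fitted with an extra species)
    s_scale = max(float(np.abs(S).max()), 1e-300)
    for i in range(n_species - 1):
        if np.linalg.norm(S[:, i] - S[:, i + 1]) \
                <= 1e-6 * s_scale * np.sqrt(S.shape[0]):
            warnings.warn(
                f"species {i + 1} and {i + 2} have indistinguishable spectra:"
                " their interconversion rate is ill-conditioned",
                IllConditionedWarning, stacklevel=2)
    # species that never accumulate are unconstrained: inherit the nearest
    # populated species' spectrum and flag the fit
    maxpop = C.max(axis=0)
    populated = np.flatnonzero(maxpop >= 1e-3)
    for i in np.flatnonzero(maxpop < 1e-3):
        nearest = populated[np.argmin(np.abs(populated - i))]
        S[:, i] = S[:, nearest]
        warnings.warn(
            f"species {i + 1} never exceeds 0.1% population: its spectrum is"
            " unconstrained (copied from the nearest populated species)",
            IllConditionedWarning, stacklevel=2,
        )

    resid_norm = float(np.linalg.norm(A - C @ S.T, "fro"))
    diag = {"nfev": int(res.nfev), "success": bool(res.success),
            "init_rates": [float(x) for x in start_used],
            "dead_time_s": dead, "nonneg_spectra": nonneg_spectra,
            "sse": sse}
    return DeconvolutionResult(n_species, rates, S, C, resid_norm, diag)


def reconstruct(dataset: RapidScanDataset, result: DeconvolutionResult,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Model matrix C S^T and residual map A - C S^T."""
    C, S = result.concentration_profiles, result.species_spectra
    if C.shape[0] != dataset.time_s.size or \
            S.shape[0] != dataset.grid_nm.size:
        raise ValueError("result dimensions do not match dataset")
    model = C @ S.T
    residual = dataset.absorbance - model
    return model, residual
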