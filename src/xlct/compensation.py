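"""Depth compensation of the single-view sensitivity matrix.

Detection sensitivity in diffuse optical imaging falls off nonlinearly
with depth, so a single-view measurement operator H is hypersensitive to
superficial voxels and reconstructions collapse toward the detector.  Two
diagonal weight matrices counteract this:

* ``W_d`` (data weight) carries a rough prior estimate of the solution —
  here a Tikhonov reconstruction — raised to an exponent q in [0.4, 0.8]
  that trades data fit against stability.
* ``W_m`` (model weight) levels the per-column dynamic range and norm of
  the sensitivity matrix: W_m[j,j] = beta_j / ||H_j||_2 with
  beta_j = 1 / |max(H_j) - min(H_j)|.

The reconstruction then runs on the transformed operator
H_tilde = H W_d W_m^-1 in the variable chi, and the concentration is
recovered from chi afterwards (see :func:`recover_rho` for the two
documented conventions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from ._errors import DataError, PriorDegenerateError

__all__ = [
    "CompensationWeights",
    "tikhonov_prior",
    "build_Wd",
    "build_Wm",
    "transform_system",
    "recover_rho",
    "default_alpha_reg",
]

log = logging.getLogger(__name__)


@dataclass
class CompensationWeights:
    """Diagonal depth-compensation weights (stored as 1-D diagonals)."""

    n_tilde: np.ndarray
    q: float
    wd: np.ndarray  # diagonal of W_d
    wm: np.ndarray  # diagonal of W_m
    beta: np.ndarray

    def __post_init__(self) -> None:
        for name, v in (("wd", self.wd), ("wm", self.wm)):
            if not np.all(np.isfinite(v)) or np.any(v <= 0):
                raise DataError(f"{name} diagonal must be strictly positive and finite")


def default_alpha_reg(H: np.ndarray) -> float:
    """Default Tikhonov strength: 1e-3 * trace(H^T H) / n_columns."""
    H = np.asarray(H)
    return 1e-3 * float(np.einsum("ij,ij->", H, H)) / H.shape[1]


def tikhonov_prior(
    H_meas: np.ndarray, phi_meas: np.ndarray, alpha_reg: float
) -> np.ndarray:
    """Minimizer of ||H n - phi||^2 + alpha ||n||^2 via the regularized
    normal equations (H^T H + alpha I) n = H^T phi."""
    H = np.asarray(H_meas, dtype=float)
    phi = np.asarray(phi_meas, dtype=float)
    if alpha_reg <= 0:
        raise DataError("alpha_reg must be > 0")
    if not (np.all(np.isfinite(H)) and np.all(np.isfinite(phi))):
        raise DataError("non-finite entries in H_meas or phi_meas")
    n = H.shape[1]
    A = H.T @ H + alpha_reg * np.eye(n)
    b = H.T @ phi
    c, low = scipy.linalg.cho_factor(A)
    return scipy.linalg.cho_solve((c, low), b)


def build_Wd(
    n_tilde: np.ndarray, q: float = 0.6, clip_floor_frac: float = 1e-4
) -> np.ndarray:
    """Diagonal of W_d: max(n_tilde, floor)^q with floor =
    clip_floor_frac * max(n_tilde); the clip keeps W_d invertible where the
    prior is zero or negative."""
    if not (0.0 < q <= 1.0):
        raise DataError("q must lie in (0, 1]")
    nt = np.asarray(n_tilde, dtype=float)
    top = nt.max() if nt.size else 0.0
    if not np.isfinite(top) or top <= 0:
        raise PriorDegenerateError("prior estimate has no positive entry")
    floor = clip_floor_frac * top
    return np.maximum(nt, floor) ** q


def build_Wm(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal of W_m and the normalization factors beta.

    beta_j = 1/|max(S_j) - min(S_j)| over column j of the sensitivity
    matrix; W_m[j,j] = beta_j / ||S_j||_2.  A constant column (zero range)
    gets the median of the valid entries, with a warning.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] < 1:
        raise DataError("S must be a 2-D matrix with at least one row")
    rng = np.abs(S.max(axis=0) - S.min(axis=0))
    norms = np.linalg.norm(S, axis=0)
    valid = (rng > 0) & (norms > 0)
    beta = np.empty(S.shape[1])
    wm = np.empty(S.shape[1])
    beta[valid] = 1.0 / rng[valid]
    wm[valid] = beta[valid] / norms[valid]
    if not valid.all():
        if not valid.any():
            raise DataError("every sensitivity column is constant")
        fill = float(np.median(wm[valid]))
        n_bad = int((~valid).sum())
        log.warning(
            "%d constant sensitivity column(s); W_m entries replaced by the "
            "median of valid entries (%.3e)",
            n_bad,
            fill,
        )
        wm[~valid] = fill
        beta[~valid] = fill * np.where(norms[~valid] > 0, norms[~valid], 1.0)
    return wm, beta


def transform_system(
    H_meas: np.ndarray, wd: np.ndarray, wm: np.ndarray
) -> np.ndarray:
    """H_tilde = H W_d W_m^-1, applied as a column scaling."""
    H = np.asarray(H_meas, dtype=float)
    wd = np.asarray(wd, dtype=float)
    wm = np.asarray(wm, dtype=float)
    if H.shape[1] != wd.shape[0] or H.shape[1] != wm.shape[0]:
        raise DataError("weight diagonals must match the column count of H")
    return H * (wd / wm)[None, :]


def recover_rho(
    chi: np.ndarray,
    wd: np.ndarray,
    wm: np.ndarray,
    mode: str = "consistent",
) -> np.ndarray:
    """Map the transformed unknown chi back to concentration rho.

    ``consistent`` (default): rho = W_d W_m^-1 chi, the substitution under
    which H rho = H_tilde chi exactly.  ``literal``: rho = W_m^-1 chi, the
    printed chi = W_m rho convention, which is only consistent with the
    transformed operator when W_d = I.  Negative entries are clamped to 0
    in both modes.
    """
    chi = np.asarray(chi, dtype=float)
    if not np.all(np.isfinite(chi)):
        raise DataError("chi must be finite")
    if mode == "consistent":
        rho = (np.asarray(wd) / np.asarray(wm)) * chi
    elif mode == "literal":
        rho = chi / np.asarray(wm)
    else:
        raise DataError(f"unknown recovery mode '{mode}'")
    log.debug("recover_rho mode=%s", mode)
    return np.maximum(rho, 0.0)
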