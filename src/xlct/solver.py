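"""L0-regularized reconstruction by restarted fast proximal gradient
descent (re-FPGD).

Inner loop (FPGD): accelerated proximal gradient on
f(chi) = ||H chi - phi||^2 + lam ||chi||_0 with Nesterov momentum
t_{k+1} = (1 + sqrt(1 + 4 t_k^2))/2, a support projection of the
extrapolated point, and the elementwise hard-threshold prox of the L0
term.  Two support-projection readings are provided: ``iterate`` projects
onto the support of the current iterate (entries may revive through the
gradient), while ``monotone`` maintains a shrinking permissible set - an
entry hard-thresholded to zero stays out until the next restart.  The
monotone reading is what makes the all-ones initialization prune: the
iterate starts on a flat "floor" of ones and only data-supported entries
outgrow the threshold.

Outer loop (restarting): after each inner solve, negative entries are
clamped to zero and the columns corresponding to zero entries are removed;
the reduced problem is re-solved from an all-ones start.  The loop stops
once at least 95 % of the full-length solution is zero, or when a round
prunes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._errors import DataError, DivergenceError, EmptySupportError

__all__ = [
    "SolverParams",
    "SolverTrace",
    "prox_l0",
    "support_projection",
    "momentum_update",
    "estimate_step",
    "fpgd_inner",
    "restart_outer",
]

log = logging.getLogger(__name__)


@dataclass
class SolverParams:
    """Tunable parameters of the restarted FPGD solver.

    lam : L0 regularization weight.  With ``lam_scale='auto'`` it is
        multiplied by ||H^T phi||_inf so the hard threshold is
        commensurate with unit-scale problems; ``'none'`` uses it as-is.
    threshold_floor : when set, overrides lam: the hard threshold
        sqrt(2 s lam_eff) is anchored at this multiple of the all-ones
        starting floor (lam_eff = threshold_floor^2 / (2 s)).  This is how
        the depth-compensated pipeline runs; see the methods note.
    inner_tol : relative iterate-change stopping threshold (inner loop).
    zero_frac : outer loop stops when this fraction of the full-length
        solution is exactly zero.
    support_mode : 'monotone' or 'iterate' (see module docstring).
    """

    lam: float = 1e-3
    lam_scale: str = "auto"  # 'auto' or 'none'
    threshold_floor: float | None = None
    inner_tol: float = 1e-5
    inner_max: int = 3000
    outer_max: int = 30
    zero_frac: float = 0.95
    step: float | None = None  # None -> 1/(2 sigma_max^2) by power iteration
    power_iters: int = 100
    support_mode: str = "monotone"
    seed: int = 0


@dataclass
class SolverTrace:
    """Per-outer-round log of the restarting solver."""

    rounds: list = field(default_factory=list)

    def append(self, **kw) -> None:
        self.rounds.append(kw)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rounds)


def prox_l0(v: np.ndarray, s: float, lam: float) -> np.ndarray:
    """Proximal operator of h = lam * ||.||_0 with step s.

    Elementwise hard threshold: keep v_i iff v_i^2 >= 2 s lam (the
    measure-zero tie is kept, for determinism); this minimizes
    (1/2)||x - v||^2 + s lam ||x||_0.
    """
    if s <= 0:
        raise DataError("step s must be > 0")
    if lam < 0:
        raise DataError("lam must be >= 0")
    v = np.asarray(v, dtype=float)
    if lam == 0.0:
        return v.copy()
    keep = v * v >= 2.0 * s * lam
    return np.where(keep, v, 0.0)


def support_projection(u: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the coordinate subspace of ``support``
    (an index array or boolean mask): entries outside the set are zeroed."""
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    out[support] = u[support]
    return out


def momentum_update(t_k: float) -> float:
    """Nesterov momentum recurrence t_{k+1} = (1 + sqrt(1 + 4 t_k^2)) / 2."""
    if t_k < 0:
        raise DataError("t_k must be >= 0")
    return (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k)) / 2.0


def estimate_step(H: np.ndarray, n_iters: int = 100, seed: int = 0) -> float:
    """Step s = 1/(2 sigma_max(H)^2), the inverse Lipschitz constant of
    grad ||H chi - phi||^2, with sigma_max^2 estimated by power iteration
    on H^T H."""
    H = np.asarray(H, dtype=float)
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(H.shape[1])
    v /= np.linalg.norm(v)
    sigma2 = 0.0
    for _ in range(n_iters):
        w = H.T @ (H @ v)
        nw = np.linalg.norm(w)
        if nw == 0:
            return 1.0
        sigma2 = nw
        v = w / nw
    return 1.0 / (2.0 * sigma2)


def fpgd_inner(
    H: np.ndarray,
    phi: np.ndarray,
    lam: float,
    s: float | None = None,
    inner_tol: float = 1e-5,
    max_iter: int = 3000,
    chi0: np.ndarray | None = None,
    seed: int = 0,
    support_mode: str = "monotone",
) -> tuple[np.ndarray, int]:
    """One FPGD solve of min ||H chi - phi||^2 + lam ||chi||_0.

    Returns ``(chi, n_iters)``.  ``lam`` is the absolute (already scaled)
    regularization weight.  The first iteration is a plain proximal
    gradient step (t_1 = 1 convention, since the t_0 = 0 extrapolation
    coefficient is undefined); later iterations extrapolate with
    (t_{k-1} - 1)/t_k and support-project the extrapolated point.
    """
    if support_mode not in ("monotone", "iterate"):
        raise DataError(f"unknown support_mode '{support_mode}'")
    H = np.asarray(H, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if s is None:
        s = estimate_step(H, seed=seed)
    chi = np.ones(H.shape[1]) if chi0 is None else np.asarray(chi0, dtype=float).copy()
    chi_prev = chi.copy()
    permissible = chi != 0.0
    t_prev = 1.0  # t_1
    k = 0
    for k in range(1, max_iter + 1):
        if k == 1:
            u = chi
        else:
            t_cur = momentum_update(t_prev)
            u = chi + ((t_prev - 1.0) / t_cur) * (chi - chi_prev)
            t_prev = t_cur
        if support_mode == "iterate":
            permissible = chi != 0.0
        z = np.where(permissible, u, 0.0)
        grad = 2.0 * (H.T @ (H @ z - phi))
        if not np.all(np.isfinite(grad)):
            raise DivergenceError(
                f"non-finite gradient at inner iteration {k} (s={s})"
            )
        chi_next = prox_l0(z - s * grad, s, lam)
        if support_mode == "monotone":
            permissible = permissible & (chi_next != 0.0)
            chi_next = np.where(permissible, chi_next, 0.0)
        delta = np.linalg.norm(chi_next - chi) / max(1.0, np.linalg.norm(chi))
        chi_prev, chi = chi, chi_next
        if delta < inner_tol:
            break
    return chi, k


def _effective_lam(H: np.ndarray, phi: np.ndarray, s: float, p: SolverParams) -> float:
    if p.threshold_floor is not None:
        return p.threshold_floor**2 / (2.0 * s)
    if p.lam_scale == "auto":
        scale = float(np.abs(H.T @ phi).max())
        return p.lam * scale if scale > 0 else p.lam
    return p.lam


def restart_outer(
    H: np.ndarray,
    phi: np.ndarray,
    params: SolverParams | None = None,
) -> tuple[np.ndarray, SolverTrace]:
    """Automated restarting loop around :func:`fpgd_inner` on a fixed
    matrix.

    Each round solves the reduced problem from an all-ones start, clamps
    negatives to zero, and drops the columns of the zero entries.  Returns
    the solution scattered back to full length plus a per-round trace.
    Raises :class:`EmptySupportError` when every entry is pruned (lam too
    large); if ``outer_max`` is reached, returns the best round by
    residual with a warning.
    """
    p = params or SolverParams()
    H = np.asarray(H, dtype=float)
    phi = np.asarray(phi, dtype=float)
    n = H.shape[1]
    active = np.arange(n)
    chi_full = np.zeros(n)
    trace = SolverTrace()
    best = None  # (residual, chi_full)
    for rnd in range(1, p.outer_max + 1):
        Hr = H[:, active]
        s = p.step if p.step is not None else estimate_step(Hr, p.power_iters, p.seed)
        lam_eff = _effective_lam(Hr, phi, s, p)
        chi_r, iters = fpgd_inner(
            Hr,
            phi,
            lam_eff,
            s=s,
            inner_tol=p.inner_tol,
            max_iter=p.inner_max,
            chi0=np.ones(len(active)),
            seed=p.seed,
            support_mode=p.support_mode,
        )
        chi_r = np.maximum(chi_r, 0.0)  # negative clamping
        chi_full = np.zeros(n)
        chi_full[active] = chi_r
        support = active[chi_r != 0.0]
        resid = float(np.linalg.norm(H @ chi_full - phi))
        zero_fraction = 1.0 - len(support) / n
        trace.append(
            round=rnd,
            inner_iters=iters,
            support_size=len(support),
            residual_l2=resid,
            sparsity_frac=zero_fraction,
        )
        if best is None or resid < best[0]:
            best = (resid, chi_full.copy())
        if len(support) == 0:
            raise EmptySupportError(
                "solver support collapsed to the empty set; try a smaller lam"
            )
        if zero_fraction >= p.zero_frac:
            return chi_full, trace
        if len(support) == len(active):
            # nothing was pruned: the restart is a fixed point
            log.info("restart fixed point at round %d (support %d)", rnd, len(support))
            return chi_full, trace
        active = support
    log.warning(
        "outer_max=%d reached; returning the best round by residual", p.outer_max
    )
    return best[1], trace
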