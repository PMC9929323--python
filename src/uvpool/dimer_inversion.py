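"""Nearest-neighbor dimeric damage model and its inversion.

A class's initial decay coefficient is, under the dimer model, a linear
combination of the 16 directional dimeric quantum yields phi_XY: every
adjacent base pair contributes its yield, pyrimidine-pyrimidine pairs
attenuated by ``(1 - q)`` per immediately adjacent guanine (charge-transfer
quenching), and pairs involving a randomized flank position enter with the
flank averaged uniformly over A, C, G, T (probability 1/4 that the flank
base is G for quench counting).

Two row conventions are provided:

* ``context="nearest"`` — only pairs touching the k-mer window itself: the
  internal pairs plus the two flank-junction pairs.  This is the classic
  i+1-dimer picture behind ``phi = mu/(i+1)``.
* ``context="pool"`` — all pairs of the full tailed construct that touch
  the randomized octamer, flank positions marginalized.  This is the exact
  expected hazard of a marginalized class under the forward model,
  including quenching that window-edge guanines exert on neighboring
  flank-flank pairs.  Inversions of pool-derived decay coefficients use
  these rows (differenced against the normalization reference class) so
  that the linear model matches what the measured coefficients actually
  estimate.

Because each guanine neighbor contributes a factor that is linear in
``t = 1 - q``, every coefficient is a quadratic polynomial in t; rows are
cached as (16, 3) tensors over the monomials t^0, t^1, t^2.

Besides the coefficient-space inversions (:func:`invert_naive`,
:func:`invert_quench`), the module provides :func:`fit_pool_model`, a joint
curve-level fit of the complete model that the analysis pipeline uses: for
heterogeneous classes a fitted decay coefficient is not the initial slope
(mixtures settle toward their slowest components), so yields near the
sensitivity floor are only recoverable from the curves themselves.
"""

from __future__ import annotations

import functools
import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar, nnls
from sklearn.base import BaseEstimator

from .sequence_space import (
    BASES,
    PYRIMIDINES,
    central_window,
    digits_of,
    index_of,
)

#: The 16 directional dimers in base-4 index order (AA, AC, ..., TT).
DIMERS: tuple[str, ...] = tuple(x + y for x in BASES for y in BASES)

_G = BASES.index("G")
_PYR = tuple(BASES.index(b) for b in PYRIMIDINES)


def dimer_index(xy: str) -> int:
    return index_of(xy)


@functools.lru_cache(maxsize=None)
def row_tensor(
    seq: str, context: str = "nearest", parent_length: int = 8, tail: str = "ACAC"
) -> np.ndarray:
    """(16, 3) coefficient tensor of a class over monomials (1-q)^g.

    ``design_row(seq, q) = tensor[:, 0] + tensor[:, 1] (1-q) +
    tensor[:, 2] (1-q)^2``.
    """
    if context not in ("nearest", "pool"):
        raise ValueError(f"unknown context {context!r}")
    k = len(seq)
    start, _ = central_window(k, parent_length)  # 1-based within the randomer
    m = (parent_length - k) // 2
    t = len(tail)
    # position template over the full construct: fixed digit or None (random)
    template: list[int | None] = (
        [int(d) for d in digits_of(tail)]
        + [None] * m
        + [int(d) for d in digits_of(seq)]
        + [None] * m
        + [int(d) for d in digits_of(tail)]
    )
    width = len(template)
    window = range(t + m, t + m + k)
    octamer = range(t, t + parent_length)
    scope = window if context == "nearest" else octamer
    pairs = [
        p
        for p in range(width - 1)
        if p in scope or (p + 1) in scope
    ]
    tensor = np.zeros((16, 3))
    pyr = set(_PYR)
    for p in pairs:
        involved = [i for i in (p - 1, p, p + 1, p + 2) if 0 <= i < width]
        choices = [
            [template[i]] if template[i] is not None else [0, 1, 2, 3]
            for i in involved
        ]
        n_random = sum(1 for i in involved if template[i] is None)
        w = 0.25**n_random
        pos = {i: j for j, i in enumerate(involved)}
        for combo in itertools.product(*choices):
            x = combo[pos[p]]
            y = combo[pos[p + 1]]
            if x in pyr and y in pyr:
                g = 0
                if p - 1 >= 0 and combo[pos[p - 1]] == _G:
                    g += 1
                if p + 2 < width and combo[pos[p + 2]] == _G:
                    g += 1
            else:
                g = 0
            tensor[4 * x + y, g] += w
    tensor.setflags(write=False)
    return tensor


def design_row(
    seq: str,
    q: float,
    context: str = "nearest",
    parent_length: int = 8,
    tail: str = "ACAC",
) -> np.ndarray:
    """Coefficient vector over the 16 dimers for one class at quench q."""
    tensor = row_tensor(seq, context, parent_length, tail)
    tvec = np.array([1.0, 1.0 - q, (1.0 - q) ** 2])
    return tensor @ tvec


@functools.lru_cache(maxsize=None)
def _design_tensor(
    sequences: tuple[str, ...], context: str, parent_length: int, tail: str
) -> np.ndarray:
    return np.stack([row_tensor(s, context, parent_length, tail) for s in sequences])


def design_matrix(
    sequences,
    q: float,
    context: str = "nearest",
    parent_length: int = 8,
    tail: str = "ACAC",
) -> np.ndarray:
    """(n_classes, 16) design matrix at quench q."""
    tensor = _design_tensor(tuple(sequences), context, parent_length, tail)
    tvec = np.array([1.0, 1.0 - q, (1.0 - q) ** 2])
    return tensor @ tvec


def predicted_hazard(
    seq: str,
    phi: np.ndarray,
    q: float,
    context: str = "nearest",
    parent_length: int = 8,
    tail: str = "ACAC",
) -> float:
    """Model decay coefficient of one class from a dimer-yield vector."""
    return float(design_row(seq, q, context, parent_length, tail) @ np.asarray(phi))


# --- tying of directional pairs -------------------------------------------

_TIED: list[tuple[int, ...]] = []
_seen: set[frozenset] = set()
for _x in range(4):
    for _y in range(4):
        key = frozenset({(_x, _y), (_y, _x)})
        if key not in _seen:
            _seen.add(key)
            idx = sorted({4 * _x + _y, 4 * _y + _x})
            _TIED.append(tuple(idx))
TIED_GROUPS: tuple[tuple[int, ...], ...] = tuple(_TIED)  # 10 unordered pairs


def _fold_columns(A: np.ndarray) -> np.ndarray:
    return np.stack([A[:, list(g)].sum(axis=1) for g in TIED_GROUPS], axis=1)


def _expand_solution(phi_tied: np.ndarray) -> np.ndarray:
    phi = np.zeros(16)
    for value, group in zip(phi_tied, TIED_GROUPS):
        for j in group:
            phi[j] = value
    return phi


@dataclass
class DimerYieldSet:
    """Estimated directional dimer yields (and quench factor).

    ``phi`` follows the :data:`DIMERS` order.  The naive (linear, q = 0)
    model is unconstrained and may return negative yields — a diagnostic
    that the no-quench model is misspecified; the quench model constrains
    ``phi >= 0`` and profiles q over [0, 1].
    """

    phi: np.ndarray
    phi_se: np.ndarray
    q: float | None
    model: str  # "naive" | "quench"
    residual: float
    covariance: np.ndarray | None = None
    q_identifiable: bool = True
    context: str = "nearest"
    reference: str | None = None
    mu_ref: float = 0.0
    tie_pairs: bool = False
    #: (rho, sigma, epsilon) when estimated by the calibrated inversion
    kinetics: tuple | None = None

    def yield_of(self, dimer: str) -> float:
        return float(self.phi[dimer_index(dimer)])

    def se_of(self, dimer: str) -> float:
        return float(self.phi_se[dimer_index(dimer)])

    def tied_yield(self, dimer: str) -> float:
        """Mean of the XY and YX estimates (the field reports these jointly)."""
        return 0.5 * (self.yield_of(dimer) + self.yield_of(dimer[::-1]))

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "q": self.q,
            "q_identifiable": self.q_identifiable,
            "context": self.context,
            "reference": self.reference,
            "mu_ref": self.mu_ref,
            "residual": self.residual,
            "kinetics": list(self.kinetics) if self.kinetics else None,
            "phi": {d: float(v) for d, v in zip(DIMERS, self.phi)},
            "phi_se": {d: float(v) for d, v in zip(DIMERS, self.phi_se)},
        }


def _prepare(
    sequences,
    mu,
    stderr,
    reference,
    mu_ref,
    context,
    parent_length,
    tail,
):
    sequences = tuple(sequences)
    y = np.asarray(mu, dtype=float).copy()
    if len(sequences) != y.size:
        raise ValueError("sequences and mu disagree in length")
    if len(sequences) < 16:
        raise ValueError("need at least 16 classes to identify 16 dimer yields")
    if stderr is None:
        w = np.ones_like(y)
    else:
        stderr = np.asarray(stderr, dtype=float)
        if np.any(stderr <= 0):
            raise ValueError("stderr must be positive")
        w = 1.0 / stderr
    def matrix(q: float) -> np.ndarray:
        A = design_matrix(sequences, q, context, parent_length, tail)
        if reference is not None:
            # Coefficients after double-ratio normalization estimate the
            # class hazard minus the reference hazard plus the reference's
            # restored self-decay; model the last term with the reference's
            # own nearest-neighbor row so the overall yield scale stays
            # identified (the pure difference leaves an all-yields shift
            # almost unconstrained).
            A = (
                A
                - design_row(reference, q, context, parent_length, tail)[None, :]
                + design_row(reference, q, "nearest", parent_length, tail)[None, :]
            )
        return A

    return sequences, y, w, matrix


def _solve_unconstrained(Aw, yw, tie_pairs):
    A_eff = _fold_columns(Aw) if tie_pairs else Aw
    if tie_pairs:
        col_names = ["/".join(DIMERS[j] for j in g) for g in TIED_GROUPS]
    else:
        col_names = list(DIMERS)
    ncol = A_eff.shape[1]
    u, s, vt = np.linalg.svd(A_eff, full_matrices=False)
    tol = s.max() * max(A_eff.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank < ncol:
        null = vt[rank:]
        combos = []
        for vec in null:
            names = [col_names[j] for j in np.argsort(-np.abs(vec))[:4]]
            combos.append("+".join(names))
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {ncol}); "
            f"unidentifiable combinations involve: {', '.join(combos)}"
        )
    sol, *_ = np.linalg.lstsq(A_eff, yw, rcond=None)
    cov = np.linalg.pinv(A_eff.T @ A_eff)
    resid = float(np.linalg.norm(A_eff @ sol - yw))
    return sol, cov, resid


def invert_naive(
    sequences,
    mu,
    stderr=None,
    *,
    reference: str | None = None,
    mu_ref: float = 0.0,
    context: str = "nearest",
    parent_length: int = 8,
    tail: str = "ACAC",
    tie_pairs: bool = False,
) -> DimerYieldSet:
    """Unconstrained weighted linear inversion of the no-quench (q=0) model.

    With ``reference`` given, the model is
    ``mu_s = (row_s - row_ref + row_ref^nearest) . phi`` — the form decay
    coefficients take after double-ratio normalization against the
    reference class with a self-consistent decay restore (``mu_ref`` is
    recorded as the restore actually used in normalization; at the
    self-consistent point it equals ``row_ref^nearest . phi``).
    """
    sequences, y, w, matrix = _prepare(
        sequences, mu, stderr, reference, mu_ref, context, parent_length, tail
    )
    A = matrix(0.0)
    sol, cov, resid = _solve_unconstrained(A * w[:, None], y * w, tie_pairs)
    if tie_pairs:
        phi = _expand_solution(sol)
        phi_se = _expand_solution(np.sqrt(np.maximum(np.diag(cov), 0.0)))
    else:
        phi = sol
        phi_se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return DimerYieldSet(
        phi=phi,
        phi_se=phi_se,
        q=None,
        model="naive",
        residual=resid,
        covariance=cov,
        context=context,
        reference=reference,
        mu_ref=mu_ref,
        tie_pairs=tie_pairs,
    )


def invert_quench(
    sequences,
    mu,
    stderr=None,
    *,
    reference: str | None = None,
    mu_ref: float = 0.0,
    context: str = "nearest",
    parent_length: int = 8,
    tail: str = "ACAC",
    tie_pairs: bool = False,
    q_step: float = 0.01,
) -> DimerYieldSet:
    """Quench-extended inversion: profile q over [0, 1], non-negative phi.

    At each q the inner problem is a convex non-negative least squares; the
    profile minimum is refined by a bounded local search.  A flat residual
    profile is reported as an unidentifiable q.
    """
    sequences, y, w, matrix = _prepare(
        sequences, mu, stderr, reference, mu_ref, context, parent_length, tail
    )
    yw = y * w

    def rss(q: float) -> float:
        Aw = matrix(q) * w[:, None]
        A_eff = _fold_columns(Aw) if tie_pairs else Aw
        _, r = nnls(A_eff, yw)
        return float(r)

    grid = np.arange(0.0, 1.0 + 1e-12, q_step)
    profile = np.array([rss(q) for q in grid])
    j = int(np.argmin(profile))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid.size - 1)]
    if hi > lo:
        res = minimize_scalar(
            rss, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4}
        )
        q_hat = float(res.x)
        if rss(q_hat) > profile[j]:
            q_hat = float(grid[j])
    else:
        q_hat = float(grid[j])
    q_identifiable = bool(profile.max() - profile.min() > 1e-12)
    if not q_identifiable:
        warnings.warn(
            "residual profile over q is flat; the quench factor is unidentifiable",
            stacklevel=2,
        )
    Aw = matrix(q_hat) * w[:, None]
    A_eff = _fold_columns(Aw) if tie_pairs else Aw
    sol, resid = nnls(A_eff, yw)
    # covariance from the weighted normal equations at q_hat; approximate
    # where non-negativity constraints are active
    cov = np.linalg.pinv(A_eff.T @ A_eff)
    if tie_pairs:
        phi = _expand_solution(sol)
        phi_se = _expand_solution(np.sqrt(np.maximum(np.diag(cov), 0.0)))
    else:
        phi = sol
        phi_se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return DimerYieldSet(
        phi=phi,
        phi_se=phi_se,
        q=q_hat,
        model="quench",
        residual=float(resid),
        covariance=cov,
        q_identifiable=q_identifiable,
        context=context,
        reference=reference,
        mu_ref=mu_ref,
        tie_pairs=tie_pairs,
    )


def _mixture_curves(
    phi: np.ndarray,
    q: float,
    doses: np.ndarray,
    k: int,
    parent_length: int,
    tail: str,
    rho: float = 0.0,
    sigma: float = 0.0,
    epsilon: float = 0.0,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Flank-averaged readable-fraction curves of every k-mer class.

    Per flank completion the two-state intact fraction with photoreversal
    ``rho`` and sink ``sigma``, plus leak-through ``epsilon``: the analytic
    expectation of a marginalized class\'s readable share under the forward
    model.  ``weights`` (one per parent-length sequence) sets the mixture
    weights of the completions; the unirradiated sample\'s octamer counts
    are the natural choice, since they measure the synthesis/readout bias
    directly.  Uniform completions when omitted.
    """
    from .synthetic_pool import PhotophysicsParams, intact_fraction, pool_hazards

    params = PhotophysicsParams(
        phi=np.maximum(phi, 0.0).reshape(4, 4), q=q, rho=0.0, sigma=0.0, epsilon=0.0
    )
    H = pool_hazards(params, tail, parent_length)
    surv = intact_fraction(H[:, None], rho, sigma, doses[None, :])
    m = (parent_length - k) // 2
    shaped = surv.reshape(4**m, 4**k, 4**m, doses.size)
    if weights is None:
        mix = shaped.mean(axis=(0, 2))
    else:
        w = np.asarray(weights, dtype=float).reshape(4**m, 4**k, 4**m, 1)
        if np.any(w < 0):
            raise ValueError("mixture weights must be non-negative")
        norm = np.maximum(w.sum(axis=(0, 2)), 1e-300)
        mix = (shaped * w).sum(axis=(0, 2)) / norm
    return mix + epsilon * (1.0 - mix)


def fit_functional_offsets(
    sequences,
    phi: np.ndarray,
    q: float,
    doses: np.ndarray,
    stderr: np.ndarray,
    reference: str,
    parent_length: int = 8,
    tail: str = "ACAC",
    fit_model: str = "auto",
    select_margin: float = 2.0,
    rho: float = 0.0,
    sigma: float = 0.0,
    epsilon: float = 0.0,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Model-implied offset between fitted coefficients and initial slopes.

    A marginalized class is a mixture over flank completions; over a finite
    dose range a mono/bi fit of the mixture returns less than the
    flank-averaged initial slope (the curve settles toward its slowest
    components, and photoreversal/leak-through add plateaus).  Given a
    candidate yield set and global kinetics, this evaluates the *same* fit
    procedure on the model's own normalized mixture curves and returns
    ``mu_fitted_model - mu_initial_slope_model`` per class, so measured
    coefficients can be corrected before a linear inversion.
    """
    from .decay_fit import fit_series

    sequences = tuple(sequences)
    k = len(sequences[0])
    curves = _mixture_curves(
        phi, q, doses, k, parent_length, tail, rho, sigma, epsilon, weights
    )
    ref_curve = curves[index_of(reference)]
    A = design_matrix(sequences, q, "pool", parent_length, tail)
    row_ref = design_row(reference, q, "pool", parent_length, tail)
    slopes = (A - row_ref[None, :]) @ phi
    offsets = np.zeros(len(sequences))
    for i, seq in enumerate(sequences):
        r_model = curves[index_of(seq)] / ref_curve
        fit = fit_series(
            doses, r_model, stderr[i], model=fit_model, select_margin=select_margin
        )
        offsets[i] = fit.mu_init - slopes[i]
    return offsets


def fit_pool_model(
    rft,
    counts=None,
    *,
    parent_length: int = 8,
    tail: str = "ACAC",
    tie_pairs: bool = True,
    weights: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    phi_max: float = 0.2,
    max_nfev: int = 400,
) -> DimerYieldSet:
    """Joint curve-level fit of the complete pool-damage model.

    Fits the dimeric yields, the quench factor and the global kinetic
    nuisances (photoreversal ``rho``, sink ``sigma``, leak-through
    ``epsilon``) in one weighted nonlinear least squares against *all*
    normalized decay curves of a :class:`~uvpool.normalization.RelFreqTable`.
    The model curve of class s is the flank-averaged two-state readable
    fraction divided by the reference class's curve (times the
    normalization's restore factor), so the reference's own decay is part
    of the model and no separate scale anchor is needed.

    This estimator uses every dose point of every class, which is what
    makes small yields (purine dimers near the sensitivity floor)
    recoverable: their information lives in the shallow curvature of slow
    classes, not in any single fitted decay coefficient.

    ``weights`` sets the flank-completion mixture weights per parent
    sequence; passing the unirradiated sample's octamer counts matches the
    model mixtures to the pool's actual synthesis bias.

    Because every class is divided by the same reference column, the
    reference's Poisson noise is a *common* per-dose disturbance, not
    independent point noise.  When the marginalized ``counts`` table is
    supplied, the fit profiles one multiplicative nuisance factor per
    nonzero dose, penalized by the reference count's known variance
    (generalized least squares via nuisance parameters); the per-point
    errors then carry only the class-specific Poisson terms.  Without
    ``counts`` the plain independent-error approximation is used.

    Parameters are tied XY/YX by default (the directional split is a gauge
    direction of the underlying linear model and is not identifiable).
    Returns a :class:`DimerYieldSet` with ``model="curve"`` and the fitted
    ``kinetics`` attached.
    """
    from scipy.optimize import least_squares as _ls

    if not tie_pairs:
        raise NotImplementedError("curve-level fit is defined on tied yields")
    k = rft.k
    rows = np.flatnonzero(rft.valid)
    data = rft.relfreq[rows]
    doses = np.asarray(rft.doses, dtype=float)
    nd = doses.size
    restore = np.exp(-rft.mu_ref * doses)[None, :]
    ref_idx = index_of(rft.reference)
    n_phi = len(TIED_GROUPS)

    if counts is not None:
        if counts.k != k:
            raise ValueError("counts table does not match the table's k")
        n_obs = counts.counts.astype(float)
        n_sj = np.maximum(n_obs[rows], 1.0)
        n_s0 = np.maximum(n_obs[rows, 0], 1.0)[:, None]
        nref = np.maximum(n_obs[ref_idx], 1.0)
        # class-specific Poisson terms only; the shared reference noise is
        # handled by the per-dose nuisance factors below
        r_floor = (1.0 / nref[None, :]) * (nref[0] / n_s0) * restore
        sigma_pt = np.maximum(data, r_floor) * np.sqrt(1.0 / n_sj + 1.0 / n_s0)
        w = 1.0 / np.maximum(sigma_pt, 1e-9)
        gamma_sd = np.sqrt(1.0 / nref[1:] + 1.0 / nref[0])
        n_gamma = nd - 1
    else:
        w = 1.0 / np.maximum(rft.stderr[rows], 1e-9)
        gamma_sd = None
        n_gamma = 0

    def unpack(p):
        phi = _expand_solution(p[:n_phi])
        q, rho, sigma, eps = p[n_phi : n_phi + 4]
        gamma = p[n_phi + 4 :]
        return phi, q, rho, sigma, eps, gamma

    def resid(p):
        phi, q, rho, sigma, eps, gamma = unpack(p)
        curves = _mixture_curves(
            phi, q, doses, k, parent_length, tail, rho, sigma, eps, weights
        )
        model = curves[rows] / curves[ref_idx][None, :] * restore
        if n_gamma:
            model = model * np.concatenate([[1.0], 1.0 + gamma])[None, :]
            penalty = gamma / gamma_sd
            return np.concatenate([((model - data) * w).ravel(), penalty])
        return ((model - data) * w).ravel()

    if x0 is None:
        x0 = np.concatenate([np.full(n_phi, 2e-3), [0.3, 1e-3, 1e-3, 1e-3]])
    x0 = np.asarray(x0, dtype=float)
    if x0.size == n_phi + 4 and n_gamma:
        x0 = np.concatenate([x0, np.zeros(n_gamma)])
    lb = np.concatenate([np.zeros(n_phi + 4), np.full(n_gamma, -0.5)])
    ub = np.concatenate(
        [np.full(n_phi, phi_max), [1.0, np.inf, np.inf, 1.0], np.full(n_gamma, 0.5)]
    )
    sol = _ls(
        resid,
        x0=np.clip(x0, lb, ub),
        bounds=(lb, ub),
        x_scale=np.concatenate(
            [np.full(n_phi, 1e-2), [0.3, 1e-2, 1e-2, 1e-2], np.full(n_gamma, 1e-2)]
        ),
        max_nfev=max_nfev,
    )
    phi, q, rho, sigma, eps, _ = unpack(sol.x)
    cov = np.linalg.pinv(sol.jac.T @ sol.jac)
    se_tied = np.sqrt(np.maximum(np.diag(cov)[:n_phi], 0.0))
    return DimerYieldSet(
        phi=phi,
        phi_se=_expand_solution(se_tied),
        q=float(q),
        model="curve",
        residual=float(np.sqrt(2.0 * sol.cost)),
        covariance=cov[: n_phi + 4, : n_phi + 4],
        context="pool",
        reference=rft.reference,
        mu_ref=rft.mu_ref,
        tie_pairs=True,
        kinetics=(float(rho), float(sigma), float(eps)),
    )


def _pool_model_x0(result: DimerYieldSet) -> np.ndarray:
    """Warm-start vector for :func:`fit_pool_model` from a previous result."""
    phi_tied = np.array([result.phi[g[0]] for g in TIED_GROUPS])
    rho, sigma, eps = result.kinetics or (1e-3, 1e-3, 1e-3)
    return np.concatenate([phi_tied, [result.q or 0.3, rho, sigma, eps]])


class DimerYieldEstimator(BaseEstimator):
    """Scikit-learn style wrapper over the dimer-yield inversions.

    ``fit(X, y, stderr=...)`` takes X as a sequence of class strings and y
    as their fitted initial decay coefficients.  Fitted attributes:
    ``phi_`` (16 directional yields in :data:`DIMERS` order), ``q_``,
    ``result_`` (the full :class:`DimerYieldSet`).
    """

    def __init__(
        self,
        model: str = "quench",
        context: str = "pool",
        reference: str | None = None,
        mu_ref: float = 0.0,
        parent_length: int = 8,
        tail: str = "ACAC",
        tie_pairs: bool = False,
        q_step: float = 0.01,
    ):
        self.model = model
        self.context = context
        self.reference = reference
        self.mu_ref = mu_ref
        self.parent_length = parent_length
        self.tail = tail
        self.tie_pairs = tie_pairs
        self.q_step = q_step

    def fit(self, X, y, stderr=None):
        kwargs = dict(
            reference=self.reference,
            mu_ref=self.mu_ref,
            context=self.context,
            parent_length=self.parent_length,
            tail=self.tail,
            tie_pairs=self.tie_pairs,
        )
        if self.model == "quench":
            result = invert_quench(X, y, stderr, q_step=self.q_step, **kwargs)
        elif self.model == "naive":
            result = invert_naive(X, y, stderr, **kwargs)
        else:
            raise ValueError(f"unknown model {self.model!r}")
        self.result_ = result
        self.phi_ = result.phi
        self.q_ = result.q
        return self

    def predict(self, X):
        """Model decay coefficients for the given classes."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        q = self.result_.q or 0.0
        A = design_matrix(tuple(X), q, self.context, self.parent_length, self.tail)
        if self.reference is not None:
            A = (
                A
                - design_row(self.reference, q, self.context, self.parent_length, self.tail)[None, :]
                + design_row(self.reference, q, "nearest", self.parent_length, self.tail)[None, :]
            )
        return A @ self.phi_
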