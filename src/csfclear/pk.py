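"""Plasma pharmacokinetics of an intrathecally injected CSF tracer.

After lumbar intrathecal injection the tracer (here gadobutrol, 0.5 mmol)
leaves the CSF compartment into blood; the plasma concentration-time profile
is described by a depot model with first-order absorption and lag:

    depot (CSF) --ka, lag tlag-->  central (plasma, volume vc,
                                   elimination clearance cl)
                                      <--q-->  peripheral (volume vp)

All volumes and clearances are *apparent* (scaled by the unknown
bioavailable fraction), the standard convention for extravascular dosing.
The closed-form solution of the linear three-state system is a
tri-exponential in ``t - tlag``.  The absorption rate ``ka`` and its
half-life ln(2)/ka quantify how fast tracer leaves the CSF, the proxy of
meningeal-lymphatic clearance capacity used downstream.

Population estimation uses log-normal inter-individual variability (IIV) on
``ka``, ``cl`` and ``vc``, a proportional residual error, and a Laplace
approximation to the marginal likelihood with per-subject empirical-Bayes
modes.  IIV on only three of the six structural parameters is a deliberate
restriction: cohorts of a few dozen subjects with sparse sampling cannot
support random effects on all six.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

logger = logging.getLogger("csfclear.pk")

__all__ = [
    "PKParameters",
    "PKDerived",
    "PKObservation",
    "PopulationPKModel",
    "IndividualFit",
    "ParameterDomainError",
    "InsufficientDataError",
    "DegenerateDataError",
    "conc_at",
    "derive_metrics",
    "fit_individual",
    "fit_population",
    "auc_trapezoid",
]

# relative nudge applied when absorption/disposition rate constants coincide
# (measure-zero case; avoids 0/0 in the tri-exponential coefficients)
_EIG_EPS = 1e-9


class ParameterDomainError(ValueError):
    """A pharmacokinetic parameter violates its positivity domain."""


class InsufficientDataError(ValueError):
    """Too few usable observations to attempt a fit."""


class DegenerateDataError(ValueError):
    """Observations carry no kinetic information (e.g. all zero)."""


@dataclass(frozen=True)
class PKParameters:
    """Structural parameters of the depot + two-compartment model.

    ka : 1/h, first-order absorption rate CSF depot -> plasma
    tlag : h, delay before absorption starts
    cl : L/h, apparent elimination clearance from the central compartment
    vc : L, apparent central volume
    q : L/h, inter-compartmental clearance
    vp : L, apparent peripheral volume
    dose : mmol, administered intrathecal amount
    """

    ka: float
    tlag: float
    cl: float
    vc: float
    q: float
    vp: float
    dose: float

    def __post_init__(self) -> None:
        bad = []
        if not (self.ka > 0):
            bad.append(f"ka={self.ka} (must be > 0)")
        if not (self.tlag >= 0):
            bad.append(f"tlag={self.tlag} (must be >= 0)")
        if not (self.cl > 0):
            bad.append(f"cl={self.cl} (must be > 0)")
        if not (self.vc > 0):
            bad.append(f"vc={self.vc} (must be > 0)")
        if not (self.q >= 0):
            bad.append(f"q={self.q} (must be >= 0)")
        if not (self.vp > 0):
            bad.append(f"vp={self.vp} (must be > 0)")
        if not (self.dose >= 0):
            bad.append(f"dose={self.dose} (must be >= 0)")
        if bad:
            raise ParameterDomainError("invalid PK parameters: " + ", ".join(bad))


@dataclass(frozen=True)
class PKDerived:
    """Summary clearance metrics derived from :class:`PKParameters`.

    t_half_abs : h, absorption half-life ln(2)/ka
    auc : mmol*h/L, area under the concentration-time curve 0->inf (= dose/cl)
    cmax : mmol/L, peak plasma concentration
    tmax : h, time of the peak (after injection)
    """

    t_half_abs: float
    auc: float
    cmax: float
    tmax: float


@dataclass(frozen=True)
class PKObservation:
    """One plasma sample: hours since injection and measured concentration."""

    subject_id: str
    time: float
    conc: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative sample time {self.time}")
        if self.conc < 0:
            raise ValueError(f"negative concentration {self.conc}")


@dataclass
class IndividualFit:
    """Single-subject least-squares fit with convergence flag."""

    params: PKParameters
    converged: bool
    cost: float


@dataclass
class PopulationPKModel:
    """Population fit: typical values, IIV spread and per-subject modes."""

    typical: PKParameters
    iiv_sd: dict  # parameter name -> SD of the log-normal random effect
    sigma_prop: float
    individual_estimates: dict  # subject_id -> PKParameters
    objective: float  # -2 log-likelihood (Laplace approximation)
    converged: bool
    se: dict | None = None  # typical-value standard errors (natural scale)


# --------------------------------------------------------------------------
# closed-form solution
# --------------------------------------------------------------------------

def _rates(cl, vc, q, vp):
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    p = k10 * k21
    root = np.sqrt(np.maximum(s * s - 4.0 * p, 0.0))
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    return k21, alpha, beta


def _tri_exp(ka, tlag, cl, vc, q, vp, dose, t):
    """Vectorized tri-exponential concentration; broadcasts over all args."""
    ka = np.asarray(ka, dtype=float)
    t = np.asarray(t, dtype=float)
    k21, alpha, beta = _rates(
        np.asarray(cl, float), np.asarray(vc, float),
        np.asarray(q, float), np.asarray(vp, float),
    )
    scale = np.maximum(alpha, 1e-300)
    # separate coincident eigenvalues / absorption rate by a relative nudge
    beta = np.where(np.abs(alpha - beta) <= _EIG_EPS * scale,
                    beta * (1.0 - 1e-6) - 1e-15, beta)
    ka_ = np.where(np.abs(ka - alpha) <= _EIG_EPS * np.maximum(ka, alpha),
                   ka * (1.0 + 3.1e-9), ka)
    ka_ = np.where(np.abs(ka_ - beta) <= _EIG_EPS * np.maximum(ka_, np.abs(beta)),
                   ka_ * (1.0 + 3.1e-9), ka_)

    tau = t - tlag
    pos = tau > 0
    tau = np.where(pos, tau, 0.0)

    c1 = (k21 - alpha) / ((ka_ - alpha) * (beta - alpha))
    c2 = (k21 - beta) / ((ka_ - beta) * (alpha - beta))
    c3 = (k21 - ka_) / ((alpha - ka_) * (beta - ka_))
    conc = (ka_ * dose / vc) * (
        c1 * np.exp(-alpha * tau) + c2 * np.exp(-beta * tau) + c3 * np.exp(-ka_ * tau)
    )
    return np.where(pos, np.maximum(conc, 0.0), 0.0)


def conc_at(params: PKParameters, t):
    """Plasma concentration at time(s) ``t`` hours after injection.

    Returns the closed-form tri-exponential solution; zero for ``t <= tlag``
    and for zero dose.  Accepts a scalar or array ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = _tri_exp(params.ka, params.tlag, params.cl, params.vc,
                   params.q, params.vp, params.dose, t_arr)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def _dconc_dtau(params: PKParameters, tau):
    """Derivative of the unit-dose profile w.r.t. time-after-lag (tau > 0)."""
    k21, alpha, beta = _rates(params.cl, params.vc, params.q, params.vp)
    ka = params.ka
    if abs(alpha - beta) <= _EIG_EPS * alpha:
        beta = beta * (1.0 - 1e-6) - 1e-15
    if abs(ka - alpha) <= _EIG_EPS * max(ka, alpha):
        ka = ka * (1.0 + 3.1e-9)
    if abs(ka - beta) <= _EIG_EPS * max(ka, abs(beta)):
        ka = ka * (1.0 + 3.1e-9)
    c1 = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    c2 = (k21 - beta) / ((ka - beta) * (alpha - beta))
    c3 = (k21 - ka) / ((alpha - ka) * (beta - ka))
    tau = np.asarray(tau, dtype=float)
    return (ka / params.vc) * (
        -alpha * c1 * np.exp(-alpha * tau)
        - beta * c2 * np.exp(-beta * tau)
        - ka * c3 * np.exp(-ka * tau)
    )


def derive_metrics(params: PKParameters) -> PKDerived:
    """Absorption half-life, AUC(0->inf), Cmax and Tmax.

    AUC is the analytic dose/cl (complete first-order absorption, linear
    kinetics); the peak is located by root-finding on the time derivative of
    the concentration profile on (tlag, inf).
    """
    if params.cl == 0:
        raise ParameterDomainError("cl = 0: AUC undefined")
    t_half_abs = math.log(2.0) / params.ka
    auc = params.dose / params.cl

    # locate the peak of the (dose-independent) profile shape
    shape = replace(params, dose=1.0)
    _, alpha, beta = _rates(params.cl, params.vc, params.q, params.vp)
    slowest = min(x for x in (params.ka, alpha, max(beta, 0.0)) if x > 0)
    t_hi = 200.0 / slowest
    grid = np.geomspace(1e-8, t_hi, 600)
    dvals = _dconc_dtau(shape, grid)
    neg = np.nonzero(dvals <= 0)[0]
    if len(neg) == 0 or neg[0] == 0:
        # profile monotone on the grid; peak at a grid end
        tau_max = grid[-1] if len(neg) == 0 else grid[0]
    else:
        i = neg[0]
        tau_max = optimize.brentq(lambda x: _dconc_dtau(shape, x),
                                  grid[i - 1], grid[i], xtol=1e-12, rtol=1e-14)
    tmax = params.tlag + float(tau_max)
    cmax = conc_at(params, tmax)
    return PKDerived(t_half_abs=t_half_abs, auc=auc, cmax=float(cmax), tmax=tmax)


# --------------------------------------------------------------------------
# numerical AUC (independent of the analytic dose/cl identity)
# --------------------------------------------------------------------------

def auc_trapezoid(curve) -> float:
    """Linear-trapezoid AUC with log-linear tail extrapolation.

    ``curve`` is a sequence of (time, conc) pairs with strictly increasing
    times starting at 0.  When a terminal slope ``lambda_z`` is estimable
    from the last three points (all positive, log-linear decline) the tail
    ``conc_last / lambda_z`` is added.
    """
    arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (time, conc) points")
    times, conc = arr[:, 0], arr[:, 1]
    if times[0] != 0:
        raise ValueError("curve must start at time 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    area = float(np.trapezoid(conc, times))
    tail = conc[-3:]
    if np.all(tail > 0):
        slope = np.polyfit(times[-3:], np.log(tail), 1)[0]
        if slope < 0:
            area += float(conc[-1] / (-slope))
    return area


# --------------------------------------------------------------------------
# single-subject fit (initializer for the population fit)
# --------------------------------------------------------------------------

def _as_time_conc(obs):
    if hasattr(obs, "to_numpy"):  # DataFrame with time/conc columns
        t = np.asarray(obs["time"], float)
        y = np.asarray(obs["conc"], float)
    else:
        pairs = [(o.time, o.conc) if isinstance(o, PKObservation) else tuple(o)
                 for o in obs]
        arr = np.asarray(pairs, dtype=float)
        t, y = arr[:, 0], arr[:, 1]
    keep = t > 0
    return t[keep], y[keep]


def _initial_guess(t, y, dose):
    ymax = float(np.max(y))
    imax = int(np.argmax(y))
    tmax_obs = float(t[imax])
    rising = np.nonzero(y > 0.02 * ymax)[0]
    t_first = float(t[rising[0]]) if len(rising) else float(t[0])
    tlag0 = 0.25 * t_first
    ka0 = 1.5 / max(tmax_obs - tlag0, 1e-3)
    auc0 = auc_trapezoid(np.column_stack([np.r_[0.0, t], np.r_[0.0, y]]))
    cl0 = dose / max(auc0, 1e-12)
    vc0 = dose / (2.5 * ymax)
    return np.array([ka0, tlag0, cl0, vc0, cl0, 2.0 * vc0])


def fit_individual(obs, dose: float, seed: int = 0, n_starts: int = 5) -> IndividualFit:
    """Weighted least squares on the proportional-error scale for one subject.

    Requires >= 5 post-injection observations with at least two after the
    observed peak; uses multi-start local optimization (log-spaced
    perturbations of a heuristic initializer), best objective wins, ties
    broken by the smaller parameter-vector norm.
    """
    t, y = _as_time_conc(obs)
    if len(t) < 5:
        raise InsufficientDataError(
            f"need >= 5 observations with time > 0, got {len(t)}")
    if np.all(y == 0):
        raise DegenerateDataError("all concentrations are zero")
    if np.ptp(y) == 0:
        raise DegenerateDataError("all concentrations identical")
    if np.sum(t > t[np.argmax(y)]) < 2:
        raise InsufficientDataError("need >= 2 observations after the observed peak")

    order = np.argsort(t)
    t, y = t[order], y[order]
    ymax = float(np.max(y))
    w = np.maximum(y, 1e-6 * ymax)  # proportional-error weights
    tlag_cap = 0.95 * float(t[y > 0][0])

    def unpack(z):
        ka, cl, vc, q, vp = np.exp(z[[0, 2, 3, 4, 5]])
        tlag = z[1]
        return ka, tlag, cl, vc, q, vp

    def resid(z):
        ka, tlag, cl, vc, q, vp = unpack(z)
        pred = _tri_exp(ka, tlag, cl, vc, q, vp, dose, t)
        return (pred - y) / w

    p0 = _initial_guess(t, y, dose)
    z0 = np.array([math.log(p0[0]), min(p0[1], tlag_cap),
                   math.log(p0[2]), math.log(p0[3]),
                   math.log(p0[4]), math.log(p0[5])])
    lo = np.array([math.log(1e-4), 0.0, math.log(1e-4),
                   math.log(1e-3), math.log(1e-8), math.log(1e-3)])
    hi = np.array([math.log(1e3), tlag_cap, math.log(1e4),
                   math.log(1e5), math.log(1e4), math.log(1e6)])
    z0 = np.clip(z0, lo + 1e-9, hi - 1e-9)

    rng = np.random.default_rng(seed)
    starts = [z0]
    for _ in range(n_starts - 1):
        dz = rng.normal(0.0, 0.5, size=6)
        dz[1] = 0.0
        starts.append(np.clip(z0 + dz, lo + 1e-9, hi - 1e-9))

    best = None
    for zs in starts:
        try:
            res = optimize.least_squares(resid, zs, bounds=(lo, hi),
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
        key = (round(res.cost, 12), float(np.linalg.norm(np.exp(res.x))))
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        raise RuntimeError("all optimization starts failed")
    res = best[1]
    ka, tlag, cl, vc, q, vp = unpack(res.x)
    converged = bool(res.status > 0)
    if not converged:
        logger.debug("individual fit did not converge (status=%s)", res.status)
    params = PKParameters(ka=ka, tlag=tlag, cl=cl, vc=vc, q=q, vp=vp, dose=dose)
    return IndividualFit(params=params, converged=converged, cost=float(res.cost))


# --------------------------------------------------------------------------
# population fit: Laplace-approximate marginal likelihood
# --------------------------------------------------------------------------

_LOG2PI = math.log(2.0 * math.pi)


def _pack_obs(obs, doses):
    """Group observations by subject into padded (n, T) arrays."""
    rows = {}
    if hasattr(obs, "to_numpy"):
        for sid, grp in obs.groupby("subject_id", sort=True):
            t = np.asarray(grp["time"], float)
            y = np.asarray(grp["conc"], float)
            keep = t > 0
            rows[sid] = (t[keep], y[keep])
    else:
        for o in obs:
            rows.setdefault(o.subject_id, []).append((o.time, o.conc))
        rows = {sid: tuple(np.asarray(v, float).T[:, np.asarray(v, float).T[0] > 0])
                for sid, v in ((s, r) for s, r in sorted(rows.items()))}
        rows = {sid: (tc[0], tc[1]) for sid, tc in rows.items()}
    sids = sorted(rows)
    tmax = max(len(rows[s][0]) for s in sids)
    n = len(sids)
    times = np.zeros((n, tmax))
    y = np.zeros((n, tmax))
    mask = np.zeros((n, tmax), dtype=bool)
    dose = np.zeros(n)
    for i, sid in enumerate(sids):
        ti, yi = rows[sid]
        times[i, : len(ti)] = ti
        y[i, : len(ti)] = yi
        mask[i, : len(ti)] = True
        dose[i] = doses[sid] if isinstance(doses, dict) else float(doses)
    return sids, times, y, mask, dose


def _subject_conc(theta_struct, eta, times, dose):
    """(n, T) predicted concentrations; eta columns perturb ka, cl, vc."""
    ka, tlag, cl, vc, q, vp = theta_struct
    return _tri_exp(ka * np.exp(eta[:, 0:1]), tlag,
                    cl * np.exp(eta[:, 1:2]), vc * np.exp(eta[:, 2:3]),
                    q, vp, dose[:, None], times)


def _inner_g(theta_struct, sigma, omega, eta, times, y, mask, dose, floor):
    """Joint -log p(y|eta) - log p(eta), without additive constants."""
    f = _subject_conc(theta_struct, eta, times, dose)
    fs = np.maximum(f, floor)
    r = (y - f) / (sigma * fs)
    gy = np.sum(np.where(mask, np.log(fs) + 0.5 * r * r, 0.0), axis=1)
    return gy + 0.5 * np.sum((eta / omega) ** 2, axis=1)


def _inner_modes(theta_struct, sigma, omega, eta0, times, y, mask, dose, floor,
                 max_iter=40, tol=1e-9):
    """Vectorized damped Newton for the per-subject random-effect modes.

    Runs from the warm start and falls back to eta = 0 for any subject whose
    warm-started solution ends up worse than the prior mode, so a stale warm
    start can never poison the marginal likelihood.
    """
    with np.errstate(all="ignore"):
        eta, g = _newton_descent(theta_struct, sigma, omega,
                                 np.clip(eta0, -20.0, 20.0), times, y, mask,
                                 dose, floor, max_iter, tol)
        zeros = np.zeros_like(eta)
        g_zero = _inner_g(theta_struct, sigma, omega, zeros, times, y, mask,
                          dose, floor)
        bad = ~np.isfinite(g) | (g > g_zero + 1e-9)
        if np.any(bad):
            eta_z, g_z = _newton_descent(theta_struct, sigma, omega, zeros,
                                         times, y, mask, dose, floor,
                                         max_iter, tol)
            take = ~np.isfinite(g) | (g_z < g)
            eta[take] = eta_z[take]
            g[take] = g_z[take]
        # curvature at the final mode (Gauss-Newton, positive definite)
        h = 1e-6
        eye = np.eye(3)
        f = _subject_conc(theta_struct, eta, times, dose)
        J = np.empty(times.shape + (3,))
        for k in range(3):
            J[..., k] = (_subject_conc(theta_struct, eta + h * eye[k],
                                       times, dose) - f) / h
        fs = np.maximum(f, floor)
        wgt = np.where(mask, 1.0 / (sigma * sigma * fs * fs), 0.0)
        H = np.einsum("ntj,nt,ntk->njk", J, wgt, J) + np.eye(3) / omega ** 2
    return eta, g, H


def _newton_descent(theta_struct, sigma, omega, eta, times, y, mask, dose,
                    floor, max_iter, tol):
    n = eta.shape[0]
    s2 = sigma * sigma
    prior_prec = np.eye(3) / omega ** 2
    eye = np.eye(3)
    h = 1e-6

    g = _inner_g(theta_struct, sigma, omega, eta, times, y, mask, dose, floor)
    f = _subject_conc(theta_struct, eta, times, dose)
    for _ in range(max_iter):
        # forward-difference Jacobian of f w.r.t. eta
        J = np.empty(times.shape + (3,))
        for k in range(3):
            J[..., k] = (_subject_conc(theta_struct, eta + h * eye[k],
                                       times, dose) - f) / h
        fs = np.maximum(f, floor)
        d = y - f
        dgdf = 1.0 / fs - d / (s2 * fs * fs) - d * d / (s2 * fs ** 3)
        grad = np.einsum("nt,ntk->nk", np.where(mask, dgdf, 0.0), J)
        grad += eta / omega ** 2
        wgt = np.where(mask, 1.0 / (s2 * fs * fs), 0.0)
        H = np.einsum("ntj,nt,ntk->njk", J, wgt, J) + prior_prec
        try:
            step = -np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = -grad * 1e-3
        # vectorized backtracking line search
        lam = np.ones(n)
        accepted = np.zeros(n, dtype=bool)
        new_eta = eta.copy()
        new_g = g.copy()
        for _ls in range(8):
            trial = eta + lam[:, None] * step
            gt = _inner_g(theta_struct, sigma, omega, trial, times, y,
                          mask, dose, floor)
            better = (gt <= g) & ~accepted
            new_eta[better] = trial[better]
            new_g[better] = gt[better]
            accepted |= better
            if accepted.all():
                break
            lam = np.where(accepted, lam, lam * 0.5)
        moved = np.max(np.abs(new_eta - eta))
        eta, g = new_eta, new_g
        f = _subject_conc(theta_struct, eta, times, dose)
        if moved < tol:
            break
    return eta, g


def _laplace_m2ll(theta, times, y, mask, dose, floor, eta_cache):
    """-2 log marginal likelihood (Laplace) at transformed parameters theta."""
    struct = np.exp(theta[:6])
    omega = np.exp(theta[6:9])
    sigma = float(np.exp(theta[9]))
    eta0 = eta_cache.get("eta")
    if eta0 is None:
        eta0 = np.zeros((times.shape[0], 3))
    eta, g, H = _inner_modes(tuple(struct), sigma, omega, eta0, times, y, mask,
                             dose, floor)
    eta_cache["eta"] = eta
    n_obs = mask.sum(axis=1)
    sign, logdet = np.linalg.slogdet(H)
    if np.any(sign <= 0):
        return 1e12
    # -log L_i = g_i + n_i (log sigma + log(2pi)/2) + sum_k log omega_k
    #            + 1.5 log(2pi) - 1.5 log(2pi) + 0.5 logdet H_i
    neg_ll = (g + n_obs * (math.log(sigma) + 0.5 * _LOG2PI)
              + np.sum(np.log(omega)) + 0.5 * logdet)
    val = 2.0 * float(np.sum(neg_ll))
    if not np.isfinite(val):
        return 1e12
    return val


def fit_population(obs, doses, seed: int = 0, compute_se: bool = False,
                   maxiter: int = 300) -> PopulationPKModel:
    """Nonlinear mixed-effects fit of the depot two-compartment model.

    Log-normal IIV on ka, cl, vc (tlag, q, vp carry typical values only),
    proportional residual error, Laplace-approximate marginal likelihood.
    ``doses`` is a scalar or a subject_id -> dose mapping.  Returns typical
    values, IIV SDs, the residual-error coefficient and per-subject
    empirical-Bayes parameter estimates.
    """
    sids, times, y, mask, dose = _pack_obs(obs, doses)
    n = len(sids)
    if n < 3:
        raise InsufficientDataError(
            f"population fit needs >= 3 subjects (got {n}); "
            "use fit_individual for a single subject")
    for i, sid in enumerate(sids):
        if mask[i].sum() < 5:
            raise InsufficientDataError(f"subject {sid}: fewer than 5 usable samples")

    floor = 1e-8 * float(np.max(y))

    # initialize typical values from the elementwise median of quick
    # per-subject fits (robust to the occasional wild individual fit) with
    # a pooled mean-curve fit as a backup start
    subj_est = []
    for i in range(min(n, 40)):
        ti, yi = times[i][mask[i]], y[i][mask[i]]
        try:
            f = fit_individual(list(zip(ti.tolist(), yi.tolist())),
                               dose=float(dose[i]), seed=seed, n_starts=3)
        except (InsufficientDataError, DegenerateDataError, RuntimeError):
            continue
        subj_est.append([f.params.ka, f.params.tlag, f.params.cl,
                         f.params.vc, f.params.q, f.params.vp])
    pooled_t = times[mask]
    pooled_y = y[mask]
    ut, inv = np.unique(pooled_t, return_inverse=True)
    uy = np.bincount(inv, weights=pooled_y) / np.bincount(inv)
    pooled = fit_individual(list(zip(ut.tolist(), uy.tolist())),
                            dose=float(np.mean(dose)), seed=seed)
    p = pooled.params
    if len(subj_est) >= 3:
        med = np.median(np.asarray(subj_est), axis=0)
    else:
        med = np.array([p.ka, p.tlag, p.cl, p.vc, p.q, p.vp])
    theta0 = np.array([
        math.log(med[0]), math.log(max(med[1], 1e-3)), math.log(med[2]),
        math.log(med[3]), math.log(max(med[4], 1e-6)), math.log(med[5]),
        math.log(0.2), math.log(0.2), math.log(0.2), math.log(0.1),
    ])
    theta_pooled = np.array([
        math.log(p.ka), math.log(max(p.tlag, 1e-3)), math.log(p.cl),
        math.log(p.vc), math.log(max(p.q, 1e-6)), math.log(p.vp),
        math.log(0.2), math.log(0.2), math.log(0.2), math.log(0.1),
    ])
    lo = np.array([math.log(1e-3), math.log(1e-3), math.log(1e-2),
                   math.log(1e-1), math.log(1e-6), math.log(1e-1),
                   math.log(1e-3), math.log(1e-3), math.log(1e-3),
                   math.log(5e-3)])
    hi = np.array([math.log(50.0), math.log(24.0), math.log(500.0),
                   math.log(5e3), math.log(500.0), math.log(5e4),
                   math.log(2.0), math.log(2.0), math.log(2.0), math.log(1.0)])
    theta0 = np.clip(theta0, lo + 1e-6, hi - 1e-6)

    eta_cache: dict = {}

    def objective(theta):
        return _laplace_m2ll(theta, times, y, mask, dose, floor, eta_cache)

    # multi-start over the absorption rate: the depot model's flip-flop
    # ambiguity (absorption vs disposition rates) creates separated basins,
    # and the pooled initializer can land in the wrong one
    starts = []
    for dka in (0.0, -math.log(2.0), math.log(2.0)):
        th = theta0.copy()
        th[0] += dka
        starts.append(np.clip(th, lo + 1e-6, hi - 1e-6))
    starts.append(np.clip(theta_pooled, lo + 1e-6, hi - 1e-6))
    res = None
    for th0 in starts:
        eta_cache.pop("eta", None)
        cand = optimize.minimize(
            objective, th0, method="L-BFGS-B",
            bounds=optimize.Bounds(lo, hi),
            options={"maxiter": maxiter, "eps": 1e-4, "ftol": 1e-11,
                     "gtol": 1e-7},
        )
        if res is None or cand.fun < res.fun:
            res = cand
    if not res.success:
        # finite-difference gradients occasionally stall; polish simplex-wise
        polish = optimize.minimize(
            objective, res.x, method="Nelder-Mead",
            bounds=optimize.Bounds(lo, hi),
            options={"maxiter": 800, "maxfev": 800,
                     "xatol": 1e-5, "fatol": 1e-6, "adaptive": True},
        )
        if polish.fun <= res.fun:
            res = polish
    theta = res.x
    objective_value = float(res.fun)
    converged = objective_value < 1e11
    if not converged:
        logger.warning("population fit flagged non-converged: %s", res.message)

    struct = np.exp(theta[:6])
    omega = np.exp(theta[6:9])
    sigma = float(np.exp(theta[9]))
    eta, _, _ = _inner_modes(tuple(struct), sigma, omega,
                             eta_cache.get("eta", np.zeros((n, 3))),
                             times, y, mask, dose, floor)
    typical = PKParameters(ka=float(struct[0]), tlag=float(struct[1]),
                           cl=float(struct[2]), vc=float(struct[3]),
                           q=float(struct[4]), vp=float(struct[5]),
                           dose=float(np.mean(dose)))
    individual = {}
    for i, sid in enumerate(sids):
        individual[sid] = PKParameters(
            ka=float(struct[0] * math.exp(eta[i, 0])), tlag=float(struct[1]),
            cl=float(struct[2] * math.exp(eta[i, 1])),
            vc=float(struct[3] * math.exp(eta[i, 2])),
            q=float(struct[4]), vp=float(struct[5]), dose=float(dose[i]))
    iiv = {"ka": float(omega[0]), "cl": float(omega[1]), "vc": float(omega[2]),
           "tlag": 0.0, "q": 0.0, "vp": 0.0}
    se = None
    if compute_se:
        se = _typical_se(theta, times, y, mask, dose, floor)
    return PopulationPKModel(typical=typical, iiv_sd=iiv, sigma_prop=sigma,
                             individual_estimates=individual,
                             objective=objective_value, converged=converged,
                             se=se)


def _typical_se(theta, times, y, mask, dose, floor):
    """Delta-method SEs of the typical values from a FD Hessian of -2LL."""
    idx = [0, 2, 3]  # log ka, log cl, log vc
    names = ["ka", "cl", "vc"]
    h = 1e-3
    sub = theta[idx]
    cache: dict = {}

    def f(x):
        th = theta.copy()
        th[idx] = x
        return _laplace_m2ll(th, times, y, mask, dose, floor, cache)

    k = len(idx)
    H = np.zeros((k, k))
    f0 = f(sub)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            fpp = f(sub + ei + ej)
            fpm = f(sub + ei - ej)
            fmp = f(sub - ei + ej)
            fmm = f(sub - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    try:
        cov_log = 2.0 * np.linalg.inv(H)  # -2LL Hessian = 2 * information
        var_log = np.clip(np.diag(cov_log), 0.0, np.inf)
    except np.linalg.LinAlgError:
        return None
    vals = np.exp(sub)
    return {nm: float(v * math.sqrt(vl)) for nm, v, vl in zip(names, vals, var_log)}
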