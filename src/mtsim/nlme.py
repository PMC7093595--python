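"""FOCE non-linear mixed-effects estimation for the maintenance-therapy model.

Population parameters (fixed effects theta, diagonal random-effect variances
omega2, residual variance sigma2) are estimated by the first-order
conditional estimation method with eta-epsilon interaction: for the current
population parameters, each patient's random-effect vector is set to its
posterior mode (empirical Bayes estimate, inner problem), and the marginal
-2 log-likelihood is approximated by a Laplace-type expansion around that
mode with a Fisher/Gauss-Newton Hessian in which the residual variance of
the proportional error model depends on eta (the interaction term).  The
outer problem minimizes the summed approximate -2 log-likelihood over the
log-transformed population parameters with a quasi-Newton method.

The objective includes all Gaussian normalizing constants, so on
linear-Gaussian problems it reproduces the exact marginal -2 log-likelihood;
its absolute value is comparable only across runs of this implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .pkpd import IndividualParameters, PKConstants, clearance_6tgn
from .cohort import PopulationModel, PatientRecord, PARAM_NAMES
from ._kernels import simulate_anc_sens, simulate_states

__all__ = ["MaintenanceModel", "FOCEResults", "fit_population",
           "individual_map_objective", "foce_objective", "standard_errors",
           "iiv_as_cv"]

LOG_2PI = math.log(2.0 * math.pi)

#: Names of the nine population parameters on the estimation (log) scale.
POP_PARAM_NAMES = ("Base", "k_tr", "gamma", "slope",
                   "w2_Base", "w2_ktr", "w2_gamma", "w2_slope", "sigma2")

_F_FLOOR = 1e-12   # floor on predictions inside the proportional variance


def iiv_as_cv(omega2) -> np.ndarray:
    """Log-normal IIV variance expressed as a coefficient of variation in
    percent: CV% = 100 * sqrt(exp(omega2) - 1)."""
    w = np.asarray(omega2, dtype=float)
    if np.any(w < 0):
        raise ValueError("omega2 must be nonnegative")
    return 100.0 * np.sqrt(np.expm1(w))


def _residual_variance(f, sigma2, error):
    if error == "proportional":
        return sigma2 * np.maximum(f, _F_FLOOR) ** 2
    if error == "additive":
        return np.full_like(f, sigma2)
    raise ValueError(f"unknown error model {error!r}")


def _map_value(y, f, eta, omega2, sigma2, error, active):
    """Inner (MAP) objective: -2 log [p(y|eta) p(eta)], all constants kept."""
    if f is None or not np.all(np.isfinite(f)):
        return np.inf
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        R = _residual_variance(f, sigma2, error)
        r = y - f
        val = float(np.sum(r * r / R + np.log(R)) + y.size * LOG_2PI)
        if active.any():
            w = omega2[active]
            e = eta[active]
            val += float(np.sum(e * e / w) + np.sum(np.log(w))
                         + active.sum() * LOG_2PI)
    if not np.isfinite(val):
        return np.inf
    return val


def _fd_jacobian(predict, eta, f0, active, step=1e-3):
    """Central-difference Jacobian of the prediction wrt the active etas
    (falls back to one-sided differences at integration-failure boundaries)."""
    G = np.zeros((f0.size, eta.size))
    for k in np.flatnonzero(active):
        ep = eta.copy()
        ep[k] += step
        em = eta.copy()
        em[k] -= step
        fp = predict(ep)
        fm = predict(em)
        ok_p = fp is not None and np.all(np.isfinite(fp))
        ok_m = fm is not None and np.all(np.isfinite(fm))
        if ok_p and ok_m:
            G[:, k] = (fp - fm) / (2.0 * step)
        elif ok_p:
            G[:, k] = (fp - f0) / step
        elif ok_m:
            G[:, k] = (f0 - fm) / step
        else:
            raise FloatingPointError("prediction failed in FD Jacobian")
    return G


def _grad_hess(y, f, G, eta, omega2, sigma2, error, active):
    """Gradient of the MAP objective and its Fisher/Gauss-Newton Hessian
    (interaction: residual variance derivatives included)."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        R = _residual_variance(f, sigma2, error)
        r = y - f
        idx = np.flatnonzero(active)
        Ga = G[:, idx]
        grad = -2.0 * Ga.T @ (r / R)
        H = 2.0 * (Ga.T * (1.0 / R)) @ Ga
        if error == "proportional":
            dR = 2.0 * sigma2 * np.maximum(f, _F_FLOOR)[:, None] * Ga  # dR/deta
            grad += dR.T @ (1.0 / R - (r * r) / (R * R))
            H += (dR.T * (1.0 / (R * R))) @ dR
        grad += 2.0 * eta[idx] / omega2[idx]
        H += 2.0 * np.diag(1.0 / omega2[idx])
    return grad, H


def _fg_from_predict(predict, active, fd_step=1e-3):
    """Wrap a value-only predictor into an ``(f, G)`` evaluator (FD Jacobian).

    Used for models without analytic sensitivities (toy problems, tests);
    the ODE model supplies exact forward sensitivities instead.
    """
    def fg(eta):
        f = predict(eta)
        if f is None or not np.all(np.isfinite(f)):
            return None, None
        return f, _fd_jacobian(predict, eta, f, active, fd_step)
    return fg


def _solve_inner(y, fg, omega2, sigma2, eta0=None, error="proportional",
                 gtol=1e-6, maxiter=100):
    """MAP estimation of one patient's random effects.

    ``fg(eta) -> (predictions, Jacobian wrt eta)`` (None, None on failure).
    Quasi-Newton (BFGS) minimization of the MAP objective with its analytic
    gradient; dimensions with omega2 == 0 are held at zero.  Returns
    ``(eta*, f*, G*, l*, converged)``; deterministic given its inputs.
    """
    omega2 = np.asarray(omega2, dtype=float)
    active = omega2 > 0
    idx = np.flatnonzero(active)
    eta = np.zeros(omega2.size) if eta0 is None else np.where(active, eta0, 0.0)

    def expand(z):
        e = np.zeros(omega2.size)
        e[idx] = z
        return e

    if not active.any():
        f, G = fg(eta)
        l = _map_value(y, f, eta, omega2, sigma2, error, active)
        return eta, f, (G if G is not None else np.zeros((y.size, omega2.size))), \
            l, np.isfinite(l)

    cache = {}

    def fun(z):
        e = expand(z)
        f, G = fg(e)
        if f is None:
            return 1e30, np.zeros(z.size)
        l = _map_value(y, f, e, omega2, sigma2, error, active)
        if not np.isfinite(l):
            return 1e30, np.zeros(z.size)
        grad, _ = _grad_hess(y, f, G, e, omega2, sigma2, error, active)
        if not np.all(np.isfinite(grad)):
            return 1e30, np.zeros(z.size)
        cache[z.tobytes()] = (e, f, G, l)
        return l, grad

    z0 = eta[idx]
    l0 = fun(z0)[0]
    if l0 >= 1e30 and np.any(z0 != 0):
        z0 = np.zeros(idx.size)
        l0 = fun(z0)[0]
    if l0 >= 1e30:
        return expand(z0), None, None, np.inf, False
    # seed the quasi-Newton with the Gauss-Newton curvature at the start
    e0, f0, G0, _ = cache[z0.tobytes()]
    _, H0 = _grad_hess(y, f0, G0, e0, omega2, sigma2, error, active)
    hinv0 = None
    if np.all(np.isfinite(H0)):
        try:
            hinv0 = np.linalg.inv(H0)
            hinv0 = 0.5 * (hinv0 + hinv0.T)
            np.linalg.cholesky(hinv0)
        except np.linalg.LinAlgError:
            hinv0 = None
    opts = {"gtol": gtol, "maxiter": maxiter}
    if hinv0 is not None:
        opts["hess_inv0"] = hinv0
    res = minimize(fun, z0, jac=True, method="BFGS", options=opts)
    hit = cache.get(np.asarray(res.x).tobytes())
    if hit is None or hit[3] > l0:
        # fall back to the best cached point (BFGS can end on a worse iterate)
        hit = min(cache.values(), key=lambda v: v[3])
    eta, f, G, l = hit
    grad, _ = _grad_hess(y, f, G, eta, omega2, sigma2, error, active)
    converged = bool(np.linalg.norm(grad) < max(gtol * 10.0,
                                                1e-4 * (1.0 + abs(l))))
    return eta, f, G, l, converged


def _focei_term(y, fg, omega2, sigma2, eta0=None, error="proportional",
                **inner_kw):
    """One patient's FOCE-I contribution to -2 log L.

    Returns ``(objective_i, eta*, f*, converged)``.
    """
    eta, f, G, l, conv = _solve_inner(y, fg, omega2, sigma2, eta0, error,
                                      **inner_kw)
    if not np.isfinite(l):
        return np.inf, eta, f, False
    active = np.asarray(omega2) > 0
    q = int(active.sum())
    if q == 0:
        return l, eta, f, conv
    _, H = _grad_hess(y, f, G, eta, np.asarray(omega2, dtype=float),
                      sigma2, error, active)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return np.inf, eta, f, False
    obj = l + logdet - q * math.log(4.0 * math.pi)
    return obj, eta, f, conv


# --------------------------------------------------------------------------
# ODE-backed patient predictors

class _PatientData:
    """Precompiled arrays for one patient's trajectory evaluations."""

    __slots__ = ("id", "y", "obs_t", "dose_t", "dose_a", "cl", "bsa")

    def __init__(self, record: PatientRecord, consts: PKConstants):
        self.id = record.id
        self.y = np.asarray(record.anc, dtype=float)
        self.obs_t = np.asarray(record.obs_times, dtype=float)
        self.dose_t = record.doses.times
        self.dose_a = record.doses.amounts
        self.bsa = record.bsa
        self.cl = clearance_6tgn(record.bsa, consts)

    def predict(self, params: np.ndarray, consts: PKConstants,
                step: float) -> Optional[np.ndarray]:
        """Model ANC at the observation times for individual parameters
        ``(Base, k_tr, gamma, slope)``; None on integration failure."""
        base, ktr, gamma, slope = params
        if not (base > 0 and ktr > 0 and gamma > 0 and slope >= 0):
            return None
        pool = base * consts.k_ma / ktr
        x0 = np.array([0.0, 0.0, 0.0, pool, pool, pool, pool, base])
        states = simulate_states(self.obs_t, self.dose_t, self.dose_a, x0, 0.0,
                                 base, ktr, gamma, slope,
                                 consts.F, consts.k_a, consts.k_20,
                                 consts.k_met, self.cl, consts.k_ma, step)
        f = states[:, 7]
        if np.any(np.isnan(f)):
            return None
        return f

    def predict_with_sens(self, params: np.ndarray, consts: PKConstants,
                          step: float):
        """ANC and its exact sensitivities wrt the individual parameters."""
        base, ktr, gamma, slope = params
        if not (base > 0 and ktr > 0 and gamma > 0 and slope >= 0):
            return None, None
        f, S = simulate_anc_sens(self.obs_t, self.dose_t, self.dose_a,
                                 base, ktr, gamma, slope,
                                 consts.F, consts.k_a, consts.k_20,
                                 consts.k_met, self.cl, consts.k_ma, step)
        if np.any(np.isnan(f)):
            return None, None
        return f, S


def _predictor(pdat: _PatientData, theta: np.ndarray, consts: PKConstants,
               step: float) -> Callable:
    def predict(eta):
        return pdat.predict(theta * np.exp(eta), consts, step)
    return predict


def _fg_ode(pdat: _PatientData, theta: np.ndarray, consts: PKConstants,
            step: float) -> Callable:
    """(f, Jacobian-wrt-eta) evaluator: by the chain rule through
    theta_i = theta * exp(eta), d f / d eta_j = (d f / d theta_ij) * theta_ij."""
    def fg(eta):
        params = theta * np.exp(eta)
        f, S = pdat.predict_with_sens(params, consts, step)
        if f is None:
            return None, None
        return f, S * params[None, :]
    return fg


def individual_map_objective(record: PatientRecord, theta, omega2, sigma2,
                             eta, consts: PKConstants = PKConstants(),
                             error: str = "proportional",
                             step: float = 0.25) -> float:
    """MAP objective of one patient's random effects at a given ``eta``."""
    theta = np.asarray(theta, dtype=float) if not isinstance(theta, IndividualParameters) \
        else theta.as_array()
    pdat = _PatientData(record, consts)
    f = _predictor(pdat, theta, consts, step)(np.asarray(eta, dtype=float))
    omega2 = np.asarray(omega2, dtype=float)
    return _map_value(pdat.y, f, np.asarray(eta, dtype=float), omega2, sigma2,
                      error, omega2 > 0)


def foce_objective(records, theta, omega2, sigma2,
                   consts: PKConstants = PKConstants(),
                   error: str = "proportional", step: float = 0.25,
                   etas0=None) -> float:
    """Summed FOCE-I approximate -2 log-likelihood over all patients."""
    theta = np.asarray(theta, dtype=float) if not isinstance(theta, IndividualParameters) \
        else theta.as_array()
    total = 0.0
    for i, rec in enumerate(records):
        pdat = _PatientData(rec, consts)
        eta0 = None if etas0 is None else etas0[i]
        obj, _, _, _ = _focei_term(pdat.y, _fg_ode(pdat, theta, consts, step),
                                   np.asarray(omega2, dtype=float), sigma2,
                                   eta0, error)
        total += obj
    return total


# --------------------------------------------------------------------------
# Model / Results

class MaintenanceModel:
    """Population PK/PD model for a cohort of maintenance-therapy patients.

    Parameters
    ----------
    records : sequence of PatientRecord
        Filtered longitudinal data (dose events + ANC observations).
    consts : PKConstants
        Fixed published PK constants.
    error : {"proportional", "additive"}
        Residual error model; the study design uses "proportional".
    ode_step : float
        Maximum RK4 step (day) for trajectory evaluation during fitting.
    """

    def __init__(self, records: Sequence[PatientRecord],
                 consts: PKConstants = PKConstants(),
                 error: str = "proportional",
                 ode_step: float = 0.25):
        if len(records) < 1:
            raise ValueError("need at least one patient record")
        self.records = list(records)
        self.consts = consts
        self.error = error
        self.ode_step = float(ode_step)
        self._pdata = [_PatientData(r, consts) for r in self.records]
        self.n_obs = int(sum(p.y.size for p in self._pdata))

    # -- objective ---------------------------------------------------------

    def _objective(self, theta, omega2, sigma2, warm_etas, inner_kw=None):
        """FOCE-I objective with warm-started inner problems.

        ``warm_etas`` (n_patients, 4) is updated in place with the new
        empirical Bayes estimates.
        """
        inner_kw = inner_kw or {}
        total = 0.0
        preds = []
        all_conv = True
        for i, pdat in enumerate(self._pdata):
            obj, eta, f, conv = _focei_term(
                pdat.y, _fg_ode(pdat, theta, self.consts, self.ode_step),
                omega2, sigma2, warm_etas[i], self.error, **inner_kw)
            if not np.isfinite(obj):
                return np.inf, preds, False
            warm_etas[i] = eta
            preds.append(f)
            all_conv = all_conv and conv
            total += obj
        return total, preds, all_conv

    def default_start(self) -> PopulationModel:
        """Literature-anchored starting values (published population
        estimates rounded to one significant figure).

        The maturation delay makes the marginal likelihood multimodal in
        k_tr (delay aliasing against the weekly sampling grid); starting far
        from the literature maturation time can converge to a spurious
        high-k_tr mode, so informed initial estimates are the default, as is
        standard pharmacometric practice.
        """
        return PopulationModel(theta=IndividualParameters(2.0, 0.15, 0.8, 0.2),
                               omega2=np.full(4, 0.05), sigma2=0.2)

    @staticmethod
    def _pack(pop: PopulationModel) -> np.ndarray:
        w = np.where(pop.omega2 > 0, pop.omega2, 1.0)  # placeholder for fixed-zero
        return np.log(np.concatenate([pop.theta.as_array(), w, [pop.sigma2]]))

    @staticmethod
    def _unpack(x: np.ndarray, zero_w: np.ndarray) -> tuple:
        v = np.exp(x)
        theta = v[:4]
        omega2 = np.where(zero_w, 0.0, v[4:8])
        return theta, omega2, float(v[8])

    def fit(self, start: Optional[PopulationModel] = None,
            fix: Sequence[str] = (),
            maxiter: int = 150,
            verbose: bool = False,
            compute_se: bool = False) -> "FOCEResults":
        """Estimate the population parameters by FOCE-I.

        ``fix`` lists parameters (names from :data:`POP_PARAM_NAMES`) held at
        their starting values; an omega2 entry started at zero is fixed at
        zero automatically (its random effect is switched off).
        """
        start = start or self.default_start()
        for name in fix:
            if name not in POP_PARAM_NAMES:
                raise ValueError(f"unknown parameter name {name!r}")
        zero_w = np.asarray(start.omega2) == 0.0
        fixed_mask = np.array([n in fix for n in POP_PARAM_NAMES])
        fixed_mask[4:8] |= zero_w
        free = ~fixed_mask
        if not free.any():
            raise ValueError("no free parameters to estimate")

        x_full = self._pack(start)
        # Inner problems start from the etas of the best point seen so far;
        # the base is frozen between improvements so the objective stays a
        # locally deterministic function of x (finite differences need this).
        warm_base = np.zeros((len(self._pdata), 4))
        best = {"obj": np.inf, "x": x_full[free].copy(), "etas": warm_base,
                "preds": None, "conv": False}
        history: list = []
        n_evals = [0]
        cache: dict = {}

        def fun(x_free):
            x = x_full.copy()
            x[free] = x_free
            theta, omega2, sigma2 = self._unpack(x, zero_w)
            etas = best["etas"].copy()
            total, preds, all_conv = self._objective(theta, omega2, sigma2, etas)
            n_evals[0] += 1
            if not np.isfinite(total):
                total = 1e30
            elif total < best["obj"]:
                best.update(obj=total, x=np.array(x_free, copy=True),
                            etas=etas, preds=preds, conv=all_conv)
            cache[np.asarray(x_free).tobytes()] = total
            return total

        def cb(x_free):
            val = cache.get(np.asarray(x_free).tobytes())
            if val is None:
                val = fun(np.asarray(x_free))
            history.append(val)
            if verbose:
                print(f"iter {len(history):3d}  objective {val:.6f}")

        # ftol is relative: with objectives O(10^3-10^4) this stops once an
        # accepted step improves the -2LL by less than ~1e-4.  L-BFGS-B can
        # stall early when a line search fails on finite-difference gradient
        # noise, so after each termination the optimizer is restarted from
        # the best point (fresh curvature memory, alternated FD step) until
        # no restart improves the objective by more than 1e-3.
        iters_left = maxiter
        res = None
        for attempt, eps in enumerate((1e-4, 3e-4, 1e-4, 3e-4)):
            if iters_left <= 0:
                break
            prev_best = best["obj"]
            res_a = minimize(fun, best["x"].copy(), method="L-BFGS-B",
                             jac=None, callback=cb,
                             options={"maxiter": iters_left, "ftol": 2e-8,
                                      "gtol": 1e-6, "eps": eps})
            iters_left -= max(int(res_a.nit), 1)
            if res is None or res_a.fun <= res.fun:
                res = res_a
            if attempt > 0 and prev_best - best["obj"] < 1e-3:
                break
        x_hat = x_full.copy()
        x_hat[free] = best["x"]
        theta, omega2, sigma2 = self._unpack(x_hat, zero_w)
        if best["preds"] is None:  # every evaluation failed
            raise FloatingPointError("FOCE objective not finite anywhere; "
                                     "check starting values")
        pop_hat = PopulationModel(theta=IndividualParameters.from_array(theta),
                                  omega2=omega2, sigma2=sigma2)
        result = FOCEResults(model=self, pop=pop_hat,
                             etas=best["etas"].copy(),
                             objective=float(best["obj"]),
                             predictions=best["preds"],
                             converged=bool(res.success) and best["conv"],
                             n_iter=int(maxiter - iters_left), n_evals=n_evals[0],
                             history=list(history), message=str(res.message),
                             free_mask=free, zero_w=zero_w, start=start)
        if compute_se:
            result.compute_standard_errors()
        return result


@dataclass
class FOCEResults:
    """Estimates, empirical Bayes etas, diagnostics and summaries of a fit."""

    model: MaintenanceModel
    pop: PopulationModel
    etas: np.ndarray
    objective: float
    predictions: list
    converged: bool
    n_iter: int
    n_evals: int
    history: list
    message: str
    free_mask: np.ndarray
    zero_w: np.ndarray
    start: PopulationModel
    rse: Optional[dict] = None
    cov: Optional[np.ndarray] = None
    se_diagnostics: Optional[dict] = None

    @property
    def theta(self) -> IndividualParameters:
        return self.pop.theta

    @property
    def iiv_cv(self) -> np.ndarray:
        """IIV expressed as CV% per parameter (Base, k_tr, gamma, slope)."""
        return iiv_as_cv(self.pop.omega2)

    def individual_parameters(self, i: int) -> IndividualParameters:
        return self.pop.theta.scaled(self.etas[i])

    def params_vector(self) -> np.ndarray:
        return np.concatenate([self.pop.theta.as_array(), self.pop.omega2,
                               [self.pop.sigma2]])

    def eta_frame(self):
        import pandas as pd

        return pd.DataFrame(self.etas,
                            columns=[f"eta_{n}" for n in PARAM_NAMES],
                            index=pd.Index([r.id for r in self.model.records],
                                           name="id"))

    def predict(self):
        """Per-observation individual predictions as a tidy DataFrame."""
        import pandas as pd

        rows = []
        for rec, f in zip(self.model.records, self.predictions):
            rows.append(pd.DataFrame({"id": rec.id, "time": rec.obs_times,
                                      "observed": rec.anc, "predicted": f}))
        return pd.concat(rows, ignore_index=True)

    def compute_standard_errors(self, step: float = 1e-3) -> dict:
        """Relative standard errors (%) from the finite-difference Hessian of
        the FOCE objective on the estimation (log) scale; covariance is
        2 H^-1, delta-method back-transformed."""
        out = standard_errors(self, step=step)
        return out

    def summary(self) -> str:
        lines = []
        w = 58
        lines.append("=" * w)
        lines.append("FOCE-I population fit: 6MP maintenance-therapy PK/PD model")
        lines.append("=" * w)
        lines.append(f"patients: {len(self.model.records):4d}    "
                     f"observations: {self.model.n_obs:5d}")
        lines.append(f"objective (-2LL approx): {self.objective:.3f}")
        lines.append(f"converged: {self.converged}   outer iterations: {self.n_iter}"
                     f"   evaluations: {self.n_evals}")
        lines.append("-" * w)
        lines.append("Fixed effects" + (" (RSE%)" if self.rse else ""))
        th = self.pop.theta.as_array()
        for k, name in enumerate(PARAM_NAMES):
            r = f"  ({self.rse[name]:.3g}%)" if self.rse else ""
            lines.append(f"  {name:<8s} {th[k]:10.4g}{r}")
        lines.append("Inter-individual variability (CV%)")
        for k, name in enumerate(PARAM_NAMES):
            nm = f"w2_{name.replace('k_tr', 'ktr')}"
            r = (f"  ({self.rse[nm]:.3g}%)"
                 if self.rse and nm in self.rse and np.isfinite(self.rse[nm]) else "")
            fixed = " (FIXED)" if self.zero_w[k] else ""
            lines.append(f"  {name:<8s} {self.iiv_cv[k]:10.4g}{fixed}{r}")
        r = (f"  ({self.rse['sigma2']:.3g}%)"
             if self.rse and np.isfinite(self.rse.get("sigma2", np.nan)) else "")
        lines.append(f"Proportional error variance: {self.pop.sigma2:.4g}{r}")
        lines.append("=" * w)
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Serialize estimates + etas as flat text artifacts."""
        import pathlib
        import pandas as pd
        import yaml

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        payload = {
            "theta": {n: float(v) for n, v in
                      zip(PARAM_NAMES, self.pop.theta.as_array())},
            "omega2": [float(v) for v in self.pop.omega2],
            "sigma2": float(self.pop.sigma2),
            "objective": float(self.objective),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }
        with open(d / "population.yaml", "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
        self.eta_frame().to_csv(d / "etas.csv", float_format="%.6g")
        with open(d / "fit_report.txt", "w") as fh:
            fh.write(self.summary() + "\n")


def load_fit(directory, records, consts: PKConstants = PKConstants(),
             ode_step: float = 0.25) -> FOCEResults:
    """Rebuild a results object from ``save`` artifacts plus the dataset."""
    import pathlib
    import pandas as pd
    import yaml

    d = pathlib.Path(directory)
    with open(d / "population.yaml") as fh:
        payload = yaml.safe_load(fh)
    pop = PopulationModel(
        theta=IndividualParameters(**{k: payload["theta"][k] for k in PARAM_NAMES}),
        omega2=np.asarray(payload["omega2"], dtype=float),
        sigma2=float(payload["sigma2"]))
    etas = pd.read_csv(d / "etas.csv", index_col=0).to_numpy()
    model = MaintenanceModel(records, consts=consts, ode_step=ode_step)
    preds = []
    for i, pdat in enumerate(model._pdata):
        preds.append(pdat.predict(pop.theta.scaled(etas[i]).as_array(),
                                  consts, ode_step))
    zero_w = pop.omega2 == 0.0
    free = np.ones(9, dtype=bool)
    free[4:8] &= ~zero_w
    return FOCEResults(model=model, pop=pop, etas=etas,
                       objective=float(payload["objective"]),
                       predictions=preds, converged=bool(payload["converged"]),
                       n_iter=int(payload["n_iter"]), n_evals=0, history=[],
                       message="loaded", free_mask=free, zero_w=zero_w,
                       start=pop)


def fit_population(records, init: Optional[PopulationModel] = None,
                   options: Optional[dict] = None) -> FOCEResults:
    """Functional wrapper: build a :class:`MaintenanceModel` and fit it."""
    options = dict(options or {})
    model = MaintenanceModel(
        records,
        consts=options.pop("consts", PKConstants()),
        error=options.pop("error", "proportional"),
        ode_step=options.pop("ode_step", 0.25))
    return model.fit(start=init, **options)


def standard_errors(fit: FOCEResults, step: float = 1e-3) -> dict:
    """RSE (%) per population parameter from the curvature of the FOCE
    objective at the optimum.

    The Hessian H of the objective (a -2 log-likelihood) on the log scale is
    computed by central finite differences; the covariance of the log
    estimates is 2 H^-1 and, by the delta method, RSE% of a natural-scale
    parameter equals 100 * SE(log parameter).  A non-positive-definite
    Hessian yields NaN RSEs and eigenvalue diagnostics.
    """
    model = fit.model
    free = fit.free_mask
    zero_w = fit.zero_w
    x_hat = np.log(np.where(
        np.concatenate([fit.pop.theta.as_array(),
                        np.where(zero_w, 1.0, fit.pop.omega2),
                        [fit.pop.sigma2]]) > 0,
        np.concatenate([fit.pop.theta.as_array(),
                        np.where(zero_w, 1.0, fit.pop.omega2),
                        [fit.pop.sigma2]]), 1.0))
    warm = fit.etas.copy()

    def fun(x):
        theta, omega2, sigma2 = MaintenanceModel._unpack(x, zero_w)
        total, _, _ = model._objective(theta, omega2, sigma2, warm)
        return total

    idx = np.flatnonzero(free)
    m = idx.size
    H = np.empty((m, m))
    f0 = fun(x_hat)
    for a in range(m):
        xp = x_hat.copy(); xp[idx[a]] += step
        xm = x_hat.copy(); xm[idx[a]] -= step
        H[a, a] = (fun(xp) - 2.0 * f0 + fun(xm)) / step ** 2
        for b in range(a + 1, m):
            xpp = x_hat.copy(); xpp[idx[a]] += step; xpp[idx[b]] += step
            xpm = x_hat.copy(); xpm[idx[a]] += step; xpm[idx[b]] -= step
            xmp = x_hat.copy(); xmp[idx[a]] -= step; xmp[idx[b]] += step
            xmm = x_hat.copy(); xmm[idx[a]] -= step; xmm[idx[b]] -= step
            H[a, b] = H[b, a] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) \
                / (4.0 * step ** 2)
    eigvals = np.linalg.eigvalsh(H)
    rse = {n: float("nan") for n in POP_PARAM_NAMES}
    diagnostics = {"eigenvalues": eigvals.tolist(), "pd": bool(eigvals.min() > 0)}
    cov = None
    if eigvals.min() > 0:
        cov = 2.0 * np.linalg.inv(H)
        se_log = np.sqrt(np.diag(cov))
        for k, j in enumerate(idx):
            rse[POP_PARAM_NAMES[j]] = float(100.0 * se_log[k])
    fit.rse = rse
    fit.cov = cov
    fit.se_diagnostics = diagnostics
    return rse
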