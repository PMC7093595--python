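"""Model validation: per-patient accuracy metrics, held-out prediction, and
the visual predictive check (VPC).

Accuracy follows the study convention: MAE and RMSE are computed per patient
from individual (empirical-Bayes) predictions, then summarized by the median
and standard deviation across patients.  The VPC simulates many replicate
cohorts from the estimated population distribution on each patient's own
design (doses, observation times, BSA) and compares observed percentiles per
time bin with the simulated percentile bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import PopulationModel, _observe
from .nlme import FOCEResults, _PatientData
from .pkpd import PKConstants

__all__ = ["AccuracyReport", "VPCResult", "accuracy_metrics", "vpc",
           "predict_held_out"]


@dataclass
class AccuracyReport:
    """Per-patient MAE/RMSE (G/L) and their cohort median and SD."""

    scope: str
    per_patient: "pd.DataFrame"  # noqa: F821  (id, n, mae, rmse)
    median_mae: float
    sd_mae: float
    median_rmse: float
    sd_rmse: float
    n_patients_scored: int
    n_patients_skipped: int

    def to_frame(self):
        return self.per_patient


def _scope_mask(n_obs: int, scope: str, train_fraction: float) -> np.ndarray:
    mask = np.ones(n_obs, dtype=bool)
    if scope == "all":
        return mask
    n_train = max(1, math.floor(train_fraction * n_obs))
    if scope == "train":
        mask[n_train:] = False
    elif scope == "test":
        mask[:n_train] = False
    else:
        raise ValueError(f"unknown scope {scope!r} (use all/train/test)")
    return mask


def _individual_predictions(records, fit: FOCEResults):
    """Individual (EBE) model ANC at each record's observation times.

    Uses the fit's theta and per-patient eta; records may extend past the
    data the fit was estimated on (held-out prediction), in which case the
    trajectory is forward-simulated with the training-data eta.
    """
    consts = fit.model.consts
    eta_by_id = {rec.id: fit.etas[i] for i, rec in enumerate(fit.model.records)}
    preds = []
    for rec in records:
        if rec.id not in eta_by_id:
            raise KeyError(f"no empirical Bayes estimate for patient {rec.id}")
        params = fit.pop.theta.scaled(eta_by_id[rec.id])
        pdat = _PatientData(rec, consts)
        f = pdat.predict(params.as_array(), consts, fit.model.ode_step)
        if f is None:
            raise FloatingPointError(f"prediction failed for patient {rec.id}")
        preds.append(f)
    return preds


def accuracy_metrics(records, fit: FOCEResults, scope: str = "all",
                     train_fraction: float = 0.7) -> AccuracyReport:
    """MAE/RMSE per patient on the selected observation scope, summarized by
    the median and SD across patients.  Patients with no scored observation
    in the scope are skipped (counted)."""
    preds = _individual_predictions(records, fit)
    return accuracy_from_predictions(records, preds, scope, train_fraction)


def accuracy_from_predictions(records, preds, scope: str = "all",
                              train_fraction: float = 0.7) -> AccuracyReport:
    """Accuracy summary from explicit per-patient prediction arrays."""
    import pandas as pd

    rows = []
    skipped = 0
    for rec, f in zip(records, preds):
        mask = _scope_mask(rec.n_obs, scope, train_fraction)
        if not mask.any():
            skipped += 1
            continue
        r = rec.anc[mask] - f[mask]
        mae = float(np.mean(np.abs(r)))
        rmse = float(np.sqrt(np.mean(r * r)))
        rows.append({"id": rec.id, "n": int(mask.sum()),
                     "mae": mae, "rmse": rmse})
    if not rows:
        raise ValueError("no patient had observations in the requested scope")
    df = pd.DataFrame(rows)
    return AccuracyReport(scope=scope, per_patient=df,
                          median_mae=float(df["mae"].median()),
                          sd_mae=float(df["mae"].std(ddof=1)) if len(df) > 1 else 0.0,
                          median_rmse=float(df["rmse"].median()),
                          sd_rmse=float(df["rmse"].std(ddof=1)) if len(df) > 1 else 0.0,
                          n_patients_scored=len(df),
                          n_patients_skipped=skipped)


def predict_held_out(records, fit_on_train: FOCEResults,
                     train_fraction: float = 0.7):
    """Predictions for each patient's final held-out observations.

    ``fit_on_train`` must have been estimated on the training portion only;
    the patient's eta (conditioned on training data) is fixed and the
    trajectory is forward-simulated over the full horizon, so no held-out
    information enters the prediction.
    """
    import pandas as pd

    preds = _individual_predictions(records, fit_on_train)
    rows = []
    for rec, f in zip(records, preds):
        mask = _scope_mask(rec.n_obs, "test", train_fraction)
        rows.append(pd.DataFrame({"id": rec.id,
                                  "time": rec.obs_times[mask],
                                  "observed": rec.anc[mask],
                                  "predicted": f[mask]}))
    return pd.concat(rows, ignore_index=True)


@dataclass
class VPCResult:
    """Percentile bands of a visual predictive check."""

    bin_edges: np.ndarray
    bin_mid: np.ndarray
    percentiles: tuple
    observed: np.ndarray       # (n_pct, n_bins)
    simulated: np.ndarray      # (n_pct, n_bins) median across replicates
    sim_ci_lo: np.ndarray      # 95% CI of each simulated percentile
    sim_ci_hi: np.ndarray
    n_sim: int
    n_obs: int
    coverage: float            # fraction of observations inside outer band

    def to_frame(self):
        import pandas as pd

        rows = {"bin_mid": self.bin_mid}
        for k, p in enumerate(self.percentiles):
            rows[f"obs_p{p}"] = self.observed[k]
            rows[f"sim_p{p}"] = self.simulated[k]
            rows[f"sim_p{p}_lo"] = self.sim_ci_lo[k]
            rows[f"sim_p{p}_hi"] = self.sim_ci_hi[k]
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4.5))
        for k, p in enumerate(self.percentiles):
            ax.fill_between(self.bin_mid, self.sim_ci_lo[k], self.sim_ci_hi[k],
                            alpha=0.3, color="C0", linewidth=0)
            ax.plot(self.bin_mid, self.simulated[k], "C0-")
            style = "k-" if p == 50 else "k--"
            ax.plot(self.bin_mid, self.observed[k], style)
        ax.set_xlabel("time (days)")
        ax.set_ylabel("ANC (G/L)")
        return ax


def _auto_bins(times: np.ndarray, n_bins: Optional[int]) -> np.ndarray:
    distinct = np.unique(times)
    if n_bins is None:
        n_bins = max(8, int(round(math.sqrt(distinct.size))))
    n_bins = min(n_bins, distinct.size)
    edges = np.quantile(times, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    return edges


def vpc(records, fit, n_sim: int = 1000,
        percentiles: tuple = (2.5, 50.0, 97.5),
        n_bins: Optional[int] = None, seed: int = 0,
        consts: Optional[PKConstants] = None,
        ode_step: float = 0.25) -> VPCResult:
    """Visual predictive check.

    ``fit`` is a :class:`FOCEResults` or a :class:`PopulationModel`; replicate
    cohorts are simulated from the population distribution on every patient's
    own design.  Time bins are observation-time quantile bins
    (round(sqrt(#distinct times)) bins, minimum 8).
    """
    import warnings

    if n_sim < 100:
        warnings.warn("n_sim < 100: VPC confidence intervals are unreliable")
    if isinstance(fit, FOCEResults):
        pop = fit.pop
        consts = consts or fit.model.consts
        ode_step = fit.model.ode_step
    else:
        pop = fit
        consts = consts or PKConstants()
    rng = np.random.default_rng(seed)

    times = np.concatenate([r.obs_times for r in records])
    y_obs = np.concatenate([r.anc for r in records])
    edges = _auto_bins(times, n_bins)
    nb = edges.size - 1
    bin_idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, nb - 1)
    bin_mid = np.array([times[bin_idx == b].mean() if np.any(bin_idx == b)
                        else 0.5 * (edges[b] + edges[b + 1]) for b in range(nb)])
    pct = np.asarray(percentiles, dtype=float)

    observed = np.vstack([
        [np.percentile(y_obs[bin_idx == b], p) if np.any(bin_idx == b) else np.nan
         for b in range(nb)] for p in pct])

    pdata = [_PatientData(r, consts) for r in records]
    sim_pct = np.empty((n_sim, pct.size, nb))
    sim_all = np.empty((n_sim, y_obs.size))
    for s in range(n_sim):
        y_sim = np.empty_like(y_obs)
        pos = 0
        for pdat in pdata:
            eta = rng.normal(0.0, np.sqrt(pop.omega2))
            f = pdat.predict(pop.theta.scaled(eta).as_array(), consts, ode_step)
            tries = 0
            while f is None and tries < 10:
                eta = rng.normal(0.0, np.sqrt(pop.omega2))
                f = pdat.predict(pop.theta.scaled(eta).as_array(), consts, ode_step)
                tries += 1
            if f is None:
                f = pdat.predict(pop.theta.as_array(), consts, ode_step)
            y, _ = _observe(f, pop.sigma2, rng)
            y_sim[pos:pos + f.size] = y
            pos += f.size
        sim_all[s] = y_sim
        for b in range(nb):
            m = bin_idx == b
            if np.any(m):
                sim_pct[s, :, b] = np.percentile(y_sim[m], pct)
            else:
                sim_pct[s, :, b] = np.nan

    simulated = np.median(sim_pct, axis=0)
    ci_lo = np.percentile(sim_pct, 2.5, axis=0)
    ci_hi = np.percentile(sim_pct, 97.5, axis=0)

    # coverage against the pooled predictive distribution per bin: tail
    # quantiles from a single replicate's ~n/bins values are order-statistic
    # biased inward, so pooling all replicates (n_sim * bin occupancy draws)
    # is used for the coverage statistic
    lo_band = np.empty(nb)
    hi_band = np.empty(nb)
    for b in range(nb):
        m = bin_idx == b
        if np.any(m):
            pool = sim_all[:, m].ravel()
            lo_band[b], hi_band[b] = np.percentile(pool, [pct[0], pct[-1]])
        else:
            lo_band[b], hi_band[b] = np.nan, np.nan
    coverage = float(np.mean((y_obs >= lo_band[bin_idx])
                             & (y_obs <= hi_band[bin_idx])))

    return VPCResult(bin_edges=edges, bin_mid=bin_mid,
                     percentiles=tuple(pct.tolist()), observed=observed,
                     simulated=simulated, sim_ci_lo=ci_lo, sim_ci_hi=ci_hi,
                     n_sim=n_sim, n_obs=y_obs.size, coverage=coverage)
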