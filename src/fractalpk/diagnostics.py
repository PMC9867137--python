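"""Numerical and visual model diagnostics for population PK fits.

Information criteria on the OFV scale (AIC = OFV + 2k,
AICc = AIC + 2k(k+1)/(n-k-1)), likelihood-ratio significance at the
chi-squared 95th percentile (3.84 for one added parameter, 5.99 for two),
goodness-of-fit residual tables (PRED/IPRED/IWRES/CWRES), the
prediction-corrected visual predictive check, and normalized prediction
distribution errors.  The visual diagnostics return plain tables; plotting
is left to the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .io import PKDataset
from .population import (
    FitResult,
    _parse_subjects,
    _predict_subject,
    _ESTIMATION_SOLVER,
)
from .simulate import SolverOptions

__all__ = [
    "CriterionSet",
    "LRTResult",
    "VPCResult",
    "NPDEResult",
    "criteria",
    "lrt_significant",
    "gof",
    "pcvpc",
    "npde",
    "prediction_discrepancy",
]


# ---------------------------------------------------------------------------
# OFV-derived criteria
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CriterionSet:
    """OFV, AIC and AICc for one fit, with deltas versus a comparator."""

    ofv: float
    k: int
    n: int
    aic: float
    aicc: float
    aicc_defined: bool
    delta_ofv: float | None = None
    delta_aic: float | None = None
    delta_aicc: float | None = None


def criteria(ofv: float, k: int, n: int, comparator: CriterionSet | None = None) -> CriterionSet:
    """Exact AIC/AICc arithmetic from an OFV (-2 log likelihood).

    AICc needs ``n > k + 1``; otherwise it is flagged undefined (NaN).
    When ``comparator`` is given, deltas are ``this - comparator``.
    """
    aic = ofv + 2.0 * k
    if n > k + 1:
        aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
        defined = True
    else:
        aicc = math.nan
        defined = False
    d_ofv = d_aic = d_aicc = None
    if comparator is not None:
        d_ofv = ofv - comparator.ofv
        d_aic = aic - comparator.aic
        d_aicc = aicc - comparator.aicc
    return CriterionSet(
        ofv=float(ofv),
        k=int(k),
        n=int(n),
        aic=float(aic),
        aicc=float(aicc),
        aicc_defined=defined,
        delta_ofv=d_ofv,
        delta_aic=d_aic,
        delta_aicc=d_aicc,
    )


@dataclass(frozen=True)
class LRTResult:
    threshold: float
    significant: bool
    delta_ofv: float
    delta_k: int
    alpha: float


def lrt_significant(delta_ofv: float, delta_k: int, alpha: float = 0.05) -> LRTResult:
    """Likelihood-ratio significance of an OFV drop for ``delta_k`` added
    parameters: the threshold is the chi-squared ``1 - alpha`` quantile
    (3.84 / 5.99 for 1 / 2 df at 5%), and the change is significant when
    the OFV decrease reaches it."""
    if delta_k < 1:
        raise ValueError("delta_k must be >= 1")
    threshold = float(stats.chi2.ppf(1.0 - alpha, delta_k))
    decrease = -float(delta_ofv)
    return LRTResult(
        threshold=threshold,
        significant=bool(decrease >= threshold),
        delta_ofv=float(delta_ofv),
        delta_k=int(delta_k),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


def _subject_jacobian(model, spec, subj, eta, solver, fd_step=1e-4):
    q = len(model.eta_names)
    f0 = _predict_subject(spec, model, eta, subj, solver)
    J = np.empty((len(f0), q))
    for k in range(q):
        step = np.zeros(q)
        step[k] = fd_step
        fp = _predict_subject(spec, model, eta + step, subj, solver)
        fm = _predict_subject(spec, model, eta - step, subj, solver)
        J[:, k] = (fp - fm) / (2 * fd_step)
    return f0, J


def gof(fit: FitResult, data: PKDataset, solver: SolverOptions | None = None) -> pd.DataFrame:
    """Per-observation residual table: DV, PRED, IPRED, IWRES, CWRES, TIME.

    PRED is the eta=0 population prediction; IPRED uses the empirical Bayes
    etas; IWRES standardizes by the residual s.d. at IPRED; CWRES comes
    from the FOCE linearization about the EBEs, decorrelated by the
    model-implied per-subject observation covariance.
    """
    if not fit.ebes:
        raise ValueError("fit has no empirical Bayes estimates; run fit() first")
    solver = solver or _ESTIMATION_SOLVER
    model = fit.model
    spec = model.substituted_spec()
    q = len(model.eta_names)
    omega = np.diag([model.omega[k] for k in model.eta_names]) if q else np.zeros((0, 0))
    frames = []
    for subj in _parse_subjects(data):
        eta = np.asarray(fit.ebes.get(subj.sid, np.zeros(q)), dtype=float)
        pred = _predict_subject(spec, model, np.zeros(q), subj, solver)
        if q:
            ipred, J = _subject_jacobian(model, spec, subj, eta, solver)
            # FOCE mean and covariance of the observation vector
            mean = ipred - J @ eta
            cov = J @ omega @ J.T + np.diag(model.residual_variance(ipred))
            L = np.linalg.cholesky(cov)
            cwres = solve_triangular(L, subj.y - mean, lower=True)
        else:
            ipred = pred
            sd = np.sqrt(model.residual_variance(ipred))
            cwres = (subj.y - ipred) / sd
        iwres = (subj.y - ipred) / np.sqrt(model.residual_variance(ipred))
        frames.append(
            pd.DataFrame(
                {
                    "ID": subj.sid,
                    "TIME": subj.times,
                    "DV": subj.y,
                    "PRED": pred,
                    "IPRED": ipred,
                    "IWRES": iwres,
                    "CWRES": cwres,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Simulation helpers (shared by pcVPC and NPDE)
# ---------------------------------------------------------------------------


def _simulate_replicates(model, subjects, n_sim, rng, solver):
    """Simulate DV replicate matrices per subject under ``model``.

    Returns a list (per subject) of arrays with shape (n_sim, n_obs_i).
    """
    spec = model.substituted_spec()
    q = len(model.eta_names)
    omega_sd = np.array(
        [math.sqrt(model.omega[k]) for k in model.eta_names], dtype=float
    )
    sims = [np.empty((n_sim, len(s.y))) for s in subjects]
    for r in range(n_sim):
        for i, subj in enumerate(subjects):
            eta = omega_sd * rng.standard_normal(q) if q else np.zeros(0)
            f = _predict_subject(spec, model, eta, subj, solver)
            sd = np.sqrt(model.residual_variance(f))
            sims[i][r] = f + sd * rng.standard_normal(len(f))
    return sims


# ---------------------------------------------------------------------------
# Prediction-corrected VPC
# ---------------------------------------------------------------------------


@dataclass
class VPCResult:
    """Binned pcVPC summary: observed 5/50/95th percentiles of
    prediction-corrected observations with simulation-based 95% bands."""

    table: pd.DataFrame
    n_sim: int
    seed: int | None
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0)


def _make_bins(times: np.ndarray, n_bins: int, edges=None) -> np.ndarray:
    """Equal-count time bins (or explicit edges); returns bin index per
    observation.  Empty bins cannot arise from quantile edges; explicit
    empty bins are merged into their left neighbor."""
    if edges is None:
        qs = np.linspace(0, 1, n_bins + 1)
        edges = np.quantile(times, qs)
        edges = np.unique(edges)
    edges = np.asarray(edges, dtype=float)
    idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)
    # merge any empty bin leftward
    for b in range(len(edges) - 1):
        if not np.any(idx == b):
            idx[idx > b] -= 1
    return idx


def pcvpc(
    fit: FitResult,
    data: PKDataset,
    n_sim: int = 500,
    bins: int = 8,
    bin_edges=None,
    seed: int | None = None,
    solver: SolverOptions | None = None,
) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Observations and simulated values are rescaled by
    (bin median PRED) / (individual PRED), then the observed 5/50/95th
    percentiles per time bin are compared with the 2.5-97.5% span of the
    same percentiles across ``n_sim`` simulated datasets.
    """
    solver = solver or _ESTIMATION_SOLVER
    model = fit.model
    spec = model.substituted_spec()
    subjects = _parse_subjects(data)
    q = len(model.eta_names)
    rng = np.random.default_rng(seed)

    times = np.concatenate([s.times for s in subjects])
    y = np.concatenate([s.y for s in subjects])
    pred = np.concatenate(
        [_predict_subject(spec, model, np.zeros(q), s, solver) for s in subjects]
    )
    bin_idx = _make_bins(times, bins, bin_edges)
    n_bins_eff = bin_idx.max() + 1

    # prediction correction: scale to the bin-typical population prediction
    pc = np.ones_like(pred)
    bin_median_pred = np.empty(n_bins_eff)
    for b in range(n_bins_eff):
        m = bin_idx == b
        bin_median_pred[b] = np.median(pred[m])
    with np.errstate(divide="ignore", invalid="ignore"):
        pc = np.where(pred > 0, bin_median_pred[bin_idx] / pred, 1.0)
    y_pc = y * pc

    pcts = (5.0, 50.0, 95.0)
    obs_stats = np.array(
        [
            [np.percentile(y_pc[bin_idx == b], p) for p in pcts]
            for b in range(n_bins_eff)
        ]
    )

    sims = _simulate_replicates(model, subjects, n_sim, rng, solver)
    sim_flat = np.concatenate([s.T for s in sims], axis=0)  # (n_obs_total, n_sim)
    sim_pc = sim_flat * pc[:, None]
    sim_stats = np.empty((n_sim, n_bins_eff, len(pcts)))
    for b in range(n_bins_eff):
        m = bin_idx == b
        sim_stats[:, b, :] = np.percentile(sim_pc[m], pcts, axis=0).T

    lo = np.percentile(sim_stats, 2.5, axis=0)
    hi = np.percentile(sim_stats, 97.5, axis=0)
    med = np.percentile(sim_stats, 50.0, axis=0)

    rows = []
    for b in range(n_bins_eff):
        m = bin_idx == b
        row = {
            "bin": b,
            "t_lo": times[m].min(),
            "t_hi": times[m].max(),
            "t_mid": np.median(times[m]),
            "n_obs": int(m.sum()),
        }
        for j, p in enumerate(pcts):
            tag = f"p{int(p)}"
            row[f"obs_{tag}"] = obs_stats[b, j]
            row[f"sim_{tag}_lo"] = lo[b, j]
            row[f"sim_{tag}_med"] = med[b, j]
            row[f"sim_{tag}_hi"] = hi[b, j]
        rows.append(row)
    return VPCResult(table=pd.DataFrame(rows), n_sim=n_sim, seed=seed)


# ---------------------------------------------------------------------------
# NPDE
# ---------------------------------------------------------------------------


@dataclass
class NPDEResult:
    """Per-observation normalized prediction distribution errors plus
    normality summaries (mean/variance tests, Shapiro-Wilk, kurtosis)."""

    table: pd.DataFrame
    n_sim: int
    seed: int | None
    mean: float = field(default=math.nan)
    variance: float = field(default=math.nan)
    p_mean: float = field(default=math.nan)
    p_variance: float = field(default=math.nan)
    shapiro_stat: float = field(default=math.nan)
    shapiro_p: float = field(default=math.nan)
    kurtosis: float = field(default=math.nan)

    @property
    def npde(self) -> np.ndarray:
        return self.table["NPDE"].to_numpy()


def prediction_discrepancy(
    obs_dec: np.ndarray, sim_dec: np.ndarray, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Rank-based pde of each decorrelated observation among its sims.

    ``sim_dec`` has shape (n_obs, n_sim).  pde = (#sims below obs)/n_sim,
    with ties broken by a uniform draw inside the tied rank cell and the
    result clamped to [1/(2 n_sim), 1 - 1/(2 n_sim)] so the normal
    quantile stays finite.
    """
    obs_dec = np.asarray(obs_dec, dtype=float)
    sim_dec = np.asarray(sim_dec, dtype=float)
    n_sim = sim_dec.shape[1]
    below = (sim_dec < obs_dec[:, None]).sum(axis=1).astype(float)
    ties = (sim_dec == obs_dec[:, None]).sum(axis=1)
    if np.any(ties > 0):
        if rng is None:
            rng = np.random.default_rng()
        below += rng.uniform(0.0, 1.0, size=len(obs_dec)) * ties
    pde = below / n_sim
    return np.clip(pde, 1.0 / (2 * n_sim), 1.0 - 1.0 / (2 * n_sim))


def npde(
    fit: FitResult,
    data: PKDataset,
    n_sim: int = 1000,
    seed: int | None = None,
    solver: SolverOptions | None = None,
) -> NPDEResult:
    """Normalized prediction distribution errors.

    ``n_sim`` replicate datasets are simulated under the model; each
    subject's observed and simulated vectors are decorrelated with the
    simulation mean and covariance (Cholesky); each observation's rank
    among its decorrelated simulations gives a prediction discrepancy
    pde = (#sims < obs)/n_sim (uniform jitter on ties, bounded away from 0
    and 1 by 1/(2 n_sim)), mapped through the standard normal quantile.
    """
    if n_sim < 100:
        raise ValueError("npde needs n_sim >= 100 for usable rank resolution")
    solver = solver or _ESTIMATION_SOLVER
    model = fit.model
    subjects = _parse_subjects(data)
    rng = np.random.default_rng(seed)
    sims = _simulate_replicates(model, subjects, n_sim, rng, solver)

    frames = []
    for subj, sim in zip(subjects, sims):
        n_i = len(subj.y)
        mu = sim.mean(axis=0)
        cov = np.cov(sim, rowvar=False, ddof=1).reshape(n_i, n_i)
        # ridge-regularize a singular simulation covariance
        ridge = 1e-10 * max(np.trace(cov) / n_i, 1.0)
        for _ in range(8):
            try:
                L = np.linalg.cholesky(cov + ridge * np.eye(n_i))
                break
            except np.linalg.LinAlgError:
                ridge *= 100.0
        else:
            raise np.linalg.LinAlgError("subject simulation covariance not PSD")
        y_dec = solve_triangular(L, subj.y - mu, lower=True)
        sim_dec = solve_triangular(L, (sim - mu).T, lower=True)  # (n_i, n_sim)
        pde = prediction_discrepancy(y_dec, sim_dec, rng)
        frames.append(
            pd.DataFrame(
                {
                    "ID": subj.sid,
                    "TIME": subj.times,
                    "DV": subj.y,
                    "PDE": pde,
                    "NPDE": stats.norm.ppf(pde),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    x = table["NPDE"].to_numpy()
    n = len(x)
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    t_p = float(stats.ttest_1samp(x, 0.0).pvalue) if n > 1 else math.nan
    # two-sided chi-squared test of variance == 1
    if n > 1:
        q = (n - 1) * var
        p_lo = stats.chi2.cdf(q, n - 1)
        p_var = float(2 * min(p_lo, 1 - p_lo))
    else:
        p_var = math.nan
    if 3 <= n <= 5000:
        sw = stats.shapiro(x)
        sw_stat, sw_p = float(sw.statistic), float(sw.pvalue)
    else:
        sw_stat, sw_p = math.nan, math.nan
    return NPDEResult(
        table=table,
        n_sim=n_sim,
        seed=seed,
        mean=mean,
        variance=var,
        p_mean=t_p,
        p_variance=p_var,
        shapiro_stat=sw_stat,
        shapiro_p=sw_p,
        kurtosis=float(stats.kurtosis(x)),
    )
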