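"""Anatomy-to-function sensitivity analyses.

Four layers, applied to the (mode weights, phenotypes) dataset produced by
the shape model and the electromechanics surrogate:

* a **normalised-range filter** that discards phenotypes whose spread over
  the imaged cohort, (max - min)/mean, falls strictly below a threshold
  (default 0.2) — outputs that barely respond to anatomy are not emulated;
* **mode-phenotype Pearson correlations** over completed cases, summarised
  per mode by the mean +/- SD of |R| across phenotypes;
* a **Gaussian-process emulator** (GPE) per phenotype, trained by
  leave-one-out cross-validation over the imaged cases with every synthetic
  case always in the training split, then used for a Saltelli/Sobol global
  sensitivity analysis: first-order indices S1, total effects ST and the
  residual "multifactorial" share max(0, 1 - sum S1);
* the **local sensitivity coefficient** SC = (x0/y0) * (y+ - y-)/(x+ - x-)
  at +/-10% parameter perturbations, and the generic percent scenario delta.

The Saltelli design and the Sobol estimators are implemented here on top of
scipy's Sobol quasi-random sequences (Jansen-form estimators); sklearn's
GaussianProcessRegressor provides the emulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

__all__ = [
    "GPEModel",
    "SobolResult",
    "LocalSensitivityInput",
    "normalized_range_filter",
    "mode_phenotype_correlations",
    "train_gpes_loo",
    "sobol_saltelli",
    "sensitivity_coefficient",
    "scenario_delta",
    "lsa_battery",
]


# ----------------------------------------------------------------------
# phenotype filtering and correlation
# ----------------------------------------------------------------------
def normalized_range_filter(
    phenos: pd.DataFrame, threshold: float = 0.2
) -> tuple[pd.Series, list[str]]:
    """Normalised range (max - min)/mean per phenotype and the retained set.

    Only completed cases contribute.  Phenotypes whose value is strictly
    below the threshold are discarded; zero-mean phenotypes are undefined
    and discarded with a warning.
    """
    if "completed" in phenos.columns:
        phenos = phenos.loc[phenos["completed"].astype(bool)].drop(columns="completed")
    values, retained = {}, []
    for col in phenos.columns:
        x = phenos[col].dropna().to_numpy(dtype=float)
        if x.size < 2:
            raise ValueError(f"phenotype {col!r} has fewer than 2 completed cases")
        mean = x.mean()
        if mean == 0.0:
            warnings.warn(
                f"phenotype {col!r} has zero mean; normalised range undefined, "
                "discarded", RuntimeWarning, stacklevel=2,
            )
            values[col] = np.nan
            continue
        # |mean| so sign-definite negative phenotypes (e.g. dP/dt minima)
        # are judged on magnitude like everything else
        nr = (x.max() - x.min()) / abs(mean)
        values[col] = nr
        if nr >= threshold:
            retained.append(col)
    return pd.Series(values, name="normalized_range"), retained


def mode_phenotype_correlations(
    weights: pd.DataFrame,
    phenos: pd.DataFrame,
    method: str = "pearson",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation of each mode weight with each phenotype.

    Computed over completed cases only (rows present in both tables with no
    missing phenotype value).  Returns (R matrix modes x phenotypes, summary
    with per-mode mean and SD of |R| across phenotypes).  Zero-variance
    columns give missing correlations.
    """
    if "completed" in phenos.columns:
        phenos = phenos.loc[phenos["completed"].astype(bool)].drop(columns="completed")
    common = weights.index.intersection(phenos.index)
    if len(common) < 3:
        raise ValueError("need at least 3 completed cases for correlations")
    w = weights.loc[common]
    p = phenos.loc[common]
    corr = pd.DataFrame(index=w.columns, columns=p.columns, dtype=float)
    for m in w.columns:
        for ph in p.columns:
            x, y = w[m].to_numpy(float), p[ph].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                corr.loc[m, ph] = np.nan
                continue
            if method == "pearson":
                corr.loc[m, ph] = np.corrcoef(x[ok], y[ok])[0, 1]
            elif method == "spearman":
                from scipy.stats import spearmanr

                corr.loc[m, ph] = spearmanr(x[ok], y[ok]).statistic
            else:
                raise ValueError(f"unknown correlation method {method!r}")
    absr = corr.abs()
    summary = pd.DataFrame(
        {"mean_absR": absr.mean(axis=1), "sd_absR": absr.std(axis=1, ddof=1)}
    )
    return corr, summary


# ----------------------------------------------------------------------
# Gaussian-process emulation
# ----------------------------------------------------------------------
@dataclass
class GPEModel:
    """Fitted Gaussian-process emulator for one phenotype.

    Inputs are mode-weight vectors (standardised internally per mode);
    outputs are standardised to zero mean / unit variance before fitting and
    de-standardised on prediction.  ``loo_mse`` records the squared error of
    each leave-one-out split (imaged cases only); the final model carries the
    hyperparameters of the best-scoring split, refit on all data.
    """

    gp: GaussianProcessRegressor
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    loo_mse: np.ndarray
    best_split: int
    input_dim: int

    @property
    def mean_loo_mse(self) -> float:
        return float(self.loo_mse.mean())

    def predict(self, x: np.ndarray, return_std: bool = False):
        x = (np.atleast_2d(x) - self.x_mean) / self.x_sd
        if return_std:
            mu, sd = self.gp.predict(x, return_std=True)
            return mu * self.y_sd + self.y_mean, sd * self.y_sd
        return self.gp.predict(x) * self.y_sd + self.y_mean


def _make_gp(dim: int, random_state: int) -> GaussianProcessRegressor:
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
        np.ones(dim), (1e-2, 1e3)
    ) + WhiteKernel(1e-6, (1e-10, 1e-1))
    return GaussianProcessRegressor(
        kernel=kernel, normalize_y=False, n_restarts_optimizer=1,
        random_state=random_state,
    )


def train_gpes_loo(
    weights: np.ndarray,
    pheno: np.ndarray,
    synthetic_mask: Optional[np.ndarray] = None,
    random_state: int = 0,
) -> GPEModel:
    """Train a GPE by leave-one-out CV over the imaged (non-synthetic) cases.

    Every synthetic case stays in the training split at every fold; the
    squared error on each left-out imaged case is recorded, and the model
    returned refits all data with the hyperparameters of the split with the
    smallest left-out error.  Degenerate kernel optimisation falls back to
    the default hyperparameters with a warning.
    """
    x = np.asarray(weights, dtype=float)
    y = np.asarray(pheno, dtype=float)
    n = x.shape[0]
    if synthetic_mask is None:
        synthetic_mask = np.zeros(n, dtype=bool)
    synthetic_mask = np.asarray(synthetic_mask, dtype=bool)
    ct_idx = np.nonzero(~synthetic_mask)[0]
    if ct_idx.size < 4:
        raise ValueError("need at least 4 imaged cases for leave-one-out CV")
    x_mean, x_sd = x.mean(axis=0), x.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    y_mean, y_sd = float(y.mean()), float(y.std())
    if y_sd == 0:
        y_sd = 1.0
    xs = (x - x_mean) / x_sd
    ys = (y - y_mean) / y_sd

    errors = np.empty(ct_idx.size)
    thetas = []
    for s, i in enumerate(ct_idx):
        train = np.ones(n, dtype=bool)
        train[i] = False
        gp = _make_gp(x.shape[1], random_state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            try:
                gp.fit(xs[train], ys[train])
                theta = gp.kernel_.theta
            except (np.linalg.LinAlgError, ValueError):
                warnings.warn(
                    "kernel optimisation failed on a split; default "
                    "hyperparameters used", RuntimeWarning, stacklevel=2,
                )
                gp = _make_gp(x.shape[1], random_state)
                gp.optimizer = None
                gp.fit(xs[train], ys[train])
                theta = gp.kernel_.theta
        errors[s] = float((gp.predict(xs[[i]])[0] - ys[i]) ** 2)
        thetas.append(theta)

    best = int(np.argmin(errors))
    final = _make_gp(x.shape[1], random_state)
    final.kernel = final.kernel.clone_with_theta(thetas[best])
    final.optimizer = None
    final.fit(xs, ys)
    return GPEModel(
        gp=final, x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
        loo_mse=errors * y_sd**2, best_split=best, input_dim=x.shape[1],
    )


# ----------------------------------------------------------------------
# Saltelli / Sobol global sensitivity analysis
# ----------------------------------------------------------------------
@dataclass
class SobolResult:
    """First-order and total Sobol indices with the multifactorial share."""

    s1: np.ndarray
    st: np.ndarray
    multifactorial: float
    n_base: int
    dim: int
    seed: int

    def shares(self) -> np.ndarray:
        """Non-negative S1 shares plus the multifactorial share (sums to 1)."""
        s1 = np.clip(self.s1, 0.0, None)
        total = s1.sum() + self.multifactorial
        return np.append(s1, self.multifactorial) / total


def saltelli_design(ranges: np.ndarray, n: int, seed: int) -> np.ndarray:
    """The (2D+2)*N Saltelli evaluation design over uniform ranges.

    Rows are stacked as [A; B; AB_1..AB_D; BA_1..BA_D], where AB_i is A with
    column i replaced from B (and vice versa).  Built from a scrambled Sobol
    sequence in 2D dimensions; deterministic for a fixed seed.
    """
    ranges = np.asarray(ranges, dtype=float)
    d = ranges.shape[0]
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non power-of-two N
        base = sampler.random(n)
    lo, hi = ranges[:, 0], ranges[:, 1]
    a = lo + (hi - lo) * base[:, :d]
    b = lo + (hi - lo) * base[:, d:]
    blocks = [a, b]
    for i in range(d):
        ab = a.copy()
        ab[:, i] = b[:, i]
        blocks.append(ab)
    for i in range(d):
        ba = b.copy()
        ba[:, i] = a[:, i]
        blocks.append(ba)
    return np.vstack(blocks)


def sobol_saltelli(
    model: Callable[[np.ndarray], np.ndarray],
    ranges: np.ndarray,
    n: int = 1000,
    seed: int = 0,
) -> SobolResult:
    """Estimate S1 and ST by the Saltelli method on a callable model.

    ``model`` maps an (m, D) array to m outputs.  Exactly (2D+2)*N model
    evaluations are used.  S1 uses the Saltelli-2010 estimator averaged over
    the AB and BA blocks; ST uses the Jansen estimator.  Raises if the model
    returns a non-finite value, naming the offending input point.
    """
    ranges = np.asarray(ranges, dtype=float)
    d = ranges.shape[0]
    if n < 64:
        raise ValueError("N must be >= 64")
    design = saltelli_design(ranges, n, seed)
    y = np.asarray(model(design), dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        bad = int(np.nonzero(~np.isfinite(y))[0][0])
        raise ValueError(
            f"model returned a non-finite output at design row {bad}: "
            f"{design[bad]}"
        )
    ya, yb = y[:n], y[n : 2 * n]
    var = np.var(np.concatenate([ya, yb]))
    s1 = np.empty(d)
    st = np.empty(d)
    for i in range(d):
        yab = y[(2 + i) * n : (3 + i) * n]
        yba = y[(2 + d + i) * n : (3 + d + i) * n]
        s1_ab = np.mean(yb * (yab - ya)) / var
        s1_ba = np.mean(ya * (yba - yb)) / var
        s1[i] = 0.5 * (s1_ab + s1_ba)
        st_ab = 0.5 * np.mean((ya - yab) ** 2) / var
        st_ba = 0.5 * np.mean((yb - yba) ** 2) / var
        st[i] = 0.5 * (st_ab + st_ba)
    return SobolResult(
        s1=s1, st=st, multifactorial=float(max(0.0, 1.0 - s1.sum())),
        n_base=n, dim=d, seed=seed,
    )


# ----------------------------------------------------------------------
# local sensitivity
# ----------------------------------------------------------------------
@dataclass
class LocalSensitivityInput:
    """Baseline and +/-10% perturbed input/output pairs."""

    x0: float
    y0: float
    x_minus: float
    x_plus: float
    y_minus: float
    y_plus: float

    def __post_init__(self) -> None:
        if self.x_plus <= self.x_minus:
            raise ValueError("x_plus must exceed x_minus")


def sensitivity_coefficient(inp: LocalSensitivityInput) -> float:
    """SC = (x0/y0) * (y+ - y-)/(x+ - x-).

    A value near +/-1 means a 10% input change moves the output by ~10%;
    near 0 means insensitive.  Undefined (raises) for y0 = 0.
    """
    if inp.y0 == 0:
        raise ZeroDivisionError("sensitivity coefficient undefined for y0 = 0")
    return (inp.x0 / inp.y0) * (inp.y_plus - inp.y_minus) / (inp.x_plus - inp.x_minus)


def scenario_delta(y_base: float, y_mod: float) -> float:
    """Percent change of a scenario output vs baseline: 100*(y_mod-y_base)/y_base."""
    if y_base == 0:
        raise ZeroDivisionError("scenario delta undefined for zero baseline")
    return 100.0 * (y_mod - y_base) / y_base


def lsa_battery(
    evaluate: Callable[[dict], dict],
    baseline_params: dict,
    parameter_names: Sequence[str],
    perturbation: float = 0.10,
) -> pd.DataFrame:
    """Local sensitivity coefficients for each (parameter, phenotype) pair.

    ``evaluate`` maps a parameter dict to a dict of phenotype values (the
    full surrogate run on the average anatomy).  Each parameter is perturbed
    to (1 +/- perturbation) of its baseline; SC is computed per phenotype via
    :func:`sensitivity_coefficient`.  A failed perturbed run (evaluate
    returning None or raising) leaves that row missing, flagged by NaNs.
    """
    y0 = evaluate(dict(baseline_params))
    if y0 is None:
        raise RuntimeError("baseline simulation did not complete")
    rows = {}
    for name in parameter_names:
        x0 = float(baseline_params[name])
        xm, xp = x0 * (1 - perturbation), x0 * (1 + perturbation)
        try:
            ym = evaluate({**baseline_params, name: xm})
            yp = evaluate({**baseline_params, name: xp})
        except Exception:
            ym = yp = None
        if ym is None or yp is None:
            rows[name] = {ph: np.nan for ph in y0}
            continue
        sc = {}
        for ph, base in y0.items():
            if (
                base == 0
                or not np.isfinite(base)
                or not np.isfinite(ym.get(ph, np.nan))
                or not np.isfinite(yp.get(ph, np.nan))
            ):
                sc[ph] = np.nan
                continue
            sc[ph] = sensitivity_coefficient(
                LocalSensitivityInput(
                    x0=x0, y0=base, x_minus=xm, x_plus=xp,
                    y_minus=ym[ph], y_plus=yp[ph],
                )
            )
        rows[name] = sc
    return pd.DataFrame(rows).T
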