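"""Channel activation scoring by robust GLM against the desired HRF.

Each channel's trial epoch ``y`` is regressed on the desired haemodynamic
response function (dHRF) — the canonical double-gamma HRF convolved with
the 60 s task / 30 s rest boxcar, truncated to the 90 s epoch and
peak-normalized:

    y = [1  dHRF] [b0  b1]' + eps,      t = b / SE(b)

The t-value on the dHRF weight ``b1`` is the channel's activation
statistic; a channel counts as a region-of-interest (ROI, "activated")
channel when this t-value exceeds a critical Student-t quantile.  Fitting
uses iteratively reweighted least squares with a bisquare (Tukey biweight)
influence function, the standard robust alternative to OLS for epochs
contaminated by residual physiological transients; plain OLS is available
as a configuration alternative.

Note on conventions: the critical value is the *two-sided* 0.05 quantile
(t_crt = 1.9632 at 730 degrees of freedom) but the selection rule is the
one-sided comparison ``t1 > t_crt``, so the effective channel-wise false
positive rate under the null is alpha/2.  Both this mixed convention
(``"upper_tail_two_sided"``, the default) and a consistent one-sided rule
(``"upper_tail"``) are implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .hrf import HRFParams, task_response

__all__ = [
    "DesignRegressor",
    "GLMFit",
    "ActivationCriterion",
    "build_design_regressor",
    "fit_glm_ols",
    "fit_glm_robust",
    "critical_t",
    "select_roi_channels",
    "activation_table",
    "ChannelActivationModel",
    "ActivationResults",
]


@dataclass(frozen=True)
class DesignRegressor:
    """The dHRF regressor: unit-peak expected response over one epoch."""

    values: np.ndarray
    fs: float

    def __len__(self) -> int:
        return self.values.size


def build_design_regressor(
    fs: float,
    task_duration_s: float = 60.0,
    rest_duration_s: float = 30.0,
    hrf: HRFParams = HRFParams(),
) -> DesignRegressor:
    """Boxcar * canonical HRF, truncated to the epoch, peak 1."""
    return DesignRegressor(values=task_response(fs, task_duration_s, rest_duration_s, hrf), fs=fs)


@dataclass(frozen=True)
class GLMFit:
    """Per-channel regression result against the dHRF regressor."""

    beta0: float
    beta1: float
    se0: float
    se1: float
    t0: float
    t1: float
    n_samples: int

    @property
    def df(self) -> int:
        return self.n_samples - 2


def _design_matrix(x: np.ndarray) -> np.ndarray:
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: regressor is constant")
    return np.column_stack([np.ones_like(x), x])


def fit_glm_ols(y: np.ndarray, x: DesignRegressor | np.ndarray) -> GLMFit:
    """Ordinary least squares fit of ``y = b0 + b1 * dHRF + eps``."""
    xv = x.values if isinstance(x, DesignRegressor) else np.asarray(x, float)
    y = np.asarray(y, dtype=float)
    if y.shape != xv.shape or y.size < 3:
        raise ValueError("y and x must be equal-length series of at least 3 samples")
    X = _design_matrix(xv)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = y.size - 2
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    return GLMFit(beta0=beta[0], beta1=beta[1], se0=se[0], se1=se[1],
                  t0=float(t[0]), t1=float(t[1]), n_samples=y.size)


def fit_glm_robust(
    y: np.ndarray,
    x: DesignRegressor | np.ndarray,
    tuning_constant: float = 4.685,
) -> GLMFit:
    """Bisquare IRLS fit (MAD scale, tuning constant 4.685 by default).

    An exactly collinear ``y`` (zero residuals) would make the robust scale
    estimate vanish; such fits are returned with zero standard errors and
    infinite t-values.
    """
    xv = x.values if isinstance(x, DesignRegressor) else np.asarray(x, float)
    y = np.asarray(y, dtype=float)
    if y.shape != xv.shape or y.size < 3:
        raise ValueError("y and x must be equal-length series of at least 3 samples")
    X = _design_matrix(xv)

    ols = fit_glm_ols(y, xv)
    resid = y - (ols.beta0 + ols.beta1 * xv)
    scale = float(np.median(np.abs(resid - np.median(resid)))) / 0.6745
    if scale < 1e-12 * max(1.0, float(np.abs(y).max())):
        return GLMFit(beta0=ols.beta0, beta1=ols.beta1, se0=0.0, se1=0.0,
                      t0=math.copysign(math.inf, ols.beta0) if ols.beta0 else 0.0,
                      t1=math.copysign(math.inf, ols.beta1) if ols.beta1 else 0.0,
                      n_samples=y.size)

    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=tuning_constant))
    res = model.fit(scale_est="mad")
    beta, se = res.params, res.bse
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    return GLMFit(beta0=float(beta[0]), beta1=float(beta[1]),
                  se0=float(se[0]), se1=float(se[1]),
                  t0=float(t[0]), t1=float(t[1]), n_samples=y.size)


def critical_t(df: int, alpha: float = 0.05, two_sided: bool = True) -> float:
    """Student-t critical value: ``t.ppf(1 - alpha/2)`` (two-sided) or
    ``t.ppf(1 - alpha)`` (one-sided) at ``df`` degrees of freedom."""
    if df < 1:
        raise ValueError("df must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    q = 1 - alpha / 2 if two_sided else 1 - alpha
    return float(stats.t.ppf(q, df))


@dataclass(frozen=True)
class ActivationCriterion:
    """ROI selection rule: significance level and comparison convention.

    ``convention="upper_tail_two_sided"`` compares the signed t1 against
    the two-sided critical value (effective null rate alpha/2);
    ``"upper_tail"`` uses the one-sided quantile (null rate alpha).
    """

    alpha: float = 0.05
    convention: str = "upper_tail_two_sided"

    def __post_init__(self) -> None:
        if self.convention not in ("upper_tail_two_sided", "upper_tail"):
            raise ValueError(f"unknown convention {self.convention!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def threshold(self, df: int) -> float:
        return critical_t(df, self.alpha, two_sided=self.convention == "upper_tail_two_sided")

    def null_rate(self) -> float:
        """Expected false-activation rate per channel under the null."""
        return self.alpha / 2 if self.convention == "upper_tail_two_sided" else self.alpha


def select_roi_channels(
    fits: Sequence[GLMFit],
    criterion: ActivationCriterion = ActivationCriterion(),
) -> np.ndarray:
    """Boolean ROI mask: channel selected iff t1 strictly exceeds t_crt."""
    if len(fits) == 0:
        raise ValueError("empty fit list")
    dfs = {f.df for f in fits}
    if len(dfs) != 1:
        raise ValueError("all fits must share the same degrees of freedom")
    t_crt = criterion.threshold(dfs.pop())
    return np.array([f.t1 > t_crt for f in fits])


def activation_table(
    counts: pd.DataFrame,
    n_channels: int = 48,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Aggregate per-subject/per-trial ROI counts into a summary table.

    ``counts`` is indexed by subject with one column per (task, trial);
    returns the table plus per-task totals and activation percentages
    (total ROI / (subjects x trials x channels) x 100).
    """
    if not isinstance(counts.columns, pd.MultiIndex):
        raise ValueError("counts must have a (task, trial) column MultiIndex")
    totals = counts.T.groupby(level=0).sum().T.sum()
    tasks = counts.columns.get_level_values(0).unique()
    n_trials = {t: len([c for c in counts.columns if c[0] == t]) for t in tasks}
    pct = pd.Series(
        {t: 100.0 * totals[t] / (len(counts) * n_trials[t] * n_channels) for t in tasks}
    )
    return counts, totals, pct


def load_reference_activation_counts() -> pd.DataFrame:
    """Bundled reference per-subject/per-trial activated-channel counts
    from a 24-subject, three-task prefrontal protocol (3 trials per task),
    as a (task, trial) MultiIndex-column table."""
    from importlib import resources

    with resources.files("nirsmap.data").joinpath("reference_activation_counts.csv").open() as fh:
        raw = pd.read_csv(fh, index_col="subject")
    cols = []
    for col in raw.columns:
        task, trial = col.rsplit("_", 1)
        cols.append((task, int(trial)))
    raw.columns = pd.MultiIndex.from_tuples(cols, names=["task", "trial"])
    return raw


class ChannelActivationModel:
    """Per-channel, per-trial activation GLM over a set of epochs.

    Parameters
    ----------
    epochs
        Mapping from ``(subject, task, trial)`` to an
        ``(n_channels, n_samples)`` dHbO epoch array.
    regressor
        The shared :class:`DesignRegressor`; its length must match the
        epochs.
    """

    def __init__(self, epochs: Mapping[tuple[str, str, int], np.ndarray],
                 regressor: DesignRegressor):
        if not epochs:
            raise ValueError("no epochs supplied")
        self.epochs = dict(epochs)
        self.regressor = regressor
        n = len(regressor)
        for key, ep in self.epochs.items():
            if ep.shape[-1] != n:
                raise ValueError(f"epoch {key} length {ep.shape[-1]} != regressor length {n}")

    def fit(self, method: str = "bisquare") -> "ActivationResults":
        """Fit every (subject, task, trial, channel) series.

        ``method`` is ``"bisquare"`` (robust IRLS, the default) or
        ``"ols"``.
        """
        fit_one = {"bisquare": fit_glm_robust, "ols": fit_glm_ols}[method]
        rows = []
        for (subject, task, trial), ep in self.epochs.items():
            for ci in range(ep.shape[0]):
                f = fit_one(ep[ci], self.regressor)
                rows.append((subject, task, trial, ci, f.beta0, f.beta1, f.t1))
        frame = pd.DataFrame(
            rows, columns=["subject", "task", "trial", "channel", "beta0", "beta1", "t1"])
        n_samples = len(self.regressor)
        return ActivationResults(fits=frame, n_samples=n_samples, method=method)


@dataclass
class ActivationResults:
    """Fitted activation statistics with ROI selection helpers."""

    fits: pd.DataFrame
    n_samples: int
    method: str
    criterion: ActivationCriterion = field(default_factory=ActivationCriterion)

    @property
    def df(self) -> int:
        return self.n_samples - 2

    @property
    def t_crt(self) -> float:
        return self.criterion.threshold(self.df)

    def roi_mask(self) -> pd.DataFrame:
        """Boolean frame indexed like ``fits`` marking ROI channels."""
        out = self.fits.copy()
        out["roi"] = out["t1"] > self.t_crt
        return out

    def roi_channels(self, subject: str, task: str, trial: int) -> np.ndarray:
        sel = self.roi_mask()
        sel = sel[(sel.subject == subject) & (sel.task == task) & (sel.trial == trial)]
        return sel.loc[sel.roi, "channel"].to_numpy()

    def counts(self) -> pd.DataFrame:
        """Per-subject/per-trial ROI channel counts (one column per
        (task, trial))."""
        mask = self.roi_mask()
        table = mask.pivot_table(index="subject", columns=["task", "trial"],
                                 values="roi", aggfunc="sum")
        return table.astype(int)

    def summary(self) -> pd.DataFrame:
        """Per-task totals and activation percentages."""
        n_channels = self.fits["channel"].nunique()
        table, totals, pct = activation_table(self.counts(), n_channels=n_channels)
        return pd.DataFrame({"total_roi": totals, "activation_pct": pct.round(2)})
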