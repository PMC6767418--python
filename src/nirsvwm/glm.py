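"""Channel-space GLM with a modified-gamma haemodynamic response function.

The HRF is h(t) = e · u · exp(−u) with u = ((t−τ)/σ)², truncated to zero for
t < τ (causality) and supported on [0, T]. The peak equals 1 exactly, at
t = τ + σ (u = 1). Condition regressors are built by placing a copy of the
kernel at every retained stimulus onset; OLS is solved per channel and
chromophore.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fnirs_preprocess import ChannelTimeSeries

__all__ = [
    "HRFParams",
    "HRF_HBO",
    "HRF_HBR",
    "DesignMatrix",
    "ChannelBetas",
    "hrf_kernel",
    "build_design",
    "fit_ols",
]

CONDITIONS = ("low", "medium", "high")


@dataclass(frozen=True)
class HRFParams:
    """Modified-gamma HRF parameters: delay τ, width σ, support T (seconds)."""

    tau: float
    sigma: float
    T: float
    chromophore: str = "HbO"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.T <= self.tau:
            raise ValueError("kernel support T must exceed tau")


#: Canonical parameters: HbO peaks at τ+σ = 3.1 s, HbR at 4.8 s.
HRF_HBO = HRFParams(tau=0.1, sigma=3.0, T=10.0, chromophore="HbO")
HRF_HBR = HRFParams(tau=1.8, sigma=3.0, T=10.0, chromophore="HbR")


def hrf_kernel(params: HRFParams, dt: float) -> np.ndarray:
    """Sample h(t) on t = 0, dt, ..., T. Zero for t < τ; peak value 1 at τ+σ."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, params.T + dt / 2, dt)
    u = ((t - params.tau) / params.sigma) ** 2
    h = np.e * u * np.exp(-u)
    h[t < params.tau] = 0.0
    return h


@dataclass
class DesignMatrix:
    """Time × regressor matrix with labelled columns."""

    X: np.ndarray
    labels: tuple
    fs: float
    missing_conditions: tuple = ()

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[1] != len(self.labels):
            raise ValueError("label/column mismatch")

    def condition_columns(self) -> dict:
        return {lab: i for i, lab in enumerate(self.labels) if lab in CONDITIONS}


@dataclass
class ChannelBetas:
    """beta[condition, channel, chromophore] plus per-channel residual variance."""

    beta: np.ndarray  # (n_conditions, n_channels, n_chrom)
    conditions: tuple
    channel_ids: tuple
    chromophores: tuple = ("HbO", "HbR")
    resid_var: np.ndarray | None = None  # (n_channels, n_chrom)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("betas must be finite")


def build_design(
    onsets: dict,
    n_samples: int,
    fs: float,
    kernel: np.ndarray,
    add_drift: bool = True,
) -> DesignMatrix:
    """Impulse-at-onset convolution design with intercept and linear drift.

    Each condition column is the sum of kernel copies placed at that
    condition's onsets (truncated at the end of the record). Conditions with
    zero retained onsets are omitted and reported in ``missing_conditions``.
    """
    cols, labels, missing = [], [], []
    for cond in CONDITIONS:
        times = np.asarray(onsets.get(cond, ()), dtype=float)
        if times.size == 0:
            missing.append(cond)
            continue
        stick = np.zeros(n_samples)
        idx = np.round(times * fs).astype(int)
        if idx.min() < 0 or idx.max() >= n_samples:
            raise ValueError("onsets outside record")
        np.add.at(stick, idx, 1.0)
        col = np.convolve(stick, kernel)[:n_samples]
        cols.append(col)
        labels.append(cond)
    # any condition names not in the canonical set are appended as extra
    for cond in onsets:
        if cond not in CONDITIONS:
            times = np.asarray(onsets[cond], dtype=float)
            if times.size == 0:
                continue
            stick = np.zeros(n_samples)
            np.add.at(stick, np.round(times * fs).astype(int), 1.0)
            cols.append(np.convolve(stick, kernel)[:n_samples])
            labels.append(cond)
    cols.append(np.ones(n_samples))
    labels.append("intercept")
    if add_drift:
        drift = np.linspace(-1.0, 1.0, n_samples)
        cols.append(drift)
        labels.append("drift")
    X = np.column_stack(cols)
    return DesignMatrix(X=X, labels=tuple(labels), fs=fs,
                        missing_conditions=tuple(missing))


def _check_rank(X: np.ndarray, labels) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in the collinearity via QR pivoting
        from scipy.linalg import qr

        _, R, piv = qr(X, pivoting=True)
        bad = sorted(labels[p] for p in piv[rank:])
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")


def fit_ols(design: DesignMatrix, series: ChannelTimeSeries) -> ChannelBetas:
    """OLS solve of the GLM per channel and chromophore.

    Returns betas for the condition columns only (nuisance estimates are
    discarded) along with per-channel residual variance.
    """
    if series.stage != "concentration":
        raise ValueError("series must be at concentration stage")
    X = design.X
    if X.shape[0] != series.n_times:
        raise ValueError("design length does not match series")
    _check_rank(X, design.labels)
    n_ch, n_chrom = series.n_channels, series.data.shape[1]
    Y = series.data.transpose(2, 0, 1).reshape(series.n_times, -1)
    coef, res, rank, sv = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ coef
    dof = max(X.shape[0] - X.shape[1], 1)
    rv = ((Y - fitted) ** 2).sum(axis=0) / dof
    cond_idx = design.condition_columns()
    conds = tuple(cond_idx)
    beta = np.empty((len(conds), n_ch, n_chrom))
    for k, cond in enumerate(conds):
        beta[k] = coef[cond_idx[cond]].reshape(n_ch, n_chrom)
    return ChannelBetas(
        beta=beta,
        conditions=conds,
        channel_ids=series.channel_ids,
        chromophores=tuple(series.bands),
        resid_var=rv.reshape(n_ch, n_chrom),
    )
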