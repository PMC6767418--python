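"""Optical preprocessing: intensity → OD → motion handling → band-pass → MBLL.

Stage order is enforced through the ``stage`` tag on :class:`ChannelTimeSeries`:
intensity → od → concentration. Optical density uses the natural-log
convention, OD(t) = −ln(I(t)/⟨I⟩); the molar extinction coefficients (which
are tabulated base-10) are rescaled by ln(10) wherever they enter OD-domain
equations so that recovered concentration changes stay in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

from .forward_model import ProbeGeometry

__all__ = [
    "ChannelTimeSeries",
    "MotionMask",
    "ExtinctionTable",
    "PRAHL_EXTINCTION",
    "intensity_to_od",
    "tpca_motion_correct",
    "detect_motion_by_channel",
    "reject_trials",
    "bandpass",
    "od_to_concentration",
]

LN10 = float(np.log(10.0))

#: Molar extinction coefficients, base-10, 1/(cm·M), at (690, 830) nm.
#: Rows: chromophore (HbO, HbR); compiled values from the Prahl/Gratzer
#: haemoglobin spectra tabulation.
PRAHL_EXTINCTION = {
    690.0: {"HbO": 276.0, "HbR": 2051.96},
    830.0: {"HbO": 974.0, "HbR": 693.44},
}


@dataclass
class ChannelTimeSeries:
    """Channel × (wavelength | chromophore) × time signal container.

    ``data`` shape (n_channels, 2, n_times); ``onsets`` maps condition name to
    stimulus onset times in seconds; ``stage`` is one of
    {"intensity", "od", "concentration"}.
    """

    data: np.ndarray
    fs: float
    channel_ids: tuple
    bands: tuple  # wavelengths (nm) or chromophores ("HbO","HbR")
    onsets: dict = field(default_factory=dict)
    stage: str = "intensity"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, bands, time)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        dur = self.n_times / self.fs
        for cond, times in self.onsets.items():
            t = np.asarray(times, dtype=float)
            if t.size and (t.min() < 0 or t.max() >= dur):
                raise ValueError(f"onsets for {cond!r} outside recording")
            self.onsets[cond] = t
        if self.stage not in ("intensity", "od", "concentration"):
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs

    def copy_with(self, **kw) -> "ChannelTimeSeries":
        out = replace(self, **{"data": self.data.copy(), **kw})
        out.onsets = {k: v.copy() for k, v in self.onsets.items()}
        return out


@dataclass
class MotionMask:
    """Per-channel contamination mask (True = contaminated sample)."""

    flags: np.ndarray  # (n_channels, n_times) bool
    fs: float

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def any_channel(self) -> np.ndarray:
        """Union mask across channels."""
        return self.flags.any(axis=0)

    def segments(self, union: bool = True, channel: int | None = None) -> list:
        """Disjoint (start, stop) sample index pairs of contaminated runs."""
        mask = self.any_channel if union else self.flags[channel]
        labels, n = ndimage.label(mask)
        return [
            (int(sl[0].start), int(sl[0].stop))
            for sl in ndimage.find_objects(labels)
        ]

    @property
    def is_empty(self) -> bool:
        return not self.flags.any()


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients and differential pathlength factors.

    ``eps`` is the 2×2 base-10 matrix [chromophore, wavelength] in 1/(cm·M);
    ``eps_ln`` rescales it for the natural-log OD convention used here.
    """

    eps: np.ndarray = None  # [ (HbO, HbR) x (λ1, λ2) ]
    dpf: tuple = (6.0, 6.0)
    wavelengths: tuple = (690.0, 830.0)

    def __post_init__(self):
        if self.eps is None:
            e = np.array(
                [[PRAHL_EXTINCTION[w]["HbO"] for w in self.wavelengths],
                 [PRAHL_EXTINCTION[w]["HbR"] for w in self.wavelengths]]
            )
            object.__setattr__(self, "eps", e)
        else:
            object.__setattr__(self, "eps", np.asarray(self.eps, dtype=float))
        if abs(np.linalg.det(self.eps)) < 1e-12:
            raise ValueError("extinction matrix is singular")

    @property
    def eps_ln(self) -> np.ndarray:
        return self.eps * LN10


def intensity_to_od(raw: ChannelTimeSeries) -> ChannelTimeSeries:
    """OD(t) = −ln(I(t) / temporal mean of I), per channel and wavelength."""
    if raw.stage != "intensity":
        raise ValueError(f"expected intensity stage, got {raw.stage!r}")
    if np.any(raw.data <= 0):
        raise ValueError("intensities must be strictly positive")
    ref = raw.data.mean(axis=2, keepdims=True)
    od = -np.log(raw.data / ref)
    out = raw.copy_with(stage="od")
    out.data = od
    return out


def tpca_motion_correct(
    od: ChannelTimeSeries,
    mask: MotionMask,
    variance_frac: float = 0.97,
) -> ChannelTimeSeries:
    """Targeted PCA: remove dominant components inside contaminated segments.

    Components are estimated from the concatenation of contaminated samples
    (union across channels); the smallest leading set cumulatively explaining
    ≥ ``variance_frac`` of segment variance is subtracted within those samples
    only. Samples outside the mask are untouched.
    """
    out = od.copy_with()
    if mask.is_empty:
        return out
    idx = np.flatnonzero(mask.any_channel)
    if idx.size < 2:
        import warnings

        warnings.warn("motion segment shorter than 2 samples; tPCA skipped")
        return out
    for bi in range(od.data.shape[1]):
        X = od.data[:, bi, idx]  # channels × contaminated samples
        # no mean removal: the artifact's segment mean is part of the artifact
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        var = s**2
        if var.sum() <= 0:
            continue
        cum = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(cum, variance_frac) + 1)
        k = min(k, len(s))
        recon = (U[:, :k] * s[:k]) @ Vt[:k]
        out.data[:, bi, idx] = X - recon
    return out


def detect_motion_by_channel(
    od: ChannelTimeSeries,
    tMotion: float = 1.0,
    tMask: float = 1.0,
    StdevThresh: float = 50.0,
    AmpThresh: float = 0.67,
) -> MotionMask:
    """Windowed per-channel artifact detection with mask dilation.

    Within every sliding window of ``tMotion`` seconds a channel is flagged if
    its signal excursion (max − min) exceeds ``StdevThresh`` × the channel's
    SD or exceeds ``AmpThresh`` in amplitude; flagged samples are dilated by
    ±``tMask`` seconds. The sliding step is one sample.
    """
    if tMotion <= 0 or tMask <= 0:
        raise ValueError("tMotion and tMask must be positive")
    n_ch, n_bands, n_t = od.data.shape
    win = max(int(round(tMotion * od.fs)), 2)
    dil = int(round(tMask * od.fs))
    flags = np.zeros((n_ch, n_t), dtype=bool)
    for ci in range(n_ch):
        for bi in range(n_bands):
            x = od.data[ci, bi]
            sd = x.std()
            hi = ndimage.maximum_filter1d(x, size=win, mode="nearest")
            lo = ndimage.minimum_filter1d(x, size=win, mode="nearest")
            rng = hi - lo
            bad = (rng > StdevThresh * sd) | (rng > AmpThresh)
            flags[ci] |= bad
    if dil > 0 and flags.any():
        structure = np.ones(2 * dil + 1, dtype=bool)
        for ci in range(n_ch):
            flags[ci] = ndimage.binary_dilation(flags[ci], structure=structure)
    return MotionMask(flags=flags, fs=od.fs)


def reject_trials(
    onsets: dict,
    mask: MotionMask,
    t_range: tuple = (-1.0, 10.0),
    per_channel: bool = False,
) -> dict:
    """Retain trials whose window avoids every contaminated segment.

    A trial is rejected iff [onset+pre, onset+post] intersects any masked
    sample (union across channels by default). Returns
    {condition: retained onset array}.
    """
    pre, post = t_range
    bad = mask.flags if per_channel else mask.any_channel[None, :]
    bad_any = bad.any(axis=0)
    n_t = bad_any.size
    retained = {}
    for cond, times in onsets.items():
        keep = []
        for t in np.asarray(times, dtype=float):
            i0 = max(int(np.floor((t + pre) * mask.fs)), 0)
            i1 = min(int(np.ceil((t + post) * mask.fs)) + 1, n_t)
            if i1 <= i0 or not bad_any[i0:i1].any():
                keep.append(t)
        retained[cond] = np.array(keep)
    return retained


def bandpass(
    series: ChannelTimeSeries,
    low: float = 0.016,
    high: float = 0.5,
    order: int = 3,
) -> ChannelTimeSeries:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    nyq = series.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError("band must satisfy 0 < low < high < fs/2")
    sos = signal.butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    out = series.copy_with()
    # the low band edge implies transients of order 1/low seconds: pad long,
    # and value-continuously ('even'), or the record edges leak broadband
    # transients through the passband
    padlen = int(min(series.n_times - 1, 6.0 * series.fs / low))
    out.data = signal.sosfiltfilt(sos, series.data, axis=2, padlen=padlen,
                                  padtype="even")
    return out


def od_to_concentration(
    od: ChannelTimeSeries,
    ext: ExtinctionTable,
    geometry: ProbeGeometry,
) -> ChannelTimeSeries:
    """Modified Beer–Lambert inversion: ΔOD at two wavelengths → (ΔHbO, ΔHbR).

    Solves, per channel and sample,
    ΔOD(λ) = ln10 · ε(λ) · [ΔHbO, ΔHbR] · d · dpf(λ),
    where d is the source-detector distance in cm. Concentrations come out in
    molar units given ε in 1/(cm·M).
    """
    if od.stage != "od":
        raise ValueError(f"expected od stage, got {od.stage!r}")
    if od.data.shape[1] != 2:
        raise ValueError("two wavelengths required")
    d = geometry.distances_cm
    if len(d) != od.n_channels:
        raise ValueError("geometry channel count mismatch")
    A = ext.eps_ln.T  # (λ, chromophore)
    Ainv = np.linalg.inv(A)
    dpf = np.asarray(ext.dpf, dtype=float)
    # scale OD per wavelength by 1/(d·dpf), then invert the 2×2 system
    scaled = od.data / (d[:, None, None] * dpf[None, :, None])
    conc = np.einsum("kw,cwt->ckt", Ainv, scaled)
    out = od.copy_with(stage="concentration", bands=("HbO", "HbR"))
    out.data = conc
    return out
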