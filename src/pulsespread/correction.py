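"""Flat-field, dark-field and photobleaching correction of raw image stacks.

The photobleaching rate gamma is estimated from glycolytically inhibited
control axons, in which active transport is blocked so that all loss of
central-window fluorescence is bleaching; the decay is fit to exp(-gamma*t)
pooled across axons (one shared gamma, per-axon amplitude).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = ["BleachModel", "flatfield_correct", "estimate_bleach_rate", "bleach_correct"]


@dataclass
class BleachModel:
    """Fitted exponential photobleaching model F(t) = F0 * exp(-gamma*t)."""

    gamma_per_s: float
    f0: float
    n_points: int
    rss: float
    clipped: bool = False  # True if a negative fitted rate was clipped to 0

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, path: str | Path) -> "BleachModel":
        return cls(**json.loads(Path(path).read_text()))


def flatfield_correct(
    raw: np.ndarray, dark: np.ndarray, flat: np.ndarray, roi: np.ndarray | None = None
) -> np.ndarray:
    """Dark-subtract and flat-field a frame or stack.

    corrected = (raw - dark) / g with g = (flat - dark)/mean(flat - dark), so a
    uniform scene keeps its mean intensity. ``roi`` (boolean mask) restricts
    the validity check and the gain normalization to the analysis region.
    """
    raw = np.asarray(raw, dtype=float)
    dark = np.asarray(dark, dtype=float)
    flat = np.asarray(flat, dtype=float)
    if dark.shape != flat.shape or raw.shape[-2:] != dark.shape:
        raise ValueError(
            f"shape mismatch: raw {raw.shape}, dark {dark.shape}, flat {flat.shape}"
        )
    gain_raw = flat - dark
    region = roi if roi is not None else np.ones_like(dark, dtype=bool)
    n_bad = int(np.count_nonzero(gain_raw[region] <= 0))
    if n_bad:
        raise ValueError(
            f"flat - dark is nonpositive at {n_bad} pixels inside the analysis region"
        )
    gain = gain_raw / gain_raw[region].mean()
    out = (raw - dark) / np.where(gain > 0, gain, np.nan)
    return out


def estimate_bleach_rate(
    series: dict[str, tuple[np.ndarray, np.ndarray]] | list[tuple[np.ndarray, np.ndarray]],
    method: str = "log",
    pooled: bool = True,
) -> BleachModel | dict[str, BleachModel]:
    """Fit the photobleaching rate from inhibited-control window series.

    ``series`` maps axon id -> (times_s, intensities). The default pooled
    log-domain fit regresses log F on t with a per-axon intercept (one shared
    gamma, per-axon amplitude); ``method='nls'`` refines with nonlinear least
    squares on the same model. A negative fitted rate (fluorescence rising,
    e.g. residual dark-state relaxation) raises a warning and is clipped to 0.
    With ``pooled=False`` returns one model per axon.
    """
    if isinstance(series, dict):
        items = list(series.items())
    else:
        items = [(str(i), s) for i, s in enumerate(series)]
    if not pooled:
        return {k: estimate_bleach_rate({k: s}, method=method) for k, s in items}

    ts, logfs, keys = [], [], []
    for k, (t, f) in items:
        t = np.asarray(t, dtype=float)
        f = np.asarray(f, dtype=float)
        if len(t) < 2:
            raise ValueError(f"axon {k}: need >= 2 time points")
        if np.any(f <= 0):
            raise ValueError(f"axon {k}: nonpositive intensities cannot be log-fit")
        ts.append(t)
        logfs.append(np.log(f))
        keys.append(k)

    # shared slope, per-axon intercept: center each axon's series
    num = sum(((t - t.mean()) * (lf - lf.mean())).sum() for t, lf in zip(ts, logfs))
    den = sum(((t - t.mean()) ** 2).sum() for t in ts)
    slope = num / den
    gamma = -slope

    if method == "nls":
        from scipy.optimize import least_squares

        amps0 = [float(np.exp(lf.mean() + gamma * t.mean())) for t, lf in zip(ts, logfs)]

        def resid(theta):
            g = theta[0]
            amps = theta[1:]
            return np.concatenate(
                [a * np.exp(-g * t) - np.exp(lf) for a, t, lf in zip(amps, ts, logfs)]
            )

        sol = least_squares(resid, x0=np.array([gamma, *amps0]))
        gamma = float(sol.x[0])
    elif method != "log":
        raise ValueError(f"unknown method {method!r}")

    clipped = False
    if gamma < 0:
        warnings.warn(
            "fitted bleaching rate is negative (fluorescence increasing); clipping to 0"
        )
        gamma = 0.0
        clipped = True

    n = sum(len(t) for t in ts)
    rss = 0.0
    for t, lf in zip(ts, logfs):
        amp = np.exp(lf.mean() + gamma * t.mean())
        rss += float(((amp * np.exp(-gamma * t) - np.exp(lf)) ** 2).sum())
    f0 = float(np.exp(logfs[0][0]))
    return BleachModel(gamma_per_s=float(gamma), f0=f0, n_points=n, rss=rss, clipped=clipped)


def bleach_correct(
    data: np.ndarray, times: np.ndarray, model: BleachModel, axis: int = 0
) -> np.ndarray:
    """Undo exponential photobleaching: multiply each frame by exp(+gamma*t)."""
    data = np.asarray(data, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.shape[0] != data.shape[axis]:
        raise ValueError("need one frame time per frame along the correction axis")
    factor = np.exp(model.gamma_per_s * times)
    shape = [1] * data.ndim
    shape[axis] = len(times)
    return data * factor.reshape(shape)
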