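"""Window measurement and the flux / velocity / directionality estimators.

The core of the pulse-spread method: background-subtracted window intensities
are normalized to the initial central-window content, the early-time (first
4 min) rise of the flanking windows is fit by ordinary least squares, and the
slopes give the directional fluxes. From slopes S_p and S_d (fraction of
F_c(0) per minute) and the activation window length a (um):

    velocity  v = a * (S_d - S_p)        [um/min -> mm/d via x1.44]
    bias        = 100 * S_d / (S_d + S_p)   (% anterograde)
    flux ratio  = S_d / S_p

Group summaries follow the population-average convention: mean S_p and S_d are
computed first and the group velocity / percent anterograde are derived from
those means, not averaged over per-axon ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WindowSet",
    "SlopeFit",
    "PulseSpreadResult",
    "windows_to_pixel_masks",
    "measure_window_series",
    "fit_initial_slopes",
    "compute_velocity",
    "compute_directionality",
    "slopes_per_min_to_velocity_mm_per_day",
    "summarize_group",
]

MIN_PER_DAY = 1440.0
UM_PER_MM = 1000.0


@dataclass(frozen=True)
class WindowSet:
    """Central activation window and flanking windows on the axon axis (um).

    Proximal is at smaller coordinates, distal at larger; windows are
    half-open intervals [start, end).
    """

    x_p: float = 0.0
    x_d: float = 40.0
    flank_lengths: tuple[float, ...] = (15.0,)

    def __post_init__(self) -> None:
        if self.x_d <= self.x_p:
            raise ValueError("need x_d > x_p")
        if any(b <= 0 for b in self.flank_lengths):
            raise ValueError("flank lengths must be > 0")

    @property
    def a(self) -> float:
        return self.x_d - self.x_p

    def windows(self) -> dict[str, tuple[float, float]]:
        w = {"central": (self.x_p, self.x_d)}
        for b in self.flank_lengths:
            w[f"proximal_{b:g}"] = (self.x_p - b, self.x_p)
            w[f"distal_{b:g}"] = (self.x_d, self.x_d + b)
        return w


def windows_to_pixel_masks(
    ws: WindowSet, x_origin_um: float, pixel_size_um: float, width_px: int
) -> dict[str, tuple[int, int]]:
    """Map um windows to half-open pixel-column ranges by center-of-pixel inclusion."""
    masks = {}
    centers = x_origin_um + (np.arange(width_px) + 0.5) * pixel_size_um
    for wid, (lo, hi) in ws.windows().items():
        inside = np.where((centers >= lo) & (centers < hi))[0]
        if len(inside) == 0:
            raise ValueError(f"window {wid} [{lo}, {hi}) contains no pixel centers")
        c0, c1 = int(inside[0]), int(inside[-1]) + 1
        if c0 < 0 or c1 > width_px:
            raise ValueError(f"window {wid} extends outside the image")
        masks[wid] = (c0, c1)
    return masks


def measure_window_series(
    stack: np.ndarray,
    frame_times: np.ndarray,
    preactivation: np.ndarray,
    col_masks: dict[str, tuple[int, int]],
    rows: tuple[int, int],
    t_start: float = 0.0,
) -> pd.DataFrame:
    """Background-subtracted, normalized window series for one axon.

    Each window's per-frame sum has the same window's preactivation sum
    subtracted, and all series are normalized by the central window's value at
    the first analyzed frame (so central starts at 1). Frames earlier than
    ``t_start`` on the analysis clock (the post-activation dark-state cutoff)
    are discarded.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if stack.shape[0] != len(frame_times):
        raise ValueError("one frame time per frame required")
    if preactivation is None:
        raise ValueError("preactivation frame is required for background subtraction")
    r0, r1 = rows
    if r0 < 0 or r1 > stack.shape[1]:
        raise ValueError("axon row band outside the image")
    keep = frame_times >= t_start
    if not np.any(keep):
        raise ValueError("no frames at or after the analysis start time")
    times = frame_times[keep]
    sub = np.asarray(stack, dtype=float)[keep][:, r0:r1, :]
    pre = np.asarray(preactivation, dtype=float)[r0:r1, :]

    sums = {}
    for wid, (c0, c1) in col_masks.items():
        if c0 < 0 or c1 > stack.shape[2]:
            raise ValueError(f"window {wid} mask outside the image")
        sums[wid] = sub[:, :, c0:c1].sum(axis=(1, 2)) - pre[:, c0:c1].sum()
    if "central" not in sums:
        raise ValueError("a 'central' window is required for normalization")
    norm = sums["central"][0]
    if norm <= 0:
        raise ValueError("nonpositive initial central-window intensity")

    rows_out = []
    for wid, vals in sums.items():
        role = "central" if wid == "central" else ("proximal" if wid.startswith("proximal") else "distal")
        for t, v in zip(times, vals):
            rows_out.append((float(t - times[0]), wid, role, float(v / norm)))
    return pd.DataFrame(rows_out, columns=["time_s", "window_id", "role", "f_norm"])


@dataclass
class SlopeFit:
    """OLS slopes of the early-time window series, in fraction of F_c(0)/min."""

    S_p: float
    S_d: float
    S_c: float
    se_S_p: float
    se_S_d: float
    n_frames: int


def _ols_slope(t_min: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and its standard error, with intercept."""
    import statsmodels.api as sm

    X = sm.add_constant(t_min)
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1])


def fit_initial_slopes(
    series: pd.DataFrame,
    t_max_min: float = 4.0,
    proximal: str | None = None,
    distal: str | None = None,
) -> SlopeFit:
    """Fit the early-time linear rise of the flanking windows.

    Uses ordinary least squares with an intercept on frames in [0, t_max_min]
    (the intercept absorbs residual dark-state relaxation and background
    subtraction error). ``proximal``/``distal`` select window ids when several
    flank sizes are present; defaults to the largest of each side. Negative
    fitted slopes are passed through (they happen with noise). S_c is the
    negated central-window slope.
    """
    wids = series["window_id"].unique()
    if proximal is None:
        cands = sorted(w for w in wids if w.startswith("proximal"))
        proximal = max(cands, key=lambda w: float(w.split("_")[1])) if cands else None
    if distal is None:
        cands = sorted(w for w in wids if w.startswith("distal"))
        distal = max(cands, key=lambda w: float(w.split("_")[1])) if cands else None
    if proximal is None or distal is None:
        raise ValueError("series must contain proximal and distal windows")

    out = {}
    for label, wid in (("p", proximal), ("d", distal), ("c", "central")):
        sel = series[series["window_id"] == wid]
        t_min = sel["time_s"].to_numpy() / 60.0
        keep = t_min <= t_max_min + 1e-9
        t_fit, y_fit = t_min[keep], sel["f_norm"].to_numpy()[keep]
        if len(t_fit) < 3:
            raise ValueError(f"need >= 3 frames within the first {t_max_min} min")
        out[label] = _ols_slope(t_fit, y_fit)
    return SlopeFit(
        S_p=out["p"][0],
        S_d=out["d"][0],
        S_c=-out["c"][0],
        se_S_p=out["p"][1],
        se_S_d=out["d"][1],
        n_frames=int(np.sum(series[series["window_id"] == "central"]["time_s"] / 60.0 <= t_max_min + 1e-9)),
    )


def slopes_per_min_to_velocity_mm_per_day(S_p, S_d, a: float):
    """v = a*(S_d - S_p) um/min converted to mm/d (positive = anterograde)."""
    if a <= 0:
        raise ValueError("activation window length a must be > 0")
    return a * (np.asarray(S_d) - np.asarray(S_p)) * MIN_PER_DAY / UM_PER_MM


def compute_velocity(S_p: float, S_d: float, a: float) -> float:
    """Population mean velocity in mm/d from per-minute fractional slopes."""
    return float(slopes_per_min_to_velocity_mm_per_day(S_p, S_d, a))


def compute_directionality(S_p: float, S_d: float) -> tuple[float, float]:
    """(percent anterograde, flux ratio S_d/S_p).

    The percentage is undefined (NaN) when S_d + S_p <= 0; the ratio is
    undefined when S_p <= 0 with the convention inf for S_d > 0.
    """
    total = S_d + S_p
    pct = 100.0 * S_d / total if total > 0 else float("nan")
    if S_p > 0:
        ratio = S_d / S_p
    else:
        ratio = float("inf") if S_d > 0 else float("nan")
    return pct, ratio


@dataclass
class PulseSpreadResult:
    """Per-axon pulse-spread estimates."""

    axon_id: str
    S_p: float            # fraction of F_c(0) per min
    S_d: float
    velocity_mm_per_day: float
    percent_anterograde: float  # NaN when S_d+S_p <= 0
    flux_ratio: float
    se_S_p: float = float("nan")
    se_S_d: float = float("nan")
    n_frames: int = 0

    @classmethod
    def from_slopes(cls, axon_id: str, fit: SlopeFit, a: float) -> "PulseSpreadResult":
        pct, ratio = compute_directionality(fit.S_p, fit.S_d)
        return cls(
            axon_id=axon_id,
            S_p=fit.S_p,
            S_d=fit.S_d,
            velocity_mm_per_day=compute_velocity(fit.S_p, fit.S_d, a),
            percent_anterograde=pct,
            flux_ratio=ratio,
            se_S_p=fit.se_S_p,
            se_S_d=fit.se_S_d,
            n_frames=fit.n_frames,
        )


def results_to_frame(results: list[PulseSpreadResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "axon_id": [r.axon_id for r in results],
            "S_p_per_min": [r.S_p for r in results],
            "S_d_per_min": [r.S_d for r in results],
            "S_p_pct_per_min": [100 * r.S_p for r in results],
            "S_d_pct_per_min": [100 * r.S_d for r in results],
            "velocity_mm_per_day": [r.velocity_mm_per_day for r in results],
            "pct_anterograde": [r.percent_anterograde for r in results],
            "flux_ratio": [r.flux_ratio for r in results],
        }
    )


def summarize_group(
    results: pd.DataFrame,
    records: pd.DataFrame | None = None,
    group_keys: list[str] | None = None,
    a: float = 40.0,
) -> pd.DataFrame:
    """Group-level summary following the population-average convention.

    Velocity and percent anterograde are computed from the group-mean S_p and
    S_d — not as means of per-axon ratios, which differ on heterogeneous
    groups. Axons with S_d + S_p <= 0 are excluded (and counted) from the
    percentage, but retained in the flux and velocity means. Per-axon
    distribution stats (median, quartiles, min, max) are included for each
    measure for box-and-whisker parity.
    """
    df = results.copy()
    if records is not None:
        df = df.merge(records, on="axon_id", how="left")
    if group_keys:
        grouped = df.groupby(group_keys, sort=True)
    else:
        grouped = [((), df)]

    rows = []
    for key, g in grouped:
        if len(g) == 0:
            raise ValueError("empty group")
        mean_Sp = g["S_p_per_min"].mean()
        mean_Sd = g["S_d_per_min"].mean()
        pct, ratio = compute_directionality(mean_Sp, mean_Sd)
        n_undef = int(np.sum((g["S_d_per_min"] + g["S_p_per_min"]) <= 0))
        row = {
            "n_axons": len(g),
            "n_pct_excluded": n_undef,
            "mean_S_p_pct_per_min": 100 * mean_Sp,
            "mean_S_d_pct_per_min": 100 * mean_Sd,
            "velocity_mm_per_day": compute_velocity(mean_Sp, mean_Sd, a),
            "pct_anterograde": pct,
            "flux_ratio": ratio,
        }
        for col in ("S_p_pct_per_min", "S_d_pct_per_min", "velocity_mm_per_day"):
            vals = g[col].to_numpy()
            row[f"{col}_median"] = float(np.median(vals))
            row[f"{col}_q1"] = float(np.percentile(vals, 25))
            row[f"{col}_q3"] = float(np.percentile(vals, 75))
            row[f"{col}_min"] = float(vals.min())
            row[f"{col}_max"] = float(vals.max())
        if group_keys:
            key = key if isinstance(key, tuple) else (key,)
            row.update(dict(zip(group_keys, key)))
        rows.append(row)
    return pd.DataFrame(rows)
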