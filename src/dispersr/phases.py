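"""Dispersal-phase segmentation.

Net squared displacement (NSD) diagnostics, a kernel-density threshold
separating stationary from travelling steps, an explicit bout rule
turning travel runs into dispersal bouts, per-phase summaries and
position semivariograms.

The step-state threshold follows the bimodal log-speed idea: animals
alternating between residency and directed travel show two modes in
the density of ln(step speed); the density minimum between the two
dominant modes, converted to a step length at the regular sampling
interval, separates the states.  When no second mode is detected the
threshold falls back to a fixed 200 m step length (flagged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .tracks import Track, build_steps

log = logging.getLogger(__name__)

STATIONARY = "stationary"
TRAVEL = "travel"
DISPERSAL = "dispersal"


@dataclass(frozen=True)
class PhaseConfig:
    """Phase-segmentation parameters.

    min_steps : minimum step count for the KDE threshold.
    fallback_tau_m : threshold used when log-speed density is unimodal.
    mode_min_frac : modes below this fraction of the peak density are
        ignored (suppresses spurious micro-modes).
    min_run / min_net_m : a travel run becomes a dispersal bout only if
        it has at least ``min_run`` steps and a net displacement of at
        least ``min_net_m`` — km-scale directed movement qualifies,
        foraging loops do not.
    """

    min_steps: int = 100
    grid_n: int = 512
    fallback_tau_m: float = 200.0
    mode_min_frac: float = 0.05
    min_run: int = 3
    min_net_m: float = 5000.0


@dataclass
class PhaseThreshold:
    tau_m: float
    bandwidth: float
    mode_lengths_m: list[float]
    fallback_used: bool


@dataclass
class PhaseLabeling:
    """Per-step states plus the bout table.

    ``labels``: 'stationary'/'travel' per step (travel only inside
    qualifying runs).  ``bouts``: DataFrame with state ('stationary' or
    'dispersal'), start_t, end_t, n_steps, first_step, last_step.
    """

    labels: np.ndarray
    bouts: pd.DataFrame = field(repr=False)


def nsd_series(track: Track) -> pd.DataFrame:
    """Net squared displacement (m^2) of each fix from the first fix."""
    f = track.fixes
    if not len(f):
        raise ValueError("empty track")
    nsd = (f["x"] - f["x"].iloc[0]) ** 2 + (f["y"] - f["y"].iloc[0]) ** 2
    return pd.DataFrame({"t": f["t"].to_numpy(), "nsd": nsd.to_numpy()})


def kde_step_threshold(steps: pd.DataFrame, cfg: PhaseConfig = PhaseConfig(),
                       interval_h: float = 3.0) -> PhaseThreshold:
    """Step-length threshold from the density of ln(step speed).

    Gaussian KDE (Silverman bandwidth) of ln(speed) on a 512-point
    grid; if at least two local maxima survive the ``mode_min_frac``
    cut, tau is the step length at the density minimum strictly between
    the two highest modes.  Otherwise the fixed fallback is returned
    with ``fallback_used=True``.  Zero-length steps are excluded before
    the log transform.
    """
    speeds = steps.loc[steps["length_m"] > 0, "speed_kmph"].to_numpy()
    if speeds.size < cfg.min_steps:
        raise ValueError(f"need >= {cfg.min_steps} positive-length steps, "
                         f"got {speeds.size}")
    ln_v = np.log(speeds)
    kde = gaussian_kde(ln_v, bw_method="silverman")
    grid = np.linspace(ln_v.min(), ln_v.max(), cfg.grid_n)
    dens = kde(grid)

    to_m = 1000.0 * interval_h  # ln(speed kmph) -> step length m at the interval
    interior = np.arange(1, cfg.grid_n - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] > dens[interior + 1])
    peaks = interior[is_max]
    peaks = peaks[dens[peaks] >= cfg.mode_min_frac * dens.max()]
    mode_lengths = [float(np.exp(grid[p]) * to_m) for p in peaks]

    if len(peaks) < 2:
        return PhaseThreshold(cfg.fallback_tau_m, float(kde.factor),
                              mode_lengths, fallback_used=True)
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + 1 + int(np.argmin(dens[lo + 1: hi]))
    tau = float(np.exp(grid[valley]) * to_m)
    return PhaseThreshold(tau, float(kde.factor), mode_lengths,
                          fallback_used=False)


def classify_steps(steps: pd.DataFrame, threshold: PhaseThreshold) -> np.ndarray:
    """Label each step stationary (length <= tau) or travel (> tau)."""
    return np.where(steps["length_m"].to_numpy() <= threshold.tau_m,
                    STATIONARY, TRAVEL)


def _runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) index ranges of constant value."""
    out = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            out.append((start, i))
            start = i
    return out


def segment_bouts(labels: np.ndarray, steps: pd.DataFrame,
                  cfg: PhaseConfig = PhaseConfig()) -> PhaseLabeling:
    """Promote qualifying travel runs to dispersal bouts.

    A maximal within-segment run of travel steps becomes a dispersal
    bout when it has >= ``min_run`` steps and a net displacement (start
    of first step to end of last step) >= ``min_net_m``; other travel
    runs are relabeled stationary.  The remaining steps form stationary
    bouts.  Deterministic and idempotent.
    """
    labels = np.asarray(labels, dtype=object).copy()
    if len(labels) != len(steps):
        raise ValueError("labels and steps misaligned")
    seg = steps["segment"].to_numpy()
    # compound key so runs never cross segment boundaries
    keyed = np.array([f"{s}:{l}" for s, l in zip(seg, labels)], dtype=object)
    for a, b in _runs(keyed):
        if labels[a] != TRAVEL:
            continue
        net = np.hypot(steps["x1"].iloc[b - 1] - steps["x0"].iloc[a],
                       steps["y1"].iloc[b - 1] - steps["y0"].iloc[a])
        if (b - a) < cfg.min_run or net < cfg.min_net_m:
            labels[a:b] = STATIONARY

    keyed = np.array([f"{s}:{l}" for s, l in zip(seg, labels)], dtype=object)
    rows = []
    for a, b in _runs(keyed):
        state = DISPERSAL if labels[a] == TRAVEL else STATIONARY
        rows.append({"state": state,
                     "start_t": steps["t0"].iloc[a], "end_t": steps["t1"].iloc[b - 1],
                     "n_steps": b - a, "first_step": a, "last_step": b - 1})
    bouts = pd.DataFrame(rows, columns=["state", "start_t", "end_t",
                                        "n_steps", "first_step", "last_step"])
    return PhaseLabeling(labels=labels.astype(str), bouts=bouts)


def step_phases(labeling: PhaseLabeling, n_steps: int) -> np.ndarray:
    """Per-step phase ('stationary'/'dispersal') implied by the bouts."""
    phase = np.full(n_steps, STATIONARY, dtype=object)
    for _, b in labeling.bouts.iterrows():
        if b["state"] == DISPERSAL:
            phase[b["first_step"]: b["last_step"] + 1] = DISPERSAL
    return phase.astype(str)


def phase_summaries(steps: pd.DataFrame, labeling: PhaseLabeling) -> pd.DataFrame:
    """Distance (m), mean speed (kmph) and duration (h) per phase."""
    phase = step_phases(labeling, len(steps))
    rows = []
    for state in (STATIONARY, DISPERSAL):
        sel = steps[phase == state]
        dist = float(sel["length_m"].sum())
        dur_s = float(sel["dt_s"].sum())
        speed = (dist / 1000.0) / (dur_s / 3600.0) if dur_s > 0 else 0.0
        rows.append({"phase": state, "distance_m": dist,
                     "duration_h": dur_s / 3600.0, "mean_speed_kmph": speed,
                     "n_steps": int(len(sel))})
    return pd.DataFrame(rows)


def semivariogram(track: Track, lags_s) -> pd.DataFrame:
    """Position semivariogram gamma(tau) = 0.5 E||z(t+tau) - z(t)||^2.

    Pairs are formed within segments at the exact requested lags
    (multiples of the regular interval); lags with no pairs are omitted
    with a warning.  Columns: lag_s, gamma_m2, n_pairs.
    """
    tr = track if track.steps is not None else build_steps(track)
    rows = []
    for lag in lags_s:
        sq, n = 0.0, 0
        for _, grp in tr.fixes.groupby("segment", sort=True):
            sec = (grp["t"] - grp["t"].iloc[0]).dt.total_seconds().to_numpy()
            x = grp["x"].to_numpy()
            y = grp["y"].to_numpy()
            # regular grid: lag k cells apart
            if len(sec) > 1:
                dt = sec[1] - sec[0]
                k = lag / dt
                if abs(k - round(k)) < 1e-9 and 1 <= round(k) < len(sec):
                    k = int(round(k))
                    dx = x[k:] - x[:-k]
                    dy = y[k:] - y[:-k]
                    sq += float(np.sum(dx ** 2 + dy ** 2))
                    n += len(dx)
        if n == 0:
            log.warning("lag %s s: no pairs, omitted", lag)
            continue
        rows.append({"lag_s": float(lag), "gamma_m2": 0.5 * sq / n,
                     "n_pairs": n})
    return pd.DataFrame(rows, columns=["lag_s", "gamma_m2", "n_pairs"])
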