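"""Integrated step-selection functions (iSSF).

Each observed ("used") dispersal step is paired with K random
candidate steps sharing its start point, drawn from a tentative
movement kernel — gamma step lengths, von Mises turn angles — fitted
to the individual's own observed steps.  Used-vs-random status is then
modelled by conditional logistic regression on the stratified partial
likelihood

    L(beta) = prod_s exp(beta' x_used,s) / sum_{j in s} exp(beta' x_j,s)

with the stratum s being one used step and its K alternatives.  The
design carries the movement-adjustment terms (step length, its log,
cosine of the turn angle), the distances of the step end point to
roads and waterbodies, and the interactions of the movement terms with
the start-point distances, so that movement can change near a
boundary.  Start-distance main effects are constant within a stratum
and hence inestimable in the conditional likelihood; they are never
included.

The solver is Newton-Raphson with analytic gradient/Hessian and
step-halving, on internally standardized columns for conditioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .landscape import DistanceRaster
from .phases import DISPERSAL, PhaseLabeling, step_phases

log = logging.getLogger(__name__)

DESIGN_TERMS = [
    "sl", "log_sl", "cos_ta", "road_end", "water_end",
    "cos_ta:road_start", "cos_ta:water_start",
    "log_sl:road_start", "log_sl:water_start",
    "sl:road_start", "sl:water_start",
]


@dataclass(frozen=True)
class MovementKernel:
    """Tentative redistribution kernel: gamma lengths, von Mises turns."""

    gamma_shape: float
    gamma_scale: float
    vm_mu_deg: float = 0.0
    vm_kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale <= 0 or self.vm_kappa < 0:
            raise ValueError("invalid kernel parameters")

    @property
    def mean_length_m(self) -> float:
        return self.gamma_shape * self.gamma_scale


def fit_gamma_mle(lengths) -> tuple[float, float]:
    """Maximum-likelihood gamma (shape, scale) for step lengths."""
    x = np.asarray(lengths, dtype=float)
    if x.size < 30:
        raise ValueError("need n >= 30 step lengths")
    if np.any(x <= 0):
        raise ValueError("step lengths must be strictly positive")
    if x.std() == 0:
        raise ValueError("degenerate (constant) sample")
    shape, loc, scale = stats.gamma.fit(x, floc=0.0)
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
        raise RuntimeError(f"gamma MLE did not converge: shape={shape}, scale={scale}")
    return float(shape), float(scale)


def _vm_A(kappa: float) -> float:
    return special.i1e(kappa) / special.i0e(kappa)


def fit_vonmises_mle(angles_deg) -> tuple[float, float]:
    """Von Mises (mu degrees, kappa) from the circular mean and
    resultant length, with Newton refinement of A(kappa) = Rbar."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size < 30:
        raise ValueError("need n >= 30 angles")
    C, S = np.mean(np.cos(a)), np.mean(np.sin(a))
    mu = float(np.degrees(np.arctan2(S, C)))
    R = float(np.hypot(C, S))
    if R < 1e-8:
        return mu, 0.0
    R = min(R, 1 - 1e-8)
    if R < 0.53:                       # Best & Fisher series
        k = 2 * R + R ** 3 + 5 * R ** 5 / 6
    elif R < 0.85:
        k = -0.4 + 1.39 * R + 0.43 / (1 - R)
    else:
        k = 1.0 / (R ** 3 - 4 * R ** 2 + 3 * R)
    for _ in range(2):                 # Newton on A(k) - R = 0
        A = _vm_A(k)
        dA = 1 - A ** 2 - A / k
        if dA <= 0:
            break
        k = max(k - (A - R) / dA, 1e-8)
    return mu, float(k)


def fit_kernel(steps: pd.DataFrame) -> MovementKernel:
    """Fit the tentative movement kernel to observed steps."""
    shape, scale = fit_gamma_mle(steps.loc[steps["length_m"] > 0, "length_m"])
    ta = steps["turn_angle_deg"].dropna()
    mu, kappa = fit_vonmises_mle(ta)
    return MovementKernel(shape, scale, mu, kappa)


def generate_random_steps(steps: pd.DataFrame, labeling: PhaseLabeling,
                          kernel: MovementKernel, K: int = 40,
                          rng: np.random.Generator | int | None = None,
                          extent: tuple[float, float, float, float] | None = None,
                          ) -> pd.DataFrame:
    """Build iSSF strata: each used dispersal step plus K random steps.

    Used steps are dispersal-phase steps with a defined turn angle (the
    first step of a segment or bout has none and is skipped, counted in
    the log).  Candidates share the used step's start fix; their length
    is gamma-distributed and their heading is the previous absolute
    heading plus a von Mises turn.  Candidates landing outside
    ``extent`` are resampled (at most 100 rounds, then an error).
    Deterministic given the rng seed.

    Returns a long DataFrame, one row per candidate, columns: stratum,
    used, x_start, y_start, x_end, y_end, sl, log_sl, cos_ta.
    """
    rng = np.random.default_rng(rng)
    phase = step_phases(labeling, len(steps))
    mask = (phase == DISPERSAL) & steps["turn_angle_deg"].notna() \
        & (steps["length_m"] > 0)
    n_skipped = int((phase == DISPERSAL).sum() - mask.sum())
    if n_skipped:
        log.info("skipped %d dispersal steps without defined turn angle "
                 "or with zero length", n_skipped)
    used = steps[mask]
    n_u = len(used)
    mu_rad = np.radians(kernel.vm_mu_deg)
    x0 = used["x0"].to_numpy()
    y0 = used["y0"].to_numpy()
    prev = np.radians((used["heading_deg"] - used["turn_angle_deg"]).to_numpy())

    def draw(n):
        sl = rng.gamma(kernel.gamma_shape, kernel.gamma_scale, size=n)
        ta = (rng.vonmises(mu_rad, kernel.vm_kappa, size=n)
              if kernel.vm_kappa > 0 else rng.uniform(-np.pi, np.pi, size=n))
        return sl, ta

    sl, ta = draw((n_u, K))
    head = prev[:, None] + ta
    ex = x0[:, None] + sl * np.sin(head)
    ey = y0[:, None] + sl * np.cos(head)
    if extent is not None:
        for _ in range(100):
            bad = ~((ex >= extent[0]) & (ex <= extent[2])
                    & (ey >= extent[1]) & (ey <= extent[3]))
            if not bad.any():
                break
            rs, rt = draw(int(bad.sum()))
            rh = np.repeat(prev[:, None], K, axis=1)[bad] + rt
            sl[bad] = rs
            ta[bad] = rt
            ex[bad] = np.repeat(x0[:, None], K, axis=1)[bad] + rs * np.sin(rh)
            ey[bad] = np.repeat(y0[:, None], K, axis=1)[bad] + rs * np.cos(rh)
        else:
            worst = int(np.flatnonzero(bad.any(axis=1))[0])
            raise RuntimeError(f"stratum {worst}: could not place {K} "
                               "candidates inside the raster extent")

    # interleave: used row first, then its K candidates, per stratum
    sl_all = np.c_[used["length_m"].to_numpy(), sl].ravel()
    ta_used = np.radians(used["turn_angle_deg"].to_numpy())
    cos_all = np.cos(np.c_[ta_used, ta]).ravel()
    out = pd.DataFrame({
        "stratum": np.repeat(np.arange(n_u), K + 1),
        "used": np.tile(np.r_[1, np.zeros(K, dtype=int)], n_u),
        "x_start": np.repeat(x0, K + 1),
        "y_start": np.repeat(y0, K + 1),
        "x_end": np.c_[used["x1"].to_numpy(), ex].ravel(),
        "y_end": np.c_[used["y1"].to_numpy(), ey].ravel(),
        "sl": sl_all,
        "log_sl": np.log(sl_all),
        "cos_ta": cos_all,
    })
    return out


def build_design_matrix(strata: pd.DataFrame, road_raster: DistanceRaster,
                        water_raster: DistanceRaster) -> pd.DataFrame:
    """Attach distance covariates and the 11-term iSSF design.

    Adds road_end/water_end (end-point distances), road_start/
    water_start (shared within a stratum) and the movement-by-start
    interaction columns.  Raises if any end point falls off a raster,
    naming the stratum.
    """
    df = strata.copy()
    try:
        df["road_end"] = road_raster.sample(df["x_end"], df["y_end"])
        df["water_end"] = water_raster.sample(df["x_end"], df["y_end"])
        df["road_start"] = road_raster.sample(df["x_start"], df["y_start"])
        df["water_start"] = water_raster.sample(df["x_start"], df["y_start"])
    except ValueError as e:
        bad = ~np.array([
            (road_raster.extent[0] <= x <= road_raster.extent[2])
            and (road_raster.extent[1] <= y <= road_raster.extent[3])
            for x, y in zip(strata["x_end"], strata["y_end"])])
        which = sorted(strata.loc[bad, "stratum"].unique().tolist())
        raise ValueError(f"end point outside raster extent in strata {which}") from e
    for mv in ("cos_ta", "log_sl", "sl"):
        for side in ("road_start", "water_start"):
            df[f"{mv}:{side}"] = df[mv] * df[side]
    return df


@dataclass
class ISSFFit:
    """Per-individual conditional-logit fit over the 11 design terms."""

    beta: pd.Series
    se: pd.Series
    loglik: float
    converged: bool
    n_strata: int
    n_iter: int
    inestimable: list[str] = field(default_factory=list)

    @property
    def or_(self) -> pd.Series:
        return np.exp(self.beta).rename("or")

    @property
    def z(self) -> pd.Series:
        return (self.beta / self.se).rename("z")

    @property
    def p(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.z)),
                         index=self.beta.index, name="p")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.beta, "se": self.se,
                             "or": self.or_, "z": self.z, "p": self.p})


def _partial_loglik_parts(X, beta, starts, used_idx):
    """Log-likelihood, per-stratum softmax weights and weighted sums."""
    eta = X @ beta
    m = np.maximum.reduceat(eta, starts)
    counts = np.diff(np.r_[starts, len(eta)])
    shifted = np.exp(eta - np.repeat(m, counts))
    denom = np.add.reduceat(shifted, starts)
    ll = float(eta[used_idx].sum() - (np.log(denom) + m).sum())
    w = shifted / np.repeat(denom, counts)
    return ll, w


def fit_conditional_logit(design: pd.DataFrame,
                          terms: list[str] = DESIGN_TERMS,
                          max_iter: int = 100, tol: float = 1e-9) -> ISSFFit:
    """Maximize the stratified partial likelihood by Newton-Raphson.

    Requires >= 2 strata, each with exactly one used row among >= 2
    rows.  Columns constant within every stratum carry no conditional-
    likelihood information; they are flagged inestimable and reported
    as NaN.  Complete separation (diverging coefficients) is flagged
    via ``converged=False``.  Standard errors come from the inverse
    observed information.
    """
    df = design.sort_values(["stratum", "used"],
                            ascending=[True, False], kind="stable")
    strat = df["stratum"].to_numpy()
    used = df["used"].to_numpy().astype(bool)
    starts = np.r_[0, 1 + np.flatnonzero(strat[1:] != strat[:-1])]
    counts = np.diff(np.r_[starts, len(df)])
    if len(starts) < 2:
        raise ValueError("need >= 2 strata")
    n_used = np.add.reduceat(used.astype(int), starts)
    if np.any(n_used != 1) or np.any(counts < 2):
        raise ValueError("each stratum needs exactly one used row and >= 2 rows")

    X_all = df[terms].to_numpy(dtype=float)
    # conditional likelihood only sees within-stratum contrasts
    grp_mean = np.add.reduceat(X_all, starts, axis=0) / counts[:, None]
    Xc = X_all - np.repeat(grp_mean, counts, axis=0)
    spread = np.abs(Xc).max(axis=0)
    colmax = np.abs(X_all).max(axis=0)
    inestimable = [t for t, s, m in zip(terms, spread, colmax)
                   if s <= 1e-9 * max(m, 1.0)]
    est = [t for t in terms if t not in inestimable]
    if inestimable:
        log.warning("inestimable (stratum-constant) terms: %s", inestimable)
    if not est:
        raise ValueError("no estimable terms")
    keep = [terms.index(t) for t in est]
    scale = Xc[:, keep].std(axis=0)
    X = Xc[:, keep] / scale
    used_idx = np.flatnonzero(used)

    p = X.shape[1]
    beta = np.zeros(p)
    ll, w = _partial_loglik_parts(X, beta, starts, used_idx)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WX = w[:, None] * X
        B = np.add.reduceat(WX, starts, axis=0)       # per-stratum E[x]
        grad = X[used_idx].sum(axis=0) - B.sum(axis=0)
        H = -(X.T @ WX - B.T @ B)
        try:
            delta = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            evals, evecs = np.linalg.eigh(-H)
            worst = np.array(est)[np.abs(evecs[:, 0]) > 0.3]
            raise np.linalg.LinAlgError(
                f"singular information; near-collinear terms: {list(worst)}")
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new, w_new = _partial_loglik_parts(X, cand, starts, used_idx)
            if ll_new >= ll - 1e-12:
                break
            step /= 2
        beta, ll_prev, ll, w = cand, ll, ll_new, w_new
        if np.max(np.abs(beta)) > 50:                 # diverging: separation
            log.warning("apparent complete separation; no finite MLE")
            break
        if abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-12):
            converged = True
            break

    WX = w[:, None] * X
    B = np.add.reduceat(WX, starts, axis=0)
    H = -(X.T @ WX - B.T @ B)
    try:
        cov = np.linalg.inv(-H)
        se_scaled = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_scaled = np.full(p, np.nan)

    beta_full = pd.Series(np.nan, index=terms, name="coef")
    se_full = pd.Series(np.nan, index=terms, name="se")
    beta_full[est] = beta / scale
    se_full[est] = se_scaled / scale
    return ISSFFit(beta=beta_full, se=se_full, loglik=ll, converged=converged,
                   n_strata=len(starts), n_iter=it, inestimable=inestimable)


def summarize_population(fits: list[ISSFFit], alpha: float = 0.05
                         ) -> pd.DataFrame:
    """Across-individual summary of converged fits.

    Per term: mean +/- SD of the coefficient, its SE and the odds
    ratio, plus the number of individuals significant at ``alpha``
    (two-sided Wald).  SDs are NaN with a single fit.
    """
    conv = [f for f in fits if f.converged]
    if not conv:
        raise ValueError("no converged fits to summarize")
    coefs = pd.DataFrame([f.beta for f in conv])
    ses = pd.DataFrame([f.se for f in conv])
    ors = pd.DataFrame([f.or_ for f in conv])
    ps = pd.DataFrame([f.p for f in conv])
    out = pd.DataFrame({
        "coef_mean": coefs.mean(), "coef_sd": coefs.std(ddof=1),
        "se_mean": ses.mean(), "se_sd": ses.std(ddof=1),
        "or_mean": ors.mean(), "or_sd": ors.std(ddof=1),
        "sig_count": (ps < alpha).sum().astype(int),
    })
    out.index.name = "term"
    out.attrs["n_individuals"] = len(conv)
    out.attrs["alpha"] = alpha
    return out
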