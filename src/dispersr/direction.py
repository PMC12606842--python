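"""Compass-sector directionality of dispersal steps.

Headings are binned into eight 45-degree sectors (left-closed, starting
due north) and tabulated per individual; Spearman rank correlations
among sector counts test for a shared preferred direction across the
population.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .phases import DISPERSAL, PhaseLabeling, step_phases

log = logging.getLogger(__name__)

SECTORS = ["N-NE", "E-NE", "E-SE", "S-SE", "S-SW", "W-SW", "W-NW", "N-NW"]


def heading_to_compass8(heading: float) -> str:
    """Map a heading in [0, 360) to one of the eight compass sectors.

    Bins are left-closed: [0, 45) -> N-NE, [45, 90) -> E-NE, ...
    """
    if not (0.0 <= heading < 360.0):
        raise ValueError(f"heading {heading!r} outside [0, 360)")
    return SECTORS[int(heading // 45.0)]


def direction_count_matrix(per_individual: dict[str, tuple[pd.DataFrame, PhaseLabeling]]
                           ) -> pd.DataFrame:
    """Count dispersal-phase steps per individual per compass sector.

    ``per_individual`` maps individual id to (steps, labeling).  Only
    steps inside dispersal bouts with a defined heading are counted;
    individuals without any such step get an all-zero row (warned).
    """
    rows = {}
    for ind, (steps, labeling) in per_individual.items():
        phase = step_phases(labeling, len(steps))
        h = steps.loc[(phase == DISPERSAL) & steps["heading_deg"].notna(),
                      "heading_deg"].to_numpy()
        counts = np.bincount((h // 45.0).astype(int), minlength=8)
        if counts.sum() == 0:
            log.warning("%s: no dispersal steps with defined heading", ind)
        rows[ind] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=SECTORS)


def spearman_rho(x, y) -> dict:
    """Spearman rank correlation with midrank ties and a t-approximate p.

    Returns ``{"rho", "p", "defined"}``; zero rank variance in either
    input yields an undefined (NaN) correlation, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of n >= 3")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        return {"rho": float("nan"), "p": float("nan"), "defined": False}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "defined": True}


def direction_correlations(counts: pd.DataFrame
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlations among sector counts across individuals.

    Returns (pairwise, table): the symmetric 8x8 rho matrix between
    sector columns, and a per-sector table with the one-vs-rest rho —
    each sector's counts against the summed counts of the other seven —
    its p-value and a 0.05 significance flag.  A sector is called
    preferred only if its one-vs-rest correlation is significant.
    """
    if len(counts) < 3:
        raise ValueError("need >= 3 individuals")
    mat = pd.DataFrame(np.eye(len(SECTORS)), index=SECTORS, columns=SECTORS)
    for i, a in enumerate(SECTORS):
        for j, b in enumerate(SECTORS):
            if j <= i:
                continue
            r = spearman_rho(counts[a], counts[b])
            mat.loc[a, b] = mat.loc[b, a] = r["rho"]
    total = counts.sum(axis=1)
    rows = []
    for a in SECTORS:
        rest = total - counts[a]
        r = spearman_rho(counts[a], rest)
        rows.append({"sector": a, "n_steps": int(counts[a].sum()),
                     "rho_one_vs_rest": r["rho"], "p": r["p"],
                     "significant_0.05": bool(r["defined"] and r["p"] < 0.05)})
    return mat, pd.DataFrame(rows)
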