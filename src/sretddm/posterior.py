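"""Posterior summaries, the overlap significance rule, drift contrasts and
posterior-predictive RT-quantile checks.

Two posteriors are called different when less than 5% of their probability
density mass overlaps.  Overlap is operationalized as the overlap
coefficient OVL = integral of min(f_a, f_b) of Gaussian kernel density
estimates (Silverman bandwidth) on a shared 512-point grid; the posterior
probability that the difference is positive is reported alongside as a
directional check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .ddm import _simulate_paths
from .design import CELLS, CELL_LABELS
from .hddm import FitResult, build_design

__all__ = [
    "OverlapResult",
    "posterior_overlap",
    "summarize_posterior",
    "drift_contrasts",
    "ppc_quantiles",
    "PPC_PROBS",
]

PPC_PROBS = (0.10, 0.30, 0.50, 0.70, 0.90)
OVERLAP_ALPHA = 0.05  # "less than 5% of the probability density mass"


@dataclass(frozen=True)
class OverlapResult:
    """Overlap mass between two posteriors and the <5% significance flag."""

    overlap_mass: float
    significant: bool
    direction: int  # sign of mean(a) - mean(b)
    prob_a_gt_b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_mass <= 1.0 + 1e-9:
            raise ValueError("overlap_mass must lie in [0, 1]")


def posterior_overlap(draws_a, draws_b) -> OverlapResult:
    """Overlap coefficient between two sets of posterior draws.

    OVL = 1 for identical distributions, 0 for disjoint ones; contrasts
    with OVL < 0.05 are flagged significant.  Degenerate (constant) draw
    sets have no density estimate and raise.
    """
    a = np.asarray(draws_a, dtype=float).reshape(-1)
    b = np.asarray(draws_b, dtype=float).reshape(-1)
    if a.size == 0 or b.size == 0:
        raise ValueError("draw sets must be nonempty")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("degenerate (constant) draws have no density")
    kde_a = gaussian_kde(a, bw_method="silverman")
    kde_b = gaussian_kde(b, bw_method="silverman")
    bw = max(kde_a.factor * a.std(ddof=1), kde_b.factor * b.std(ddof=1))
    lo = min(a.min(), b.min()) - 3 * bw
    hi = max(a.max(), b.max()) + 3 * bw
    grid = np.linspace(lo, hi, 512)
    fa = kde_a(grid)
    fb = kde_b(grid)
    ovl = float(np.trapezoid(np.minimum(fa, fb), grid))
    ovl = min(ovl, 1.0)
    # paired when sizes match (e.g. two cells of one posterior), else pooled
    if a.size == b.size:
        p_gt = float(np.mean(a - b > 0))
    else:
        p_gt = float(np.mean(a[:, None] > b[None, :]))
    mean_diff = float(a.mean() - b.mean())
    return OverlapResult(
        overlap_mass=ovl,
        significant=ovl < OVERLAP_ALPHA,
        direction=int(np.sign(mean_diff)),
        prob_a_gt_b=p_gt,
    )


def summarize_posterior(draws) -> pd.DataFrame:
    """Mean, SD and central 95% credible interval per parameter.

    ``draws`` is a mapping name -> array of draws (any shape) or a single
    array (summarized under the name "value").
    """
    if isinstance(draws, np.ndarray):
        draws = {"value": draws}
    if len(draws) == 0:
        raise ValueError("no draws to summarize")
    rows = []
    for name, arr in draws.items():
        flat = np.asarray(arr, dtype=float).reshape(-1)
        if flat.size == 0:
            raise ValueError(f"empty draw set for {name!r}")
        lo, hi = np.quantile(flat, [0.025, 0.975])
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
                "ci_2.5": float(lo),
                "ci_97.5": float(hi),
            }
        )
    return pd.DataFrame(rows)


def drift_contrasts(fit: FitResult) -> pd.DataFrame:
    """Condition contrasts of the cell drift rates, with overlap results.

    Per valence: blue-enriched vs blue-depleted drift; plus |negative| vs
    |positive| drift within each condition (rejecting negative words vs
    endorsing positive ones).  Requires a fit whose drift varies by cell.
    """
    if "v" not in fit.spec.varying:
        raise ValueError("drift_contrasts needs a fit with cell-varying drift")
    names = build_design(fit.spec)["v"]
    by_cell = {cell: fit.pooled(name) for cell, name in zip(CELLS, names)}
    rows = []

    def add(label, a, b):
        res = posterior_overlap(a, b)
        rows.append(
            {
                "contrast": label,
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
                "mean_diff": float(np.mean(a) - np.mean(b)),
                "overlap_mass": res.overlap_mass,
                "significant": res.significant,
                "direction": res.direction,
                "prob_a_gt_b": res.prob_a_gt_b,
            }
        )

    for val in ("negative", "positive"):
        add(
            f"{val}: enriched - depleted",
            by_cell[("blue_enriched", val)],
            by_cell[("blue_depleted", val)],
        )
    for cond in ("blue_enriched", "blue_depleted"):
        add(
            f"{cond}: |negative| - |positive|",
            np.abs(by_cell[(cond, "negative")]),
            np.abs(by_cell[(cond, "positive")]),
        )
    return pd.DataFrame(rows)


_TRIM_SD = 3.29  # observed RTs beyond this many SDs of the cell mean are dropped
_MIN_TRIALS = 5


def ppc_quantiles(
    fit: FitResult,
    data: pd.DataFrame,
    n_sim_per_cell: int = 500,
    seed: int = 0,
    probs=PPC_PROBS,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Posterior-predictive RT quantiles against observed ones.

    For every (participant, condition, valence, boundary) the observed
    quantiles (after trimming RTs beyond 3.29 SD of the cell mean) are
    paired with quantiles of trials simulated from that participant's
    posterior-mean boundary separation, start point and non-decision time
    combined with the group posterior-mean drift of the cell.  Cells with
    fewer than five retained trials per boundary are flagged and excluded
    from summaries.
    """
    pm = fit.participant_means.set_index("participant_id")
    design = build_design(fit.spec)
    rng = np.random.default_rng(seed)
    probs = list(probs)
    rows = []
    for (pid, cond, val), grp in data.groupby(
        ["participant_id", "condition", "valence"], observed=True
    ):
        cell_ix = CELLS.index((cond, val))
        lab = CELL_LABELS[cell_ix]
        v = fit.group_means[
            design["v"][cell_ix] if "v" in fit.spec.varying else "v"
        ]
        a = float(pm.loc[pid, "a"])
        z = float(
            pm.loc[pid, f"z[{lab}]" if "z" in fit.spec.varying else "z"]
        )
        t = float(
            pm.loc[pid, f"t[{lab}]" if "t" in fit.spec.varying else "t"]
        )
        rts, upper = _simulate_paths(
            int(n_sim_per_cell), v, a, z, t, dt,
            int(rng.integers(2**31 - 1)), int(30.0 / dt),
        )
        obs_rt = grp["rt"].to_numpy()
        mu, sd = obs_rt.mean(), obs_rt.std(ddof=1) if obs_rt.size > 1 else 0.0
        keep = (
            np.abs(obs_rt - mu) <= _TRIM_SD * sd if sd > 0
            else np.ones_like(obs_rt, bool)
        )
        obs_resp = grp["response"].to_numpy()[keep]
        obs_rt = obs_rt[keep]
        for boundary, code in (("upper", 1), ("lower", 0)):
            o = obs_rt[obs_resp == code]
            s = rts[upper == (code == 1)]
            flagged = o.size < _MIN_TRIALS or s.size < _MIN_TRIALS
            oq = np.quantile(o, probs) if o.size else np.full(len(probs), np.nan)
            sq = np.quantile(s, probs) if s.size else np.full(len(probs), np.nan)
            for p, ov, sv in zip(probs, oq, sq):
                rows.append(
                    {
                        "participant_id": pid,
                        "condition": cond,
                        "valence": val,
                        "boundary": boundary,
                        "prob": p,
                        "observed": float(ov),
                        "simulated": float(sv),
                        "n_observed": int(o.size),
                        "flagged": bool(flagged),
                    }
                )
    return pd.DataFrame(rows)
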