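"""Hierarchical Bayesian estimation of the diffusion model.

Six model variants let drift rate ``v``, start point ``z`` and/or
non-decision time ``t`` differ across the four (condition x valence) cells
via cell-means coding with no intercept; boundary separation ``a`` never
varies (variants with cell-varying boundaries are rejected as a modelling
choice: they are known not to converge on this design).  Drift is a
group-level quantity; boundary separation, start point and non-decision
time additionally carry participant-level deviations drawn from normal
hierarchies, so each participant has their own (a, z, t).

Sampling is adaptive Metropolis-within-Gibbs over parameter blocks
(group-cell coefficients, per-participant deviation triples, hierarchy
scales), with likelihood-invariant recentering moves that decorrelate the
shared group coefficients from the mean of the participant deviations.
Convergence is summarised by split-chain potential scale reduction factors
(R-hat) and autocorrelation profiles; model comparison uses the deviance
information criterion DIC = Dbar + pD with pD = Dbar - D(posterior mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator

from .ddm import _wfpt_logpdf
from .design import CELLS, CELL_LABELS, cell_index

__all__ = [
    "ModelSpec",
    "MCMCSettings",
    "Priors",
    "FitResult",
    "HierarchicalDDM",
    "build_design",
    "log_likelihood",
    "sample_posterior",
    "gelman_rubin",
    "autocorrelation",
    "compute_dic",
    "select_best_model",
    "MODEL_VARIANTS",
]

# hard support bounds enforced in the likelihood
_A_MIN = 0.1
_Z_LO, _Z_HI = 0.02, 0.98
_T_MIN = 0.01


@dataclass(frozen=True)
class ModelSpec:
    """Which diffusion parameters vary over (condition x valence) cells."""

    varying: frozenset = frozenset({"v"})

    def __init__(self, varying: Iterable[str] = ("v",)):
        varying = frozenset(varying)
        if "a" in varying:
            raise ValueError(
                "boundary separation cannot vary by cell: cell-varying "
                "boundary models do not converge on this design"
            )
        bad = varying - {"v", "z", "t"}
        if bad:
            raise ValueError(f"unknown varying parameters: {sorted(bad)}")
        object.__setattr__(self, "varying", varying)

    @property
    def name(self) -> str:
        return "".join(p for p in "vzt" if p in self.varying) or "null"


#: The candidate set: null, t, v, vt, vz, z, zt.
MODEL_VARIANTS: tuple[ModelSpec, ...] = (
    ModelSpec(()),
    ModelSpec(("t",)),
    ModelSpec(("v",)),
    ModelSpec(("v", "t")),
    ModelSpec(("v", "z")),
    ModelSpec(("z",)),
    ModelSpec(("z", "t")),
)


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings: draw count, burn-in, thinning, chains, seed."""

    n_samples: int = 30_000
    burn_in: int = 5_000
    thin: int = 10
    n_chains: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_samples:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_samples")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_samples - self.burn_in) // self.thin

    @classmethod
    def desk(cls, seed: int = 0, n_chains: int = 3) -> "MCMCSettings":
        """Scaled-down profile for interactive runs (3 x 6,000 / 1,000 / 5)."""
        return cls(n_samples=6_000, burn_in=1_000, thin=5, n_chains=n_chains, seed=seed)


@dataclass(frozen=True)
class Priors:
    """Weakly informative priors constraining parameters to plausible ranges.

    Group drift-cell means are Normal(0, 2^2); group boundary separation is
    Normal(1.5, 0.75^2) on (0.3, 4); the group start point has a
    Normal(0, 0.5^2) prior on the logit scale; group non-decision time is
    Normal(0.4, 0.3^2) on (0.05, 2); hierarchy scales are Half-Normal(0.3).
    """

    v_sd: float = 2.0
    a_mean: float = 1.5
    a_sd: float = 0.75
    a_bounds: tuple[float, float] = (0.3, 4.0)
    z_logit_sd: float = 0.5
    t_mean: float = 0.4
    t_sd: float = 0.3
    t_bounds: tuple[float, float] = (0.05, 2.0)
    sigma_scale: float = 0.3

    def scaled(self, factor: float) -> "Priors":
        """Priors with all SDs multiplied by ``factor`` (sensitivity runs)."""
        return replace(
            self,
            v_sd=self.v_sd * factor,
            a_sd=self.a_sd * factor,
            z_logit_sd=self.z_logit_sd * factor,
            t_sd=self.t_sd * factor,
            sigma_scale=self.sigma_scale * factor,
        )


def build_design(spec: ModelSpec) -> dict[str, list[str]]:
    """Parameter names implied by a model spec, keyed by diffusion parameter.

    Varying parameters get four cell coefficients (cell-means coding, no
    intercept); non-varying parameters a single shared coefficient.
    Boundary separation is always the single shared ``a``.
    """
    out: dict[str, list[str]] = {}
    for p in ("v", "z", "t"):
        if p in spec.varying:
            out[p] = [f"{p}[{lab}]" for lab in CELL_LABELS]
        else:
            out[p] = [p]
    out["a"] = ["a"]
    return out


# ---------------------------------------------------------------------------
# numba likelihood kernel


@njit(cache=False)
def _loglik_idx(
    idx, rt, resp, cell, part,
    vc, cmv, ac, adev, zc, cmz, zdev, tc, cmt, tdev,
    out,
):
    """Sum of per-trial log likelihoods over ``idx``; fills ``out[idx]``.

    Returns -inf as soon as any trial has zero density (invalid parameter
    for that participant, or rt at or below non-decision time).
    """
    total = 0.0
    for n in range(idx.shape[0]):
        j = idx[n]
        p = part[j]
        c = cell[j]
        a = ac + adev[p]
        if a < _A_MIN:
            return -np.inf
        z = zc[cmz[c]] + zdev[p]
        if z <= _Z_LO or z >= _Z_HI:
            return -np.inf
        t = tc[cmt[c]] + tdev[p]
        if t < _T_MIN:
            return -np.inf
        ll = _wfpt_logpdf(rt[j], resp[j] == 1, vc[cmv[c]], a, z, t)
        if ll == -np.inf:
            return -np.inf
        out[j] = ll
        total += ll
    return total


# ---------------------------------------------------------------------------
# priors on the sampler state


def _logit(x: float) -> float:
    return math.log(x / (1.0 - x))


def _lp_vc(v: float, pri: Priors) -> float:
    return -0.5 * (v / pri.v_sd) ** 2


def _lp_ac(a: float, pri: Priors) -> float:
    lo, hi = pri.a_bounds
    if not lo < a < hi:
        return -np.inf
    return -0.5 * ((a - pri.a_mean) / pri.a_sd) ** 2


def _lp_zc(z: float, pri: Priors) -> float:
    if not 0.0 < z < 1.0:
        return -np.inf
    lz = _logit(z)
    # normal on the logit scale plus the change-of-variable Jacobian
    return -0.5 * (lz / pri.z_logit_sd) ** 2 - math.log(z * (1.0 - z))


def _lp_tc(t: float, pri: Priors) -> float:
    lo, hi = pri.t_bounds
    if not lo < t < hi:
        return -np.inf
    return -0.5 * ((t - pri.t_mean) / pri.t_sd) ** 2


def _lp_halfnormal(s: float, scale: float) -> float:
    if s <= 0:
        return -np.inf
    return -0.5 * (s / scale) ** 2


def _lp_devs(dev: np.ndarray, sig: float) -> float:
    return -0.5 * float(np.sum(dev**2)) / sig**2 - dev.size * math.log(sig)


# ---------------------------------------------------------------------------
# results container


@dataclass
class FitResult:
    """Posterior draws plus convergence and model-fit summaries."""

    spec: ModelSpec
    settings: MCMCSettings
    draws: dict[str, np.ndarray]  # name -> (n_chains, n_retained)
    deviance: np.ndarray  # (n_chains, n_retained)
    dic: float
    pd_: float
    rhat: dict[str, float]
    participant_means: pd.DataFrame  # per-participant posterior-mean a, z, t
    group_means: dict[str, float]
    accept_rates: dict[str, float] = field(default_factory=dict)

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.max_rhat < 1.01

    def pooled(self, name: str) -> np.ndarray:
        """All retained draws of one parameter, chains concatenated."""
        return self.draws[name].reshape(-1)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, 95% credible interval and R-hat per parameter."""
        rows = []
        for name, arr in self.draws.items():
            flat = arr.reshape(-1)
            lo, hi = np.quantile(flat, [0.025, 0.975])
            rows.append(
                {
                    "parameter": name,
                    "mean": float(flat.mean()),
                    "sd": float(flat.std(ddof=1)),
                    "ci_2.5": float(lo),
                    "ci_97.5": float(hi),
                    "rhat": self.rhat[name],
                }
            )
        return pd.DataFrame(rows)

    def to_tidy(self) -> pd.DataFrame:
        """Tidy (chain, iteration, parameter, value) export of the draws."""
        frames = []
        for name, arr in self.draws.items():
            n_chains, n_draws = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(n_chains), n_draws),
                        "iteration": np.tile(np.arange(n_draws), n_chains),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# data preparation


def _prepare(data: pd.DataFrame):
    df = data.reset_index(drop=True)
    for col in ("participant_id", "condition", "valence", "response", "rt"):
        if col not in df.columns:
            raise ValueError(f"trial table missing column {col!r}")
    if len(df) == 0:
        raise ValueError("trial table is empty")
    pids = np.sort(df["participant_id"].unique())
    pid_ix = {p: i for i, p in enumerate(pids)}
    part = df["participant_id"].map(pid_ix).to_numpy(np.int64)
    cell = np.array(
        [cell_index(c, v) for c, v in zip(df["condition"], df["valence"])],
        dtype=np.int64,
    )
    rt = df["rt"].to_numpy(np.float64)
    if np.any(rt <= 0):
        raise ValueError("all rt must be > 0")
    resp = df["response"].to_numpy(np.int64)
    if not np.isin(resp, (0, 1)).all():
        raise ValueError("response must be 0 or 1")
    return rt, resp, cell, part, pids


def _cell_maps(spec: ModelSpec):
    full = np.arange(4, dtype=np.int64)
    shared = np.zeros(4, dtype=np.int64)
    cmv = full if "v" in spec.varying else shared
    cmz = full if "z" in spec.varying else shared
    cmt = full if "t" in spec.varying else shared
    return cmv, cmz, cmt


# ---------------------------------------------------------------------------
# the sampler


class _Chain:
    """One MCMC chain: adaptive Metropolis-within-Gibbs state and sweep."""

    def __init__(self, rt, resp, cell, part, n_part, spec, priors, rng,
                 prior_only: bool = False):
        self.rt, self.resp, self.cell, self.part = rt, resp, cell, part
        self.n_part = n_part
        self.spec = spec
        self.pri = priors
        self.rng = rng
        self.prior_only = prior_only
        self.cmv, self.cmz, self.cmt = _cell_maps(spec)
        nv = 4 if "v" in spec.varying else 1
        nz = 4 if "z" in spec.varying else 1
        nt = 4 if "t" in spec.varying else 1

        self.idx_all = np.arange(rt.size, dtype=np.int64)
        self.idx_v = [np.where(self.cmv[cell] == k)[0].astype(np.int64) for k in range(nv)]
        self.idx_z = [np.where(self.cmz[cell] == k)[0].astype(np.int64) for k in range(nz)]
        self.idx_t = [np.where(self.cmt[cell] == k)[0].astype(np.int64) for k in range(nt)]
        self.idx_p = [np.where(part == i)[0].astype(np.int64) for i in range(n_part)]
        self.min_rt = np.array([rt[ix].min() for ix in self.idx_p])

        # state
        self.vc = np.zeros(nv)
        self.ac = 1.5
        self.zc = np.full(nz, 0.5)
        t0 = max(_T_MIN + 0.01, min(0.35, 0.5 * float(self.min_rt.min())))
        self.tc = np.full(nt, t0)
        self.adev = np.zeros(n_part)
        self.zdev = np.zeros(n_part)
        self.tdev = np.zeros(n_part)
        self.sig_a = 0.1
        self.sig_z = 0.05
        self.sig_t = 0.05

        # per-trial log-likelihood cache
        self.ll = np.empty(rt.size)
        tot = self._ll_idx(self.idx_all, out=self.ll)
        if not np.isfinite(tot):
            raise RuntimeError("non-finite likelihood at the initial state")

        # proposal scales, adapted during burn-in
        self.scales = {
            **{f"v{k}": 0.08 for k in range(nv)},
            **{f"z{k}": 0.02 for k in range(nz)},
            **{f"t{k}": 0.02 for k in range(nt)},
            "a": 0.05,
            **{f"p{i}a": 0.08 for i in range(n_part)},
            **{f"p{i}z": 0.03 for i in range(n_part)},
            **{f"p{i}t": 0.03 for i in range(n_part)},
            "ra": 0.05,
            "rz": 0.02,
            "rt": 0.02,
            "sa": 0.3,
            "sz": 0.3,
            "st": 0.3,
        }
        self.acc = {k: 0 for k in self.scales}
        self.tries = {k: 0 for k in self.scales}
        self.acc_total = {k: 0 for k in self.scales}
        self.tries_total = {k: 0 for k in self.scales}

    # -- likelihood helpers -------------------------------------------------

    def _ll_idx(self, idx, vc=None, ac=None, adev=None, zc=None, zdev=None,
                tc=None, tdev=None, out=None):
        if out is None:
            out = self._scratch()
        if self.prior_only:
            out[idx] = 0.0
            return 0.0
        return _loglik_idx(
            idx, self.rt, self.resp, self.cell, self.part,
            self.vc if vc is None else vc, self.cmv,
            self.ac if ac is None else ac,
            self.adev if adev is None else adev,
            self.zc if zc is None else zc, self.cmz,
            self.zdev if zdev is None else zdev,
            self.tc if tc is None else tc, self.cmt,
            self.tdev if tdev is None else tdev,
            out,
        )

    def _scratch(self):
        if not hasattr(self, "_scr"):
            self._scr = np.empty(self.rt.size)
        return self._scr

    def _accept(self, key, delta) -> bool:
        self.tries[key] += 1
        self.tries_total[key] += 1
        if delta >= 0 or math.log(self.rng.random()) < delta:
            self.acc[key] += 1
            self.acc_total[key] += 1
            return True
        return False

    # -- one sweep ----------------------------------------------------------

    def sweep(self) -> None:
        rng = self.rng
        pri = self.pri
        scr = self._scratch()

        # group drift-cell coefficients
        for k in range(self.vc.size):
            key = f"v{k}"
            prop = self.vc.copy()
            prop[k] += rng.normal(0.0, self.scales[key])
            idx = self.idx_v[k]
            new = self._ll_idx(idx, vc=prop, out=scr)
            cur = float(self.ll[idx].sum())
            delta = new - cur + _lp_vc(prop[k], pri) - _lp_vc(self.vc[k], pri)
            if self._accept(key, delta):
                self.vc = prop
                self.ll[idx] = scr[idx]

        # group start-point coefficients
        for k in range(self.zc.size):
            key = f"z{k}"
            prop = self.zc.copy()
            prop[k] += rng.normal(0.0, self.scales[key])
            lp_new = _lp_zc(prop[k], pri)
            if lp_new == -np.inf:
                self._accept(key, -np.inf)
                continue
            idx = self.idx_z[k]
            new = self._ll_idx(idx, zc=prop, out=scr)
            cur = float(self.ll[idx].sum())
            delta = new - cur + lp_new - _lp_zc(self.zc[k], pri)
            if self._accept(key, delta):
                self.zc = prop
                self.ll[idx] = scr[idx]

        # group non-decision-time coefficients
        for k in range(self.tc.size):
            key = f"t{k}"
            prop = self.tc.copy()
            prop[k] += rng.normal(0.0, self.scales[key])
            lp_new = _lp_tc(prop[k], pri)
            if lp_new == -np.inf:
                self._accept(key, -np.inf)
                continue
            idx = self.idx_t[k]
            new = self._ll_idx(idx, tc=prop, out=scr)
            cur = float(self.ll[idx].sum())
            delta = new - cur + lp_new - _lp_tc(self.tc[k], pri)
            if self._accept(key, delta):
                self.tc = prop
                self.ll[idx] = scr[idx]

        # group boundary separation
        ap = self.ac + rng.normal(0.0, self.scales["a"])
        lp_new = _lp_ac(ap, pri)
        if lp_new > -np.inf:
            new = self._ll_idx(self.idx_all, ac=ap, out=scr)
            delta = new - float(self.ll.sum()) + lp_new - _lp_ac(self.ac, pri)
            if self._accept("a", delta):
                self.ac = ap
                self.ll[:] = scr
        else:
            self._accept("a", -np.inf)

        # participant deviations, componentwise with per-component scales
        for i in range(self.n_part):
            idx = self.idx_p[i]
            for comp, attr, sig in (
                ("a", "adev", self.sig_a),
                ("z", "zdev", self.sig_z),
                ("t", "tdev", self.sig_t),
            ):
                key = f"p{i}{comp}"
                dev = getattr(self, attr)
                prop = dev.copy()
                prop[i] += rng.normal(0.0, self.scales[key])
                new = self._ll_idx(idx, **{attr: prop}, out=scr)
                cur = float(self.ll[idx].sum())
                dprior = -0.5 * (prop[i] ** 2 - dev[i] ** 2) / sig**2
                if self._accept(key, new - cur + dprior):
                    setattr(self, attr, prop)
                    self.ll[idx] = scr[idx]

        # likelihood-invariant recentering: shift a group coefficient and
        # subtract the same shift from every participant deviation
        d = rng.normal(0.0, self.scales["ra"])
        ap = self.ac + d
        lp = _lp_ac(ap, pri) - _lp_ac(self.ac, pri)
        if lp > -np.inf:
            lp += _lp_devs(self.adev - d, self.sig_a) - _lp_devs(self.adev, self.sig_a)
        if self._accept("ra", lp):
            self.ac = ap
            self.adev = self.adev - d

        d = rng.normal(0.0, self.scales["rz"])
        zp = self.zc + d
        lp = sum(_lp_zc(x, pri) for x in zp) - sum(_lp_zc(x, pri) for x in self.zc)
        if lp > -np.inf:
            lp += _lp_devs(self.zdev - d, self.sig_z) - _lp_devs(self.zdev, self.sig_z)
        if self._accept("rz", lp):
            self.zc = zp
            self.zdev = self.zdev - d

        d = rng.normal(0.0, self.scales["rt"])
        tp = self.tc + d
        lp = sum(_lp_tc(x, pri) for x in tp) - sum(_lp_tc(x, pri) for x in self.tc)
        if lp > -np.inf:
            lp += _lp_devs(self.tdev - d, self.sig_t) - _lp_devs(self.tdev, self.sig_t)
        if self._accept("rt", lp):
            self.tc = tp
            self.tdev = self.tdev - d

        # hierarchy scales (random walk on the log scale)
        for key, attr, dev in (
            ("sa", "sig_a", self.adev),
            ("sz", "sig_z", self.zdev),
            ("st", "sig_t", self.tdev),
        ):
            cur = getattr(self, attr)
            prop = cur * math.exp(rng.normal(0.0, self.scales[key]))
            delta = (
                _lp_halfnormal(prop, pri.sigma_scale)
                - _lp_halfnormal(cur, pri.sigma_scale)
                + _lp_devs(dev, prop)
                - _lp_devs(dev, cur)
                + math.log(prop) - math.log(cur)  # log-scale proposal Jacobian
            )
            if self._accept(key, delta):
                setattr(self, attr, prop)

    def adapt(self) -> None:
        """Batch adaptation of proposal scales toward ~35% acceptance."""
        for key in self.scales:
            if self.tries[key] == 0:
                continue
            rate = self.acc[key] / self.tries[key]
            self.scales[key] *= math.exp(np.clip(rate - 0.35, -0.5, 0.5))
            self.acc[key] = 0
            self.tries[key] = 0

    # -- bookkeeping ----------------------------------------------------------

    def tracked(self) -> dict[str, float]:
        out = {}
        design = build_design(self.spec)
        for name, val in zip(design["v"], self.vc):
            out[name] = float(val)
        out["a"] = float(self.ac)
        for name, val in zip(design["z"], self.zc):
            out[name] = float(val)
        for name, val in zip(design["t"], self.tc):
            out[name] = float(val)
        out["sigma_a"] = self.sig_a
        out["sigma_z"] = self.sig_z
        out["sigma_t"] = self.sig_t
        for i in range(self.n_part):
            out[f"a_dev[{i}]"] = float(self.adev[i])
            out[f"z_dev[{i}]"] = float(self.zdev[i])
            out[f"t_dev[{i}]"] = float(self.tdev[i])
        return out


def sample_posterior(
    data: pd.DataFrame,
    spec: ModelSpec = ModelSpec(("v",)),
    priors: Priors | None = None,
    settings: MCMCSettings | None = None,
    progress: bool = False,
    prior_only: bool = False,
) -> FitResult:
    """Draw from the posterior of a hierarchical diffusion model variant.

    Runs ``settings.n_chains`` independent chains, discards ``burn_in``
    sweeps (during which proposal scales adapt), retains every ``thin``-th
    sweep thereafter, and reports split-chain R-hat, DIC and posterior-mean
    participant parameters.  With ``prior_only`` the likelihood is switched
    off and the sampler draws from the prior (a sampler self-check).
    """
    priors = priors or Priors()
    settings = settings or MCMCSettings()
    rt, resp, cell, part, pids = _prepare(data)
    n_part = pids.size

    all_draws: list[dict[str, np.ndarray]] = []
    deviance = np.empty((settings.n_chains, settings.n_retained))
    acc_rates: dict[str, float] = {}
    for c in range(settings.n_chains):
        rng = np.random.default_rng(settings.seed + 1000 * c)
        chain = _Chain(rt, resp, cell, part, n_part, spec, priors, rng,
                       prior_only=prior_only)
        names = list(chain.tracked())
        store = {name: np.empty(settings.n_retained) for name in names}
        kept = 0
        for sweep in range(settings.n_samples):
            chain.sweep()
            if sweep < settings.burn_in:
                if (sweep + 1) % 50 == 0:
                    chain.adapt()
                continue
            if (sweep - settings.burn_in) % settings.thin == settings.thin - 1:
                if kept < settings.n_retained:
                    state = chain.tracked()
                    for name in names:
                        store[name][kept] = state[name]
                    deviance[c, kept] = -2.0 * float(chain.ll.sum())
                    kept += 1
            if progress and (sweep + 1) % 1000 == 0:
                print(f"chain {c}: sweep {sweep + 1}/{settings.n_samples}")
        all_draws.append(store)
        for key in chain.tries_total:
            if chain.tries_total[key]:
                acc_rates[key] = acc_rates.get(key, 0.0) + (
                    chain.acc_total[key] / chain.tries_total[key]
                ) / settings.n_chains

    names = list(all_draws[0])
    draws = {
        name: np.stack([d[name] for d in all_draws]) for name in names
    }
    rhat = gelman_rubin(draws) if settings.n_chains >= 2 else {n: np.nan for n in names}

    # posterior-mean participant-level parameters (for predictive checks)
    design = build_design(spec)
    group_means = {
        name: float(draws[name].mean())
        for name in [*design["v"], "a", *design["z"], *design["t"],
                     "sigma_a", "sigma_z", "sigma_t"]
    }
    part_rows = []
    for i, pid in enumerate(pids):
        row = {"participant_id": pid,
               "a": group_means["a"] + float(draws[f"a_dev[{i}]"].mean())}
        for p, base in (("z", "zdev"), ("t", "tdev")):
            dev = float(draws[f"{p}_dev[{i}]"].mean())
            if p in spec.varying:
                for lab, name in zip(CELL_LABELS, design[p]):
                    row[f"{p}[{lab}]"] = group_means[name] + dev
            else:
                row[p] = group_means[design[p][0]] + dev
        part_rows.append(row)
    participant_means = pd.DataFrame(part_rows)

    fit = FitResult(
        spec=spec,
        settings=settings,
        draws=draws,
        deviance=deviance,
        dic=np.nan,
        pd_=np.nan,
        rhat=rhat,
        participant_means=participant_means,
        group_means=group_means,
        accept_rates=acc_rates,
    )
    dic, pd_eff = compute_dic(fit, data, spec)
    fit.dic, fit.pd_ = dic, pd_eff
    return fit


# ---------------------------------------------------------------------------
# likelihood as a standalone operation (used by DIC and by oracle tests)


def log_likelihood(
    data: pd.DataFrame,
    v: float | Mapping[tuple[str, str], float],
    a: float | Mapping[int, float],
    z: float | Mapping[int, float],
    t: float | Mapping[int, float],
) -> float:
    """Total Wiener first-passage log likelihood of a trial table.

    ``v`` is shared or a map from (condition, valence) cells to drifts;
    ``a``, ``z``, ``t`` are shared or maps from participant id to values.
    Response 1 is the upper boundary.  Returns ``-inf`` if any trial is
    impossible under the parameters.
    """
    rt, resp, cell, part, pids = _prepare(data)
    if isinstance(v, Mapping):
        vc = np.array([v[c] for c in CELLS])
        cmv = np.arange(4, dtype=np.int64)
    else:
        vc = np.array([float(v)])
        cmv = np.zeros(4, dtype=np.int64)

    def per_part(x) -> np.ndarray:
        if isinstance(x, Mapping):
            return np.array([float(x[p]) for p in pids])
        return np.full(pids.size, float(x))

    a_i, z_i, t_i = per_part(a), per_part(z), per_part(t)
    out = np.empty(rt.size)
    total = _loglik_idx(
        np.arange(rt.size, dtype=np.int64), rt, resp, cell, part,
        vc, cmv,
        0.0, a_i,
        np.zeros(1), np.zeros(4, dtype=np.int64), z_i,
        np.zeros(1), np.zeros(4, dtype=np.int64), t_i,
        out,
    )
    return float(total)


def compute_dic(fit: FitResult, data: pd.DataFrame, spec: ModelSpec | None = None):
    """Deviance information criterion and effective parameter count.

    DIC = Dbar + pD with pD = Dbar - D(thetabar): the posterior-mean
    deviance plus a complexity penalty equal to its excess over the
    deviance at the posterior-mean parameters.  Lower DIC is better.
    """
    spec = spec or fit.spec
    dbar = float(fit.deviance.mean())
    design = build_design(spec)
    gm = {name: float(fit.draws[name].mean()) for name in fit.draws}
    pm = fit.participant_means
    if "v" in spec.varying:
        v = {c: gm[n] for c, n in zip(CELLS, design["v"])}
    else:
        v = gm["v"]
    a = dict(zip(pm["participant_id"], pm["a"]))

    def part_map(p: str):
        if p in spec.varying:
            # cell-varying: return per-participant deviation handled below
            return None
        return dict(zip(pm["participant_id"], pm[p]))

    if ("z" not in spec.varying) and ("t" not in spec.varying):
        ll_hat = log_likelihood(data, v, a, part_map("z"), part_map("t"))
    else:
        # cell-varying z or t: evaluate through the sampler kernel directly
        rt, resp, cell, part, pids = _prepare(data)
        cmv, cmz, cmt = _cell_maps(spec)
        vc = (
            np.array([gm[n] for n in design["v"]])
            if "v" in spec.varying
            else np.array([gm["v"]])
        )
        zc = (
            np.array([gm[n] for n in design["z"]])
            if "z" in spec.varying
            else np.array([gm["z"]])
        )
        tc = (
            np.array([gm[n] for n in design["t"]])
            if "t" in spec.varying
            else np.array([gm["t"]])
        )
        nd = pids.size
        adev = np.array([gm[f"a_dev[{i}]"] for i in range(nd)])
        zdev = np.array([gm[f"z_dev[{i}]"] for i in range(nd)])
        tdev = np.array([gm[f"t_dev[{i}]"] for i in range(nd)])
        out = np.empty(rt.size)
        ll_hat = float(
            _loglik_idx(
                np.arange(rt.size, dtype=np.int64), rt, resp, cell, part,
                vc, cmv, gm["a"], adev, zc, cmz, zdev, tc, cmt, tdev, out,
            )
        )
    d_hat = -2.0 * ll_hat
    pd_eff = dbar - d_hat
    return dbar + pd_eff, pd_eff


# ---------------------------------------------------------------------------
# convergence diagnostics


def gelman_rubin(draws: Mapping[str, np.ndarray]) -> dict[str, float]:
    """Split-chain potential scale reduction factor per parameter.

    Each chain is split in half; R-hat compares between-half and
    within-half variances.  Requires >= 2 chains and >= 10 draws per chain.
    """
    out = {}
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("gelman_rubin needs draws shaped (n_chains>=2, n_draws)")
        n_chains, n_draws = arr.shape
        if n_draws < 10:
            raise ValueError("gelman_rubin needs >= 10 draws per chain")
        half = n_draws // 2
        splits = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
        m, n = splits.shape
        chain_means = splits.mean(axis=1)
        w = float(splits.var(axis=1, ddof=1).mean())
        b = n * float(chain_means.var(ddof=1))
        if w == 0:
            out[name] = 1.0
            continue
        var_plus = (n - 1) / n * w + b / n
        out[name] = math.sqrt(var_plus / w)
    return out


def autocorrelation(x: np.ndarray, max_lag: int = 50) -> np.ndarray:
    """Normalized autocorrelation of a draw sequence; lag 0 equals 1."""
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size == 0:
        raise ValueError("empty draw sequence")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("constant draw sequence has no autocorrelation")
    max_lag = min(max_lag, x.size - 1)
    acf = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        acf[lag] = np.dot(x[: x.size - lag], x[lag:]) / denom
    return acf


def select_best_model(
    data: pd.DataFrame,
    specs: Sequence[ModelSpec] = MODEL_VARIANTS,
    settings: MCMCSettings | None = None,
    priors: Priors | None = None,
) -> pd.DataFrame:
    """Fit each candidate spec and rank by DIC (ascending).

    The returned table carries DIC, pD, the DIC difference from the null
    (nothing-varies) model when present, the maximum R-hat and a
    convergence flag; non-converged fits are flagged, never dropped.
    """
    if len(specs) < 1:
        raise ValueError("need at least one spec")
    rows = []
    for spec in specs:
        fit = sample_posterior(data, spec=spec, priors=priors, settings=settings)
        rows.append(
            {
                "model": spec.name,
                "dic": fit.dic,
                "pd": fit.pd_,
                "max_rhat": fit.max_rhat,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)
    null_rows = table.loc[table["model"] == "null", "dic"]
    ref = float(null_rows.iloc[0]) if len(null_rows) else float(table["dic"].iloc[0])
    table["delta_dic_vs_null"] = table["dic"] - ref
    return table


# ---------------------------------------------------------------------------
# estimator facade


class HierarchicalDDM(BaseEstimator):
    """Hierarchical Bayesian drift-diffusion model, estimator-style.

    Parameters
    ----------
    varying : iterable of {"v", "z", "t"}
        Diffusion parameters allowed to differ across the four
        (condition x valence) cells.  Boundary separation cannot vary.
    n_samples, burn_in, thin, n_chains, seed
        MCMC settings (see :class:`MCMCSettings`).
    priors : Priors, optional

    Attributes (after ``fit``)
    --------------------------
    result_ : FitResult with draws, DIC, R-hat and accept rates
    posterior_ : dict of parameter name -> (n_chains, n_retained) draws
    dic_, pd_ : model-fit criterion and effective parameter count
    rhat_ : dict of parameter name -> split-chain R-hat
    group_means_ : posterior means of the group-level parameters
    participant_means_ : per-participant posterior-mean (a, z, t)
    """

    def __init__(
        self,
        varying: tuple = ("v",),
        n_samples: int = 6_000,
        burn_in: int = 1_000,
        thin: int = 5,
        n_chains: int = 3,
        seed: int = 0,
        priors: Priors | None = None,
    ):
        self.varying = varying
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.seed = seed
        self.priors = priors

    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalDDM":
        spec = ModelSpec(self.varying)
        settings = MCMCSettings(
            n_samples=self.n_samples,
            burn_in=self.burn_in,
            thin=self.thin,
            n_chains=self.n_chains,
            seed=self.seed,
        )
        self.result_ = sample_posterior(
            X, spec=spec, priors=self.priors, settings=settings
        )
        self.posterior_ = self.result_.draws
        self.dic_ = self.result_.dic
        self.pd_ = self.result_.pd_
        self.rhat_ = self.result_.rhat
        self.group_means_ = self.result_.group_means
        self.participant_means_ = self.result_.participant_means
        return self

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Total log likelihood of a trial table at the posterior means."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "result_")
        fit = self.result_
        design = build_design(fit.spec)
        if "v" in fit.spec.varying:
            v = {c: fit.group_means[n] for c, n in zip(CELLS, design["v"])}
        else:
            v = fit.group_means["v"]
        pm = fit.participant_means
        if "z" in fit.spec.varying or "t" in fit.spec.varying:
            raise NotImplementedError(
                "score() supports cell-varying drift models only"
            )
        return log_likelihood(
            X,
            v,
            dict(zip(pm["participant_id"], pm["a"])),
            dict(zip(pm["participant_id"], pm["z"])),
            dict(zip(pm["participant_id"], pm["t"])),
        )
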