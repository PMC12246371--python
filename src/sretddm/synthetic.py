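"""Synthetic SRET data with the study's design and statistical structure.

Two generators are provided: a hierarchical diffusion generator
(:func:`generate_dataset`) whose group truth defaults to the best-fit group
parameters of the original analysis, and a logistic random-intercept
generator (:func:`generate_logistic_dataset`) mirroring the trial-level
mixed-model analysis.  Both emit the canonical trial table (one row per
trial) and are byte-reproducible given a seed.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    CELLS,
    TRIAL_COLUMNS,
    GroupTruth,
    ParticipantParameters,
    StudyDesign,
    VALENCES,
)
from .ddm import _simulate_paths

__all__ = [
    "generate_word_lists",
    "sample_participants",
    "generate_dataset",
    "generate_logistic_dataset",
    "write_trials",
    "read_trials",
]

# Fixed lexicon of valenced adjectives styled on the common SRET stimulus
# sets (26 per valence).  Word identity carries no effect in generation; the
# generating models depend on valence only.
POSITIVE_WORDS: tuple[str, ...] = (
    "good", "joyful", "gentle", "funny", "kind", "capable", "warm",
    "honest", "bright", "caring", "friendly", "helpful", "cheerful",
    "patient", "creative", "reliable", "generous", "thoughtful", "calm",
    "confident", "loyal", "sincere", "lively", "strong", "graceful",
    "hopeful",
)
NEGATIVE_WORDS: tuple[str, ...] = (
    "terrible", "disloyal", "alone", "dumb", "useless", "awful", "weak",
    "lazy", "selfish", "bitter", "gloomy", "hopeless", "careless",
    "foolish", "cruel", "boring", "clumsy", "cowardly", "dull",
    "helpless", "jealous", "mean", "miserable", "nasty", "pathetic",
    "worthless",
)

_TRUNC = {"a": (0.1, np.inf), "z": (0.05, 0.95), "t": (0.1, 1.0)}


def generate_word_lists(design: StudyDesign) -> tuple[list[str], list[str]]:
    """Positive and negative adjective lists for a design.

    Deterministic given the design: the first ``words_per_valence`` entries
    of the packaged lexicon (cycled with numeric suffixes if a design asks
    for more words than the lexicon holds).
    """
    def take(words: Sequence[str], k: int) -> list[str]:
        out = []
        for i in range(k):
            base = words[i % len(words)]
            out.append(base if i < len(words) else f"{base}{i // len(words) + 1}")
        return out

    return (
        take(POSITIVE_WORDS, design.words_per_valence),
        take(NEGATIVE_WORDS, design.words_per_valence),
    )


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Draw from Normal(mean, sd) restricted to (lo, hi) by resampling.

    Resampling (rather than clipping) avoids probability atoms at the
    bounds.  With sd = 0 the mean is returned (it must lie inside).
    """
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError("degenerate truncated normal outside bounds")
        return np.full(size, float(mean)) if size else float(mean)
    n = int(np.prod(size)) if size else 1
    out = np.empty(n)
    filled = 0
    for _ in range(1000):
        draws = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        ok = draws[(draws > lo) & (draws < hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
        if filled == n:
            break
    else:
        raise RuntimeError("truncated-normal resampling failed to terminate")
    return out.reshape(size) if size else float(out[0])


def sample_participants(
    truth: GroupTruth, design: StudyDesign, seed: int | None = None
) -> list[ParticipantParameters]:
    """Draw per-participant diffusion parameters from the group hierarchy.

    Boundary separation, start point and non-decision time are drawn from
    truncated normals around the group means; drifts per cell from plain
    normals.  Hue awareness is Bernoulli(design.hue_aware_rate); sex is
    assigned near the 22:13 female:male ratio of the analyzed sample.
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    n = design.n_participants
    n_female = int(round(n * 22 / 35))
    sexes = ["female"] * n_female + ["male"] * (n - n_female)
    out = []
    for i in range(n):
        v = {
            cell: float(rng.normal(truth.v_mean[cell], truth.v_sd_between))
            for cell in CELLS
        }
        a = _truncated_normal(rng, truth.a_mean, truth.a_sd, *_TRUNC["a"])
        z = _truncated_normal(rng, truth.z_mean, truth.z_sd, *_TRUNC["z"])
        t = _truncated_normal(rng, truth.t_mean, truth.t_sd, *_TRUNC["t"])
        out.append(
            ParticipantParameters(
                participant_id=i + 1,
                v=v,
                a=float(a),
                z=float(z),
                t=float(t),
                hue_aware=bool(rng.random() < design.hue_aware_rate),
                sex=sexes[i],
            )
        )
    return out


def _session_conditions(design: StudyDesign, pid: int) -> list[str]:
    """Condition order for a participant; counterbalanced to within one."""
    first, second = design.conditions
    if design.n_sessions == 1:
        return [first]
    if design.counterbalanced and pid % 2 == 0:
        return [second, first]
    return [first, second]


def generate_dataset(
    truth: GroupTruth,
    design: StudyDesign,
    seed: int | None = None,
    dt: float = 1e-3,
    include_covariates: bool = True,
) -> pd.DataFrame:
    """Simulate a full SRET dataset from the hierarchical diffusion truth.

    Each trial's choice and RT come from a Wiener first-passage simulation
    with that participant's cell drift and (a, z, t).  At defaults the table
    has 33 x 2 x 156 = 10,296 rows, 5,148 per valence.
    """
    if seed is None:
        seed = design.seed
    participants = sample_participants(truth, design, seed=seed)
    pos_words, neg_words = generate_word_lists(design)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for p in participants:
        conds = _session_conditions(design, p.participant_id)
        for s_idx, cond in enumerate(conds, start=1):
            for block in range(1, design.n_blocks + 1):
                words = [("positive", w) for w in pos_words] + [
                    ("negative", w) for w in neg_words
                ]
                order = rng.permutation(len(words))
                for k in order:
                    valence, word = words[k]
                    rts, upper = _simulate_paths(
                        1,
                        p.v[(cond, valence)],
                        p.a,
                        p.z,
                        p.t,
                        dt,
                        int(rng.integers(2**31 - 1)),
                        int(30.0 / dt),
                    )
                    rows.append(
                        {
                            "participant_id": p.participant_id,
                            "session": s_idx,
                            "condition": cond,
                            "valence": valence,
                            "word": word,
                            "block": block,
                            "response": int(upper[0]),
                            "rt": float(rts[0]),
                            "sex": p.sex,
                            "hue_aware": p.hue_aware,
                        }
                    )
    df = pd.DataFrame(rows)
    if not include_covariates:
        df = df[list(TRIAL_COLUMNS)]
    return df


def generate_logistic_dataset(
    coefs: Mapping[str, float] | None = None,
    tau00: float = 1.88,
    design: StudyDesign | None = None,
    rt_model: Mapping[str, float] | None = None,
    seed: int = 0,
    valence: str = "negative",
) -> pd.DataFrame:
    """Simulate trial-level binary responses from a random-intercept logit.

    The linear predictor is ``logit P(reject) = intercept + b_i +
    condition * 1[blue-enriched] + rt * RT`` with participant intercepts
    ``b_i ~ Normal(0, tau00)``.  Coefficient defaults are the log odds
    ratios of the negative-word trial-level analysis (intercept ln 12.07,
    condition ln 1.24, rt ln 0.68).  RTs are lognormal with moments matched
    to the observed negative-word summaries (mean ~0.85 s, SD ~0.45 s).
    """
    if tau00 < 0:
        raise ValueError("tau00 must be >= 0")
    if valence not in VALENCES:
        raise ValueError(f"unknown valence {valence!r}")
    design = design or StudyDesign()
    defaults = {
        "intercept": math.log(12.07),
        "condition": math.log(1.24),
        "rt": math.log(0.68),
    }
    if coefs:
        defaults.update(coefs)
    coefs = defaults
    rt_model = dict(rt_model or {"mean": 0.85, "sd": 0.45})
    # lognormal parameters matched to the requested mean/SD
    m, s = rt_model["mean"], rt_model["sd"]
    sigma2 = math.log(1.0 + (s / m) ** 2)
    mu = math.log(m) - sigma2 / 2.0
    rng = np.random.default_rng(seed)
    pos_words, neg_words = generate_word_lists(design)
    words = pos_words if valence == "positive" else neg_words
    b = rng.normal(0.0, math.sqrt(tau00), size=design.n_participants)
    n_female = int(round(design.n_participants * 22 / 35))
    rows = []
    for i in range(design.n_participants):
        pid = i + 1
        hue = bool(rng.random() < design.hue_aware_rate)
        sex = "female" if i < n_female else "male"
        for s_idx, cond in enumerate(_session_conditions(design, pid), start=1):
            for block in range(1, design.n_blocks + 1):
                for word in words:
                    rt = float(rng.lognormal(mu, math.sqrt(sigma2)))
                    eta = (
                        coefs["intercept"]
                        + b[i]
                        + coefs["condition"] * (cond == "blue_enriched")
                        + coefs["rt"] * rt
                    )
                    p_reject = 1.0 / (1.0 + math.exp(-eta))
                    reject = rng.random() < p_reject
                    rows.append(
                        {
                            "participant_id": pid,
                            "session": s_idx,
                            "condition": cond,
                            "valence": valence,
                            "word": word,
                            "block": block,
                            "response": int(reject),
                            "rt": rt,
                            "sex": sex,
                            "hue_aware": hue,
                        }
                    )
    return pd.DataFrame(rows)


def write_trials(records: pd.DataFrame, path) -> None:
    """Write a trial table as UTF-8 CSV using the canonical schema."""
    df = records.copy()
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    extras = [c for c in df.columns if c not in TRIAL_COLUMNS]
    df = df[list(TRIAL_COLUMNS) + extras]
    df.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV, validating the schema and row invariants."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        return df
    bad_rt = df.index[df["rt"] <= 0]
    if len(bad_rt):
        # +2: header line plus 1-based indexing
        raise ValueError(f"{path}: non-positive rt at line {bad_rt[0] + 2}")
    bad_resp = df.index[~df["response"].isin([0, 1])]
    if len(bad_resp):
        raise ValueError(f"{path}: response not in {{0,1}} at line {bad_resp[0] + 2}")
    return df
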