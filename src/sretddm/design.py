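"""Study design and generating-truth containers for the light-exposure SRET.

The self-referential encoding task (SRET) asks a participant to answer
"yes"/"no" to whether positive and negative adjectives describe them.  The
study crossed two light conditions (blue-enriched vs blue-depleted, one per
session, counterbalanced) with word valence, giving a 2 x 2 within-subject
cell structure.  Responses are coded 0 = "yes, describes me" (endorse) and
1 = "no" (reject), so for the diffusion model the upper boundary is the
rejection response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

CONDITIONS: tuple[str, str] = ("blue_enriched", "blue_depleted")
VALENCES: tuple[str, str] = ("positive", "negative")

#: Cell order used throughout: (valence, condition) with blue-depleted first.
CELLS: tuple[tuple[str, str], ...] = (
    ("blue_depleted", "positive"),
    ("blue_enriched", "positive"),
    ("blue_depleted", "negative"),
    ("blue_enriched", "negative"),
)

CELL_LABELS: tuple[str, ...] = tuple(f"{v}:{c}" for c, v in CELLS)


def cell_index(condition: str, valence: str) -> int:
    """Map a (condition, valence) pair to its cell index in :data:`CELLS`."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if valence not in VALENCES:
        raise ValueError(f"unknown valence {valence!r}")
    return 2 * (valence == "negative") + (condition == "blue_enriched")


@dataclass
class StudyDesign:
    """Layout of the two-session, counterbalanced SRET protocol.

    Defaults reproduce the analyzed sample: 33 participants, 26 adjectives
    per valence repeated over 3 blocks (156 trials per session), two
    sessions with the condition order counterbalanced, and roughly a quarter
    of participants able to tell the two light hues apart.
    """

    n_participants: int = 33
    words_per_valence: int = 26
    n_blocks: int = 3
    n_sessions: int = 2
    conditions: tuple[str, str] = CONDITIONS
    counterbalanced: bool = True
    hue_aware_rate: float = 0.26
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.words_per_valence < 1:
            raise ValueError("words_per_valence must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.n_sessions not in (1, 2):
            raise ValueError("n_sessions must be 1 or 2")
        if not 0.0 <= self.hue_aware_rate <= 1.0:
            raise ValueError("hue_aware_rate must be a probability")
        if len(set(self.conditions)) != 2:
            raise ValueError("conditions must be two distinct labels")

    @property
    def trials_per_session(self) -> int:
        return 2 * self.words_per_valence * self.n_blocks

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d


def _default_v_mean() -> dict[tuple[str, str], float]:
    # Group-mean drift per (condition, valence) cell; positive drift pushes
    # toward the "reject" boundary, so negative words carry positive drifts.
    return {
        ("blue_depleted", "positive"): -0.73,
        ("blue_enriched", "positive"): -0.71,
        ("blue_depleted", "negative"): 1.13,
        ("blue_enriched", "negative"): 1.36,
    }


@dataclass
class GroupTruth:
    """Group-level generating parameters of the hierarchical diffusion model.

    ``v_mean`` maps each (condition, valence) cell to its mean drift rate in
    evidence units per second.  The remaining parameters are the group means
    and between-participant SDs of boundary separation ``a``, relative start
    point ``z`` (0-1 scale) and non-decision time ``t`` (seconds).  The
    between-participant SDs are not pinned down by group-level summaries, so
    the defaults are plausible magnitudes relative to the group means and
    are meant to be overridden when exploring other regimes.
    """

    v_mean: Mapping[tuple[str, str], float] = field(default_factory=_default_v_mean)
    v_sd_between: float = 0.25
    a_mean: float = 1.42
    a_sd: float = 0.20
    z_mean: float = 0.49
    z_sd: float = 0.04
    t_mean: float = 0.46
    t_sd: float = 0.05

    def __post_init__(self) -> None:
        self.v_mean = dict(self.v_mean)
        missing = [cell for cell in CELLS if cell not in self.v_mean]
        if missing:
            raise ValueError(f"v_mean missing cells: {missing}")
        if self.a_mean <= 0:
            raise ValueError("a_mean must be > 0")
        if not 0.0 < self.z_mean < 1.0:
            raise ValueError("z_mean must lie in (0, 1)")
        if self.t_mean < 0:
            raise ValueError("t_mean must be >= 0")
        for name in ("v_sd_between", "a_sd", "z_sd", "t_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def v_cells(self) -> list[float]:
        """Drift means in canonical cell order."""
        return [self.v_mean[cell] for cell in CELLS]

    def to_dict(self) -> dict:
        return {
            "v_mean": {f"{c}|{v}": val for (c, v), val in self.v_mean.items()},
            "v_sd_between": self.v_sd_between,
            "a_mean": self.a_mean,
            "a_sd": self.a_sd,
            "z_mean": self.z_mean,
            "z_sd": self.z_sd,
            "t_mean": self.t_mean,
            "t_sd": self.t_sd,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroupTruth":
        d = dict(d)
        if "v_mean" in d:
            v_mean = {}
            for key, val in dict(d["v_mean"]).items():
                cond, valence = key.split("|")
                v_mean[(cond, valence)] = float(val)
            d["v_mean"] = v_mean
        return cls(**d)


@dataclass
class ParticipantParameters:
    """Realized diffusion parameters for one participant."""

    participant_id: int
    v: dict[tuple[str, str], float]
    a: float
    z: float
    t: float
    hue_aware: bool
    sex: str

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if not 0.0 < self.z < 1.0:
            raise ValueError("z must lie in (0, 1)")
        if self.t < 0:
            raise ValueError("t must be >= 0")


#: Columns of the canonical trial table, in file order.
TRIAL_COLUMNS = (
    "participant_id",
    "session",
    "condition",
    "valence",
    "word",
    "block",
    "response",
    "rt",
)
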