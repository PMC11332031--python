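"""Two-step task environment: transitions, drifting rewards, blocks, target hits.

The task has a single first-stage choice between two containers.  Each
container is dominated by one outcome colour; the outcome colour on a trial
matches the chosen container's majority colour with probability ``p_common``
(a *common* transition) and the minority colour otherwise (*rare*).  Each
colour carries an independently drifting Bernoulli reward probability.  A
rewarded trial may additionally score a target hit, with a per-difficulty
hit probability; hits are impossible on unrewarded trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

CHOICES = ("left", "right")
COLOURS = ("purple", "pink")
DIFFICULTIES = ("easy", "medium", "hard")

#: majority outcome colour of each container (fixed display convention)
MAJORITY_COLOUR = {"left": "purple", "right": "pink"}
MINORITY_COLOUR = {"left": "pink", "right": "purple"}

#: column order of the trial-log CSV interface
TRIAL_COLUMNS = [
    "subject", "session", "block", "trial", "choice", "transition",
    "outcome_colour", "reward", "hit", "difficulty", "missed",
]


class InvalidArgument(ValueError):
    """Raised when an operation's preconditions are violated."""


# ---------------------------------------------------------------------------
# drift series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftSeries:
    """Per-colour reward-probability sequences with bounds and moments."""

    q_purple: np.ndarray
    q_pink: np.ndarray
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self):
        qp = np.asarray(self.q_purple, dtype=float)
        qk = np.asarray(self.q_pink, dtype=float)
        object.__setattr__(self, "q_purple", qp)
        object.__setattr__(self, "q_pink", qk)
        if qp.shape != qk.shape or qp.ndim != 1:
            raise InvalidArgument("drift sequences must be 1-d and equal length")
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise InvalidArgument("require 0 <= lower < upper <= 1")
        for q in (qp, qk):
            if q.size and (q.min() < self.lower - 1e-12 or q.max() > self.upper + 1e-12):
                raise InvalidArgument("drift values outside declared bounds")

    def __len__(self) -> int:
        return self.q_purple.size

    def q(self, colour: str) -> np.ndarray:
        return self.q_purple if colour == "purple" else self.q_pink

    @property
    def summary(self) -> dict:
        """Recomputed per-colour mean and SD (population SD, ddof=0)."""
        return {
            "mean_purple": float(self.q_purple.mean()),
            "mean_pink": float(self.q_pink.mean()),
            "sd_purple": float(self.q_purple.std()),
            "sd_pink": float(self.q_pink.std()),
        }


def _reflect(x: np.ndarray, lower: float, upper: float) -> np.ndarray:
    """Fold values into [lower, upper] by reflection at both bounds."""
    width = upper - lower
    y = np.mod(x - lower, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return lower + y


def generate_random_walk_drift(
    n: int,
    sd: float,
    lower: float = 0.25,
    upper: float = 0.75,
    init_purple: float = 0.5,
    init_pink: float = 0.5,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> DriftSeries:
    """Independent Gaussian random walks per colour, reflected at the bounds.

    Reflection (rather than clipping) is used so the walk does not
    accumulate mass on the boundaries.
    """
    if n < 1:
        raise InvalidArgument("n must be >= 1")
    if not (0.0 <= lower < upper <= 1.0):
        raise InvalidArgument("bounds must satisfy 0 <= lower < upper <= 1")
    if sd < 0:
        raise InvalidArgument("sd must be non-negative")
    for init in (init_purple, init_pink):
        if not (lower <= init <= upper):
            raise InvalidArgument("initial values must lie within the bounds")
    if rng is None:
        rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, sd, size=(2, n - 1)) if n > 1 else np.zeros((2, 0))
    walks = np.concatenate(
        [np.array([[init_purple], [init_pink]]), steps], axis=1
    ).cumsum(axis=1)
    walks = _reflect(walks, lower, upper)
    return DriftSeries(walks[0], walks[1], lower=lower, upper=upper)


def generate_target_moment_drift(
    n: int,
    target_mean_purple: float,
    target_mean_pink: float,
    target_sd_purple: float,
    target_sd_pink: float,
    lower: float = 0.0,
    upper: float = 1.0,
    tol: float = 0.005,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 500,
) -> DriftSeries:
    """Smooth drift whose realized per-colour moments match the targets.

    A standardized random walk is affinely rescaled to the target moments,
    clipped to the bounds, and iteratively re-standardized; attempts are
    resampled until both colours match within ``tol``.  Used to emulate
    drift sets for which only summary moments are known.
    """
    if tol <= 0:
        raise InvalidArgument("tol must be positive")
    targets = [
        ("purple", target_mean_purple, target_sd_purple),
        ("pink", target_mean_pink, target_sd_pink),
    ]
    for _, m, s in targets:
        if not (lower <= m <= upper):
            raise InvalidArgument("target means must lie within the bounds")
        if s < 0:
            raise InvalidArgument("target SDs must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)

    seqs = {}
    for colour, m, s in targets:
        if s == 0.0:
            seqs[colour] = np.full(n, m)
            continue
        ok = False
        for _ in range(max_attempts):
            walk = rng.normal(0.0, 1.0, size=n).cumsum()
            seq = walk
            for _ in range(50):
                sd_now = seq.std()
                if sd_now == 0:
                    break
                seq = (seq - seq.mean()) / sd_now * s + m
                seq = np.clip(seq, lower, upper)
                if abs(seq.mean() - m) < tol and abs(seq.std() - s) < tol:
                    ok = True
                    break
            if ok:
                seqs[colour] = seq
                break
        if not ok:
            raise InvalidArgument(
                f"could not reach mean={m}, sd={s} within [{lower}, {upper}] "
                f"after {max_attempts} attempts; targets may be infeasible"
            )
    return DriftSeries(seqs["purple"], seqs["pink"], lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# task configuration
# ---------------------------------------------------------------------------

#: per-difficulty hit probabilities; easy/medium are block-average hit rates
DEFAULT_HIT_RATES = {"easy": 0.52, "medium": 0.45, "hard": 0.30}


@dataclass
class BlockSpec:
    """One block of trials at a fixed difficulty with its own drift."""

    n_trials: int
    difficulty: str = "easy"
    #: a concrete DriftSeries, or a generator spec dict
    #: {"kind": "random_walk"|"target_moment", "params": {...}, "seed": int}
    drift: Union[DriftSeries, dict, None] = None

    def __post_init__(self):
        if self.n_trials <= 0:
            raise InvalidArgument("n_trials must be positive")
        if self.difficulty not in DIFFICULTIES:
            raise InvalidArgument(f"unknown difficulty {self.difficulty!r}")
        if isinstance(self.drift, DriftSeries) and len(self.drift) != self.n_trials:
            raise InvalidArgument("drift length must equal n_trials")

    def resolve_drift(self, rng: np.random.Generator) -> DriftSeries:
        """Materialize the drift, drawing from ``rng`` when given a spec."""
        if isinstance(self.drift, DriftSeries):
            return self.drift
        spec = self.drift or {"kind": "random_walk", "params": {}}
        kind = spec.get("kind", "random_walk")
        params = dict(spec.get("params", {}))
        sub = np.random.default_rng(spec["seed"]) if "seed" in spec else rng
        if kind == "random_walk":
            params.setdefault("sd", 0.025)
            params.setdefault("lower", 0.25)
            params.setdefault("upper", 0.75)
            lo, hi = params["lower"], params["upper"]
            params.setdefault("init_purple", float(sub.uniform(lo, hi)))
            params.setdefault("init_pink", float(sub.uniform(lo, hi)))
            return generate_random_walk_drift(self.n_trials, rng=sub, **params)
        if kind == "target_moment":
            return generate_target_moment_drift(self.n_trials, rng=sub, **params)
        raise InvalidArgument(f"unknown drift kind {kind!r}")


@dataclass
class TaskConfig:
    """Full description of one session of the task."""

    p_common: float = 0.8
    blocks: Sequence[BlockSpec] = field(default_factory=list)
    reward_lower: float = 0.25
    reward_upper: float = 0.75
    hit_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HIT_RATES))
    miss_rate: float = 0.0

    def __post_init__(self):
        if not (0.5 < self.p_common <= 1.0):
            raise InvalidArgument("p_common must be in (0.5, 1]")
        if not (0.0 <= self.reward_lower < self.reward_upper <= 1.0):
            raise InvalidArgument("reward bounds inverted")
        for level, p in self.hit_rates.items():
            if not (0.0 <= p <= 1.0):
                raise InvalidArgument(f"hit rate for {level!r} outside [0, 1]")
        if not (0.0 <= self.miss_rate <= 1.0):
            raise InvalidArgument("miss_rate must be in [0, 1]")
        if not self.blocks:
            self.blocks = [
                BlockSpec(100, "easy"),
                BlockSpec(100, "medium"),
            ]

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)


def default_config(p_common: float = 0.8, miss_rate: float = 0.0,
                   n_blocks: int = 2, block_length: int = 100) -> TaskConfig:
    """Standard session: blocks of 100 trials, easy first then medium."""
    difficulties = ["easy", "medium"] + ["medium"] * max(0, n_blocks - 2)
    blocks = [BlockSpec(block_length, difficulties[i]) for i in range(n_blocks)]
    return TaskConfig(p_common=p_common, blocks=blocks, miss_rate=miss_rate)


# ---------------------------------------------------------------------------
# trial records and simulation
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    subject: str
    session: int
    block: int
    trial: int
    choice: Optional[str]
    transition: Optional[str]
    outcome_colour: Optional[str]
    reward: Optional[int]
    hit: Optional[int]
    difficulty: str
    missed: bool

    def __post_init__(self):
        if self.missed:
            if any(v is not None for v in
                   (self.choice, self.transition, self.reward)):
                raise InvalidArgument("missed trials carry no choice/outcome")
        else:
            if self.hit == 1 and self.reward != 1:
                raise InvalidArgument("hit requires reward")
            common = self.transition == "common"
            majority = MAJORITY_COLOUR[self.choice]
            if (self.outcome_colour == majority) != common:
                raise InvalidArgument("outcome colour inconsistent with transition")


def outcome_colour_for(choice: str, transition: str) -> str:
    if transition == "common":
        return MAJORITY_COLOUR[choice]
    return MINORITY_COLOUR[choice]


def simulate_session(
    agent,
    config: TaskConfig,
    seed: Optional[int] = None,
    subject: str = "s0",
    session: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> list[TrialRecord]:
    """Run one agent through one session; returns the trial log.

    The agent must expose ``choose(rng) -> "left"|"right"`` and
    ``update(choice, outcome_colour, reward, hit)``.  Missed trials are
    injected independently at ``config.miss_rate`` and do not reach the
    agent.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    t = 0
    for b_index, block in enumerate(config.blocks, start=1):
        drift = block.resolve_drift(rng)
        hit_rate = config.hit_rates.get(block.difficulty, 0.0)
        for i in range(block.n_trials):
            if config.miss_rate > 0 and rng.random() < config.miss_rate:
                records.append(TrialRecord(
                    subject, session, b_index, t, None, None, None, None,
                    None, block.difficulty, True))
                t += 1
                continue
            choice = agent.choose(rng)
            if choice not in CHOICES:
                raise InvalidArgument(
                    f"agent returned invalid choice {choice!r}")
            common = rng.random() < config.p_common
            transition = "common" if common else "rare"
            colour = outcome_colour_for(choice, transition)
            reward = int(rng.random() < drift.q(colour)[i])
            hit: Optional[int] = None
            if reward == 1:
                hit = int(rng.random() < hit_rate)
            records.append(TrialRecord(
                subject, session, b_index, t, choice, transition, colour,
                reward, hit, block.difficulty, False))
            agent.update(choice, colour, reward, hit=hit or 0)
            t += 1
    return records


# ---------------------------------------------------------------------------
# trial-log I/O
# ---------------------------------------------------------------------------

def trials_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {col: [getattr(r, col) for r in records] for col in TRIAL_COLUMNS})


def write_trials_csv(trials: Union[pd.DataFrame, Sequence[TrialRecord]],
                     path) -> None:
    """Trial-log CSV with the documented column order; absent hit is empty."""
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    out = df[TRIAL_COLUMNS].copy()
    for col in ("reward", "hit", "session", "block", "trial"):
        out[col] = out[col].astype("Int64")
    out["missed"] = out["missed"].astype(bool)
    out.to_csv(path, index=False)


def read_trials_csv(path, column_map: Optional[Mapping[str, str]] = None
                    ) -> pd.DataFrame:
    """Read a trial log; ``column_map`` renames foreign columns to ours."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidArgument(f"trial log missing columns: {missing}")
    df = df[TRIAL_COLUMNS].copy()
    for col in ("reward", "hit", "session", "block", "trial"):
        df[col] = df[col].astype("Int64")
    df["missed"] = df["missed"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# structured config I/O
# ---------------------------------------------------------------------------

def config_to_dict(config: TaskConfig) -> dict:
    blocks = []
    for b in config.blocks:
        entry: dict = {"n_trials": b.n_trials, "difficulty": b.difficulty}
        if isinstance(b.drift, dict):
            entry["drift"] = b.drift
        elif isinstance(b.drift, DriftSeries):
            entry["drift"] = {
                "kind": "explicit",
                "params": {
                    "q_purple": b.drift.q_purple.tolist(),
                    "q_pink": b.drift.q_pink.tolist(),
                    "lower": b.drift.lower,
                    "upper": b.drift.upper,
                },
            }
        blocks.append(entry)
    return {
        "p_common": config.p_common,
        "blocks": blocks,
        "reward_lower": config.reward_lower,
        "reward_upper": config.reward_upper,
        "hit_rates": dict(config.hit_rates),
        "miss_rate": config.miss_rate,
    }


def config_from_dict(d: Mapping) -> TaskConfig:
    blocks = []
    for entry in d.get("blocks", []):
        drift = entry.get("drift")
        if isinstance(drift, dict) and drift.get("kind") == "explicit":
            p = drift["params"]
            drift = DriftSeries(np.asarray(p["q_purple"]),
                                np.asarray(p["q_pink"]),
                                lower=p.get("lower", 0.0),
                                upper=p.get("upper", 1.0))
        blocks.append(BlockSpec(entry["n_trials"],
                                entry.get("difficulty", "easy"), drift))
    kwargs = {k: d[k] for k in
              ("p_common", "reward_lower", "reward_upper", "hit_rates",
               "miss_rate") if k in d}
    return TaskConfig(blocks=blocks, **kwargs)


def save_config(config: TaskConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(source) -> TaskConfig:
    """Read a task config from a path, an open stream, or a dict."""
    if isinstance(source, Mapping):
        d = source
    elif hasattr(source, "read"):
        d = yaml.safe_load(source)
    else:
        with open(source) as fh:
            d = yaml.safe_load(fh)
    return config_from_dict(d)
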