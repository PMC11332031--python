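"""Generative choice models used as synthetic players.

The main agent is a hybrid learner mixing a model-based valuation (through
the known transition structure) with a model-free container value, combined
by a weight ``w`` and passed through a sticky softmax.  Degenerate agents
(uniform-random, fixed-side, win-stay/lose-shift) exist for calibration and
exclusion testing.

There is no eligibility-trace parameter: the task has a single choice
stage.  One learning rate is shared by the model-free and colour-value
updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .taskmodel import CHOICES, MAJORITY_COLOUR, MINORITY_COLOUR, InvalidArgument


@dataclass
class AgentParams:
    w: float = 0.5              # model-based weight in [0, 1]
    alpha: float = 0.6          # shared learning rate in (0, 1]
    beta_temp: float = 5.0      # softmax inverse temperature >= 0
    stickiness: float = 0.2     # additive bonus for repeating the last choice
    p_common_belief: float = 0.8  # transition rate used in MB valuation
    hit_distraction: float = 1.0  # alpha multiplier on hit trials (1 = off)

    def __post_init__(self):
        if not (0.0 <= self.w <= 1.0):
            raise InvalidArgument("w must be in [0, 1]")
        if not (0.0 < self.alpha <= 1.0):
            raise InvalidArgument("alpha must be in (0, 1]")
        if not (np.isfinite(self.beta_temp) and self.beta_temp >= 0):
            raise InvalidArgument("beta_temp must be finite and >= 0")
        if not (0.0 <= self.p_common_belief <= 1.0):
            raise InvalidArgument("p_common_belief must be a probability")
        if not (0.0 <= self.hit_distraction <= 1.0):
            raise InvalidArgument("hit_distraction must be in [0, 1]")


@dataclass
class AgentState:
    q_mf: dict = field(default_factory=lambda: {"left": 0.5, "right": 0.5})
    v_colour: dict = field(default_factory=lambda: {"purple": 0.5, "pink": 0.5})
    last_choice: str | None = None


class HybridAgent:
    """Hybrid model-based / model-free learner with a sticky softmax policy."""

    def __init__(self, params: AgentParams | None = None, **kwargs):
        if params is None:
            params = AgentParams(**kwargs)
        elif kwargs:
            raise InvalidArgument("pass either params or keyword overrides")
        self.params = params
        self.state = AgentState()

    def q_mb(self, choice: str) -> float:
        p = self.params.p_common_belief
        v = self.state.v_colour
        return p * v[MAJORITY_COLOUR[choice]] + (1 - p) * v[MINORITY_COLOUR[choice]]

    def p_left(self) -> float:
        pr = self.params
        st = self.state
        q_net = {
            c: pr.w * self.q_mb(c) + (1 - pr.w) * st.q_mf[c] for c in CHOICES
        }
        rep = 0.0
        if st.last_choice == "left":
            rep = 1.0
        elif st.last_choice == "right":
            rep = -1.0
        arg = pr.beta_temp * (q_net["left"] - q_net["right"]) + pr.stickiness * rep
        return float(expit(arg))

    def choose(self, rng: np.random.Generator) -> str:
        return "left" if rng.random() < self.p_left() else "right"

    def update(self, choice: str, outcome_colour: str, reward: int,
               hit: int = 0) -> None:
        pr = self.params
        st = self.state
        alpha = pr.alpha * (pr.hit_distraction if hit else 1.0)
        st.v_colour[outcome_colour] += alpha * (reward - st.v_colour[outcome_colour])
        st.q_mf[choice] += alpha * (reward - st.q_mf[choice])
        st.last_choice = choice


class UniformRandomAgent:
    """Chooses each container with probability 0.5, ignoring history."""

    def choose(self, rng: np.random.Generator) -> str:
        return "left" if rng.random() < 0.5 else "right"

    def update(self, choice, outcome_colour, reward, hit=0):
        pass


class FixedSideAgent:
    """Always returns the same container (mirrors perseverative responders)."""

    def __init__(self, side: str = "left"):
        if side not in CHOICES:
            raise InvalidArgument(f"unknown side {side!r}")
        self.side = side

    def choose(self, rng: np.random.Generator) -> str:
        return self.side

    def update(self, choice, outcome_colour, reward, hit=0):
        pass


class WinStayLoseShiftAgent:
    """Repeats the last choice after reward, switches after non-reward."""

    def __init__(self):
        self.last_choice: str | None = None
        self.last_reward: int | None = None

    def choose(self, rng: np.random.Generator) -> str:
        if self.last_choice is None:
            return "left" if rng.random() < 0.5 else "right"
        if self.last_reward == 1:
            return self.last_choice
        return "right" if self.last_choice == "left" else "left"

    def update(self, choice, outcome_colour, reward, hit=0):
        self.last_choice = choice
        self.last_reward = reward


def make_degenerate_agent(kind: str, **kwargs):
    if kind == "uniform_random":
        return UniformRandomAgent()
    if kind == "fixed_side":
        return FixedSideAgent(**kwargs)
    if kind == "win_stay_lose_shift":
        return WinStayLoseShiftAgent()
    raise InvalidArgument(f"unknown degenerate agent kind {kind!r}")
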