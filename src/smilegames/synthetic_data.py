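"""Synthetic dyadic smile data with the structure the analysis assumes.

The generator emulates the regularities reported for face-to-face
mother-infant play at ~1 s resolution: the partner (mother) smiles more
readily when the agent (infant) is smiling (responsive onsets), becomes
increasingly likely to stop smiling the longer she smiles alone
(duration-dependent cessation), and the infant's gaze at her comes in
intermittent runs.  The agent side is generated from the planner itself
— it samples actions from a Boltzmann policy over the optimal action
values for an assigned goal — so the full fit/plan/infer pipeline can
be validated by parameter and goal recovery.  A hand-coded reflex agent
is also provided to probe inference under misspecification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from smilegames.dyad_io import SmileSeries
from smilegames.partner_model import HazardModel
from smilegames.planner import GoalSpec, PlanResult, build_mdp, value_iteration


@dataclass
class GeneratorParams:
    """Hazard and session parameters of the synthetic dyad generator.

    All hazards are probabilities per 1 s bin and are capped at 0.5 to
    keep toggling identifiable at this resolution.
    """

    base_onset_hazard: float = 0.03
    responsive_onset_boost: float = 4.0
    offset_c0: float = 0.02  # offset hazard when smiling alone: c0 + c1 * tau
    offset_c1: float = 0.02
    offset_hazard_mutual: float = 0.05
    gaze_on_prob: float = 0.6
    gaze_run_mean_bins: float = 8.0
    session_len_bins: int = 300
    n_sessions: int = 10
    K: int = 30

    def __post_init__(self) -> None:
        for name in ("base_onset_hazard", "offset_c0", "offset_hazard_mutual"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5], got {v}")
        if self.offset_c1 < 0:
            raise ValueError("offset_c1 must be >= 0")
        if self.responsive_onset_boost <= 0:
            raise ValueError("responsive_onset_boost must be positive")
        if not 0.0 <= self.gaze_on_prob <= 1.0:
            raise ValueError("gaze_on_prob must lie in [0, 1]")
        if self.gaze_run_mean_bins < 1:
            raise ValueError("gaze_run_mean_bins must be >= 1")
        if self.session_len_bins < 1 or self.n_sessions < 1:
            raise ValueError("session lengths and counts must be positive")


def make_partner_hazard(params: GeneratorParams) -> HazardModel:
    """Exact ground-truth hazard table realizing the parametric hazards.

    Onset (s_self = 0): ``base_onset_hazard``, multiplied by
    ``responsive_onset_boost`` when the other partner smiles; flat in
    tau.  Offset (s_self = 1): ``min(c0 + c1 * tau, 0.5)`` when smiling
    alone, flat ``offset_hazard_mutual`` during mutual smiling.
    """
    K = params.K
    h = np.zeros((2, 2, K))
    tau = np.arange(K)
    h[0, 0, :] = params.base_onset_hazard
    h[0, 1, :] = min(params.base_onset_hazard * params.responsive_onset_boost, 0.5)
    h[1, 0, :] = np.minimum(params.offset_c0 + params.offset_c1 * tau, 0.5)
    h[1, 1, :] = params.offset_hazard_mutual
    return HazardModel.from_table(h, modeled_partner="mother")


def _gaze_chain(
    n: int, on_prob: float, run_mean: float, rng: np.random.Generator
) -> np.ndarray:
    """Two-state Markov gaze chain with given stationary on-fraction and
    mean on-run length."""
    if on_prob >= 1.0:
        return np.ones(n, dtype=np.int8)
    if on_prob <= 0.0:
        return np.zeros(n, dtype=np.int8)
    p_off = 1.0 / run_mean  # on -> off
    p_on = min(1.0, on_prob * p_off / (1.0 - on_prob))  # off -> on
    gaze = np.empty(n, dtype=np.int8)
    state = int(rng.random() < on_prob)
    for t in range(n):
        gaze[t] = state
        if state == 1:
            state = 0 if rng.random() < p_off else 1
        else:
            state = 1 if rng.random() < p_on else 0
    return gaze


def simulate_dyad(
    partner_truth: HazardModel,
    agent_goal: GoalSpec,
    agent_beta: float,
    params: GeneratorParams,
    seed,
    dyad_id: str = "d0",
    plan: PlanResult | None = None,
) -> list[SmileSeries]:
    """Simulate one dyad's sessions: softmax-rational agent vs hazard plant.

    The agent samples keep/toggle from softmax(beta * Q) under the
    optimal plan for ``agent_goal`` against ``partner_truth``; the
    partner responds per its hazard table evaluated at the pre-action
    agent state (the planner's causal ordering).  Gaze is an independent
    two-state Markov chain.  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    if plan is None:
        plan = value_iteration(build_mdp(partner_truth, agent_goal))
    mdp = plan.mdp
    if agent_beta == 0:
        p_toggle = np.full(mdp.n_states, 0.5)
    else:
        q = agent_beta * plan.Q
        q -= q.max(axis=1, keepdims=True)
        e = np.exp(q)
        p_toggle = e[:, 1] / e.sum(axis=1)
    hz = mdp.hazard
    nxt_stay = mdp.next_stay
    nxt_tog = mdp.next_toggle

    sessions: list[SmileSeries] = []
    n = params.session_len_bins
    for sess in range(params.n_sessions):
        a_ch = np.empty(n, dtype=np.int8)
        p_ch = np.empty(n, dtype=np.int8)
        s = 0  # (a=0, p=0, tau_a=0, tau_p=0)
        for t in range(n):
            st = mdp.state_tuple(s)
            a_ch[t], p_ch[t] = st.a, st.p
            u = int(rng.random() < p_toggle[s])
            s = nxt_tog[s, u] if rng.random() < hz[s] else nxt_stay[s, u]
        gaze = _gaze_chain(n, params.gaze_on_prob, params.gaze_run_mean_bins, rng)
        if agent_goal.agent_role == "mother":
            infant, mother = p_ch, a_ch
        else:
            infant, mother = a_ch, p_ch
        sessions.append(
            SmileSeries(
                dyad_id=dyad_id,
                session_id=f"s{sess}",
                infant_smile=infant,
                mother_smile=mother,
                gaze=gaze,
            )
        )
    return sessions


def simulate_reflex_dyad(
    partner_truth: HazardModel,
    params: GeneratorParams,
    seed,
    dyad_id: str = "d0",
    delay_bins: int = 1,
    onset_prob: float = 0.5,
    offset_hazard: float = 0.2,
) -> list[SmileSeries]:
    """Hand-coded reflex agent: smile ``delay_bins`` after a partner onset.

    The agent starts smiling with probability ``onset_prob`` once the
    partner has smiled for exactly ``delay_bins`` bins, and stops with a
    flat ``offset_hazard``.  No planning is involved; this generator
    tests goal inference under model misspecification.
    """
    rng = np.random.default_rng(seed)
    h = partner_truth.h
    K = partner_truth.K
    sessions: list[SmileSeries] = []
    n = params.session_len_bins
    for sess in range(params.n_sessions):
        a_ch = np.empty(n, dtype=np.int8)
        p_ch = np.empty(n, dtype=np.int8)
        a = p = 0
        tau_p = 0  # partner's own elapsed time (for its hazard)
        p_run = 0  # bins the partner has been smiling
        for t in range(n):
            a_ch[t], p_ch[t] = a, p
            a_prev = a
            if a == 0 and p == 1 and p_run == delay_bins:
                if rng.random() < onset_prob:
                    a = 1
            elif a == 1 and rng.random() < offset_hazard:
                a = 0
            if rng.random() < h[p, a_prev, tau_p]:
                p, tau_p = 1 - p, 0
            else:
                tau_p = min(tau_p + 1, K - 1)
            p_run = p_run + 1 if p == 1 else 0
        gaze = _gaze_chain(n, params.gaze_on_prob, params.gaze_run_mean_bins, rng)
        sessions.append(
            SmileSeries(
                dyad_id=dyad_id,
                session_id=f"s{sess}",
                infant_smile=a_ch,
                mother_smile=p_ch,
                gaze=gaze,
            )
        )
    return sessions


def _jitter_params(
    params: GeneratorParams, rng: np.random.Generator, sigma: float = 0.2
) -> GeneratorParams:
    """Per-dyad individual differences: lognormal (~±20%) jitter on hazards."""

    def jit(v: float, cap: float = 0.5) -> float:
        return float(min(v * rng.lognormal(0.0, sigma), cap))

    return replace(
        params,
        base_onset_hazard=jit(params.base_onset_hazard),
        offset_c0=jit(params.offset_c0),
        offset_c1=float(params.offset_c1 * rng.lognormal(0.0, sigma)),
        offset_hazard_mutual=jit(params.offset_hazard_mutual),
    )


@dataclass
class Cohort:
    """A synthetic cohort: per-dyad sessions plus the ground-truth manifest."""

    dataset: dict[str, list[SmileSeries]]
    manifest: pd.DataFrame
    truths: dict[str, HazardModel] = field(default_factory=dict)


def make_cohort(
    n_dyads: int = 13,
    goal_assignment: list[str] | None = None,
    params: GeneratorParams | None = None,
    seed: int = 0,
    agent_beta: float = 20.0,
    agent_role: str = "infant",
) -> Cohort:
    """Generate a cohort of dyads with known goals and jittered hazards.

    ``goal_assignment`` defaults to every agent pursuing partner-only
    smiling (``mother_only`` for an infant agent), the configuration
    infants are reported to maximize.  The manifest records each dyad's
    true goal, rationality beta and hazard parameters.
    """
    params = params or GeneratorParams()
    if goal_assignment is None:
        goal_assignment = ["mother_only"] * n_dyads
    if len(goal_assignment) != n_dyads:
        raise ValueError("goal_assignment length must equal n_dyads")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_dyads)
    dataset: dict[str, list[SmileSeries]] = {}
    truths: dict[str, HazardModel] = {}
    rows = []
    for i in range(n_dyads):
        dyad_id = f"d{i:02d}"
        rng = np.random.default_rng(children[i])
        dyad_params = _jitter_params(params, rng)
        truth = make_partner_hazard(dyad_params)
        goal = GoalSpec(target=goal_assignment[i], agent_role=agent_role)
        sessions = simulate_dyad(
            truth,
            goal,
            agent_beta,
            dyad_params,
            seed=rng.integers(2**31),
            dyad_id=dyad_id,
        )
        dataset[dyad_id] = sessions
        truths[dyad_id] = truth
        rows.append(
            {
                "dyad_id": dyad_id,
                "true_goal": goal_assignment[i],
                "agent_beta": agent_beta,
                "base_onset_hazard": dyad_params.base_onset_hazard,
                "responsive_onset_boost": dyad_params.responsive_onset_boost,
                "offset_c0": dyad_params.offset_c0,
                "offset_c1": dyad_params.offset_c1,
                "offset_hazard_mutual": dyad_params.offset_hazard_mutual,
            }
        )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "dyad_id",
            "true_goal",
            "agent_beta",
            "base_onset_hazard",
            "responsive_onset_boost",
            "offset_c0",
            "offset_c1",
            "offset_hazard_mutual",
        ],
    )
    return Cohort(dataset=dataset, manifest=manifest, truths=truths)
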