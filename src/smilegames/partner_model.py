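"""Discrete-time hazard model of a partner's smile onsets and offsets.

The "plant" of the control problem.  At each one-bin transition the
modeled partner toggles its smile state with a probability that depends
on the joint smile configuration and on tau, the number of bins since
the partner's own last toggle.  Conditioning on tau captures
duration-dependent dynamics — in particular, a mother becomes more
likely to cease smiling the longer she has been smiling alone.
Hazards are estimated by Laplace-smoothed toggle/exposure counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from smilegames.dyad_io import Episode

logger = logging.getLogger(__name__)


@dataclass
class HazardModel:
    """Toggle-hazard table h[s_self, s_other, tau] with diagnostic counts.

    ``s_self`` is the modeled partner's own smile state, ``s_other`` the
    other member's, and ``tau`` the bins elapsed since the partner's last
    toggle, capped at ``K - 1``.  ``h = (toggles + alpha) / (exposures +
    2 * alpha)`` entrywise.
    """

    modeled_partner: str = "mother"
    K: int = 30
    alpha: float = 1.0
    toggles: np.ndarray = field(default=None, repr=False)
    exposures: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        shape = (2, 2, self.K)
        if self.toggles is None:
            self.toggles = np.zeros(shape)
        if self.exposures is None:
            self.exposures = np.zeros(shape)
        self.toggles = np.asarray(self.toggles, dtype=float)
        self.exposures = np.asarray(self.exposures, dtype=float)
        if self.toggles.shape != shape or self.exposures.shape != shape:
            raise ValueError(f"count tables must have shape {shape}")

    @property
    def h(self) -> np.ndarray:
        """Smoothed hazard table, shape (2, 2, K)."""
        denom = self.exposures + 2.0 * self.alpha
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (self.toggles + self.alpha) / denom
        # unsmoothed model with unvisited cells: no information -> 1/2
        return np.where(denom > 0, out, 0.5)

    @classmethod
    def from_table(
        cls, h: np.ndarray, modeled_partner: str = "mother", pseudo_n: float = 1e6
    ) -> "HazardModel":
        """Build a model whose smoothed hazards equal ``h`` exactly.

        Used for ground-truth plants: counts are scaled so smoothing with
        alpha=0 reproduces ``h``.
        """
        h = np.asarray(h, dtype=float)
        if h.ndim != 3 or h.shape[:2] != (2, 2):
            raise ValueError("h must have shape (2, 2, K)")
        if (h < 0).any() or (h > 1).any():
            raise ValueError("hazards must lie in [0, 1]")
        K = h.shape[2]
        exposures = np.full(h.shape, pseudo_n)
        return cls(
            modeled_partner=modeled_partner,
            K=K,
            alpha=0.0,
            toggles=h * pseudo_n,
            exposures=exposures,
        )


def _walk_transitions(episodes: list[Episode], K: int):
    """Yield (s_self, s_other, tau, toggled) for every bin transition.

    tau counts bins since the modeled partner's (``partner_smile``
    channel) last toggle, reset at each episode start, capped at K-1.
    """
    for ep in episodes:
        tau = 0
        partner = ep.partner_smile
        agent = ep.agent_smile
        for t in range(len(partner) - 1):
            toggled = partner[t + 1] != partner[t]
            yield int(partner[t]), int(agent[t]), tau, bool(toggled)
            tau = 0 if toggled else min(tau + 1, K - 1)


def fit_hazard(
    episodes: list[Episode],
    modeled_partner: str = "mother",
    K: int = 30,
    alpha: float = 1.0,
) -> HazardModel:
    """Fit the toggle-hazard table from gaze-gated episodes.

    Each bin transition increments the exposure of its (s_self, s_other,
    tau) cell, and the toggle count when the partner's state changes at
    the next bin.  Empty input yields the pure-prior model (h = 1/2
    everywhere when alpha > 0).
    """
    model = HazardModel(modeled_partner=modeled_partner, K=K, alpha=alpha)
    for s_self, s_other, tau, toggled in _walk_transitions(episodes, K):
        model.exposures[s_self, s_other, tau] += 1
        if toggled:
            model.toggles[s_self, s_other, tau] += 1
    return model


def step_partner(
    model: HazardModel, s_self: int, s_other: int, tau: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Sample one forward step of the partner: returns (new s_self, new tau)."""
    if not 0 <= tau <= model.K - 1:
        raise ValueError(f"tau must lie in [0, {model.K - 1}], got {tau}")
    if rng.random() < model.h[s_self, s_other, tau]:
        return 1 - s_self, 0
    return s_self, min(tau + 1, model.K - 1)


def log_likelihood(model: HazardModel, episodes: list[Episode]) -> float:
    """Summed log probability of observed partner transitions under the model.

    Returns 0.0 for empty input and -inf (with a log message) when a
    zero-probability outcome is observed under an unsmoothed model.
    """
    h = model.h
    total = 0.0
    for s_self, s_other, tau, toggled in _walk_transitions(episodes, model.K):
        p = h[s_self, s_other, tau] if toggled else 1.0 - h[s_self, s_other, tau]
        if p <= 0.0:
            logger.warning(
                "zero-probability transition at cell (%d, %d, %d); "
                "log-likelihood is -inf",
                s_self,
                s_other,
                tau,
            )
            return float("-inf")
        total += float(np.log(p))
    return total


def write_hazard_csv(model: HazardModel, path) -> None:
    """Serialize as '# key=value' header lines plus a cell table."""
    h = model.h
    rows = []
    for s_self in (0, 1):
        for s_other in (0, 1):
            for tau in range(model.K):
                rows.append(
                    {
                        "s_self": s_self,
                        "s_other": s_other,
                        "tau": tau,
                        "toggles": model.toggles[s_self, s_other, tau],
                        "exposures": model.exposures[s_self, s_other, tau],
                        "h": h[s_self, s_other, tau],
                    }
                )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# modeled_partner={model.modeled_partner}\n")
        fh.write(f"# K={model.K}\n")
        fh.write(f"# alpha={model.alpha}\n")
        df.to_csv(fh, index=False)


def read_hazard_csv(path) -> HazardModel:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    K = int(meta["K"])
    model = HazardModel(
        modeled_partner=meta.get("modeled_partner", "mother"),
        K=K,
        alpha=float(meta.get("alpha", 1.0)),
    )
    for _, row in df.iterrows():
        idx = (int(row["s_self"]), int(row["s_other"]), int(row["tau"]))
        model.toggles[idx] = row["toggles"]
        model.exposures[idx] = row["exposures"]
    return model
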