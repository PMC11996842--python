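"""Pre-configured end-to-end decision tasks.

Four scenario kinds wire the lower-level modules together:

``linda_qpt``
    The 2-D angle model of the conjunction fallacy plus the observer
    perturbation layer (angle shifts and the conscious-influence factor).
``linda_collapse``
    The three-state (F, F∧BT, BT) non-Hermitian collapse model: salience
    couplings λ₁>λ₂>λ₃, decay ordering γ_BT>γ_{F∧BT}>γ_F (the least
    congruent state decays fastest), conjunction interference, and a final
    probability ranking.
``prisoner_dilemma``
    The sure-thing-principle violation: under an unknown opponent the
    cooperation probability is boosted by interference with the
    cooperation∧defection superposition state, so
    P(A_unknown) > P(A_cooperate) > P(A_defect).
``two_path_shift``
    A seeded two-outcome (random-number-generator style) session simulator
    in which an observer's focus shifts the baseline probability by the
    factor 1 + η·|⟨focus|init⟩|².

Scenario parameters are validated fail-closed against per-kind schemas:
unknown keys are rejected.  Runs are fully reproducible from
(config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import collapse as clp
from . import conjunction as cj
from . import perturbation as pt

__all__ = [
    "ScenarioConfig",
    "Ranking",
    "ConfigError",
    "SCENARIO_KINDS",
    "run_linda_qpt",
    "run_linda_collapse",
    "run_prisoner_dilemma",
    "run_two_path_shift",
    "run_scenario",
]


class ConfigError(ValueError):
    """A scenario configuration violates its kind's schema or constraints."""


# ----------------------------------------------------------------- schemas

_LINDA_QPT_SCHEMA: dict[str, Any] = {
    "theta_deg": 60.0,
    "phi_deg": 50.0,
    "delta_theta_deg": 0.0,
    "delta_phi_deg": 0.0,
    "eta": 0.0,
    "overlap_sq": 0.0,
}

# Default λ/γ values satisfy the qualitative constraints of the collapse
# model: salience ordering λ₁>λ₂>λ₃ (feminist most congruent with the
# description) and decay ordering γ_F<γ_{F∧BT}<γ_BT (bank teller is the
# high-free-energy, fastest-decaying state).  Magnitudes are this package's
# choice; only the orderings are constrained by the model.
_LINDA_COLLAPSE_SCHEMA: dict[str, Any] = {
    "labels": ["F", "F∧BT", "BT"],
    "lam": [1.2, 0.7, 0.2],
    "gamma": [0.1, 0.3, 0.6],
    "a0_magnitude": [1.0 / math.sqrt(2.0), 0.0, 1.0 / math.sqrt(2.0)],
    "a0_phase": [0.0, 0.0, 0.0],
    "t_max": 5.0,
    "n_times": 201,
    "t_eval": None,          # None → time maximizing top-two separation
    "strict_ordering": True,
    "tie_tol": 1e-9,
}

_PD_SCHEMA: dict[str, Any] = {
    "labels": ["A", "A∧B", "B"],
    "lam": [1.2, 0.7, 0.2],
    "gamma": [0.1, 0.3, 0.6],
    "a0_magnitude": [1.0 / math.sqrt(2.0), 0.0, 1.0 / math.sqrt(2.0)],
    "a0_phase": [0.0, 0.0, 0.0],
    "t_eval": 1.0,
    "strict_ordering": True,
    "tie_tol": 1e-9,
}

_TWO_PATH_SCHEMA: dict[str, Any] = {
    "baseline_p": 0.5,
    "eta": 0.01,
    "overlap_sq": 1.0,
    "n_trials": 1_000_000,
    "n_sessions": 1,
}

_SCHEMAS = {
    "linda_qpt": _LINDA_QPT_SCHEMA,
    "linda_collapse": _LINDA_COLLAPSE_SCHEMA,
    "prisoner_dilemma": _PD_SCHEMA,
    "two_path_shift": _TWO_PATH_SCHEMA,
}

SCENARIO_KINDS = tuple(_SCHEMAS)


@dataclass(frozen=True)
class ScenarioConfig:
    """A declarative scenario: kind + parameters (+ seed for stochastic kinds).

    Parameters not supplied take the kind's defaults; unknown keys raise
    :class:`ConfigError` (fail-closed validation).
    """

    kind: str
    parameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _SCHEMAS:
            raise ConfigError(
                f"unknown scenario kind {self.kind!r}; one of {SCENARIO_KINDS}"
            )
        schema = _SCHEMAS[self.kind]
        unknown = set(self.parameters) - set(schema)
        if unknown:
            raise ConfigError(
                f"unknown parameter(s) {sorted(unknown)} for kind "
                f"{self.kind!r}; allowed: {sorted(schema)}"
            )

    def resolved(self) -> dict[str, Any]:
        """Parameters merged over the kind's defaults."""
        out = dict(_SCHEMAS[self.kind])
        out.update(self.parameters)
        return out


@dataclass(frozen=True)
class Ranking:
    """An ordered outcome ranking with its probabilities and evaluation time.

    Sorted by non-increasing probability; ties (within ``tie_tol`` at
    construction) are broken lexicographically by label and reported in
    ``tied_groups``.
    """

    labels: tuple[str, ...]
    probabilities: tuple[float, ...]
    t_eval: float
    tied_groups: tuple[tuple[str, ...], ...] = ()

    @classmethod
    def from_distribution(
        cls, dist: dict[str, float], t_eval: float, tie_tol: float = 1e-9
    ) -> "Ranking":
        items = sorted(dist.items(), key=lambda kv: (-kv[1], kv[0]))
        labels = tuple(k for k, _ in items)
        probs = tuple(float(v) for _, v in items)
        ties: list[tuple[str, ...]] = []
        group = [labels[0]]
        for i in range(1, len(labels)):
            if abs(probs[i] - probs[i - 1]) <= tie_tol:
                group.append(labels[i])
            else:
                if len(group) > 1:
                    ties.append(tuple(group))
                group = [labels[i]]
        if len(group) > 1:
            ties.append(tuple(group))
        return cls(labels, probs, t_eval, tuple(ties))


# ------------------------------------------------------------- linda_qpt

def run_linda_qpt(cfg: ScenarioConfig) -> dict[str, float | bool]:
    """Closed-form conjunction-fallacy pipeline with optional perturbation.

    Returns every quantity of the worked pipeline: the standard single and
    conjunction probabilities, the fallacy flag, the exact and first-order
    perturbed conjunction probabilities, the conscious-influence factor g,
    and the combined (perturbed × g) probability.
    """
    if cfg.kind != "linda_qpt":
        raise ConfigError("config kind must be 'linda_qpt'")
    p = cfg.resolved()
    model = cj.AngleModel.from_degrees(p["theta_deg"], p["phi_deg"])
    pert = pt.PerturbationParams.from_degrees(
        p["delta_theta_deg"], p["delta_phi_deg"]
    )
    ctx = pt.ObserverContext.from_overlap(eta=p["eta"], overlap_sq=p["overlap_sq"])
    g = pt.conscious_influence_factor(ctx)
    exact = pt.exact_perturbed_conjunction(model, pert)
    return {
        "theta_deg": float(p["theta_deg"]),
        "phi_deg": float(p["phi_deg"]),
        "p_single": cj.p_single(model),
        "p_conjunction": cj.p_conjunction(model),
        "fallacy": cj.fallacy_holds(model),
        "p_single_perturbed": math.cos(
            model.theta + pert.delta_theta
        ) ** 2,
        "p_conjunction_perturbed_exact": exact,
        "p_conjunction_perturbed_first_order": pt.first_order_conjunction_shift(
            model, pert
        ),
        "g": g,
        "p_combined": exact * g,
    }


# -------------------------------------------------- three-state collapse

def _build_system(p: dict[str, Any], order_desc: str) -> clp.NonHermitianSystem:
    lam = np.asarray(p["lam"], dtype=float)
    gamma = np.asarray(p["gamma"], dtype=float)
    if p["strict_ordering"]:
        if not (lam[0] > lam[1] > lam[2]):
            raise ConfigError(
                f"{order_desc}: salience couplings must satisfy "
                f"λ₁ > λ₂ > λ₃, got {lam.tolist()}"
            )
        if not (gamma[0] < gamma[1] < gamma[2]):
            raise ConfigError(
                f"{order_desc}: decay rates must increase from the most to "
                f"the least congruent state (γ₁ < γ₂ < γ₃), got "
                f"{gamma.tolist()}"
            )
    mags = np.asarray(p["a0_magnitude"], dtype=float)
    phases = np.asarray(p["a0_phase"], dtype=float)
    a0 = mags * np.exp(1j * phases)
    n = np.linalg.norm(a0)
    if n <= 0:
        raise ConfigError("initial amplitudes are all zero")
    return clp.NonHermitianSystem(
        labels=tuple(p["labels"]), lam=lam, gamma=gamma, a0=a0 / n
    )


def _pick_t_eval(result: clp.EvolutionResult) -> tuple[int, float]:
    """Index/time maximizing the gap between the top two reported outcomes."""
    sorted_p = np.sort(result.reported_probabilities, axis=1)[:, ::-1]
    separation = sorted_p[:, 0] - sorted_p[:, 1]
    idx = int(np.argmax(separation))
    return idx, float(result.times[idx])


def run_linda_collapse(
    cfg: ScenarioConfig,
) -> tuple[Ranking, pd.DataFrame]:
    """Time-resolved three-state collapse run and its final ranking.

    With the shipped defaults the reported ranking at the evaluation time is
    (F, F∧BT, BT): the congruent feminist state survives longest, the
    conjunction is sustained by constructive interference, and the bank
    teller state decays fastest.

    Returns ``(ranking, table)`` where ``table`` has one row per
    (time, state) with raw and reported probabilities and the norm.
    """
    if cfg.kind != "linda_collapse":
        raise ConfigError("config kind must be 'linda_collapse'")
    p = cfg.resolved()
    sys = _build_system(p, "linda_collapse")
    times = np.linspace(0.0, float(p["t_max"]), int(p["n_times"]))
    result = clp.probabilities_with_interference(sys, times)
    if p["t_eval"] is None:
        idx, t_eval = _pick_t_eval(result)
    else:
        t_eval = float(p["t_eval"])
        idx = int(np.argmin(np.abs(result.times - t_eval)))
        t_eval = float(result.times[idx])
    ranking = Ranking.from_distribution(result.at(idx), t_eval, p["tie_tol"])

    rows = []
    for k, t in enumerate(result.times):
        for j, lbl in enumerate(result.labels):
            a = result.amplitudes[k, j]
            rows.append(
                {
                    "t": float(t),
                    "state": lbl,
                    "re_amp": float(a.real),
                    "im_amp": float(a.imag),
                    "raw_p": float(result.raw_probabilities[k, j]),
                    "reported_p": float(result.reported_probabilities[k, j]),
                    "norm": float(result.norm[k]),
                }
            )
    return ranking, pd.DataFrame(rows)


# ------------------------------------------------------ prisoner dilemma

def run_prisoner_dilemma(
    cfg: ScenarioConfig,
) -> tuple[dict[str, float], Ranking, bool]:
    """Sure-thing-principle violation in the quantum prisoner's dilemma.

    At the evaluation time t:

    * ``P(A_unknown)   = |a₁(t)|² + |a₂(t)|²`` — cooperation boosted by the
      interference of the cooperation∧defection superposition;
    * ``P(A_cooperate) = |a₁(t)|²`` — the opponent is known to cooperate,
      the state collapses to the bare cooperation branch (slow decay, no
      interference);
    * ``P(A_defect)    = |a₁(0)|²·e^{−2γ_B t}`` — the opponent is known to
      defect, collapse favors defection and the cooperation amplitude is
      re-assigned the fast defection-branch decay rate.

    Returns ``(probabilities, ranking, violation_flag)``; the flag is the
    sure-thing-principle violation P(A_unknown) > max(others), true under
    the shipped defaults.
    """
    if cfg.kind != "prisoner_dilemma":
        raise ConfigError("config kind must be 'prisoner_dilemma'")
    p = cfg.resolved()
    sys = _build_system(p, "prisoner_dilemma")
    t = float(p["t_eval"])
    result = clp.probabilities_with_interference(sys, [t])
    p_conj = float(result.raw_probabilities[0, 1])
    p_coop_amp = float(result.raw_probabilities[0, 0])   # |a1(t)|², rate γ_A
    gamma_fast = float(sys.gamma[2])
    p_defect = float(abs(sys.a0[0]) ** 2 * math.exp(-2.0 * gamma_fast * t))
    probs = {
        "A_unknown": p_coop_amp + p_conj,
        "A_cooperate": p_coop_amp,
        "A_defect": p_defect,
    }
    ranking = Ranking.from_distribution(probs, t, p["tie_tol"])
    violation = probs["A_unknown"] > max(probs["A_cooperate"], probs["A_defect"])
    return probs, ranking, violation


# -------------------------------------------------------- two-path shift

def run_two_path_shift(cfg: ScenarioConfig) -> pd.DataFrame:
    """Seeded Bernoulli sessions at the observer-shifted probability.

    The analytic shifted probability is
    ``p' = baseline_p · (1 + η·overlap²)``; each session draws ``n_trials``
    Bernoulli outcomes at p' and reports the observed frequency and its
    z-score against the *baseline* (the statistic a focused-intent
    experiment would test).  Fully deterministic given ``cfg.seed``.
    """
    if cfg.kind != "two_path_shift":
        raise ConfigError("config kind must be 'two_path_shift'")
    p = cfg.resolved()
    n = int(p["n_trials"])
    if n <= 0:
        raise ConfigError("n_trials must be > 0")
    n_sessions = int(p["n_sessions"])
    if n_sessions <= 0:
        raise ConfigError("n_sessions must be > 0")
    baseline = float(p["baseline_p"])
    if not (0.0 < baseline < 1.0):
        raise ConfigError("baseline_p must be in (0, 1)")
    shifted = baseline * (1.0 + float(p["eta"]) * float(p["overlap_sq"]))
    shifted = min(shifted, 1.0)
    analytic_shift = shifted - baseline

    rng = np.random.default_rng(cfg.seed)
    rows = []
    se_baseline = math.sqrt(baseline * (1.0 - baseline) / n)
    for s in range(n_sessions):
        hits = int(rng.binomial(n, shifted))
        freq = hits / n
        rows.append(
            {
                "session": s,
                "n_trials": n,
                "baseline_p": baseline,
                "shifted_p": shifted,
                "analytic_shift": analytic_shift,
                "hits": hits,
                "observed_freq": freq,
                "z_vs_baseline": (freq - baseline) / se_baseline,
            }
        )
    return pd.DataFrame(rows)


def run_scenario(cfg: ScenarioConfig):
    """Dispatch a config to its kind's runner."""
    return {
        "linda_qpt": run_linda_qpt,
        "linda_collapse": run_linda_collapse,
        "prisoner_dilemma": run_prisoner_dilemma,
        "two_path_shift": run_two_path_shift,
    }[cfg.kind](cfg)
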