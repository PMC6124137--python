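"""Zero-sum model of post-resolution chases.

After a contest is resolved the winner keeps chasing the loser at high
speed without ever closing in to bite.  The chase is modelled as a
zero-sum game: both fish swim at velocity v, requiring force F(v) at
cost C(F).  Biting at speed v would cost the winner an extra force
``delta_F`` (cost C(F + delta_F)) and deliver an extra cost ``C_b`` to
the loser.  With C convex, the biting premium
``dC(F) = C(F + delta_F) - C(F)`` increases in F, so there is a unique
chase intensity at which biting stops being profitable:
``dC(F*) = C_b``.  If instead force is capped at a physiological
maximum ``F_max`` below that point, the equilibrium is pinned at
``F(v_eq) = F_max - delta_F``.  Either way the equilibrium velocity
``v_eq`` rises (weakly) with the damage a bite inflicts.

The concrete laws used here are power laws — F(v) = k v**gamma
(monotone, gamma >= 1) and C(F) = c F**beta (strictly convex,
beta > 1) — the minimal family satisfying the model's qualitative
assumptions; both exponents are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError

INTERIOR, BOUNDARY, CAPPED = "interior", "boundary", "capped"


@dataclass(frozen=True)
class ChaseGameModel:
    """Force law F(v) = k v**gamma, cost law C(F) = c F**beta, biting
    parameters delta_F (extra force to bite), C_b (cost a bite inflicts
    on the loser) and optional force cap F_max."""

    k: float = 1.0
    gamma: float = 2.0
    c: float = 1.0
    beta: float = 2.0
    delta_F: float = 1.0
    C_b: float = 1.0
    F_max: float | None = None

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ConfigError("k must be > 0")
        if not self.gamma >= 1:
            raise ConfigError("gamma must be >= 1 (monotone force law)")
        if not self.c > 0:
            raise ConfigError("c must be > 0")
        if not self.beta > 1:
            raise ConfigError("beta must be > 1 (strictly convex cost)")
        if not self.delta_F > 0:
            raise ConfigError("delta_F must be > 0")
        if self.C_b < 0:
            raise ConfigError("C_b must be >= 0")
        if self.F_max is not None and not self.F_max > self.delta_F:
            raise ConfigError("F_max must exceed delta_F")


def force_required(v, model: ChaseGameModel):
    """Force needed to sustain velocity v: F(v) = k v**gamma."""
    v = np.asarray(v, float)
    if (v < 0).any():
        raise ValueError("velocity must be >= 0")
    out = model.k * v ** model.gamma
    return float(out) if out.ndim == 0 else out


def cost(F, model: ChaseGameModel):
    """Cost of sustaining force F: C(F) = c F**beta."""
    F = np.asarray(F, float)
    if (F < 0).any():
        raise ValueError("force must be >= 0")
    out = model.c * F ** model.beta
    return float(out) if out.ndim == 0 else out


def biting_marginal_cost(F, model: ChaseGameModel):
    """Extra cost of biting at force F: C(F + delta_F) - C(F)."""
    F = np.asarray(F, float)
    if (F < 0).any():
        raise ValueError("force must be >= 0")
    out = model.c * ((F + model.delta_F) ** model.beta - F ** model.beta)
    return float(out) if out.ndim == 0 else out


def equilibrium_force(model: ChaseGameModel, tol: float = 1e-12):
    """Chase force at equilibrium.

    Interior regime: unique root of dC(F) = C_b (dC is strictly
    increasing for convex C).  If the interior root exceeds
    F_max - delta_F the equilibrium is capped there.  If even biting
    at rest costs more than C_b (C_b < dC(0)) the interior root would
    be negative; the chase collapses to F* = 0 (boundary regime).

    Returns
    -------
    (F_star, regime) with regime in {"interior", "boundary", "capped"}.
    """
    if model.C_b < biting_marginal_cost(0.0, model):
        f_star, regime = 0.0, BOUNDARY
    else:
        def g(F):
            return biting_marginal_cost(F, model) - model.C_b

        hi = max(model.delta_F, 1.0)
        while g(hi) < 0:
            hi *= 2.0
            if hi > 1e30:
                raise ConfigError("no finite interior equilibrium")
        f_star = float(brentq(g, 0.0, hi, xtol=tol, rtol=8.9e-16))
        regime = INTERIOR
    if model.F_max is not None and f_star > model.F_max - model.delta_F:
        return model.F_max - model.delta_F, CAPPED
    return f_star, regime


def equilibrium_velocity(model: ChaseGameModel):
    """Equilibrium chase velocity v_eq = (F*/k)**(1/gamma)."""
    f_star, regime = equilibrium_force(model)
    return (f_star / model.k) ** (1.0 / model.gamma), regime


@dataclass(frozen=True)
class ChasePayoffs:
    """Zero-sum rewards from incurred costs: r_w = C_l - C_w = -r_l."""

    C_w: float
    C_l: float

    def __post_init__(self) -> None:
        if self.C_w < 0 or self.C_l < 0:
            raise ValueError("costs must be >= 0")

    @property
    def r_w(self) -> float:
        return self.C_l - self.C_w

    @property
    def r_l(self) -> float:
        return self.C_w - self.C_l


def payoffs(C_w: float, C_l: float) -> ChasePayoffs:
    """Winner/loser rewards for given incurred costs."""
    return ChasePayoffs(C_w, C_l)


def comparative_statics(model: ChaseGameModel, C_b_grid) -> pd.DataFrame:
    """(C_b, F*, v_eq, regime) over a grid of biting damages.

    v_eq is non-decreasing in C_b, strictly increasing on the interior
    regime and constant once the force cap binds: more damaging bites
    predict faster chases.
    """
    rows = []
    for cb in np.asarray(C_b_grid, float):
        if cb < 0:
            raise ValueError("C_b must be >= 0")
        m = ChaseGameModel(model.k, model.gamma, model.c, model.beta,
                           model.delta_F, float(cb), model.F_max)
        f_star, regime = equilibrium_force(m)
        v_eq = (f_star / m.k) ** (1.0 / m.gamma)
        rows.append({"C_b": float(cb), "F_star": f_star, "v_eq": v_eq,
                     "regime": regime})
    return pd.DataFrame(rows)
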