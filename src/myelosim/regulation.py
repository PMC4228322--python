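"""Feedback and forcing functions of the ODE granulopoiesis model.

These are the pure scalar building blocks of the lineage model: the bounded
monotone Z regulation function, the stem-cell self-renewal probability, the
regulated proliferative fraction of S and CG, the characteristic (on/off)
functions of chemotherapy and prednisone, endogenous cytokine production and
granulocyte-mediated G-CSF clearance.  They are reused verbatim by both the
pure ODE engine and the hybrid engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .params import CytokineBlock, OdeParams, StemBlock

# Relative cellularities below this floor are clamped before taking logs;
# depletion scenarios initialise compartments at 1e-15 of normal, so the floor
# sits at that scale.
CELLULARITY_FLOOR = 1e-15

__all__ = [
    "ZSpec",
    "z_value",
    "ChemoApplication",
    "chemo_psi",
    "prednisone_psi",
    "gra_lifetime",
    "self_renewal_p",
    "proliferative_fraction",
    "endogenous_production",
    "gcsf_clearance_rate",
    "CELLULARITY_FLOOR",
]


# --------------------------------------------------------------------------- #
# Z-function
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ZSpec:
    """Anchors of a Z regulation: value at relative regulator 0 / 1 / infinity
    plus the sensitivity exponent.

    Decreasing regulations (``Y_min > Y_max``, e.g. cytokine production that is
    maximal at low cellularity) are valid; the only structural requirement is
    that ``Y_nor`` lies strictly between ``Y_min`` and ``Y_max``.
    """

    Y_min: float
    Y_nor: float
    Y_max: float
    b_Y: float

    def validate(self) -> None:
        if self.b_Y <= 0:
            raise ValueError("ZSpec: b_Y must be > 0")
        lo, hi = sorted((self.Y_min, self.Y_max))
        if not lo < self.Y_nor < hi:
            raise ValueError(
                f"ZSpec: Y_nor={self.Y_nor} must lie strictly between "
                f"Y_min={self.Y_min} and Y_max={self.Y_max}"
            )

    @property
    def log_coefficient(self) -> float:
        # (Y_max - Y_min)/(Y_max - Y_nor) > 1 whenever Y_nor is strictly
        # between the bounds, so the log is defined and positive.
        return math.log((self.Y_max - self.Y_min) / (self.Y_max - self.Y_nor))


def z_value(c_rel: float, spec: ZSpec) -> float:
    """Z(C^rel): bounded monotone regulation between Y_min (at 0) and Y_max
    (saturation), passing through Y_nor at C^rel = 1."""
    c = max(float(c_rel), 0.0)
    exponent = spec.log_coefficient * c ** spec.b_Y
    return spec.Y_max - (spec.Y_max - spec.Y_min) * math.exp(-exponent)


# --------------------------------------------------------------------------- #
# Chemotherapy and prednisone characteristic functions
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ChemoApplication:
    """One drug-block administration.

    The cytotoxic effect acts over the half-open day ``(t, t + 24 h]``;
    the very first application of a block carries the first-cycle factor.
    """

    t: float                 # application time [h]
    block: str               # drug-block label in the ToxicityParams table
    is_first_cycle: bool = False

    WINDOW: float = 24.0


def chemo_psi(t: float, applications: Sequence[ChemoApplication],
              f_fc: float = 1.3) -> dict[str, float]:
    """Per-block chemotherapy factor Psi_CX at time t.

    Returns ``f_fc`` inside the first application's 1-day window of a block,
    1 inside subsequent windows and 0 outside; overlapping windows of the same
    block (different schedules) add.
    """
    psi: dict[str, float] = {}
    for app in applications:
        if app.t < t <= app.t + ChemoApplication.WINDOW:
            w = f_fc if app.is_first_cycle else 1.0
            psi[app.block] = psi.get(app.block, 0.0) + w
    return psi


def prednisone_psi(t: float, windows: Iterable[tuple[float, float]]) -> float:
    """Characteristic function of prednisone: 1 inside any ``(start, end]``
    administration window, else 0.  No first-cycle amplification."""
    for start, end in windows:
        if start < t <= end:
            return 1.0
    return 0.0


def gra_lifetime(t: float, windows: Iterable[tuple[float, float]],
                 T_nor: float = 5.0, T_pred: float = 0.66) -> float:
    """Granulocyte life-time, prolonged by factor (1 + T_pred) under
    prednisone."""
    return T_nor * (1.0 + T_pred * prednisone_psi(t, windows))


# --------------------------------------------------------------------------- #
# Stem cell self-renewal and proliferative fraction
# --------------------------------------------------------------------------- #


def self_renewal_p(c_s_rel: float, c_g_rel: float, s: StemBlock) -> float:
    """Probability of self-renewal in S.

    ``p = p_delta * tanh(S_term - theta_G (C_G^rel - 1)) + 0.5`` confined to
    [0.5 - p_delta, 0.5 + p_delta], where the stem-cell term uses the model
    family's below/above-equilibrium coordinate (logarithmic under depletion,
    linear above — the same convention as the proliferative-fraction
    regulator): ``S_term = -theta_S ln(C_S^rel)`` for C_S^rel <= 1 and
    ``-theta_S_high (C_S^rel - 1)`` above.

    The logarithmic branch makes the stem-cell term dominate the bone-marrow
    term under strong stem-cell depletion (p -> 0.5 + p_delta), giving the
    stem-cell feedback priority over the marrow feedback and bounding the
    maximal regrowth rate at ``(2 p_max - 1) a_S^max / tau_S``.
    """
    if c_s_rel <= 1.0:
        s_term = -s.theta_S * math.log(max(c_s_rel, CELLULARITY_FLOOR))
    else:
        s_term = -s.theta_S_high * (c_s_rel - 1.0)
    arg = s_term - s.theta_G * (c_g_rel - 1.0)
    return s.p_delta * math.tanh(arg) + 0.5


def proliferative_fraction(c_s_rel: float, c_g_rel: float, compartment: str,
                           params: OdeParams) -> float:
    """Regulated proliferative fraction a_X of compartment S or CG.

    The regulator is the weighted log-relative cellularity
    ``x = omega_G ln(C_G^rel) + omega_S * (ln(C_S^rel) if C_S^rel <= 1 else
    C_S^rel - 1)``; the sigmoid in x is anchored so that x = 0 gives a^nor and
    x = -ln 2 (a halving of the regulating cellularity) gives a^int, and
    saturates at a^max under depletion and a^min under hypercellularity.
    """
    if compartment == "S":
        blk = params.S
    elif compartment == "CG":
        blk = params.CG
    else:
        raise ValueError("proliferative fraction is regulated only in S and CG")
    s = params.S
    c_s = max(c_s_rel, CELLULARITY_FLOOR)
    c_g = max(c_g_rel, CELLULARITY_FLOOR)
    x_s = math.log(c_s) if c_s <= 1.0 else c_s - 1.0
    x = s.omega_G * math.log(c_g) + s.omega_S * x_s

    # y-coordinates reproducing a^nor at x = 0 and a^int at x = -ln 2.
    y_nor = 0.5 * math.log((blk.a_nor - blk.a_max) / (blk.a_min - blk.a_nor))
    y_int = 0.5 * math.log((blk.a_int - blk.a_max) / (blk.a_min - blk.a_int))
    y = y_nor + (y_int - y_nor) * (x / (-math.log(2.0)))
    return (blk.a_max * math.exp(-y) + blk.a_min * math.exp(y)) / (
        math.exp(-y) + math.exp(y)
    )


# --------------------------------------------------------------------------- #
# Cytokines
# --------------------------------------------------------------------------- #


def weighted_cellularity(values: dict[str, float], nor: dict[str, float],
                         block: CytokineBlock) -> float:
    """Weighted relative cellularity driving endogenous production: the
    weighted sum of compartment contents normalised by its equilibrium value
    (equal to 1 at full equilibrium)."""
    num = sum(w * values[k] for k, w in block.weights.items())
    den = sum(w * nor[k] for k, w in block.weights.items())
    return num / den


def endogenous_production(values: dict[str, float], nor: dict[str, float],
                          block: CytokineBlock) -> float:
    """Endogenous production rate P^endo = Z_P(weighted relative cellularity).

    The regulation is decreasing: production is maximal (P^min as printed in
    the parameter table) when the regulating compartments are empty, equals
    P^nor = 1 at equilibrium and falls towards P^max under hypercellularity.
    """
    r = max(weighted_cellularity(values, nor, block), 0.0)
    spec = ZSpec(Y_min=block.P_min, Y_nor=block.P_nor, Y_max=block.P_max,
                 b_Y=block.b_P)
    return z_value(r, spec)


def gcsf_clearance_rate(c_gra_rel: float, T_ren: float = 20.0,
                        T_gra: float = 2.8) -> float:
    """Total G-CSF clearance rate 1/T [1/h]: unspecific (renal) plus
    granulocyte-mediated, the latter proportional to circulating
    granulocytes."""
    return 1.0 / T_ren + max(c_gra_rel, 0.0) / T_gra
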