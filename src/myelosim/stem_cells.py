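"""Deterministic difference-equation stem-cell model with two growth
environments.

Stem cells carry a niche affinity ``a`` on the geometric grid
``a_k = exp(-k*rho)``, ``k = 0..k_max``.  In the quiescent niche environment Α
affinity regenerates (index shift −2 per step, capped at ``k = 0``); in the
proliferative environment Ω it decays (index shift +1 per step) while the cell
advances through a 49-position cell-cycle grid (G1 positions ``c < 32``,
S/G2/M positions ``c >= 32``).  Division at the last cycle position produces
two daughters at ``c = 0`` of the next affinity index.  Cells pushed past
``k_max`` lose the stem-cell state irreversibly and are collected as efflux
into downstream granulopoiesis.

Switching between the environments happens with intensities that combine the
cell's affinity and a sigmoidal capacity function of the *target* environment
(Ω→Α intensity ``alpha = (a/a_max) f_alpha(N_A)``, Α→Ω intensity
``omega = (a_min/a) f_omega(N_O)``).  No Ω→Α switch is allowed from the
mitotic phase.  The binomially distributed switch counts of the underlying
agent-based picture are replaced by their expectation values, which makes the
update deterministic with continuous (fractional) cell counts; re-introducing
binomial sampling is a straightforward extension hook.

Chemotherapy and irradiation act as a per-step survival factor applied to Ω
only (cell-cycle specific kill) and optionally — chronic irradiation in
"both-GEs" mode — to Α as well.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import ClassVar

import numpy as np

from .params import ScParams, SigmoidAnchors

__all__ = [
    "AffinityGrid",
    "SigmoidShape",
    "ScState",
    "ScKill",
    "ScModel",
    "build_affinity_grid",
    "fit_sigmoid",
    "transition_alpha",
    "transition_omega",
    "apply_kill_omega",
    "sc_step",
    "sc_equilibrium",
    "sc_metrics",
]


# --------------------------------------------------------------------------- #
# Affinity grid
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class AffinityGrid:
    """Geometric affinity grid a_k = exp(-k*rho), k = 0..k_max."""

    rho: float
    a_min: float
    k_max: int
    affinities: np.ndarray

    @property
    def n(self) -> int:
        return self.k_max + 1


def build_affinity_grid(rho: float, a_min: float) -> AffinityGrid:
    """Largest grid with all affinities strictly above the efflux threshold:
    ``k_max = max{k : exp(-k*rho) > a_min}``."""
    if rho <= 0:
        raise ValueError("rho must be > 0")
    if not 0.0 < a_min < 1.0:
        raise ValueError("require 0 < a_min < 1")
    k_max = int(math.floor(-math.log(a_min) / rho))
    if math.exp(-k_max * rho) <= a_min:  # guard the floating-point edge
        k_max -= 1
    affinities = np.exp(-rho * np.arange(k_max + 1))
    return AffinityGrid(rho=rho, a_min=a_min, k_max=k_max, affinities=affinities)


# --------------------------------------------------------------------------- #
# Sigmoidal transition characteristics
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SigmoidShape:
    """Four-parameter sigmoid ``f(N) = 1/(nu1 + nu2 exp(nu3 N/N~)) + nu4``."""

    nu1: float
    nu2: float
    nu3: float
    nu4: float
    N_tilde: float

    def __call__(self, N: float | np.ndarray) -> float | np.ndarray:
        z = np.minimum(self.nu3 * np.asarray(N, dtype=float) / self.N_tilde, 700.0)
        return 1.0 / (self.nu1 + self.nu2 * np.exp(z)) + self.nu4


def fit_sigmoid(f0: float, f_half: float, f_N: float, f_inf: float,
                N_tilde: float) -> SigmoidShape:
    """Construct the sigmoid from its anchor values f(0), f(N~/2), f(N~),
    f(inf) via the auxiliary quantities h_i = 1/(f(.) - f(inf))."""
    if N_tilde <= 0:
        raise ValueError("N_tilde must be > 0")
    for label, v in (("f0", f0), ("f_half", f_half), ("f_N", f_N)):
        if v == f_inf:
            raise ValueError(f"degenerate anchors: {label} equals f_inf")
    h1 = 1.0 / (f0 - f_inf)
    h2 = 1.0 / (f_half - f_inf)
    h3 = 1.0 / (f_N - f_inf)
    denom = h1 + h3 - 2.0 * h2
    if denom == 0.0:
        raise ValueError("degenerate anchors: h1 + h3 - 2 h2 = 0")
    nu1 = (h1 * h3 - h2 * h2) / denom
    nu2 = h1 - nu1
    if nu2 == 0.0 or (h3 - nu1) / nu2 <= 0.0:
        raise ValueError("degenerate anchors: log step of nu3 undefined")
    nu3 = math.log((h3 - nu1) / nu2)
    return SigmoidShape(nu1=nu1, nu2=nu2, nu3=nu3, nu4=f_inf, N_tilde=N_tilde)


def fit_from_anchors(anchors: SigmoidAnchors) -> SigmoidShape:
    return fit_sigmoid(anchors.f0, anchors.f_half, anchors.f_N, anchors.f_inf,
                       anchors.N_tilde)


def transition_alpha(a_k: float | np.ndarray, N_A: float, shape: SigmoidShape,
                     a_max: float = 1.0):
    """Ω→Α switch intensity per step: (a_k/a_max) * f_alpha(N_A)."""
    return (np.asarray(a_k) / a_max) * shape(N_A)


def transition_omega(a_k: float | np.ndarray, N_O: float, shape: SigmoidShape,
                     a_min: float = 0.002):
    """Α→Ω switch intensity per step: (a_min/a_k) * f_omega(N_O)."""
    return (a_min / np.asarray(a_k)) * shape(N_O)


# --------------------------------------------------------------------------- #
# State and kill
# --------------------------------------------------------------------------- #


@dataclass
class ScState:
    """Cell counts per affinity index (Α) and per affinity × cycle position
    (Ω), plus the bookkeeping of the most recent step."""

    A: np.ndarray                 # shape (k_max+1,)
    Omega: np.ndarray             # shape (k_max+1, tau_c)
    efflux: float = 0.0           # cells differentiated out in the last step
    deaths: float = 0.0           # drug/irradiation deaths in the last step
    divisions: float = 0.0        # divisions completed in the last step

    @property
    def N_A(self) -> float:
        return float(self.A.sum())

    @property
    def N_Omega(self) -> float:
        return float(self.Omega.sum())

    @property
    def N_S(self) -> float:
        return self.N_A + self.N_Omega

    def copy(self) -> "ScState":
        return ScState(self.A.copy(), self.Omega.copy(), self.efflux,
                       self.deaths, self.divisions)


@dataclass(frozen=True)
class ScKill:
    """Per-step kill probabilities (already multiplied by Psi and the step
    length): Ω is always a valid target; Α only in chronic-irradiation
    "both-GEs" mode."""

    omega: float = 0.0
    alpha: float = 0.0

    NONE: ClassVar["ScKill"]


ScKill.NONE = ScKill()


def apply_kill_omega(state: ScState, kill_rate: float, psi: float = 1.0,
                     dt: float = 1.0) -> ScState:
    """Cell-cycle specific drug kill: scale Ω elementwise by the survival
    factor ``1 - kill_rate * psi * dt`` leaving Α untouched.  Fractions above
    1 are clamped (total kill) with a warning."""
    frac = kill_rate * psi * dt
    if frac < 0:
        raise ValueError("kill fraction must be >= 0")
    if frac > 1.0:
        warnings.warn(f"kill fraction {frac:.3g} > 1 clamped to total kill",
                      stacklevel=2)
        frac = 1.0
    out = state.copy()
    out.deaths = float(state.Omega.sum()) * frac
    out.Omega = state.Omega * (1.0 - frac)
    return out


# --------------------------------------------------------------------------- #
# Engine
# --------------------------------------------------------------------------- #


class ScModel:
    """Pre-assembled difference-equation engine for a given parameter set.

    Holds the affinity grid, the fitted transition characteristics and the
    per-index affinity factors so that one step is a handful of vectorised
    array operations.
    """

    def __init__(self, params: ScParams | None = None):
        self.params = params or ScParams()
        self.params.validate()
        self.grid = build_affinity_grid(self.params.rho, self.params.a_min)
        self.f_alpha = fit_from_anchors(self.params.anchors_A)
        self.f_omega = fit_from_anchors(self.params.anchors_O)
        a = self.grid.affinities
        self._a_over_amax = a / self.params.a_max
        self._amin_over_a = self.params.a_min / a
        self.tau_c = self.params.tau_c
        self.cm = self.params.c_mitosis_start

    # -- construction -------------------------------------------------------

    def empty_state(self) -> ScState:
        return ScState(A=np.zeros(self.grid.n),
                       Omega=np.zeros((self.grid.n, self.tau_c)))

    def seed_state(self, n_cells: float = 1e3) -> ScState:
        """All seed cells dormant at maximal affinity."""
        s = self.empty_state()
        s.A[0] = n_cells
        return s

    # -- one step ------------------------------------------------------------

    def step(self, state: ScState, kill: ScKill = ScKill.NONE) -> ScState:
        """Advance one time step Δt: kill (Ω, optionally Α), environment
        switches, Α regeneration shift, Ω differentiation/cycle progression,
        divisions and boundary efflux."""
        A = state.A
        O = state.Omega
        deaths = 0.0
        if kill.omega > 0.0:
            frac = min(kill.omega, 1.0)
            deaths += float(O.sum()) * frac
            O = O * (1.0 - frac)
        if kill.alpha > 0.0:
            frac = min(kill.alpha, 1.0)
            deaths += float(A.sum()) * frac
            A = A * (1.0 - frac)

        K, cm, tc = self.grid.n, self.cm, self.tau_c
        N_A = float(A.sum())
        N_O = float(O.sum())
        alpha = self._a_over_amax * float(self.f_alpha(N_A))
        omega = self._amin_over_a * float(self.f_omega(N_O))
        one_m_alpha = 1.0 - alpha

        stay_A = A * (1.0 - omega)
        # Ω→Α switches conserve affinity; only G1 cells may switch.
        switch_in = alpha * O[:, :cm].sum(axis=1)

        new_A = np.zeros(K)
        new_A[0] = stay_A[: min(3, K)].sum()
        if K > 3:
            new_A[1 : K - 2] = stay_A[3:]
        new_A += switch_in

        new_O = np.zeros((K, tc))
        # G1 progression (affinity decays: k-1 -> k), switch loss applied
        new_O[1:, 1:cm] = O[:-1, : cm - 1] * one_m_alpha[:-1, None]
        # G1 -> mitotic handover plus fresh Α→Ω switches entering at c = cm
        new_O[1:, cm] = O[:-1, cm - 1] * one_m_alpha[:-1] + A[1:] * omega[1:]
        new_O[0, cm] = A[0] * omega[0]
        # mitotic progression: no switching allowed
        new_O[1:, cm + 1 :] = O[:-1, cm:-1]
        # division at the last cycle position: two daughters at c = 0
        new_O[1:, 0] = 2.0 * O[:-1, -1]

        divisions = float(O[:, -1].sum())
        # Everything the update would place past k_max leaves the compartment.
        efflux = (
            float((O[-1, :cm] * one_m_alpha[-1]).sum())
            + float(O[-1, cm:-1].sum())
            + 2.0 * float(O[-1, -1])
        )
        return ScState(A=new_A, Omega=new_O, efflux=efflux, deaths=deaths,
                       divisions=divisions)

    # -- equilibrium ---------------------------------------------------------

    def equilibrium(self, seed: float = 1e3, tol: float = 1e-10,
                    max_steps: int = 2_000_000,
                    check_interval: int = 1000) -> ScState:
        """Iterate from a seed population until the summaries (N_Α, N_Ω,
        efflux) are stationary to relative tolerance ``tol`` over a check
        window.  Raises on extinction or a blown step budget."""
        state = self.seed_state(seed)
        prev: np.ndarray | None = None
        for _ in range(max_steps // check_interval):
            for _ in range(check_interval):
                state = self.step(state)
            summ = np.array([state.N_A, state.N_Omega, state.efflux])
            if state.N_S <= 0:
                raise RuntimeError("stem cell population went extinct while "
                                   "searching for the equilibrium")
            if prev is not None:
                rel = np.abs(summ - prev) / np.maximum(np.abs(prev), 1e-300)
                if float(rel.max()) < tol:
                    return state
            prev = summ
        raise RuntimeError(
            f"stem-cell equilibrium not reached within {max_steps} steps; "
            f"last summaries N_A={state.N_A:.6g}, N_O={state.N_Omega:.6g}, "
            f"efflux={state.efflux:.6g}"
        )


# --------------------------------------------------------------------------- #
# Functional wrappers (operation surface)
# --------------------------------------------------------------------------- #


def sc_step(state: ScState, params: ScParams | ScModel,
            kill: ScKill = ScKill.NONE) -> ScState:
    """One difference-equation update; accepts a parameter set or a
    pre-assembled :class:`ScModel`."""
    model = params if isinstance(params, ScModel) else ScModel(params)
    return model.step(state, kill)


def sc_equilibrium(params: ScParams | ScModel, seed: float = 1e3,
                   tol: float = 1e-10, max_steps: int = 2_000_000) -> ScState:
    model = params if isinstance(params, ScModel) else ScModel(params)
    return model.equilibrium(seed=seed, tol=tol, max_steps=max_steps)


def sc_metrics(state: ScState, dt: float = 1.0) -> dict[str, float]:
    """Summary bookkeeping: totals, dormant and proliferative fractions and
    the relative per-hour efflux.  Fractions of an empty state are reported
    as 0 with the ``empty`` flag set."""
    n_a, n_o = state.N_A, state.N_Omega
    n_s = n_a + n_o
    empty = n_s <= 0.0
    return {
        "N_A": n_a,
        "N_Omega": n_o,
        "N_S": n_s,
        "fraction_A": 0.0 if empty else n_a / n_s,
        "fraction_dormant": 0.0 if empty else float(state.A[0]) / n_s,
        "proliferative_fraction": 0.0 if empty else n_o / n_s,
        "relative_efflux": 0.0 if empty else state.efflux / (n_s * dt),
        "empty": float(empty),
    }
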