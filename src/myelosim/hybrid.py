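"""Hybrid engine: the difference-equation stem-cell model driving the ODE
lineage.

The ODE stem cell compartment is replaced by the two-growth-environment
difference model.  Every hour the stem-cell engine advances one step (with
cell-cycle-specific chemotherapy kill applied to Ω only), its per-step efflux
is rescaled into ODE flux units and held constant over the hour as the CG
influx, and the ODE lineage (CG onward) is integrated across the hour with
the relative stem number ``N_S / N_S_hat`` supplied to the a_CG regulation.

The efflux rescaling uses ``k_scaling`` chosen so that the coupled influx to
CG at the joint equilibrium equals the ODE model's equilibrium stem efflux
``a_S^nor / tau_S = 0.01875 / h``; the mismatch between the two models'
equilibrium effluxes is a pure scaling (normalisation) issue.  The marrow →
stem feedback of the ODE model is dropped: the intrinsic niche regulation of
the stem-cell model replaces all stem-side feedback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .events import EventSchedule
from .ode_model import ExternalStem, I_S, N_STATE, OdeModel
from .params import OdeParams, ScParams
from .results import SimResult
from .stem_cells import ScKill, ScModel, ScState

__all__ = ["CouplingSpec", "HybridModel", "compute_k_scaling",
           "simulate_hybrid"]


@dataclass(frozen=True)
class CouplingSpec:
    """Flux translation between the stem-cell engine and the ODE lineage."""

    k_scaling: float          # ODE-units per stem cell
    N_S_hat: float            # equilibrium total stem cell number
    N_Sout_hat: float         # equilibrium efflux per step
    C_S_out_nor: float        # ODE equilibrium stem efflux [1/h]
    dt: float = 1.0           # stem-engine step [h]

    def efflux_to_ode(self, n_sout: float) -> float:
        """Instantaneous CG influx in ODE units from one step's efflux."""
        return self.k_scaling * n_sout / self.dt


def compute_k_scaling(sc_equilibrium: ScState, ode_s_out_nor: float,
                      dt: float = 1.0) -> CouplingSpec:
    """k_scaling such that the coupled equilibrium influx to CG equals the
    ODE equilibrium stem efflux."""
    if sc_equilibrium.efflux <= 0:
        raise ValueError("stem-cell equilibrium efflux must be > 0")
    k_scaling = ode_s_out_nor * dt / sc_equilibrium.efflux
    return CouplingSpec(k_scaling=k_scaling,
                        N_S_hat=sc_equilibrium.N_S,
                        N_Sout_hat=sc_equilibrium.efflux,
                        C_S_out_nor=ode_s_out_nor,
                        dt=dt)


class HybridModel:
    """Lockstep coupling of :class:`ScModel` and :class:`OdeModel`."""

    def __init__(self, ode_params: OdeParams | None = None,
                 sc_params: ScParams | None = None,
                 sc_equilibrium: ScState | None = None):
        self.ode = OdeModel(ode_params)
        self.sc = ScModel(sc_params)
        self.sc_eq = (sc_equilibrium if sc_equilibrium is not None
                      else self.sc.equilibrium())
        self.coupling = compute_k_scaling(self.sc_eq, self.ode.steady.S_out,
                                          self.sc.params.dt)

    # ------------------------------------------------------------------ #

    def initial_sc_state(self, alpha_factor: float = 1.0,
                         omega_factor: float = 1.0) -> ScState:
        """Equilibrium stem-cell state with per-environment multipliers."""
        s = self.sc_eq.copy()
        s.A = s.A * alpha_factor
        s.Omega = s.Omega * omega_factor
        return s

    def step(self, sc_state: ScState, y: np.ndarray, t: float,
             schedule: EventSchedule, rtol: float = 1e-8,
             atol: float = 1e-8) -> tuple[ScState, np.ndarray]:
        """One lockstep hour: stem engine first (kill evaluated at the
        interval start), then the ODE lineage under the frozen coupled
        influx."""
        dt = self.coupling.dt
        k_omega, k_alpha = schedule.sc_kill_per_step(t, dt)
        sc_state = self.sc.step(sc_state, ScKill(omega=k_omega, alpha=k_alpha))
        external = ExternalStem(
            C_S_out=self.coupling.efflux_to_ode(sc_state.efflux),
            C_S_rel=sc_state.N_S / self.coupling.N_S_hat,
        )
        y = self.ode.advance(y, t, t + dt, schedule, external=external,
                             rtol=rtol, atol=atol)
        return sc_state, y

    def simulate(self, schedule: EventSchedule,
                 init: Mapping[str, float] | None = None,
                 sc_init: ScState | None = None,
                 t_end: float = 2400.0,
                 rtol: float = 1e-8, atol: float = 1e-8,
                 day_callback=None,
                 meta: Mapping[str, object] | None = None) -> SimResult:
        """Run the hybrid model on the hourly grid.

        ``init`` holds lineage multipliers (as in
        :meth:`OdeModel.initial_state`; an "S" key also scales both stem-cell
        growth environments unless ``sc_init`` is given).  ``day_callback``,
        if set, is invoked at the start of every simulated day with
        ``(t, sc_state, y, schedule)`` and may return a replacement schedule —
        the hook used for administer-until-recovery G-CSF policies.
        """
        init = dict(init or {})
        s_factor = init.pop("S", 1.0)
        if sc_init is not None:
            sc_state = sc_init.copy()
        else:
            sc_state = self.initial_sc_state(s_factor, s_factor)
        y = self.ode.initial_state(init)
        y[I_S] = sc_state.N_S / self.coupling.N_S_hat

        dt = self.coupling.dt
        n_steps = int(round(t_end / dt))
        t_grid = np.arange(n_steps + 1) * dt
        traj = np.empty((n_steps + 1, N_STATE))
        sc_traj = np.empty((n_steps + 1, 4))   # N_A, N_Omega, N_S, efflux
        traj[0] = y
        sc_traj[0] = (sc_state.N_A, sc_state.N_Omega, sc_state.N_S,
                      self.sc_eq.efflux * sc_state.N_S / self.coupling.N_S_hat)
        for i in range(n_steps):
            t = t_grid[i]
            if day_callback is not None and i % 24 == 0:
                new_schedule = day_callback(t, sc_state, y, schedule)
                if new_schedule is not None:
                    schedule = new_schedule
            sc_state, y = self.step(sc_state, y, t, schedule, rtol, atol)
            y[I_S] = sc_state.N_S / self.coupling.N_S_hat
            traj[i + 1] = y
            sc_traj[i + 1] = (sc_state.N_A, sc_state.N_Omega, sc_state.N_S,
                              sc_state.efflux)

        result_meta = {"engine": "hybrid"}
        result_meta.update(meta or {})
        res = self.ode._package(t_grid, traj, result_meta)
        res.series["N_A"] = sc_traj[:, 0]
        res.series["N_Omega"] = sc_traj[:, 1]
        res.series["N_S"] = sc_traj[:, 2]
        res.series["efflux"] = sc_traj[:, 3]
        res.nor["N_A"] = self.sc_eq.N_A
        res.nor["N_Omega"] = self.sc_eq.N_Omega
        res.nor["N_S"] = self.sc_eq.N_S
        res.nor["efflux"] = self.sc_eq.efflux
        # the lineage S slot mirrors the relative stem number
        res.nor["S"] = 1.0
        return res


def simulate_hybrid(ode_params: OdeParams | None, sc_params: ScParams | None,
                    schedule: EventSchedule,
                    init: Mapping[str, float] | None = None,
                    t_end: float = 2400.0, **kwargs) -> SimResult:
    return HybridModel(ode_params, sc_params).simulate(
        schedule, init, t_end=t_end, **kwargs)
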