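"""Time-stamped forcing of a simulation: chemotherapy applications, G-CSF
administrations, prednisone windows and constant irradiation kill.

All times are hours from the start of the simulation; scenario builders
convert day-based calendars (day 1 = hours [0, 24)) before constructing the
schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ToxicityParams, default_toxicity
from .regulation import ChemoApplication, chemo_psi, prednisone_psi

__all__ = ["GcsfAdministration", "IrradiationSpec", "EventSchedule"]

IRRADIATION_MODES = ("ode", "hybrid-both", "hybrid-omega")

# Committed progenitors and precursors are less radiosensitive than stem
# cells; a fixed ratio ties their chronic kill rates to k_S.
IRRADIATION_LINEAGE_FACTOR = 0.66


@dataclass(frozen=True)
class GcsfAdministration:
    """One subcutaneous G-CSF application: a short constant-rate infusion into
    the first depot compartment starting at ``t``."""

    t: float
    dose: float | None = None    # None -> parameter default d_gcsf


@dataclass(frozen=True)
class IrradiationSpec:
    """Chronic irradiation as a constant first-order kill.

    ``k_S`` acts on the stem cell compartment (in the hybrid engine on Ω, or
    on both growth environments in mode "hybrid-both"); CG and PGB are killed
    at ``0.66 * k_S``.
    """

    k_S: float
    mode: str = "ode"

    def __post_init__(self) -> None:
        if self.mode not in IRRADIATION_MODES:
            raise ValueError(f"irradiation mode must be one of "
                             f"{IRRADIATION_MODES}, got {self.mode!r}")
        if self.k_S < 0:
            raise ValueError("k_S must be >= 0")

    @property
    def k_CG(self) -> float:
        return IRRADIATION_LINEAGE_FACTOR * self.k_S

    @property
    def k_PGB(self) -> float:
        return IRRADIATION_LINEAGE_FACTOR * self.k_S


@dataclass
class EventSchedule:
    """Bundle of every scheduled or constant forcing plus the toxicity table
    used to translate drug blocks into kill rates."""

    chemo: list[ChemoApplication] = field(default_factory=list)
    gcsf: list[GcsfAdministration] = field(default_factory=list)
    prednisone: list[tuple[float, float]] = field(default_factory=list)
    irradiation: IrradiationSpec | None = None
    toxicity: ToxicityParams = field(
        default_factory=lambda: default_toxicity("CHOP-21"))

    def __post_init__(self) -> None:
        self.chemo = sorted(self.chemo, key=lambda a: a.t)
        self.gcsf = sorted(self.gcsf, key=lambda a: a.t)
        self.prednisone = sorted(self.prednisone)
        for app in self.chemo:
            if app.t < 0:
                raise ValueError("chemo application times must be >= 0")
            if app.block not in self.toxicity.blocks:
                raise ValueError(f"chemo block {app.block!r} not in toxicity "
                                 f"table {sorted(self.toxicity.blocks)}")

    # -- forcing evaluation --------------------------------------------------

    def psi_chemo(self, t: float) -> dict[str, float]:
        return chemo_psi(t, self.chemo, self.toxicity.f_fc)

    def kill_rates(self, t: float) -> np.ndarray:
        """Instantaneous (k_S, k_CG, k_PGB, k_MGB) [1/h] from chemotherapy
        plus any chronic irradiation (ODE-engine view: irradiation k_S on S)."""
        rates = np.zeros(4)
        for block_label, w in self.psi_chemo(t).items():
            blk = self.toxicity.blocks[block_label]
            rates += w * np.array([blk.k_S, blk.k_CG, blk.k_PGB, blk.k_MGB])
        if self.irradiation is not None:
            irr = self.irradiation
            k_s = irr.k_S if irr.mode == "ode" else 0.0
            rates += np.array([k_s, irr.k_CG, irr.k_PGB, 0.0])
        return rates

    def sc_kill_per_step(self, t: float, dt: float = 1.0) -> tuple[float, float]:
        """Per-step kill probabilities (Ω, Α) for the stem-cell difference
        engine at the step starting at ``t`` (hybrid engine)."""
        k_omega = 0.0
        for block_label, w in self.psi_chemo(t).items():
            k_omega += w * self.toxicity.blocks[block_label].k_S * dt
        k_alpha = 0.0
        if self.irradiation is not None and self.irradiation.mode != "ode":
            k_omega += self.irradiation.k_S * dt
            if self.irradiation.mode == "hybrid-both":
                k_alpha = self.irradiation.k_S * dt
        return min(k_omega, 1.0), min(k_alpha, 1.0)

    def psi_prednisone(self, t: float) -> float:
        return prednisone_psi(t, self.prednisone)

    def sc_exo(self, t: float, d_gcsf: float, t_inf: float) -> float:
        """Exogenous G-CSF input rate into the first depot compartment: the
        administered dose delivered at constant rate over the infusion
        window ``[t_i, t_i + t_inf)``."""
        rate = 0.0
        for adm in self.gcsf:
            if adm.t <= t < adm.t + t_inf:
                rate += (adm.dose if adm.dose is not None else d_gcsf) / t_inf
        return rate

    # -- integration support -------------------------------------------------

    def discontinuity_times(self, t0: float, t1: float,
                            t_inf: float) -> list[float]:
        """Sorted forcing discontinuities strictly inside (t0, t1): chemo
        window edges, prednisone window edges, infusion start/end."""
        edges: set[float] = set()
        for app in self.chemo:
            edges.update((app.t, app.t + ChemoApplication.WINDOW))
        for start, end in self.prednisone:
            edges.update((start, end))
        for adm in self.gcsf:
            edges.update((adm.t, adm.t + t_inf))
        return sorted(e for e in edges if t0 < e < t1)

    def with_extra_gcsf(self, t: float,
                        dose: float | None = None) -> "EventSchedule":
        """Copy of the schedule with one additional G-CSF administration
        (used by administer-until-recovery scenarios)."""
        out = EventSchedule(chemo=list(self.chemo),
                            gcsf=list(self.gcsf) + [GcsfAdministration(t, dose)],
                            prednisone=list(self.prednisone),
                            irradiation=self.irradiation,
                            toxicity=self.toxicity)
        return out
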