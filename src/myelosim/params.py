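"""Parameter registries for the granulopoiesis models.

Three immutable parameter sets are shipped:

* :class:`OdeParams` — the compartment (ODE) lineage model of human
  granulopoiesis: stem cells S, progenitors CG, proliferating precursors PGB,
  maturing precursors G4–G6, circulating granulocytes GRA, and the cytokines
  GM-CSF and G-CSF including a two-compartment subcutaneous G-CSF depot.
* :class:`ScParams` — the difference-equation stem-cell model with two growth
  environments (quiescent niche Α, proliferative Ω) on a geometric affinity
  grid ``a_k = exp(-k*rho)``.
* :class:`ToxicityParams` / :class:`RegimenSpec` — cell-stage specific kill
  rates of CHOP-like drug blocks and their administration calendars.

All times are hours internally; scenario-level inputs in days are converted
(1 d = 24 h) by the scenario builders.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

HOURS_PER_DAY = 24.0

__all__ = [
    "OdeParams",
    "ScParams",
    "ToxicityParams",
    "DrugBlock",
    "RegimenSpec",
    "default_ode_params",
    "default_sc_params",
    "default_toxicity",
    "default_regimen",
    "REGIMEN_NAMES",
    "load_config",
    "save_config",
    "dump_default_config",
]


# --------------------------------------------------------------------------- #
# ODE model parameters
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class StemBlock:
    """Stem cell compartment S."""

    tau_S: float = 8.0          # average cell-cycle duration [h]
    p_delta: float = 0.1        # amplitude of self-renewal regulation
    a_min: float = 0.01         # minimal proliferative fraction
    a_nor: float = 0.15         # proliferative fraction at equilibrium
    a_int: float = 0.45         # proliferative fraction at intensified stimulation
    a_max: float = 1.0          # maximal proliferative fraction
    theta_S: float = 2.0        # weight of -ln(C_S^rel) in p for C_S^rel <= 1
    theta_S_high: float = 0.62  # weight of (C_S^rel - 1) in p for C_S^rel > 1
    theta_G: float = -10.0      # weight of bone-marrow cells in p
    omega_S: float = 1.0        # weight of stem cells in the a-regulation
    omega_G: float = 0.4        # weight of bone-marrow cells in the a-regulation


@dataclass(frozen=True)
class ProgenitorBlock:
    """Granulopoietic progenitors CG (CFU-GM)."""

    a_min: float = 0.3
    a_nor: float = 0.33
    a_int: float = 0.6
    a_max: float = 1.0
    A_min: float = 1.0
    A_nor: float = 64.0
    A_max: float = 333.0
    b_A: float = 0.4
    T: float = 112.0            # transit time [h]


@dataclass(frozen=True)
class PrecursorBlock:
    """Proliferating granulopoietic precursors PGB."""

    a: float = 1.0
    A_min: float = 4.0
    A_nor: float = 32.0
    A_max: float = 330.0
    b_A: float = 0.27
    T: float = 148.0


@dataclass(frozen=True)
class MaturingBlock:
    """One of the maturing precursor stages G4/G5/G6.

    Transit time is G-CSF regulated in all three stages; amplification only in
    G6 (A < 1, post-mitotic apoptosis), G4/G5 have fixed A = 1.  The stage is
    chained from ``n_sub`` identical subcompartments so that transit times are
    gamma distributed.
    """

    n_sub: int
    T_min: float                # transit time at zero G-CSF (longest) [h]
    T_nor: float
    T_max: float                # transit time at saturating G-CSF (shortest) [h]
    b_T: float
    A: float = 1.0              # fixed amplification (G4/G5)
    A_min: float | None = None  # regulated amplification (G6 only)
    A_nor: float | None = None
    A_max: float | None = None
    b_A: float | None = None

    @property
    def regulated_amplification(self) -> bool:
        return self.A_nor is not None


@dataclass(frozen=True)
class GranulocyteBlock:
    """Circulating granulocytes GRA."""

    T_nor: float = 5.0          # life-time [h]
    T_pred: float = 0.66        # prednisone prolongation factor


@dataclass(frozen=True)
class CytokineBlock:
    """Endogenous production parameters of GM-CSF or G-CSF.

    The production rate is Z-regulated by a weighted relative cellularity; the
    printed parameter labels are used verbatim (``P_min`` is the production at
    vanishing cellularity, which is the *largest* value — the regulation is
    decreasing)."""

    P_max: float
    P_nor: float
    P_min: float
    b_P: float
    T: float | None = None      # cytokine life-time [h] (GM-CSF only)
    weights: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class GcsfKineticsBlock:
    """G-CSF pharmacokinetics: subcutaneous depot and clearance."""

    k_sc: float = 0.75          # depot transition rate [1/h]
    d_gcsf: float = 5.6e6       # administered dose-equivalent per application
    t_inf: float = 1.0 / 30.0   # infusion duration [h] (2 min)
    T_ren: float = 20.0         # unspecific (renal) clearance time constant [h]
    T_gra: float = 2.8          # granulocyte-mediated clearance time constant [h]


@dataclass(frozen=True)
class OdeParams:
    """Full parameter set of the ODE granulopoiesis model."""

    S: StemBlock = field(default_factory=StemBlock)
    CG: ProgenitorBlock = field(default_factory=ProgenitorBlock)
    PGB: PrecursorBlock = field(default_factory=PrecursorBlock)
    G4: MaturingBlock = field(
        default_factory=lambda: MaturingBlock(n_sub=5, T_min=60.0, T_nor=51.0,
                                              T_max=1.0, b_T=0.845)
    )
    G5: MaturingBlock = field(
        default_factory=lambda: MaturingBlock(n_sub=5, T_min=100.0, T_nor=92.0,
                                              T_max=46.0, b_T=0.845)
    )
    G6: MaturingBlock = field(
        default_factory=lambda: MaturingBlock(n_sub=5, T_min=140.0, T_nor=22.0,
                                              T_max=20.0, b_T=0.845,
                                              A_min=0.01, A_nor=0.4277,
                                              A_max=1.0, b_A=1.52)
    )
    GRA: GranulocyteBlock = field(default_factory=GranulocyteBlock)
    GM_CSF: CytokineBlock = field(
        default_factory=lambda: CytokineBlock(
            P_max=0.91, P_nor=1.0, P_min=310.0, b_P=1.7, T=2.0,
            weights={"CG": 1.0, "PGB": 1.0, "G4": 1.0, "G5": 1.0, "G6": 0.2},
        )
    )
    G_CSF: CytokineBlock = field(
        default_factory=lambda: CytokineBlock(
            P_max=0.97, P_nor=1.0, P_min=410.0, b_P=0.33, T=None,
            weights={"G6": 0.2, "GRA": 1.0},
        )
    )
    G_CSF_kinetics: GcsfKineticsBlock = field(default_factory=GcsfKineticsBlock)
    split_exponent: float = 0.5  # gamma: A_in = A**gamma, A_out = A**(1-gamma)

    def validate(self) -> None:
        """Raise :class:`ValueError` naming the offending key on violation."""
        s, cg = self.S, self.CG
        for label, blk in (("S", s), ("CG", cg)):
            if not (0.0 < blk.a_min <= blk.a_nor <= blk.a_int <= blk.a_max <= 1.0):
                raise ValueError(
                    f"{label}: require 0 < a_min <= a_nor <= a_int <= a_max <= 1, "
                    f"got ({blk.a_min}, {blk.a_nor}, {blk.a_int}, {blk.a_max})"
                )
        for label, lo, nor, hi in (
            ("CG.A", cg.A_min, cg.A_nor, cg.A_max),
            ("PGB.A", self.PGB.A_min, self.PGB.A_nor, self.PGB.A_max),
            ("G6.A", self.G6.A_min, self.G6.A_nor, self.G6.A_max),
        ):
            if not (lo <= nor <= hi):
                raise ValueError(f"{label}: require A_min <= A_nor <= A_max, "
                                 f"got ({lo}, {nor}, {hi})")
        positive = {
            "S.tau_S": s.tau_S, "CG.T": cg.T, "PGB.T": self.PGB.T,
            "GRA.T_nor": self.GRA.T_nor, "GM_CSF.T": self.GM_CSF.T,
            "G_CSF_kinetics.T_ren": self.G_CSF_kinetics.T_ren,
            "G_CSF_kinetics.T_gra": self.G_CSF_kinetics.T_gra,
            "G_CSF_kinetics.k_sc": self.G_CSF_kinetics.k_sc,
            "G_CSF_kinetics.t_inf": self.G_CSF_kinetics.t_inf,
        }
        for g in ("G4", "G5", "G6"):
            blk: MaturingBlock = getattr(self, g)
            positive[f"{g}.T_min"] = blk.T_min
            positive[f"{g}.T_nor"] = blk.T_nor
            positive[f"{g}.T_max"] = blk.T_max
            if blk.n_sub < 1:
                raise ValueError(f"{g}.n_sub must be >= 1")
        for key, val in positive.items():
            if not (val is not None and val > 0):
                raise ValueError(f"{key} must be strictly positive, got {val}")
        if not 0.0 <= self.split_exponent <= 1.0:
            raise ValueError("split_exponent must be in [0, 1]")


# --------------------------------------------------------------------------- #
# Stem cell (difference equation) parameters
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SigmoidAnchors:
    """Anchor parametrisation (f(0), f(N~/2), f(N~), f(inf), N~) of a
    transition characteristic."""

    f0: float
    f_half: float
    f_N: float
    f_inf: float
    N_tilde: float


@dataclass(frozen=True)
class ScParams:
    """Parameters of the two-growth-environment stem-cell model.

    The regeneration coefficient ``r`` (affinity growth per step in niche Α)
    and differentiation coefficient ``d`` (affinity decay per step in Ω) are
    stored constructively as ``e^{2 rho}`` and ``e^{rho}`` so that the affinity
    grid identity ``a_k = e^{-k rho}`` is exact.
    """

    dt: float = 1.0                   # simulation step [h]
    rho: float = 0.0488               # log-affinity grid step
    a_min: float = 0.002              # efflux threshold affinity
    a_max: float = 1.0
    tau_c: int = 49                   # cell-cycle grid length (49 positions)
    c_mitosis_start: int = 32         # first S/G2/M position
    anchors_A: SigmoidAnchors = field(
        default_factory=lambda: SigmoidAnchors(0.5, 0.45, 0.05, 0.0, 1e5)
    )  # f_alpha: Omega -> Alpha characteristic vs N_Alpha
    anchors_O: SigmoidAnchors = field(
        default_factory=lambda: SigmoidAnchors(0.5, 0.3, 0.1, 0.0, 1e5)
    )  # f_omega: Alpha -> Omega characteristic vs N_Omega

    @property
    def r(self) -> float:
        """Regeneration coefficient, e^{2 rho} (1.10252 for the default grid)."""
        return math.exp(2.0 * self.rho)

    @property
    def d(self) -> float:
        """Differentiation coefficient, e^{rho} (1.05001 for the default grid)."""
        return math.exp(self.rho)

    def validate(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if not (0.0 < self.a_min < self.a_max):
            raise ValueError("require 0 < a_min < a_max")
        if self.a_max != 1.0:
            raise ValueError("a_max must be 1 (affinities are normalised)")
        if self.tau_c < 2 or not 0 < self.c_mitosis_start < self.tau_c:
            raise ValueError("cycle grid requires 0 < c_mitosis_start < tau_c")
        for label, anc in (("anchors_A", self.anchors_A),
                           ("anchors_O", self.anchors_O)):
            for fname in ("f0", "f_half", "f_N", "f_inf"):
                v = getattr(anc, fname)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{label}.{fname} must lie in [0, 1]")
            if anc.N_tilde <= 0:
                raise ValueError(f"{label}.N_tilde must be > 0")


# --------------------------------------------------------------------------- #
# Chemotherapy toxicity and regimens
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class DrugBlock:
    """Kill rates [1/h] of one drug (combination) per cell stage."""

    k_S: float
    k_CG: float
    k_PGB: float
    k_MGB: float

    def validate(self, label: str = "drug block") -> None:
        for name in ("k_S", "k_CG", "k_PGB", "k_MGB"):
            if getattr(self, name) < 0:
                raise ValueError(f"{label}.{name} must be >= 0")


@dataclass(frozen=True)
class ToxicityParams:
    """Kill-rate table of a regimen plus the first-cycle factor f_fc."""

    blocks: Mapping[str, DrugBlock]
    f_fc: float = 1.3

    def validate(self) -> None:
        if self.f_fc < 1.0:
            raise ValueError("f_fc must be >= 1")
        for name, blk in self.blocks.items():
            blk.validate(label=name)


@dataclass(frozen=True)
class RegimenSpec:
    """Administration calendar of a multi-cycle regimen (days within cycle,
    day 1 = cycle start)."""

    name: str
    cycle_length_d: int
    n_cycles: int
    drug_days: Mapping[str, tuple[int, ...]]   # block label -> days
    gcsf_days: tuple[int, ...] = ()
    prednisone_days: tuple[int, ...] = ()

    def validate(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for label, days in list(self.drug_days.items()) + [
            ("gcsf", self.gcsf_days), ("prednisone", self.prednisone_days)
        ]:
            for day in days:
                if not 1 <= day <= self.cycle_length_d:
                    raise ValueError(
                        f"{self.name}: {label} day {day} outside "
                        f"[1, {self.cycle_length_d}]"
                    )


CHOP_BLOCK = "C750+D50+V2"
ETOPOSIDE_BLOCK = "E100"
REGIMEN_NAMES = ("CHOP-21", "CHOP-14", "CHOEP-21", "CHOEP-14")


# --------------------------------------------------------------------------- #
# Defaults
# --------------------------------------------------------------------------- #


def default_ode_params() -> OdeParams:
    """Shipped ODE-model parameter set (validated)."""
    p = OdeParams()
    p.validate()
    return p


def default_sc_params() -> ScParams:
    """Shipped stem-cell parameter set for the human system (validated)."""
    p = ScParams()
    p.validate()
    return p


def default_toxicity(regimen_name: str, *, warn_k_cg: bool = False) -> ToxicityParams:
    """Kill-rate table for one of the four CHOP-like regimens.

    The published kill-rate table carries no value for the progenitor
    compartment CG although the model defines one; CFU-GM cycle as actively
    as the precursor stages, so ``k_CG = k_PGB`` is shipped as the default.
    It is an ordinary config knob and can be overridden per drug block.
    """
    if regimen_name not in REGIMEN_NAMES:
        raise ValueError(
            f"unknown regimen {regimen_name!r}; valid options: "
            + ", ".join(REGIMEN_NAMES)
        )
    if warn_k_cg:
        warnings.warn(
            "k_CG is not part of the published toxicity table; defaulting to "
            "k_CG = k_PGB. Override via the toxicity section of the config "
            "if needed.",
            stacklevel=2,
        )
    blocks = {CHOP_BLOCK: DrugBlock(k_S=0.1951, k_CG=0.5, k_PGB=0.5, k_MGB=0.0)}
    if regimen_name.startswith("CHOEP"):
        blocks[ETOPOSIDE_BLOCK] = DrugBlock(k_S=0.005, k_CG=1.0, k_PGB=1.0,
                                            k_MGB=0.005)
    tox = ToxicityParams(blocks=blocks, f_fc=1.3)
    tox.validate()
    return tox


def default_regimen(regimen_name: str) -> RegimenSpec:
    """Administration calendar of one of the four CHOP-like regimens."""
    if regimen_name not in REGIMEN_NAMES:
        raise ValueError(
            f"unknown regimen {regimen_name!r}; valid options: "
            + ", ".join(REGIMEN_NAMES)
        )
    cycle_length = 21 if regimen_name.endswith("21") else 14
    drug_days: dict[str, tuple[int, ...]] = {CHOP_BLOCK: (1,)}
    if regimen_name.startswith("CHOEP"):
        drug_days[ETOPOSIDE_BLOCK] = (1, 2, 3)
    gcsf_days: tuple[int, ...] = tuple(range(4, 14)) if cycle_length == 14 else ()
    spec = RegimenSpec(
        name=regimen_name,
        cycle_length_d=cycle_length,
        n_cycles=6,
        drug_days=drug_days,
        gcsf_days=gcsf_days,
        prednisone_days=(1, 2, 3, 4, 5),
    )
    spec.validate()
    return spec


# --------------------------------------------------------------------------- #
# Config round-tripping (YAML)
# --------------------------------------------------------------------------- #


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _merge(cls: type, defaults: Any, override: Mapping[str, Any] | None) -> Any:
    """Rebuild a dataclass from its default instance with nested overrides."""
    if override is None:
        return defaults
    kwargs: dict[str, Any] = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key in override:
        if key not in fields:
            raise ValueError(f"unknown config key {cls.__name__}.{key}")
    for name, f in fields.items():
        current = getattr(defaults, name)
        if name in override:
            val = override[name]
            if dataclasses.is_dataclass(current) and isinstance(val, Mapping):
                val = _merge(type(current), current, val)
            elif isinstance(current, tuple) and isinstance(val, (list, tuple)):
                val = tuple(val)
            kwargs[name] = val
        else:
            kwargs[name] = current
    return cls(**kwargs)


def _toxicity_from_dict(d: Mapping[str, Any] | None,
                        defaults: ToxicityParams) -> ToxicityParams:
    if d is None:
        return defaults
    blocks = dict(defaults.blocks)
    for label, spec in (d.get("blocks") or {}).items():
        base = blocks.get(label, DrugBlock(0.0, 0.0, 0.0, 0.0))
        blocks[label] = dataclasses.replace(base, **dict(spec))
    return ToxicityParams(blocks=blocks, f_fc=d.get("f_fc", defaults.f_fc))


def load_config(path: str) -> tuple[OdeParams, ScParams, ToxicityParams, dict]:
    """Read a YAML config and return the effective parameter sets.

    Missing keys fall back to the shipped defaults; every returned set is
    validated.  The fourth element is the ``scenario`` section verbatim (an
    empty dict if absent), carrying e.g. the regimen name used to pick the
    toxicity defaults (key ``regimen``, default CHOP-21).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"config root of {path!r} must be a mapping")
    for key in raw:
        if key not in ("ode", "sc", "toxicity", "scenario"):
            raise ValueError(f"unknown config section {key!r}")
    scenario = dict(raw.get("scenario") or {})
    regimen = scenario.get("regimen", "CHOP-21")
    ode = _merge(OdeParams, OdeParams(), raw.get("ode"))
    sc = _merge(ScParams, ScParams(), raw.get("sc"))
    tox = _toxicity_from_dict(raw.get("toxicity"), default_toxicity(regimen))
    ode.validate()
    sc.validate()
    tox.validate()
    return ode, sc, tox, scenario


def save_config(path: str, ode: OdeParams, sc: ScParams, tox: ToxicityParams,
                scenario: Mapping[str, Any] | None = None) -> None:
    """Write the full effective configuration as YAML (round-trip stable)."""
    doc = {
        "ode": _to_plain(ode),
        "sc": _to_plain(sc),
        "toxicity": _to_plain(tox),
        "scenario": dict(scenario or {}),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def dump_default_config() -> str:
    """YAML text of the complete default configuration."""
    doc = {
        "ode": _to_plain(default_ode_params()),
        "sc": _to_plain(default_sc_params()),
        "toxicity": _to_plain(default_toxicity("CHOP-21")),
        "scenario": {"regimen": "CHOP-21"},
    }
    return yaml.safe_dump(doc, sort_keys=False)
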