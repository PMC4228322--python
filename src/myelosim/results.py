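"""Simulation result container with CSV export."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .params import HOURS_PER_DAY

__all__ = ["SimResult"]


@dataclass
class SimResult:
    """Named trajectories on a uniform time grid.

    ``series`` holds absolute values; ``nor`` the equilibrium reference of
    each series (1.0 where no normalisation applies), so that relative
    trajectories ``C^rel = C / C^nor`` are always recoverable.
    """

    t: np.ndarray                       # hours
    series: dict[str, np.ndarray]
    nor: dict[str, float]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name, arr in self.series.items():
            if len(arr) != n:
                raise ValueError(f"series {name!r} length {len(arr)} != grid "
                                 f"length {n}")

    @property
    def t_days(self) -> np.ndarray:
        return self.t / HOURS_PER_DAY

    def rel(self, name: str) -> np.ndarray:
        """Relative trajectory of one series."""
        return self.series[name] / self.nor.get(name, 1.0)

    def names(self) -> list[str]:
        return list(self.series)

    # -- export --------------------------------------------------------------

    def to_frame(self, tidy: bool = False, relative: bool = True) -> pd.DataFrame:
        if tidy:
            rows = []
            for name in self.series:
                rows.append(pd.DataFrame({
                    "time_h": self.t,
                    "compartment": name,
                    "value": self.series[name],
                    "value_rel": self.rel(name),
                }))
            return pd.concat(rows, ignore_index=True)
        data: dict[str, np.ndarray] = {"time_h": self.t}
        for name in self.series:
            data[name] = self.series[name]
            if relative:
                data[name + "_rel"] = self.rel(name)
        return pd.DataFrame(data)

    def save_csv(self, path: str, tidy: bool = False) -> None:
        """CSV with ``#``-prefixed metadata header lines."""
        meta = dict(self.meta)
        meta.setdefault("parameter_hash", self.parameter_hash())
        with open(path, "w", encoding="utf-8") as fh:
            for key in sorted(meta):
                fh.write(f"# {key}: {meta[key]}\n")
            self.to_frame(tidy=tidy).to_csv(fh, index=False)

    def parameter_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.meta.items() if k != "parameter_hash"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
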