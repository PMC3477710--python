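"""Isotropic tissue conductivities and label-to-sigma volume mapping.

The default table holds representative literature averages (S/m) for a DC
volume-conduction head model: skin 0.465, skull 0.01, CSF 1.65, gray matter
0.276, white matter 0.126, air 1e-7 (small positive so the insulating
boundary emerges physically), electrode 5.8e7 (metal), saline-soaked sponge
1.4, conductive gel 0.3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .phantoms import LabelVolume

DEFAULT_SIGMA_S_PER_M: dict[str, float] = {
    "skin": 0.465,
    "skull": 0.01,
    "csf": 1.65,
    "gray": 0.276,
    "white": 0.126,
    "air": 1e-7,
    "electrode": 5.8e7,
    "sponge": 1.4,
    "gel": 0.3,
}


@dataclass(frozen=True)
class ConductivityTable:
    """Mapping tissue/material label -> isotropic conductivity sigma (S/m)."""

    sigma: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGMA_S_PER_M)
    )

    def __post_init__(self) -> None:
        for name, value in self.sigma.items():
            if not value > 0:
                raise ValueError(
                    f"conductivity for {name!r} must be > 0 S/m (got {value}); "
                    "use a small positive value for insulators"
                )
        object.__setattr__(self, "sigma", dict(self.sigma))

    def lookup(self, label: str) -> float:
        try:
            return self.sigma[label]
        except KeyError:
            raise KeyError(f"no conductivity defined for label {label!r}") from None

    def with_overrides(self, **overrides: float) -> "ConductivityTable":
        """New table with some values replaced; unknown labels are rejected."""
        unknown = sorted(set(overrides) - set(self.sigma))
        if unknown:
            raise KeyError(f"unknown conductivity labels in overrides: {unknown}")
        merged = dict(self.sigma)
        merged.update(overrides)
        return ConductivityTable(merged)

    def to_dict(self) -> dict[str, float]:
        return dict(self.sigma)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ConductivityTable":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping label -> S/m")
        return cls({str(k): float(v) for k, v in data.items()})


def default_table() -> ConductivityTable:
    """The package's default conductivity table (see module docstring)."""
    return ConductivityTable()


def build_sigma_volume(vol: LabelVolume, table: ConductivityTable) -> np.ndarray:
    """Elementwise label -> sigma lookup; float64 grid in S/m, same shape as vol.

    Raises if any label present in ``vol`` has no table entry, listing all
    unmapped labels.
    """
    present_codes = np.unique(vol.labels)
    code_to_name = {v: k for k, v in vol.label_codes.items()}
    unmapped = sorted(
        code_to_name[c] for c in present_codes.tolist() if code_to_name[c] not in table.sigma
    )
    if unmapped:
        raise KeyError(f"labels present in volume but missing from table: {unmapped}")
    lut = np.zeros(int(max(vol.label_codes.values())) + 1, dtype=np.float64)
    for name, code in vol.label_codes.items():
        if name in table.sigma:
            lut[code] = table.sigma[name]
    return lut[vol.labels]
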