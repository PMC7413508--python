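"""Nuclide physical constants.

Values live in ``data/nuclides.yaml`` so sites can add isotopes or adjust
decay data without touching code. Energies are mean emitted energy per decay
split into a non-penetrating (electron: beta + conversion/Auger) and a
penetrating (photon) component, the partition the MIRD formalism uses for
electron-dominated therapy nuclides such as 177Lu.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from importlib import resources

import yaml

MEV_TO_J = 1.602176634e-13
#: decays per MBq.s
DECAYS_PER_MBQ_S = 1.0e6


@dataclass(frozen=True)
class NuclideData:
    name: str
    half_life_h: float
    electron_energy_mev: float  # mean non-penetrating energy per decay
    photon_energy_mev: float    # mean penetrating energy per decay

    @property
    def decay_constant_per_h(self) -> float:
        return math.log(2.0) / self.half_life_h

    @property
    def decay_constant_per_s(self) -> float:
        return self.decay_constant_per_h / 3600.0

    @property
    def total_energy_mev(self) -> float:
        return self.electron_energy_mev + self.photon_energy_mev

    @property
    def electron_energy_j(self) -> float:
        return self.electron_energy_mev * MEV_TO_J

    @property
    def total_energy_j(self) -> float:
        return self.total_energy_mev * MEV_TO_J


@functools.lru_cache(maxsize=None)
def get_nuclide(name: str = "Lu-177") -> NuclideData:
    """Look up a nuclide by name (case-sensitive, e.g. ``"Lu-177"``)."""
    text = resources.files("prrtdose.data").joinpath("nuclides.yaml").read_text()
    table = yaml.safe_load(text)
    if name not in table:
        raise KeyError(f"unknown nuclide {name!r}; known: {sorted(table)}")
    entry = table[name]
    return NuclideData(
        name=name,
        half_life_h=float(entry["half_life_h"]),
        electron_energy_mev=float(entry["electron_energy_mev"]),
        photon_energy_mev=float(entry["photon_energy_mev"]),
    )
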