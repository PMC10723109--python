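"""Light-weight record types for interactions and detected photons."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Interaction:
    """One energy deposition: true (from transport) or observed (blurred)."""

    position: np.ndarray  # (3,) mm
    energy: float         # keV
    kind: str             # "compton" | "photoelectric"
    time: float = 0.0     # ns
    module_id: int = 0
    is_true: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.energy <= 0:
            raise ValueError("interaction energy must be positive")


@dataclass
class PhotonEvent:
    """One detected photon: one or more (merged, blurred) interaction sites."""

    sites: list[Interaction] = field(default_factory=list)
    panel_id: int = 0
    timestamp: float = 0.0  # ns

    def __post_init__(self):
        if not self.sites:
            raise ValueError("a photon event needs at least one site")

    @property
    def total_energy(self) -> float:
        return float(sum(s.energy for s in self.sites))

    @property
    def n_sites(self) -> int:
        return len(self.sites)
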