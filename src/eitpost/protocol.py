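"""Adjacent stimulation/measurement protocol.

Sixteen adjacent electrode pairs drive current in turn; for every drive all
sixteen adjacent pairs are read, giving 16 x 16 = 256 channels per frame.
Channels whose measurement pair shares an electrode with the drive pair are
kept (common practice, they help average noise down) but carry no extra
information; reciprocity pairs the remaining channels two by two, leaving
N(N-3)/2 = 104 independent measurements for N = 16 electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulationProtocol",
    "adjacent_protocol",
    "independent_channel_count",
    "reciprocal_channel",
]


@dataclass(frozen=True)
class StimulationProtocol:
    """Adjacent-pair drive and measurement pattern.

    ``drive_pairs[d] = (d, (d+1) % n)`` injects +I at electrode ``d`` and
    -I at its neighbor; ``measure_pairs`` are the same adjacent pairs.  The
    channel for (drive d, measure m) sits at flat index ``16*d + m``.
    """

    n_electrodes: int = 16
    current_amplitude: float = 1e-3  # A, nominal; cancels in difference imaging
    frequency: float = 100_000.0  # Hz carrier of the injected sine
    drive_pairs: tuple = field(init=False)
    measure_pairs: tuple = field(init=False)

    def __post_init__(self):
        n = self.n_electrodes
        if n < 4:
            raise ValueError("adjacent protocol needs at least 4 electrodes")
        pairs = tuple((k, (k + 1) % n) for k in range(n))
        object.__setattr__(self, "drive_pairs", pairs)
        object.__setattr__(self, "measure_pairs", pairs)

    @property
    def n_channels(self) -> int:
        return self.n_electrodes * self.n_electrodes

    def channel_index(self, drive: int, measure: int) -> int:
        return self.n_electrodes * drive + measure

    def channel_pairs(self) -> np.ndarray:
        """(n_channels, 2) array of (drive, measure) indices, flat order."""
        n = self.n_electrodes
        d, m = np.divmod(np.arange(n * n), n)
        return np.column_stack([d, m])


def adjacent_protocol(n_electrodes: int = 16, current_amplitude: float = 1e-3) -> StimulationProtocol:
    """The standard 16-electrode adjacent protocol (256 channels)."""
    return StimulationProtocol(n_electrodes=n_electrodes, current_amplitude=current_amplitude)


def reciprocal_channel(protocol: StimulationProtocol, drive: int, measure: int) -> int:
    """Flat index of the reciprocity partner (roles of pairs exchanged)."""
    return protocol.channel_index(measure, drive)


def independent_channel_count(protocol: StimulationProtocol) -> int:
    """Number of independent channels under reciprocity.

    Channels whose measurement pair touches a drive electrode are excluded
    (their value is fixed by the drive, not by interior conductivity
    information beyond what other channels carry); the rest pair up by
    reciprocity.  For adjacent pairs on N electrodes this counts
    N(N-3)/2.
    """
    n = protocol.n_electrodes
    seen = set()
    for d, (da, db) in enumerate(protocol.drive_pairs):
        for m, (ma, mb) in enumerate(protocol.measure_pairs):
            if {ma, mb} & {da, db}:
                continue
            key = frozenset([(da, db), (ma, mb)])
            seen.add(key)
    return len(seen)
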