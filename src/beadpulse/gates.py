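"""Rule-based gating of bead records into metallization subpopulations.

Negative dZp at any of the three middle carriers (150 kHz, 380 kHz, 2 MHz)
marks a bead as metallized, since nonmetallized beads never dip negative.
Within that set, a large positive-to-negative drop between 45 and 150 kHz
marks the densely metallized M_hi subset; the rest are M_med.  Beads whose
spectra stay positive match nonmetallized beads and are labelled M_lo.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .circuits import coulter_delta_r, default_aperture
from .errors import ConfigError
from .pulses import BeadRecord

__all__ = ["DEFAULT_DROP_THRESHOLD", "GateConfig", "gate_beads", "mean_spectrum"]

#: Default "large decrease" scale: half the resistive-pulse amplitude of the
#: working 8.2 um bead in the default aperture (~169 ohm).
DEFAULT_DROP_THRESHOLD = coulter_delta_r(8.2e-6, default_aperture()) / 2.0


@dataclass(frozen=True)
class GateConfig:
    """Spectral gate criteria.

    ``neg_indices`` are the channel indices checked for strict negativity
    (defaults to the three middle carriers); ``drop_threshold`` (ohm) is the
    minimum dZp(45 kHz) - dZp(150 kHz) decrease qualifying as "large".
    """

    neg_indices: tuple[int, ...] = (1, 2, 3)
    drop_threshold: float = DEFAULT_DROP_THRESHOLD

    def __post_init__(self) -> None:
        if not self.neg_indices or any(
            not 0 <= i < 6 for i in self.neg_indices
        ):
            raise ConfigError("neg_indices must be channel indices 0-5")
        if self.drop_threshold <= 0:
            raise ConfigError("drop_threshold must be positive")


def gate_beads(
    records: list[BeadRecord], cfg: GateConfig | None = None
) -> list[BeadRecord]:
    """Label every record M_hi, M_med or M_lo (a partition).

    M_hi: negative dZp at one of the middle carriers *and* a 45->150 kHz
    decrease of at least ``drop_threshold``.  M_med: negativity only.
    M_lo: everything else (spectra matching nonmetallized beads).
    """
    cfg = cfg or GateConfig()
    out = []
    for rec in records:
        negative = bool(np.min(rec.dzp[list(cfg.neg_indices)]) < 0)
        sharp_drop = rec.dzp[0] - rec.dzp[1] >= cfg.drop_threshold
        if negative and sharp_drop:
            gate = "M_hi"
        elif negative:
            gate = "M_med"
        else:
            gate = "M_lo"
        out.append(replace(rec, gate=gate))
    return out


def mean_spectrum(
    records: list[BeadRecord],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-frequency arithmetic mean of dZp and dPhip over the records."""
    if not records:
        raise ConfigError("mean_spectrum requires at least one record")
    dzp = np.mean([r.dzp for r in records], axis=0)
    dphip = np.mean([r.dphip for r in records], axis=0)
    return dzp, dphip, len(records)
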