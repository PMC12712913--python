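"""Stimulation protocol parameters and validation.

The pulsing scheme is the standard low-intensity focused-ultrasound hierarchy:
a carrier at the fundamental frequency (FF, MHz) is gated into tone bursts of
duration TBD (ms) repeated at the pulse repetition frequency (PRF, kHz), giving
the duty cycle DC = TBD x PRF; bursts are delivered for a sonication duration
SD (s) per stimulus, stimuli separated by an inter-stimulus interval ISI (s).
Intensity levels are empirical (Ispta mW/cm², PNP MPa) calibration pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["StimProtocol", "ProtocolValidationError", "standard_protocol", "load_protocol"]

_DC_TOL = 1e-9


class ProtocolValidationError(ValueError):
    pass


@dataclass
class StimProtocol:
    """Ultrasound stimulation schedule and intensity calibration.

    Attributes
    ----------
    ff : float
        Fundamental (center) frequency, MHz.
    prf : float
        Pulse repetition frequency, kHz.
    dc : float
        Duty cycle as a fraction in (0, 1]; must equal ``tbd * prf``.
    tbd : float
        Tone burst duration, ms.
    sd : float
        Sonication duration per stimulus, s.
    isi : float
        Inter-stimulus interval (off time between stimuli), s.
    levels : list of (float, float)
        Empirical calibration pairs (Ispta mW/cm², PNP MPa).
    phase_len : float
        Duration of each experiment phase (pre / stim / post), s.
    """

    ff: float = 1.0
    prf: float = 1.0
    dc: float = 0.5
    tbd: float = 0.5
    sd: float = 0.3
    isi: float = 3.0
    levels: list[tuple[float, float]] = field(
        default_factory=lambda: [(100.0, 0.15), (250.0, 0.25), (400.0, 0.35)]
    )
    phase_len: float = 150.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> "StimProtocol":
        """Check internal consistency; returns self for chaining."""
        if not 0 < self.dc <= 1:
            raise ProtocolValidationError(f"dc must be in (0, 1], got {self.dc}")
        if abs(self.tbd * self.prf - self.dc) > _DC_TOL:
            raise ProtocolValidationError(
                f"dc={self.dc} inconsistent with tbd*prf={self.tbd * self.prf} "
                f"(tbd={self.tbd} ms, prf={self.prf} kHz)"
            )
        for name in ("ff", "prf", "tbd", "sd", "isi", "phase_len"):
            if getattr(self, name) <= 0:
                raise ProtocolValidationError(f"{name} must be positive")
        if not self.levels:
            raise ProtocolValidationError("levels must be non-empty")
        for ispta, pnp in self.levels:
            if ispta <= 0 or pnp <= 0:
                raise ProtocolValidationError(
                    f"calibration entries must be positive, got ({ispta}, {pnp})"
                )
        return self

    @property
    def cycle(self) -> float:
        """Stimulus cycle length SD + ISI, s."""
        return self.sd + self.isi

    def onsets_in_phase(self, phase_start: float = 0.0) -> list[float]:
        """Stimulus onset times within one phase starting at ``phase_start``.

        A stimulus is scheduled only when its full SD + ISI cycle fits in the
        phase, giving ``floor(phase_len / (sd + isi))`` onsets.
        """
        out, t = [], phase_start
        while t + self.cycle <= phase_start + self.phase_len + 1e-9:
            out.append(t)
            t += self.cycle
        return out

    def to_dict(self) -> dict:
        return {
            "ff_mhz": self.ff,
            "prf_khz": self.prf,
            "dc": self.dc,
            "tbd_ms": self.tbd,
            "sd_s": self.sd,
            "isi_s": self.isi,
            "phase_len_s": self.phase_len,
            "levels": [list(pair) for pair in self.levels],
        }


def standard_protocol() -> StimProtocol:
    """The study's stimulation settings: 1.0 MHz carrier, 1.0 kHz PRF, 50% duty
    cycle (0.5 ms tone bursts), 0.3 s sonication every 3.3 s, 150 s phases,
    levels 100/250/400 mW/cm² calibrated at 0.15/0.25/0.35 MPa."""
    return StimProtocol()


def load_protocol(path: str | Path) -> StimProtocol:
    """Load a protocol from a YAML/JSON mapping (keys as in ``to_dict``)."""
    data = yaml.safe_load(Path(path).read_text())
    return StimProtocol(
        ff=data.get("ff_mhz", 1.0),
        prf=data.get("prf_khz", 1.0),
        dc=data.get("dc", 0.5),
        tbd=data.get("tbd_ms", 0.5),
        sd=data.get("sd_s", 0.3),
        isi=data.get("isi_s", 3.0),
        levels=[tuple(pair) for pair in data.get("levels", [[400.0, 0.35]])],
        phase_len=data.get("phase_len_s", 150.0),
    )
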