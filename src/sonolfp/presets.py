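"""Packaged generator presets for the four expression groups.

Each preset bundles a group's spontaneous band composition, overall signal
scale, stimulation power gains per intensity, and evoked-deflection
parameters into a :class:`~sonolfp.synth.SynthSpec`. See
``presets/presets.yaml`` for provenance notes on each value.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .synth import EvokedSpec, SynthSpec

__all__ = ["available_presets", "load_preset"]

_cache: dict | None = None


def _table() -> dict:
    global _cache
    if _cache is None:
        text = (
            resources.files("sonolfp").joinpath("presets/presets.yaml").read_text()
        )
        _cache = yaml.safe_load(text)
    return _cache


def available_presets() -> list[str]:
    """Names of the packaged group presets."""
    return list(_table())


def load_preset(
    group: str,
    intensity: float | None = None,
    seed: int | None = None,
    fs: float = 1000.0,
    phase_len: float = 150.0,
) -> SynthSpec:
    """Build a :class:`SynthSpec` for a group at an optional intensity level.

    Parameters
    ----------
    group : str
        One of ``CON``, ``MscL-G22S``, ``MscL-G22N``, ``MscS``.
    intensity : float, optional
        Stimulation level in mW/cm² (100, 250 or 400). When given, the
        intensity-specific stimulation power gain and evoked parameters are
        attached; otherwise the spec describes spontaneous activity only.
    seed : int, optional
        RNG seed recorded on the spec.
    """
    table = _table()
    if group not in table:
        raise KeyError(f"unknown preset {group!r}; available: {sorted(table)}")
    entry = table[group]
    gain = 0.0
    evoked = None
    if intensity is not None:
        key = int(intensity)
        gains = {int(k): v for k, v in entry["stim_power_gain"].items()}
        if key not in gains:
            raise KeyError(f"no gain entry for {group} at {intensity} mW/cm²")
        gain = float(gains[key])
        ev_entry = {int(k): v for k, v in entry["evoked"]["by_intensity"].items()}[key]
        if ev_entry is not None:
            evoked = EvokedSpec(
                n1_amp=float(ev_entry["n1_amp_uv"]),
                n1_latency_ms=float(ev_entry["n1_latency_ms"]),
                width_ms=float(ev_entry["width_ms"]),
                jitter_amp=float(ev_entry["jitter_amp"]),
                jitter_lat_ms=float(ev_entry["jitter_lat_ms"]),
                background_rms=float(entry["evoked"]["background_rms_uv"]),
            )
    return SynthSpec(
        band_fractions={k: float(v) for k, v in entry["band_fractions"].items()},
        total_rms=float(entry["total_rms_uv"]),
        evoked=evoked,
        stim_power_gain=gain,
        line_noise_amp=float(entry.get("line_noise_uv", 0.0)),
        fs=fs,
        phase_len=phase_len,
        seed=seed,
    )
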