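"""Genotype presets for the synthetic session generator.

The two presets encode the qualitative contrasts between wildtype-like
("control") and DISC1-overexpressing-like ("tgDISC1like") CA1 populations:
smaller place fields, weaker speed modulation, stronger novelty theta
locking with more dispersed preferred phases, and a weaker pyramidal rate
increase inside sharp-wave ripples for the transgenic-like preset.  The
numeric values are generator choices that realise those directions, not
measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenotypePreset:
    label: str
    #: place-field Gaussian width (cm)
    field_sigma_cm: float
    #: linear speed gain beta, per (cm/s); rate factor (1 + beta*(v - v_mean))+
    speed_gain_beta: float
    #: von Mises concentration of spike-phase coupling to theta
    theta_kappa_familiar: float
    theta_kappa_novel: float
    #: circular spread (wrapped-normal SD, deg) of population preferred phases
    preferred_phase_spread_deg: float
    #: pyramidal rate gain inside sharp-wave ripples (dimensionless)
    swr_rate_gain: float
    #: typical in-field peak rate (Hz); per-cell peaks are lognormal around it
    mean_rate_hz: float
    #: von Mises concentration of pyramidal locking to REM-sleep theta
    rem_theta_kappa: float = 1.0
    #: planted novelty shift of the population preferred theta phase (deg)
    novelty_phase_shift_deg: float = 0.0
    #: log-SD of the shared per-assembly gain (cofiring / dispersion structure)
    assembly_gain_sigma: float = 0.4

    def __post_init__(self) -> None:
        if self.field_sigma_cm <= 0 or self.mean_rate_hz < 0:
            raise ValueError("field width and rates must be positive")
        if min(self.theta_kappa_familiar, self.theta_kappa_novel, self.rem_theta_kappa) < 0:
            raise ValueError("von Mises concentration must be >= 0")
        if not 0 <= self.preferred_phase_spread_deg < 360:
            raise ValueError("phase spread must lie in [0, 360)")
        if self.swr_rate_gain < 0:
            raise ValueError("SWR rate gain must be >= 0")


CONTROL = GenotypePreset(
    label="control",
    field_sigma_cm=10.0,
    speed_gain_beta=0.020,
    theta_kappa_familiar=0.8,
    theta_kappa_novel=0.8,
    preferred_phase_spread_deg=40.0,
    swr_rate_gain=3.0,
    mean_rate_hz=15.0,
    rem_theta_kappa=1.2,
    novelty_phase_shift_deg=40.0,
    assembly_gain_sigma=1.0,
)

TGDISC1_LIKE = GenotypePreset(
    label="tgDISC1like",
    field_sigma_cm=7.0,
    speed_gain_beta=0.008,
    theta_kappa_familiar=0.8,
    theta_kappa_novel=1.6,
    preferred_phase_spread_deg=100.0,
    swr_rate_gain=1.5,
    mean_rate_hz=15.0,
    rem_theta_kappa=0.6,
    novelty_phase_shift_deg=0.0,
    assembly_gain_sigma=0.4,
)

PRESETS = {p.label: p for p in (CONTROL, TGDISC1_LIKE)}
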