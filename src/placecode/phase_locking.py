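"""Spike-phase circular statistics and population comparisons.

Per neuron, the phases at which spikes occur are averaged as unit phasors
into a mean vector: its length is the phase-locking strength, its angle
the preferred firing phase, with significance from the Rayleigh test.
Population measures follow: the mean of all mean-vector lengths, the
concentration r (and angular variance S^2 = 1 - r) of significantly
locked units' preferred phases with chi-square confidence bounds, a
variance-ratio test comparing two angular variances, and the
Watson-Williams test for equal circular means.

Angles are degrees externally, radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pingouin import circ_rayleigh
from scipy.special import i0, i1
from scipy.stats import chi2
from scipy.stats import f as f_dist

from .lfp_events import times_in_intervals
from .synth.util import PhaseInterp

RAYLEIGH_ALPHA = 0.05


# ---------------------------------------------------------------------------
# circular primitives
# ---------------------------------------------------------------------------

def resultant_vector(angles_deg: np.ndarray) -> tuple[float, float]:
    """(length, mean angle deg) of the unit-phasor mean of ``angles_deg``."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    vec = np.exp(1j * a).mean()
    return float(np.abs(vec)), float(np.degrees(np.angle(vec)) % 360.0)


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    return resultant_vector(angles_deg)[1]


def vm_expected_length(kappa: float) -> float:
    """Population mean-vector length A(kappa) = I1(kappa)/I0(kappa)."""
    return float(i1(kappa) / i0(kappa))


def rayleigh_test(angles_deg: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: (z statistic, p value)."""
    z, p = circ_rayleigh(np.radians(np.asarray(angles_deg, dtype=float)))
    return float(z), float(p)


def vm_kappa_of_length(rbar: float) -> float:
    """Approximate inverse of A(kappa) (Fisher's piecewise formula)."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


# ---------------------------------------------------------------------------
# per-unit mean vectors
# ---------------------------------------------------------------------------

@dataclass
class MeanVector:
    unit_id: int
    band: str
    angle_deg: float
    length: float
    n_spikes: int
    rayleigh_p: float

    @property
    def significant(self) -> bool:
        return self.rayleigh_p < RAYLEIGH_ALPHA


def spike_phase_mean_vector(
    spike_times: np.ndarray,
    phase: PhaseInterp,
    epochs: np.ndarray,
    *,
    unit_id: int = 0,
    band: str = "theta",
    min_spikes: int = 20,
) -> MeanVector | None:
    """Mean vector of a unit's spike phases within the given epochs.

    Returns None (unit excluded) when fewer than ``min_spikes`` spikes fall
    inside the epochs.
    """
    st = np.asarray(spike_times, dtype=float)
    st = st[times_in_intervals(st, epochs)]
    if st.size < min_spikes:
        return None
    phases = phase.deg_at(st)
    length, angle = resultant_vector(phases)
    _, p = circ_rayleigh(np.radians(phases))
    return MeanVector(
        unit_id=unit_id, band=band, angle_deg=angle, length=length,
        n_spikes=int(st.size), rayleigh_p=float(p),
    )


def population_mean_vectors(
    units,
    phase: PhaseInterp,
    epochs: np.ndarray,
    *,
    band: str = "theta",
    min_spikes: int = 20,
) -> list[MeanVector]:
    out = []
    for u in units:
        mv = spike_phase_mean_vector(
            u.spike_times, phase, epochs, unit_id=u.unit_id, band=band, min_spikes=min_spikes
        )
        if mv is not None:
            out.append(mv)
    return out


def population_locking_strength(mean_vectors, significant_only: bool = False) -> float:
    """Mean of the units' mean-vector lengths (all units by default)."""
    mvs = [m for m in mean_vectors if (m.significant if significant_only else True)]
    if not mvs:
        raise ValueError("no units to average")
    return float(np.mean([m.length for m in mvs]))


# ---------------------------------------------------------------------------
# population concentration of preferred phases
# ---------------------------------------------------------------------------

@dataclass
class PhaseConcentration:
    r: float
    s2: float  # angular variance 1 - r
    n: int
    #: chi-square interval transformed back through r = 1 - S^2; these
    #: bracket the concentration r (the error bars drawn on r)
    ci_lower: float
    ci_upper: float


def preferred_phase_concentration(
    mean_vectors, *, min_units: int = 5, alpha: float = 0.05
) -> PhaseConcentration:
    """Concentration of significantly locked units' preferred phases.

    r = sqrt(X^2 + Y^2) with X, Y the mean rectangular coordinates of the
    angles; S^2 = 1 - r, with chi-square confidence bounds
    Upper = 1 - (n-1) S^2 / chi2_{1-alpha/2, n-1} and
    Lower = 1 - (n-1) S^2 / chi2_{alpha/2, n-1}.
    """
    angles = np.array([m.angle_deg for m in mean_vectors if m.significant])
    n = len(angles)
    if n < min_units:
        raise ValueError("need at least 5 significantly locked units")
    a = np.radians(angles)
    x, y = np.cos(a).mean(), np.sin(a).mean()
    r = float(np.hypot(x, y))
    s2 = 1.0 - r
    upper = 1.0 - (n - 1) * s2 / chi2.ppf(1 - alpha / 2, n - 1)
    lower = 1.0 - (n - 1) * s2 / chi2.ppf(alpha / 2, n - 1)
    return PhaseConcentration(r=r, s2=s2, n=n, ci_lower=float(lower), ci_upper=float(upper))


def variance_ratio_test(s2_a: float, n_a: int, s2_b: float, n_b: int) -> dict:
    """F-ratio comparison of two angular variances (two-sided).

    The larger variance goes in the numerator; reference distribution
    F(n-1, n-1).  A zero variance in the denominator floors the p-value at
    machine precision with a flag.
    """
    if s2_a <= 0 and s2_b <= 0:
        raise ValueError("at least one angular variance must be positive")
    if s2_a >= s2_b:
        num, dfn, den, dfd = s2_a, n_a - 1, s2_b, n_b - 1
    else:
        num, dfn, den, dfd = s2_b, n_b - 1, s2_a, n_a - 1
    if den == 0:
        return {"F": np.inf, "p": np.finfo(float).tiny, "df": (dfn, dfd),
                "degenerate": True}
    F = num / den
    p = min(1.0, 2.0 * float(f_dist.sf(F, dfn, dfd)))
    return {"F": float(F), "p": p, "df": (dfn, dfd), "degenerate": False}


def watson_williams_test(angles_a_deg: np.ndarray, angles_b_deg: np.ndarray) -> dict:
    """Watson-Williams F test for equality of two circular means.

    Uses the standard concentration-based correction factor
    K = 1 + 3/(8 kappa_hat); a warning flag is set when the pooled mean
    resultant length is below 0.45, where the test's assumptions weaken.
    """
    a = np.radians(np.asarray(angles_a_deg, dtype=float))
    b = np.radians(np.asarray(angles_b_deg, dtype=float))
    n1, n2 = len(a), len(b)
    if min(n1, n2) < 10:
        raise ValueError("need at least 10 angles per group")
    nn = n1 + n2
    r1 = np.abs(np.exp(1j * a).sum())
    r2 = np.abs(np.exp(1j * b).sum())
    r_all = np.abs(np.exp(1j * np.r_[a, b]).sum())
    rbar = (r1 + r2) / nn
    kappa = vm_kappa_of_length(rbar)
    K = 1 + 3 / (8 * kappa) if kappa > 0 else np.inf
    denom = nn - (r1 + r2)
    if denom <= 0:
        return {"F": np.inf, "p": 0.0, "rbar": float(rbar), "low_concentration": False}
    F = K * (nn - 2) * (r1 + r2 - r_all) / denom
    F = max(F, 0.0)
    p = float(f_dist.sf(F, 1, nn - 2))
    return {
        "F": float(F),
        "p": p,
        "rbar": float(rbar),
        "low_concentration": bool(rbar < 0.45),
    }


def novelty_phase_shift(mean_vectors_familiar, mean_vectors_novel) -> dict:
    """Population preferred-phase shift between two epochs, with W-W test.

    Uses the significantly locked units of each epoch; the shift is the
    circular difference of the two population circular means.
    """
    ang_f = np.array([m.angle_deg for m in mean_vectors_familiar if m.significant])
    ang_n = np.array([m.angle_deg for m in mean_vectors_novel if m.significant])
    mu_f = circular_mean_deg(ang_f)
    mu_n = circular_mean_deg(ang_n)
    shift = (mu_n - mu_f + 180.0) % 360.0 - 180.0
    ww = watson_williams_test(ang_f, ang_n)
    return {
        "mean_familiar_deg": mu_f,
        "mean_novel_deg": mu_n,
        "shift_deg": float(shift),
        **{f"ww_{k}": v for k, v in ww.items()},
    }
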