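"""Odor inputs and glomerular-layer normalization.

Each glomerulus responds to an odorant concentration through a Hill
dose-response curve; the resulting activation vector S is normalized by an
abstract glomerular-layer circuit (periglomerular/external-tufted effects
are implicit) that suppresses glomeruli whose activation falls below a
multiple of the bulb-wide mean — a winners-take-all operation yielding a
sparse, concentration-invariant pattern.  The surviving drive is delivered
identically to the MC and mTC tufts of each glomerulus.

Temporal structure: a raised-cosine sniff modulation (default 3 Hz, shallow
depth so the activation is almost constant over the cycle) or a pulse mode
delivering brief drive packets at fixed intervals (used by the two-cell
synchronization protocols, 350 ms spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class OdorSpec:
    """Per-glomerulus Hill dose-response parameters.

    affinity: half-activation concentrations K_i (> 0, arbitrary units);
    hill_n: Hill exponents n_i (> 0); max_drive: saturating activation
    (spikes/s-equivalent units).
    """

    affinity: np.ndarray
    hill_n: np.ndarray
    max_drive: float = 1.0

    def __post_init__(self):
        self.affinity = np.atleast_1d(np.asarray(self.affinity, dtype=float))
        self.hill_n = np.broadcast_to(
            np.asarray(self.hill_n, dtype=float), self.affinity.shape
        ).copy()
        if np.any(self.affinity <= 0) or np.any(self.hill_n <= 0):
            raise ValueError("affinities and Hill exponents must be > 0")

    @property
    def n_glomeruli(self) -> int:
        return self.affinity.shape[0]

    @classmethod
    def random(
        cls,
        n_glomeruli: int,
        seed: int,
        k_range: tuple[float, float] = (0.03, 30.0),
        hill_n: float = 1.5,
        max_drive: float = 1.0,
    ) -> "OdorSpec":
        """Affinities drawn log-uniformly per glomerulus; n = 1.5 default."""
        rng = np.random.default_rng(seed)
        k = np.exp(rng.uniform(np.log(k_range[0]), np.log(k_range[1]), n_glomeruli))
        return cls(k, np.full(n_glomeruli, hill_n), max_drive)


def hill_activation(odor: OdorSpec, concentration: float, glom_id=None):
    """S = max_drive * c^n / (c^n + K^n); vector if glom_id is None."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    k = odor.affinity if glom_id is None else odor.affinity[glom_id]
    n = odor.hill_n if glom_id is None else odor.hill_n[glom_id]
    if concentration == 0:
        return np.zeros_like(k) if glom_id is None else 0.0
    cn = concentration**n
    s = odor.max_drive * cn / (cn + k**n)
    return s if glom_id is None else float(s)


def sniff_modulate(
    S,
    t,
    sniff_rate: float = 3.0,
    modulation_depth: float = 0.3,
    mode: str = "sniff",
    pulse_interval_ms: float = 350.0,
    pulse_width_ms: float = 60.0,
):
    """Temporal modulation of a (scalar or vector) activation level.

    'sniff' mode multiplies S by a raised cosine
    ``1 - depth*(1+cos(2*pi*f*t))/2`` (period 1/sniff_rate; depth 0 gives a
    constant drive; at the default depth the waveform's coefficient of
    variation stays below 0.15).  'pulse' mode emits raised-cosine packets
    of ``pulse_width_ms`` whose onsets are spaced exactly
    ``pulse_interval_ms`` apart.  ``t`` is in ms (scalar or array).
    """
    if sniff_rate <= 0:
        raise ValueError("sniff_rate must be > 0")
    t = np.asarray(t, dtype=float)
    S = np.asarray(S, dtype=float)
    if mode == "pulse":
        phase = np.mod(t, pulse_interval_ms)
        w = np.where(
            phase < pulse_width_ms,
            0.5 * (1 - np.cos(2 * np.pi * phase / pulse_width_ms)),
            0.0,
        )
    elif mode == "sniff":
        f = sniff_rate / 1000.0  # cycles per ms
        w = 1.0 - modulation_depth * 0.5 * (1.0 + np.cos(2 * np.pi * f * t))
    else:
        raise ValueError(f"unknown modulation mode {mode!r}")
    if S.ndim == 0 or w.ndim == 0:
        return S * w
    return np.multiply.outer(S, w)


def glomerular_inhibition(
    S_vector,
    theta: float = 0.75,
    gate_width: float = 0.1,
    mean_ref: float | None = None,
) -> np.ndarray:
    """Winners-take-all suppression of weakly activated glomeruli.

    The residual r_i = max(0, S_i - theta*mean(S)) is passed through a
    contrast-enhancing sigmoid gate r^2/(r^2 + h^2) with half-point
    h = gate_width*theta*mean(S); the output is S_i scaled by the gate, so
    surviving glomeruli keep their relative strengths while sub-mean
    glomeruli are turned off.  Because the gate depends only on ratios to
    the mean, uniformly scaling all S_i preserves the set of survivors
    (relational, concentration-invariant representation).  The same drive
    vector feeds both the MC and mTC tufts of each glomerulus.
    """
    S = np.asarray(S_vector, dtype=float)
    if np.any(S < 0):
        raise ValueError("activations must be >= 0")
    m = float(np.mean(S)) if mean_ref is None else float(mean_ref)
    if m <= 0:
        return np.zeros_like(S)
    r = S - theta * m
    h = gate_width * theta * m
    gate = np.where(r > 0, r**2 / (r**2 + h**2), 0.0)
    return S * gate


def delta_S(S_i: float, S_j: float) -> float:
    """Relative glomerular activation difference (S_i - S_j) / S_j."""
    if S_j == 0:
        raise ValueError("reference activation S_j must be nonzero")
    return (S_i - S_j) / S_j


@dataclass
class GlomerularDrive:
    """Post-normalization drive amplitudes with sniff-cycle dynamics.

    ``amplitudes`` holds the per-glomerulus activation S delivered to the
    apical tufts; ``waveform`` renders the (n_glom, n_steps) array consumed
    by the simulation engine.  Per-glomerulus amplitude and phase jitter
    emulate the physiological variability of the inputs to different
    glomerular units.
    """

    amplitudes: np.ndarray
    sniff_rate: float = 3.0
    modulation_depth: float = 0.3
    mode: str = "sniff"
    pulse_interval_ms: float = 350.0
    pulse_width_ms: float = 60.0
    amp_jitter: float = 0.0
    phase_jitter_ms: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if np.any(self.amplitudes < 0):
            raise ValueError("drive amplitudes must be >= 0")

    @property
    def n_glomeruli(self) -> int:
        return self.amplitudes.shape[0]

    def waveform(self, n_steps: int, dt: float, t0: float = 0.0) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        n = self.n_glomeruli
        amps = self.amplitudes * (
            1.0 + self.amp_jitter * rng.uniform(-1, 1, n)
        )
        phases = self.phase_jitter_ms * rng.uniform(-1, 1, n)
        t = t0 + dt * (np.arange(n_steps) + 1)
        out = np.empty((n, n_steps))
        for i in range(n):
            out[i] = sniff_modulate(
                amps[i],
                t + phases[i],
                self.sniff_rate,
                self.modulation_depth,
                self.mode,
                self.pulse_interval_ms,
                self.pulse_width_ms,
            )
        return out
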