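"""External rhythmic drive: septal theta and entorhinal spike trains.

The medial septum paces hippocampal interneurons at theta rhythm
(4-12 Hz); entorhinal afferents (EC2 to DG/CA3, EC3 to CA1) fire as
inhomogeneous Poisson processes whose rate envelopes are theta
modulated, with faster gamma oscillations nested in the depolarizing
half of each theta cycle.  EC2 and EC3 envelopes are in antiphase:
strong excitation from one layer coincides with weak excitation from
the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

THETA_BAND = (4.0, 12.0)


@dataclass(frozen=True)
class DriveConfig:
    theta_freq: float = 8.0        # Hz, within 4-12
    gamma_freq: float = 40.0       # Hz, nested oscillation
    gamma_depth: float = 0.5       # modulation depth within theta peak
    ec2_phase: float = 0.0         # radians
    ec3_phase: float = math.pi     # radians; antiphase with EC2
    ec_rate_max: float = 120.0     # Hz, per-fibre peak rate
    septal_rate_max: float = 80.0  # Hz, per septal cell peak rate
    septal_phase: float = math.pi  # inhibition of interneurons peaks here
    theta_sharpness: float = 1.0   # exponent sharpening the theta envelope
    seed: int = 0

    def __post_init__(self):
        lo, hi = THETA_BAND
        if not (lo <= self.theta_freq <= hi):
            raise ValueError(
                f"theta_freq must lie in the {lo:g}-{hi:g} Hz band")
        if self.gamma_freq <= self.theta_freq:
            raise ValueError("gamma_freq must exceed theta_freq")
        if not (0.0 <= self.gamma_depth < 1.0):
            raise ValueError("gamma_depth must lie in [0, 1)")
        if self.ec_rate_max < 0 or self.septal_rate_max < 0:
            raise ValueError("rates must be >= 0")


def septal_theta(t, cfg: DriveConfig | None = None):
    """Septal inhibition level in [0, 1] at time(s) t (seconds).

    Periodic with period 1/theta_freq; interneurons are inhibited at
    its peak, which disinhibits principal cells at the theta trough.
    """
    cfg = cfg or DriveConfig()
    t = np.asarray(t, dtype=float)
    level = 0.5 * (1.0 + np.cos(2 * math.pi * cfg.theta_freq * t
                                - cfg.septal_phase))
    return level if level.ndim else float(level)


def _theta_envelope(t, phase, cfg: DriveConfig):
    env = 0.5 * (1.0 + np.cos(2 * math.pi * cfg.theta_freq * t - phase))
    return env ** cfg.theta_sharpness


def rate_envelope(t, layer: str, cfg: DriveConfig | None = None):
    """Instantaneous afferent firing rate (Hz) of one fibre of a layer.

    Theta envelope (sharpened, phase per layer) with nested gamma
    amplitude modulation; SEPTUM uses the septal phase and peak rate.
    """
    cfg = cfg or DriveConfig()
    t = np.asarray(t, dtype=float)
    if layer == "EC2":
        phase, rmax = cfg.ec2_phase, cfg.ec_rate_max
    elif layer == "EC3":
        phase, rmax = cfg.ec3_phase, cfg.ec_rate_max
    elif layer == "SEPTUM":
        phase, rmax = cfg.septal_phase, cfg.septal_rate_max
    else:
        raise ValueError(f"unknown afferent layer {layer!r}")
    env = _theta_envelope(t, phase, cfg)
    gamma = 1.0 + cfg.gamma_depth * np.cos(2 * math.pi * cfg.gamma_freq * t)
    return rmax * env * gamma / (1.0 + cfg.gamma_depth)


def ec_spike_trains(duration: float, layer: str, cfg: DriveConfig,
                    n_fibres: int = 10, seed: int | None = None,
                    rate_scale: float = 1.0, dt: float = 1e-4):
    """Spike-time lists for ``n_fibres`` afferents of a layer.

    Inhomogeneous Poisson trains generated by per-bin thinning of the
    theta-gamma rate envelope; reproducible under seed.  ``rate_scale``
    multiplies the envelope (per-hippocampus synaptic-function factor).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    spikes = binned_spike_matrix(duration, layer, cfg, n_fibres,
                                 seed if seed is not None else cfg.seed,
                                 rate_scale, dt)
    return [np.flatnonzero(spikes[i]) * dt for i in range(n_fibres)]


def binned_spike_matrix(duration: float, layer: str, cfg: DriveConfig,
                        n_fibres: int, seed: int, rate_scale: float = 1.0,
                        dt: float = 1e-4) -> np.ndarray:
    """Boolean (n_fibres, n_steps) spike raster on the engine time grid."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps) * dt
    p = np.clip(rate_scale * rate_envelope(t, layer, cfg) * dt, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    return rng.random((n_fibres, n_steps)) < p[None, :]


def expected_spike_count(duration: float, layer: str, cfg: DriveConfig,
                         rate_scale: float = 1.0, dt: float = 1e-4) -> float:
    """Analytic mean spike count per fibre: the integral of the envelope."""
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps) * dt
    return float(np.sum(rate_scale * rate_envelope(t, layer, cfg)) * dt)
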