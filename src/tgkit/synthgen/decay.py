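"""First-order mRNA decay series with multiplicative log-normal noise.

Observations are (time since transcription block, fraction remaining
relative to an unblocked reference); the noise-free model is
``fraction = 2^(-t / t_half)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..decay_kinetics import DecayObservation, fraction_remaining


@dataclass
class DecaySeriesSpec:
    times: tuple[float, ...] = (15.0, 30.0, 45.0, 60.0)
    t_half: float = 45.0
    log_noise_sd: float = 0.1
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValueError("t_half must be > 0")
        if any(t < 0 for t in self.times):
            raise ValueError("times must be >= 0")
        if self.log_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    @classmethod
    def culture_decay(cls, **kw) -> "DecaySeriesSpec":
        """Defaults mirror the cultured-neuron Arc decay time course (45-min
        half-life, samples every 15 min out to 1 h)."""
        return cls(**kw)

    @classmethod
    def in_vivo_decay(cls, **kw) -> "DecaySeriesSpec":
        """30/60-min transcription-block design with a 30-min half-life."""
        kw.setdefault("times", (30.0, 60.0))
        kw.setdefault("t_half", 30.0)
        return cls(**kw)


def simulate_decay_series(spec: DecaySeriesSpec | None = None) -> list[DecayObservation]:
    spec = spec or DecaySeriesSpec()
    rng = np.random.default_rng(spec.seed)
    obs = []
    for t in spec.times:
        for _ in range(spec.replicates):
            f = fraction_remaining(t, spec.t_half) * np.exp(rng.normal(0.0, spec.log_noise_sd))
            obs.append(DecayObservation(time=float(t), fraction=float(max(f, 1e-12))))
    return obs
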