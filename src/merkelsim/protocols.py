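"""Stimulus protocols: time-dependent external drive for the simulator.

A protocol supplies, for any time t (s):

* the injected current I_app(t) (A),
* the external solution (deltas applied to the configured baseline),
* the indentation depth d(t) (m) and the Piezo2 phase flag,

plus the list of breakpoints at which the drive is discontinuous, used as
solver restart points.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

PROTOCOL_KINDS = ("none", "current_pulse", "high_K", "hypotonic", "compression")


@dataclass(frozen=True)
class ExternalSolution:
    """External bath composition in SI (mol/m^3) plus temperature (K)."""
    c_na: float = 145.0
    c_k: float = 5.0
    c_cl: float = 110.0
    c_ca: float = 2.0
    c_mannitol: float = 0.0
    temperature: float = 310.0

    @property
    def osmolarity(self) -> float:
        return self.c_na + self.c_k + self.c_cl + self.c_ca + self.c_mannitol


@dataclass(frozen=True)
class StimulusProtocol:
    """One stimulus episode.

    Magnitudes by kind (all SI):

    * ``current_pulse``: ``current`` (A), rectangular between onset and
      onset+duration.
    * ``high_K``: ``delta_k`` added to external K+ and ``delta_na`` added
      to external Na+ (mol/m^3) from onset to onset+duration.
    * ``hypotonic``: ``delta_mannitol`` added to external mannitol from
      onset (use a negative value for osmolyte removal; the baseline
      solution must contain enough mannitol).
    * ``compression``: ramp at ``ramp_speed`` (m/s) from onset to depth
      ``depth`` (m), hold for ``duration`` after the ramp, then release at
      the same speed; Piezo2 phase is "loading" until release.
    """
    kind: str = "none"
    onset: float = 0.0
    duration: float = math.inf
    current: float = 0.0
    delta_k: float = 0.0
    delta_na: float = 0.0
    delta_mannitol: float = 0.0
    depth: float = 0.0
    ramp_speed: float = 1e-3  # 1 um/ms

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.kind == "compression" and self.ramp_speed <= 0:
            raise ValueError("ramp speed must be positive")

    # -- time course ---------------------------------------------------------
    def _active(self, t: float) -> bool:
        return self.onset <= t < self.onset + self.duration

    def applied_current(self, t: float) -> float:
        if self.kind == "current_pulse" and self._active(t):
            return self.current
        return 0.0

    def external(self, t: float, baseline: ExternalSolution) -> ExternalSolution:
        if self.kind == "high_K" and self._active(t):
            return ExternalSolution(
                c_na=baseline.c_na + self.delta_na,
                c_k=baseline.c_k + self.delta_k,
                c_cl=baseline.c_cl, c_ca=baseline.c_ca,
                c_mannitol=baseline.c_mannitol,
                temperature=baseline.temperature)
        if self.kind == "hypotonic" and t >= self.onset:
            c_man = baseline.c_mannitol + self.delta_mannitol
            if c_man < 0:
                raise ValueError("hypotonic protocol would make external "
                                 "mannitol negative; raise the baseline")
            return ExternalSolution(
                c_na=baseline.c_na, c_k=baseline.c_k, c_cl=baseline.c_cl,
                c_ca=baseline.c_ca, c_mannitol=c_man,
                temperature=baseline.temperature)
        return baseline

    def indentation(self, t: float) -> tuple[float, str]:
        """(depth in m, Piezo2 phase flag) at time t."""
        if self.kind != "compression" or t < self.onset:
            return 0.0, "loading"
        t_ramp = self.depth / self.ramp_speed
        t_release = self.onset + t_ramp + self.duration
        if t < self.onset + t_ramp:
            return self.ramp_speed * (t - self.onset), "loading"
        if t < t_release:
            return self.depth, "loading"
        d = self.depth - self.ramp_speed * (t - t_release)
        return max(d, 0.0), "unloading"

    def breakpoints(self, horizon: float) -> list[float]:
        """Drive discontinuities/kinks inside (0, horizon), sorted."""
        pts: list[float] = []
        if self.kind in ("current_pulse", "high_K"):
            pts = [self.onset, self.onset + self.duration]
        elif self.kind == "hypotonic":
            pts = [self.onset]
        elif self.kind == "compression":
            t_ramp = self.depth / self.ramp_speed
            t_release = self.onset + t_ramp + self.duration
            pts = [self.onset, self.onset + t_ramp,
                   t_release, t_release + t_ramp]
        return sorted(t for t in pts if 0.0 < t < horizon and math.isfinite(t))
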