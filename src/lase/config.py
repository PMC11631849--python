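"""Run configuration: every tunable of the pipeline in one serializable place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    Units: distances in mm, amplitudes in a.u. unless the name says mV.
    ``au_to_mv`` is the mapping-system conversion factor (0.003 mV/a.u.).
    ``noise_threshold_mv`` excludes traces whose peak-to-peak exceeds it
    from neighbor averaging when set (e.g. 3.5); it is off by default.
    ``log_base`` is ``"2"`` (entropy in bits) or ``"e"`` (nats).
    """

    target_vertices: int = 5000
    tolerance: int = 100
    resample: bool = True
    sphere_mm: float = 8.0
    cylinder_mm: float = 2.0
    bin_width_au: float = 100.0
    au_to_mv: float = 0.003
    w0: float = 0.0
    entropy_mode: str = "plain"
    log_base: str = "2"
    denominator: str = "valid"
    lva_threshold_mv: float = 0.5
    lva_min_points: int = 5
    noise_threshold_mv: float | None = None
    cutoff: float = 6.06
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "target_vertices", "sphere_mm", "cylinder_mm", "bin_width_au",
            "au_to_mv", "lva_threshold_mv", "lva_min_points", "cutoff",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tolerance < 0 or self.w0 < 0:
            raise ValueError("tolerance and w0 must be >= 0")
        if self.entropy_mode not in ("plain", "width_corrected"):
            raise ValueError(f"unknown entropy_mode {self.entropy_mode!r}")
        if self.log_base not in ("2", "e"):
            raise ValueError("log_base must be '2' or 'e'")
        if self.denominator not in ("valid", "all"):
            raise ValueError("denominator must be 'valid' or 'all'")
        if self.noise_threshold_mv is not None and self.noise_threshold_mv <= 0:
            raise ValueError("noise_threshold_mv must be positive or None")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def hash(self) -> str:
        """Stable digest of the full configuration, echoed into results."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
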