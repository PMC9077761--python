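"""Run configuration shared across subcommands.

Collects every tunable the pipeline exposes, with the documented defaults,
and round-trips through a single JSON file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .exceptions import ValidationError


@dataclass
class RunConfig:
    """All pipeline tunables in one serializable object.

    Units: ``tau0_s`` seconds; ``gas_constant`` J/mol/K; ``diffusion_limit``
    M^-1 s^-1; thresholds are fractions or percent as named; CD constants in
    deg cm^2 dmol^-1 (the 0% and 100% helix anchors of -MRE_208).
    """

    tau0_s: float = 5.073e-9
    gas_constant: float = 8.314
    diffusion_limit: float = 2.0e10
    lifetime_threshold: float = 0.10
    peak_shift_tolerance_nm: float = 2.0
    displacement_threshold_pct: float = 20.0
    mre_coil: float = 4000.0
    mre_helix: float = 33000.0
    csv_sep: str = ","
    csv_conc_unit: str = "uM"
    seed: int = 20180126
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.tau0_s <= 0:
            raise ValidationError("tau0_s must be positive")
        if self.gas_constant <= 0:
            raise ValidationError("gas_constant must be positive")
        if not 0 < self.lifetime_threshold < 1:
            raise ValidationError("lifetime_threshold must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
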