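"""Run configuration shared by the mining pipeline and the CLI.

Defaults follow the published workflow wherever it states a value: 0.5-Da
bins, a 0.01 (1%) mean-intensity floor for ratio eligibility, 70/20/10
train/validation/test fractions, candidate tree depths around the
two-to-three range that usually suffices.  Deliberate deviations from
library defaults (the min_leaf floor of 5, min_class_spectra of 10) are
listed in ``deviations()`` and echoed in run logs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass(frozen=True)
class RunConfig:
    bin_width: float = 0.5  # Da
    ratio_min_mean: float = 0.01  # 1% of base peak, on training spectra
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    depths: tuple[int, ...] = (1, 2, 3, 4)
    min_leaf: int = 5
    min_class_spectra: int = 10
    match_tolerance: float = 0.2  # Da, fragment annotation
    losses: tuple[tuple[str, ...], ...] = (
        ("H2O",),
        ("H2O", "H2O"),
        ("CO2",),
        ("C2H4O2",),
        ("C2H6O3",),
        ("C2H6O4",),
    )
    seed: int = 0

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not 0 <= self.ratio_min_mean <= 1:
            raise ValueError("ratio_min_mean must be in [0, 1]")
        if len(self.fractions) != 3 or abs(sum(self.fractions) - 1) > 1e-9:
            raise ValueError("fractions must be three values summing to 1")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def deviations(self) -> list[str]:
        """Settings that deviate from plain library-default tree training."""
        out = []
        if self.min_leaf != 1:
            out.append(
                f"min_leaf={self.min_leaf} (library default would be 1; the "
                "floor avoids singleton leaves that inflate rule confidence)"
            )
        out.append(
            f"min_class_spectra={self.min_class_spectra} (floor preventing "
            "degenerate trees on sparsely observed isomers)"
        )
        return out
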