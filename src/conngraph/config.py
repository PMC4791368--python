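"""Run configuration with defaults anchored to the analysis protocol.

Defaults: discard 10 initial volumes, FD spike threshold 0.5 mm, band-pass
0.01–0.08 Hz, functional thresholds {P<0.05 Bonferroni, P<0.001 uncorrected,
P<0.01 Bonferroni}, structural threshold >= 3 fibers, 1000 matched random
networks, 10000 permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .networks import DEFAULT_SCHEMES, ThresholdScheme

__all__ = ["RunConfig", "stage_seed"]

# stage codes for deterministic sub-seed derivation
STAGES = {"simulate": 0, "nulls": 1, "anova": 2, "pairwise": 3}


@dataclass(frozen=True)
class RunConfig:
    manifest: str | None = None
    out_dir: str = "conngraph_out"
    k_discard: int = 10
    fd_threshold: float = 0.5
    band: tuple[float, float] = (0.01, 0.08)
    schemes: tuple[ThresholdScheme, ...] = DEFAULT_SCHEMES
    min_fibers: int = 3
    n_null: int = 1000
    swaps_per_edge: int = 10
    n_perm: int = 10000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        if "schemes" in raw:
            raw["schemes"] = tuple(
                ThresholdScheme(**s) if isinstance(s, dict) else s
                for s in raw["schemes"]
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["band"] = list(self.band)
        d["schemes"] = [
            {"alpha": s.alpha, "correction": s.correction, "n_tests": s.n_tests}
            for s in self.schemes
        ]
        return d

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage/per-subject sub-seed below 2**31."""
    ss = np.random.SeedSequence([int(master), STAGES[stage], int(index)])
    return int(ss.generate_state(1)[0] % (2**31))
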