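"""Run configuration: one flat record of every pipeline knob.

Defaults follow the protocol the system was validated with: 3x3(x3)
windows, 5 scales (0..4), +/-45 degree Z-rotations and left-right/up-down
flips for boundary patches, 1% intensity clipping, 10-fold CV for the SVM
grid search, and weighted confidence voting.  The config round-trips
losslessly through a flat ``key = value`` text file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from .classifier import GridSearchSpec
from .neighborhoods import PatchSpec

__all__ = ["RunConfig"]


def _parse_scalar(text: str):
    text = text.strip()
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


@dataclass
class RunConfig:
    """All tunables of the train/segment/evaluate pipeline."""

    # neighborhood / scales
    N: int = 3
    S: int = 4  # scales 0..S, i.e. S+1 scales
    rotation_angles_deg: tuple[float, ...] = (45.0, -45.0)
    flips: tuple[str, ...] = ("lr", "ud")
    type_window: int = 3
    # normalization
    clip_fraction: float = 0.01
    # sampling
    Q: int = 5000
    R: int = 4
    # grid search
    k_folds: int = 10
    grid_max_fit_samples: int = 1024
    # voting
    strategy: str = "weighted_confidence"
    weight_resolution: float = 0.1
    weight_opt_max_pixels: int = 20000
    # reproducibility
    seed: int = 0

    def patch_spec(self) -> PatchSpec:
        return PatchSpec(
            N=self.N,
            scales=tuple(range(self.S + 1)),
            rotation_angles_deg=tuple(self.rotation_angles_deg),
            flips=tuple(self.flips),
        )

    def grid_spec(self) -> GridSearchSpec:
        return GridSearchSpec(k=self.k_folds, max_fit_samples=self.grid_max_fit_samples)

    def sub_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the single config seed."""
        h = np.frombuffer(stage.encode(), dtype=np.uint8).astype(np.uint64).sum()
        return int(
            np.random.SeedSequence((self.seed, int(h))).generate_state(1)[0] % (2**31)
        )

    # -- flat key=value round-trip ------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        tuple_fields = {"rotation_angles_deg": float, "flips": str}
        valid = {f.name for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in valid:
                raise ValueError(f"unknown config key {key!r}")
            if key in tuple_fields:
                cast = tuple_fields[key]
                items = [s.strip() for s in value.split(",") if s.strip()]
                kwargs[key] = tuple(cast(s) for s in items)
            else:
                kwargs[key] = _parse_scalar(value)
        return cls(**kwargs)
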