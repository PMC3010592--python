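"""Run configuration with flat key=value file round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from .detection import default_alpha_grid

__all__ = ["RunConfig", "parse_grid"]


def parse_grid(text: str) -> tuple:
    """Parse an alpha grid: ``start:stop:step`` or a comma list."""
    text = text.strip()
    if ":" in text:
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"grid must be start:stop:step, got {text!r}")
        start, stop, step = (float(p) for p in parts)
        if step <= 0:
            raise ValueError("grid step must be positive")
        return tuple(np.round(np.arange(start, stop + 1e-9, step), 10))
    return tuple(float(p) for p in text.split(","))


@dataclass
class RunConfig:
    """Knobs shared by the command-line workflows.

    alpha : enhancement coefficient (1.5 for H&E; 1.2 suits IHC with a
        light hematoxylin counterstain).
    alpha_grid : sweep grid for coefficient selection.
    plateau_tol : luminance-plateau threshold per grid step.
    n_bins : S-V histogram bin count over [-1, 1].
    seed : seed for every stochastic step (phantoms, sampling).
    output_dir : destination for written results.
    """

    alpha: float = 1.5
    alpha_grid: tuple = field(default_factory=lambda: tuple(default_alpha_grid()))
    plateau_tol: float = 0.01
    n_bins: int = 64
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.plateau_tol <= 0:
            raise ValueError("plateau_tol must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a flat ``key=value`` text file (# starts a comment)."""
        known = {f.name for f in fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            if key == "alpha_grid":
                kwargs[key] = parse_grid(value)
            elif key in ("alpha", "plateau_tol"):
                kwargs[key] = float(value)
            elif key in ("n_bins", "seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = [
            f"alpha={self.alpha}",
            "alpha_grid=" + ",".join(str(a) for a in self.alpha_grid),
            f"plateau_tol={self.plateau_tol}",
            f"n_bins={self.n_bins}",
            f"seed={self.seed}",
            f"output_dir={self.output_dir}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")
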