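"""Matrix and configuration I/O for the command-line tools."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RunConfig", "load_matrix", "save_matrix"]


def _detect_delimiter(line: str) -> str | None:
    """Pick among comma / tab / whitespace from a sample line."""
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # generic whitespace


def load_matrix(path: str | Path, transpose: bool = False) -> np.ndarray:
    """Read a dense numeric matrix from delimited text.

    The delimiter is auto-detected among comma, tab, and whitespace.  Ragged
    or non-numeric rows raise a ValueError naming the offending line.
    """
    path = Path(path)
    lines = [
        (i + 1, ln.strip())
        for i, ln in enumerate(path.read_text().splitlines())
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: no data")
    delim = _detect_delimiter(lines[0][1])
    rows = []
    width = None
    for lineno, ln in lines:
        cells = [c for c in (ln.split(delim) if delim else ln.split()) if c != ""]
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(cells)} fields, expected {width})"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell at line {lineno}") from exc
    M = np.asarray(rows, dtype=float)
    return M.T if transpose else M


def save_matrix(path: str | Path, M: np.ndarray, delimiter: str = "\t") -> None:
    np.savetxt(path, np.asarray(M, dtype=float), delimiter=delimiter)


@dataclass
class RunConfig:
    """Pipeline configuration (JSON-serializable).

    Counts must be positive, ``alpha`` in (0, 1), thresholds ordered
    ``r_lo < r_hi``.
    """

    K: int = 30
    n_ensembles: int = 30
    decimation_factor: int = 2
    n_components: int | None = None
    r_hi: float = 0.9
    r_lo: float = 0.3
    d_lo: float = 0.1
    match: str = "rank"
    n_null: int = 1000
    n_perm: int = 999
    alpha: float = 0.05
    level: float = 0.95
    tol: float = 1e-5
    max_iter: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("K", "n_ensembles", "decimation_factor", "n_null",
                     "n_perm", "max_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")
        if not self.r_lo < self.r_hi:
            raise ValueError("thresholds must satisfy r_lo < r_hi")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
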