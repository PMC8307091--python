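"""Run configuration and CSV emission for the command-line tools.

Configurations are flat TOML; every CLI run writes its resolved
configuration next to its output so results are reproducible from the
artifacts alone.  CSV output is RFC-4180 style with a header row and full
double precision (``%.17g``).
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

__all__ = ["RunConfig", "write_csv", "read_csv_records"]


@dataclass
class RunConfig:
    """Resolved settings of one CLI run.

    Geometry is per species (species B fields ignored by pure-component
    commands); angular defaults follow the standard 100 x 50 discretization.
    """

    a: float = 3.0
    c: float = 9.0
    a_B: float | None = None
    c_B: float | None = None
    method: str = "rigorous"
    z: float = 3.0
    n_theta: int = 100
    n_phi: int = 50
    n_table: int = 201
    tol: float = 1e-9
    mixing: float = 0.3
    seed: int = 0
    extra: dict[str, Any] = field(default_factory=dict)

    def to_toml(self) -> str:
        lines = []
        data = asdict(self)
        extra = data.pop("extra")
        data.update(extra)
        for key, val in data.items():
            if val is None:
                continue
            if isinstance(val, bool):
                lines.append(f"{key} = {'true' if val else 'false'}")
            elif isinstance(val, (int, float)):
                lines.append(f"{key} = {val!r}")
            else:
                lines.append(f'{key} = "{val}"')
        return "\n".join(lines) + "\n"

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kw = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        return cls(**kw, extra=extra)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_mapping(tomllib.load(fh))

    def digest(self) -> str:
        """Short hash of the resolved configuration, for logging."""
        return hashlib.sha256(self.to_toml().encode()).hexdigest()[:12]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_toml())


def write_csv(records: Sequence[Mapping[str, Any]], schema: Sequence[str], path: str | Path) -> None:
    """Write records as CSV with the exact column order of ``schema``.

    Floats are rendered at full double precision; an empty record set
    produces a header-only file.
    """
    for rec in records:
        missing = set(schema) - set(rec)
        if missing:
            raise ValueError(f"record missing columns {sorted(missing)}")
    lines = [",".join(schema)]
    for rec in records:
        cells = []
        for col in schema:
            val = rec[col]
            if isinstance(val, bool):
                cells.append(str(val).lower())
            elif isinstance(val, float):
                cells.append(f"{val:.17g}")
            else:
                cells.append(str(val))
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_csv_records(path: str | Path) -> list[dict[str, str]]:
    """Read back a CSV written by :func:`write_csv` (values as strings)."""
    lines = Path(path).read_text().strip().split("\n")
    header = lines[0].split(",")
    return [dict(zip(header, line.split(","))) for line in lines[1:]]
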