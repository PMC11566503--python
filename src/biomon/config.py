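"""Package-wide configuration with documented defaults.

Round-trips through a plain ``key = value`` file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .ranks import RANKS


@dataclass
class Config:
    ranks: tuple[str, ...] = RANKS
    suggestion_cutoff: int = 2
    abundance_class_breakpoints: tuple[float, ...] = (10.0, 100.0, 1000.0)
    axis_threshold: float = 0.95  # corr / r2 axis-selection threshold
    alpha: float = 0.05  # indicator-taxon significance level
    seed: int = 0
    delimiter: str = ","
    decimal: str = "."

    def save(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ";".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Config":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key == "ranks":
                kwargs[key] = tuple(raw.split(";"))
            elif key == "abundance_class_breakpoints":
                kwargs[key] = tuple(float(x) for x in raw.split(";"))
            elif key in {"suggestion_cutoff", "seed"}:
                kwargs[key] = int(raw)
            elif key in {"axis_threshold", "alpha"}:
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)
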