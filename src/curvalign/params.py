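"""Pipeline parameters and named presets.

Four parameters steer the method.  ``r_c`` (Angstrom) is the curvature
averaging radius and sets the feature scale; ``t_s`` is the persistence
simplification threshold as a fraction of the mean positive-maximum
curvature; ``t_ms`` bounds descriptor differences on the same normalised
scale; ``t_mrd`` (Angstrom) bounds relative landmark-distance
differences.  By default ``t_ms = t_s`` and ``t_mrd = r_c``; ``t_s = 0.1``
is a good general-purpose choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace


@dataclass(frozen=True)
class Params:
    r_c: float = 3.0
    t_s: float = 0.1
    t_ms: float | None = None
    t_mrd: float | None = None
    n_scales: int = 15
    min_area_fraction: float = 0.15
    min_clique_size: int = 3
    max_cliques: int = 10**6
    top_k: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        if self.t_s < 0:
            raise ValueError("t_s must be non-negative")
        if self.t_ms is None:
            object.__setattr__(self, "t_ms", self.t_s)
        if self.t_mrd is None:
            object.__setattr__(self, "t_mrd", self.r_c)
        if self.t_mrd <= 0:
            raise ValueError("t_mrd must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Params":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})

    @classmethod
    def from_file(cls, path) -> "Params":
        """Read parameters from JSON or simple ``key = value`` text."""
        text = open(path).read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                val = val.strip()
                if key in ("n_scales", "min_clique_size", "max_cliques", "top_k", "seed"):
                    data[key] = int(val)
                else:
                    data[key] = float(val)
        return cls.from_dict(data)


# Parameter profiles matching the published protocols: protein skin
# surfaces (features of 2-4 atoms), small-ligand surfaces (single-atom
# scale), and ~20 A resolution cryo-EM iso-surfaces.
PRESETS = {
    "protein": Params(r_c=3.0, t_s=0.1, t_ms=0.1, t_mrd=1.0),
    "ligand": Params(r_c=1.2, t_s=0.1, t_ms=0.1, t_mrd=1.2),
    "em": Params(r_c=30.0, t_s=0.05, t_ms=0.1, t_mrd=30.0),
}


def preset(name: str, **overrides) -> Params:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[name]
    return replace(p, **overrides) if overrides else p
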