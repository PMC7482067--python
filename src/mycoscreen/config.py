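"""Pipeline configuration: screening thresholds and extension parameters.

Defaults reproduce the survey protocol where it states them: the E-value gate
(1e-10), the RdRp domain-coverage threshold for the census (0.60), the
contig-extension overlap/identity/cycle parameters (30 nt, 0.80, 0.90, 10
cycles per block), and the strict/loose phred read filters (20 / 5). The
remaining knobs (endogeny match thresholds, profile bit-score gate,
Karlin-Altschul parameters for BLOSUM62 11/1) are this pipeline's own choices
and are documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class Config:
    evalue_threshold: float = 1e-10
    coverage_threshold: float = 0.60
    min_overlap_nt: int = 30
    edge_identity: float = 0.80
    seed_identity: float = 0.90
    cycles_per_block: int = 10
    max_blocks: int = 10
    min_phred_strict: int = 20
    min_phred_loose: int = 5
    min_orf_aa: int = 100
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    endo_identity: float = 0.90
    endo_min_len_nt: int = 200
    profile_hit_bits: float = 20.0
    rng_seed: int = 0

    _FRACTIONS = ("coverage_threshold", "edge_identity", "seed_identity",
                  "endo_identity")
    _COUNTS = ("min_overlap_nt", "cycles_per_block", "max_blocks",
               "min_orf_aa", "endo_min_len_nt")

    def __post_init__(self) -> None:
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in self._COUNTS:
            v = getattr(self, name)
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Parse a flat ``key = value`` config file; unknown keys are errors."""
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            caster = int if "int" in str(known[key]) else float
            kwargs[key] = caster(value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")
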