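"""Pipeline-wide numeric thresholds.

The defaults reproduce the published analysis settings for plant
mitochondrial repeat/recombination surveys: repeats of at least 50 bp at
>85% identity, 1000 bp flanks on each conformation reference, long reads
accepted as support at >95% alignment identity with at least 200 bp of
coverage in both repeat flanks, and a 1e-6 e-value cutoff for homology
annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    #: minimum repeat unit length considered (bp)
    min_repeat_len: int = 50
    #: repeats kept when pairwise identity is strictly above this percentage
    min_repeat_identity: float = 85.0
    #: flank taken up- and down-stream of each repeat copy when building
    #: conformation references (bp)
    flank_len: int = 1000
    #: a read supports a reference when a single alignment exceeds this identity
    read_support_identity: float = 95.0
    #: ... and covers at least this many bp of flank on BOTH sides of the repeat
    read_support_flank_cov: int = 200
    #: e-value cutoff for homology annotation and mt-read extraction
    homology_evalue: float = 1e-6
    #: size-class boundaries: small [min,small_max), medium [small_max,medium_max],
    #: large > medium_max
    size_class_small_max: int = 100
    size_class_medium_max: int = 1000
    #: an alternative conformation is discarded when it aligns to the genome
    #: (either strand) at >= this identity over its full length
    screen_identity: float = 95.0
    #: blastn settings for the genome self-scan
    scan_word_size: int = 11
    scan_evalue: float = 1e-3
    #: RNG seed for any stochastic step
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_repeat_len <= 0 or self.flank_len <= 0 or self.read_support_flank_cov <= 0:
            raise ValueError("length thresholds must be positive")
        if not (0 < self.min_repeat_identity <= 100 and 0 < self.read_support_identity <= 100):
            raise ValueError("identity thresholds must be in (0, 100]")
        if not self.size_class_small_max < self.size_class_medium_max:
            raise ValueError("size-class bounds must be ordered")
        if self.homology_evalue <= 0:
            raise ValueError("e-value cutoff must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read ``key = value`` lines overriding the defaults.

        Blank lines and ``#`` comments are ignored; unknown keys raise.
        """
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(cls(), key)
            kwargs[key] = type(current)(float(value)) if isinstance(current, (int, float)) else value
        return cls(**kwargs)
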