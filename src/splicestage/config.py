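"""Run configuration: sample manifest, gene list and all thresholds."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class SampleSpec:
    name: str
    path: Path
    role: str = "rna"      # 'rna' or 'dna_control'


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Thresholds default to the operational values of the method: 650 bp
    for both the expected mapping distance and the large-distance flag,
    a 3-base anchor for boundary/junction spanning, splice-ratio cutoff
    0.5, Q1 coverage quartile, novel-exon coverage ratio 2x and a
    2-read minimum per-sample peak magnitude.
    """

    samples: list[SampleSpec]
    gtf: Path
    genes: list[str]
    out_dir: Path
    genome: Path | None = None
    transcript_overrides: Mapping[str, str] = field(default_factory=dict)

    expected_distance: int = 650
    large_distance: int = 650
    anchor: int = 3
    min_samples: int | None = None       # default: all RNA samples
    ratio_cutoff: float = 0.5
    quartile: str = "Q1"
    novel_exon_ratio: float = 2.0
    min_peak_magnitude: int = 2
    retention_alpha: float = 0.1

    def __post_init__(self) -> None:
        controls = [s for s in self.samples if s.role == "dna_control"]
        if len(controls) > 1:
            raise ConfigError(
                f"{len(controls)} dna_control samples in manifest; at most 1 "
                "is allowed"
            )
        roles = {s.role for s in self.samples}
        if not roles <= {"rna", "dna_control"}:
            raise ConfigError(f"unknown sample role(s): {roles - {'rna', 'dna_control'}}")
        if not self.rna_samples:
            raise ConfigError("manifest contains no RNA samples")
        if self.quartile not in ("Q1", "Q3"):
            raise ConfigError(f"quartile must be Q1 or Q3, got {self.quartile!r}")
        for s in self.samples:
            if not Path(s.path).exists():
                raise ConfigError(f"sample {s.name}: missing file {s.path}")
        if not Path(self.gtf).exists():
            raise ConfigError(f"missing GTF {self.gtf}")
        if self.genome is not None and not Path(self.genome).exists():
            raise ConfigError(f"missing genome FASTA {self.genome}")

    @property
    def rna_samples(self) -> list[SampleSpec]:
        return [s for s in self.samples if s.role == "rna"]

    @property
    def dna_control(self) -> SampleSpec | None:
        for s in self.samples:
            if s.role == "dna_control":
                return s
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            samples = [
                SampleSpec(s["name"], Path(s["path"]), s.get("role", "rna"))
                for s in raw["samples"]
            ]
            kwargs = dict(
                samples=samples,
                gtf=Path(raw["gtf"]),
                genes=list(raw["genes"]),
                out_dir=Path(raw["out_dir"]),
            )
        except KeyError as exc:
            raise ConfigError(f"missing required config key: {exc}") from exc
        if raw.get("genome"):
            kwargs["genome"] = Path(raw["genome"])
        for key in ("transcript_overrides", "expected_distance",
                    "large_distance", "anchor", "min_samples", "ratio_cutoff",
                    "quartile", "novel_exon_ratio", "min_peak_magnitude",
                    "retention_alpha"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)
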