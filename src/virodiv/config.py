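"""Pipeline configuration: one namespace of thresholds, YAML in/out.

Defaults are the study thresholds: round-1 AVQ screen (>=10% ORFs with pVOG
hits, AVQ >= 2, HMMER E <= 1e-5), round-2 baiting (>=20% of ORFs, minimum 3,
matching a single round-1 scaffold under identity >= 30%, bit score >= 50,
alignment >= 30 aa, E <= 1e-5), SNP validity (count >= 4, frequency >= 1%,
codon coverage >= 5x), 5 kbp scaffold floor, and population clustering at
95% ANI over 80% of the shorter sequence. Every threshold is echoed to the
log at startup for reproducibility.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("virodiv")


@dataclass
class AvqConfig:
    min_percent: float = 10.0
    min_avq: float = 2.0
    max_evalue: float = 1e-5


@dataclass
class BaitConfig:
    min_percent: float = 20.0
    min_matches: int = 3
    min_identity: float = 30.0
    min_bitscore: float = 50.0
    min_aln_len: int = 30
    max_evalue: float = 1e-5
    best_hit_only: bool = False


@dataclass
class SnpConfig:
    min_count: int = 4
    min_freq: float = 0.01
    min_cov: int = 5
    count_mode: str = "alleles"  # alleles | reads


@dataclass
class PopulationConfig:
    ani: float = 95.0
    cov: float = 80.0
    kmer: int = 15


@dataclass
class HostConfig:
    homology_min_len: int = 1000
    homology_min_identity: float = 90.0
    spacer_max_mismatches: int = 1
    spacer_min_len: int = 20


@dataclass
class TaxonomyConfig:
    min_identity: float = 30.0
    min_bitscore: float = 50.0
    min_aln_len: int = 30
    max_evalue: float = 1e-5


@dataclass
class ClassifierLabelConfig:
    virsorter_categories: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    virfinder_min_score: float = 0.7
    virfinder_max_p: float = 0.05


@dataclass
class PipelineConfig:
    min_scaffold_length: int = 5000
    subsample_n: int | None = None
    seed: int = 0
    avq: AvqConfig = field(default_factory=AvqConfig)
    bait: BaitConfig = field(default_factory=BaitConfig)
    snp: SnpConfig = field(default_factory=SnpConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    host: HostConfig = field(default_factory=HostConfig)
    taxonomy: TaxonomyConfig = field(default_factory=TaxonomyConfig)
    labels: ClassifierLabelConfig = field(default_factory=ClassifierLabelConfig)

    def log_thresholds(self) -> None:
        for line in yaml.safe_dump(self.to_dict(), sort_keys=True).splitlines():
            logger.info("config: %s", line)

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            return obj

        return listify(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "avq", "bait", "snp", "population", "host", "taxonomy", "labels"
            ):
                sub_cls = cls.__dataclass_fields__[f.name].default_factory  # type: ignore[union-attr]
                known = {sf.name for sf in dataclasses.fields(sub_cls)}
                unknown = set(value) - known
                if unknown:
                    raise ValueError(
                        f"config section {f.name!r}: unknown keys {sorted(unknown)}"
                    )
                if "virsorter_categories" in value:
                    value = dict(value)
                    value["virsorter_categories"] = tuple(value["virsorter_categories"])
                kwargs[f.name] = sub_cls(**value)
            else:
                kwargs[f.name] = value
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig.from_dict(data)
    cfg.log_thresholds()
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
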