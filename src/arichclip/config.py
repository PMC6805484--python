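"""Pipeline configuration: every stage parameter with its published default,
YAML round-trip, and a stable config hash recorded in output manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import ConfigurationError
from .synthetic import SimulationConfig


@dataclass
class SiteCallingConfig:
    nb_window: int = 500
    alpha: float = 0.01
    site_width: int = 9
    min_covered: int = 3  # sparse filter: covered nt within the 9-nt window
    min_events: int = 3  # reproducibility: events per replicate
    merge_direction: str = "genomic"  # or 'transcript'
    exclude_introns: bool = True
    support_max_level: int = 2
    support_max_tsl: int = 3
    support_direction: str = "le"


@dataclass
class SobConfig:
    min_background: int = 10
    buffer: int = 5
    utr3_fallback: int = 500
    past_site: int = 10
    strict: bool = False


@dataclass
class StretchConfig:
    search_space: int = 55
    min_window: int = 8
    max_window: int = 30
    min_a_content: float = 0.70
    min_weighted_a: float = 11.0
    min_lca: int = 4
    exclusion_mode: str = "any"


@dataclass
class KmerConfig:
    flank: int = 40
    bg_windows: int = 1000
    bg_repeats: int = 100
    profile_halfwindow: int = 50
    profile_kmers: tuple[str, ...] = ("AAAA", "CCCC", "GGGG", "TTTT")


@dataclass
class MetaProfileConfig:
    polya_radius: int = 1000
    min_events: int = 10
    min_utr3: int = 1000
    smooth: int = 50
    stretch_radius: int = 100
    matrix_radius: int = 50
    enrichment_near: tuple[int, int] = (-150, -50)
    enrichment_body: tuple[int, int] = (-750, -650)


@dataclass
class BarcodeConfig:
    min_qual_random: int = 17
    min_qual_experimental: int = 20
    max_low_experimental: int = 1


@dataclass
class PipelineConfig:
    genome: Optional[str] = None
    annotation: Optional[str] = None
    tracks: list[dict] = field(default_factory=list)  # [{replicate, plus, minus}]
    reads: Optional[str] = None
    outdir: str = "arichclip_out"
    seed: int = 0
    simulate: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    barcode: BarcodeConfig = field(default_factory=BarcodeConfig)
    sitecalling: SiteCallingConfig = field(default_factory=SiteCallingConfig)
    sob: SobConfig = field(default_factory=SobConfig)
    stretch: StretchConfig = field(default_factory=StretchConfig)
    kmer: KmerConfig = field(default_factory=KmerConfig)
    metaprofile: MetaProfileConfig = field(default_factory=MetaProfileConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis parameters; file locations are excluded so
        identical runs in different directories hash identically."""
        d = self.to_dict()
        for path_key in ("genome", "annotation", "tracks", "reads", "outdir"):
            d.pop(path_key, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if isinstance(value, list) and "tuple" in str(ftype):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


_SECTIONS = {
    "simulation": SimulationConfig,
    "barcode": BarcodeConfig,
    "sitecalling": SiteCallingConfig,
    "sob": SobConfig,
    "stretch": StretchConfig,
    "kmer": KmerConfig,
    "metaprofile": MetaProfileConfig,
}


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> PipelineConfig:
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    kwargs: dict = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if key == "simulation":
                for rk in ("gene_length_range", "utr5_length_range", "utr3_length_range",
                           "stretch_length_range"):
                    if rk in value and isinstance(value[rk], list):
                        value[rk] = tuple(value[rk])
            kwargs[key] = _build(_SECTIONS[key], value)
        else:
            kwargs[key] = value
    return _build(PipelineConfig, kwargs)


def save_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
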