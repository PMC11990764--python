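"""Configuration objects for simulation and pipeline runs.

All thresholds that govern filtering, testing, and classification live here so
that every output file can echo the exact settings it was produced with.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

#: Tissues assayed by targeted deep sequencing, in canonical output order.
TISSUES = ("child_blood", "father_blood", "mother_blood", "father_sperm")

#: Mutational-origin categories a de novo variant can fall into.
ORIGIN_CATEGORIES = (
    "one_off",
    "pre_pgc_blood",
    "post_pgc_sperm_only",
    "child_postzygotic",
)


class ConfigError(ValueError):
    """Raised when a configuration field fails validation; names the field."""


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class MosaicSpec:
    """How many mosaics of one origin category to inject per trio, and at what VAF.

    ``count_range`` is inclusive; a count is drawn uniformly from it per trio.
    ``vaf_range`` bounds the true mosaic fraction drawn log-uniformly, matching
    the wide dynamic range (sub-percent to >10%) seen in deep-sequencing data.
    """

    category: str
    count_range: tuple[int, int]
    vaf_range: tuple[float, float]

    def __post_init__(self) -> None:
        _check(self.category in ORIGIN_CATEGORIES[1:], "mosaic_spec.category",
               f"must be one of {ORIGIN_CATEGORIES[1:]}, got {self.category!r}")
        lo, hi = self.count_range
        _check(0 <= lo <= hi, "mosaic_spec.count_range", "must satisfy 0 <= lo <= hi")
        vlo, vhi = self.vaf_range
        _check(0 < vlo <= vhi <= 0.5, "mosaic_spec.vaf_range",
               "bounds must be ordered and within (0, 0.5]")


def default_mosaic_spec() -> tuple[MosaicSpec, ...]:
    """Injection defaults emulating the observed cohort: 1-4 parental blood
    mosaics per child (VAF 0.35-14.7%), 1-2 sperm-confined paternal mosaics
    (VAF down to 0.24%), and occasional child postzygotic variants."""
    return (
        MosaicSpec("pre_pgc_blood", (1, 4), (0.0035, 0.147)),
        MosaicSpec("post_pgc_sperm_only", (1, 2), (0.0024, 0.05)),
        MosaicSpec("child_postzygotic", (0, 2), (0.10, 0.40)),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic trio cohort.

    Defaults reproduce the study conditions: 5 trios averaging 85.6 DNMs each
    with an 80% paternal bias, deduplicated deep-count depths of 5557x (child
    blood), 8314x (parental blood) and 5755x (sperm), and a global sequencing
    noise floor with VAF 0.022%.
    """

    n_trios: int = 5
    mean_dnms_per_trio: float = 85.6
    paternal_fraction: float = 0.8
    noise_vaf: float = 2.2e-4
    depths: Mapping[str, float] = field(default_factory=lambda: {
        "child_blood": 5557.0,
        "father_blood": 8314.0,
        "mother_blood": 8314.0,
        "father_sperm": 5755.0,
    })
    wgs_depth: float = 40.0
    longread_depth: float = 30.0
    untagged_read_fraction: float = 0.1
    indel_fraction: float = 0.105  # mean 77 SNVs + 9 indels per trio
    depth_dispersion: float = 0.0  # gamma CV on per-site depth; 0 = Poisson only
    noise_dispersion: float = 0.0  # gamma CV on per-site noise rate; 0 = global
    mosaic_spec: Sequence[MosaicSpec] = field(default_factory=default_mosaic_spec)
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_trios >= 1, "n_trios", "must be a positive integer")
        _check(self.mean_dnms_per_trio > 0, "mean_dnms_per_trio", "must be positive")
        _check(0.0 <= self.paternal_fraction <= 1.0, "paternal_fraction",
               "must lie in [0, 1]")
        _check(0.0 <= self.noise_vaf < 1.0, "noise_vaf", "must lie in [0, 1)")
        for tissue in TISSUES:
            _check(tissue in self.depths, "depths", f"missing tissue {tissue!r}")
            _check(self.depths[tissue] > 0, "depths", f"{tissue} depth must be > 0")
        _check(self.wgs_depth > 0, "wgs_depth", "must be positive")
        _check(self.longread_depth > 0, "longread_depth", "must be positive")
        _check(0.0 <= self.untagged_read_fraction < 1.0, "untagged_read_fraction",
               "must lie in [0, 1)")
        _check(0.0 <= self.indel_fraction <= 1.0, "indel_fraction", "must lie in [0, 1]")
        _check(self.depth_dispersion >= 0, "depth_dispersion", "must be >= 0")
        _check(self.noise_dispersion >= 0, "noise_dispersion", "must be >= 0")


@dataclass(frozen=True)
class Thresholds:
    """Every numeric decision rule of the pipeline, in one echoable place."""

    # trio DNM filters
    min_depth: int = 20            # strict: DP > 20 in all three members
    min_gq: int = 29               # strict: GQ > 29 in all three members
    min_child_vaf: float = 0.25    # strict: child VAF > 0.25
    biallelic_fraction: float = 0.7  # (AD_ref + AD_alt) > 0.7 x DP
    vaf_shift: float = 4.0         # child VAF >= 4 x parent VAF
    cluster_gap_bp: int = 20_000
    # phasing
    min_alt_reads: int = 3
    max_minor_fraction: float = 0.1
    # mosaic testing
    alpha: float = 0.05
    naive_poisson: bool = False
    # postzygotic calling
    postzygotic_max_smmip_vaf: float = 0.45
    postzygotic_max_hap_vaf: float = 0.9
    postzygotic_min_hap_depth: int = 4
    # WGS alt-read screen
    wgs_screen_min_alt: int = 1
    # recurrence
    high_risk_vaf: float = 0.01
    bootstrap_ci: bool = False
    n_bootstrap: int = 10_000

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level run configuration: simulation block, thresholds, seed."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


_KNOWN_TOP = {"simulation", "thresholds", "seed"}


def load_config(path: str) -> PipelineConfig:
    """Read a YAML pipeline configuration, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_TOP
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    sim_raw = dict(raw.get("simulation", {}))
    if "mosaic_spec" in sim_raw:
        sim_raw["mosaic_spec"] = tuple(
            MosaicSpec(m["category"], tuple(m["count_range"]), tuple(m["vaf_range"]))
            for m in sim_raw["mosaic_spec"]
        )
    sim_known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(sim_raw) - sim_known
    if unknown:
        raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
    thr_raw = dict(raw.get("thresholds", {}))
    unknown = set(thr_raw) - set(Thresholds.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")
    return PipelineConfig(
        simulation=SimulationConfig(**sim_raw),
        thresholds=Thresholds(**thr_raw),
        seed=int(raw.get("seed", 0)),
    )
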