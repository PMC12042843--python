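"""Structured pipeline configuration and per-stage random-number streams.

The config file is YAML with flat key/value sections, one section per stage.
Every stochastic operation draws from a generator derived from the pair
(global seed, stage name), so each stage is independently reproducible: the
`gsea` stage gives the same answer whether or not `simulate` ran first.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class TraOptions:
    n_groups: int = 11
    j_max: int = 5
    threshold_form: str = "gap"  # or "saturating"


@dataclass
class GseaOptions:
    n_perm: int = 10000
    weight: float = 1.0


@dataclass
class DiversityOptions:
    n_boot: int = 200
    extrapolation_factor: float = 2.0  # m* = factor x smallest population's UMI total


@dataclass
class Thresholds:
    lfc_cut: float = -1.0
    fdr_cut: float = 0.05


@dataclass
class PipelineConfig:
    """Validated configuration for a pipeline run.

    ``seed`` is mandatory: every stochastic stage derives its own stream from
    it, so omitting it would make reruns irreproducible.
    """

    seed: int
    out_dir: str = "run"
    thresholds: Thresholds = field(default_factory=Thresholds)
    tra: TraOptions = field(default_factory=TraOptions)
    gsea: GseaOptions = field(default_factory=GseaOptions)
    diversity: DiversityOptions = field(default_factory=DiversityOptions)
    simulate: dict = field(default_factory=dict)  # generator overrides
    paths: dict = field(default_factory=dict)  # optional external inputs

    def __post_init__(self) -> None:
        # allow plain dicts for the option sections
        for name, cls in (("thresholds", Thresholds), ("tra", TraOptions),
                          ("gsea", GseaOptions), ("diversity", DiversityOptions)):
            val = getattr(self, name)
            if isinstance(val, dict):
                setattr(self, name, cls(**val))
        if self.seed is None or int(self.seed) < 0:
            raise ValueError("config requires a non-negative integer seed")
        self.seed = int(self.seed)
        if self.tra.n_groups < 2:
            raise ValueError("tra.n_groups must be >= 2")
        if not 1 <= self.tra.j_max:
            raise ValueError("tra.j_max must be >= 1")
        if self.tra.threshold_form not in {"gap", "saturating"}:
            raise ValueError("tra.threshold_form must be 'gap' or 'saturating'")
        if self.gsea.n_perm < 1:
            raise ValueError("gsea.n_perm must be >= 1")
        if self.diversity.n_boot < 50:
            raise ValueError("diversity.n_boot must be >= 50")
        if not 0 < self.thresholds.fdr_cut < 1:
            raise ValueError("thresholds.fdr_cut must be in (0, 1)")

    # -- seeding ------------------------------------------------------------

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Generator for ``stage``, a pure function of (seed, stage name)."""
        return np.random.default_rng(stage_seed(self.seed, stage))

    # -- (de)serialization ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "seed" not in raw:
            raise ValueError("config missing required key 'seed'")
        return cls(
            seed=raw["seed"],
            out_dir=raw.get("out_dir", "run"),
            thresholds=Thresholds(**raw.get("thresholds", {})),
            tra=TraOptions(**raw.get("tra", {})),
            gsea=GseaOptions(**raw.get("gsea", {})),
            diversity=DiversityOptions(**raw.get("diversity", {})),
            simulate=raw.get("simulate", {}),
            paths=raw.get("paths", {}),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the analysis-relevant configuration.

        Filesystem locations (out_dir, paths) are excluded so that the same
        analysis in two directories carries the same stamp.
        """
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("paths", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def output_header(self, stage: str) -> str:
        return f"aireflow stage={stage} config_hash={self.config_hash()} seed={self.seed}"


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2**31 from the global seed and stage name."""
    mix = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(mix.generate_state(1, dtype=np.uint32)[0] % (2**31))
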