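"""Run configuration: every tunable threshold, with its default.

Defaults are the analysis cut-offs of the study this pipeline reproduces:
cell QC (<2,000 detected genes, >15% mitochondrial, >10% hemoglobin),
90% dropout gene filter, universal-profile contrasts (log2FC > 1,
FDR < 0.05, expressed in >=33% of HE cells), inter-HE contrasts
(log2FC > 1.5, FDR < 0.05, >50% expressing cells in the upregulated
population), batch-gene rule (log2FC > 1.5, padj < 0.01, detection-rate
difference > 50%), entropy (mean difference > 0.1, FDR < 0.05, gene total
>= 10 per cell), dIF (|dIF| > 0.1, FDR < 0.05, >=10 qualifying cells), and
rank-based scoring with r_max = 1500.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid configuration: {msg}")


@dataclass
class QCConfig:
    min_genes: int = 2000
    max_mito: float = 15.0
    max_hb: float = 10.0
    batch_lfc: float = 1.5
    batch_padj: float = 0.01
    batch_det_diff: float = 0.50

    def validate(self) -> None:
        _check(self.min_genes >= 0, "min_genes >= 0")
        _check(0 <= self.max_mito <= 100, "max_mito in [0,100]")
        _check(0 <= self.max_hb <= 100, "max_hb in [0,100]")
        _check(0 <= self.batch_det_diff <= 1, "batch_det_diff in [0,1]")


@dataclass
class DEConfig:
    lfc_universal: float = 1.0
    lfc_interhe: float = 1.5
    fdr: float = 0.05
    pct_universal: float = 0.33
    pct_interhe: float = 0.50
    dropout_max: float = 0.90

    def validate(self) -> None:
        _check(0 < self.fdr < 1, "fdr in (0,1)")
        _check(0 <= self.pct_universal <= 1, "pct_universal in [0,1]")
        _check(0 <= self.pct_interhe <= 1, "pct_interhe in [0,1]")
        _check(0 <= self.dropout_max <= 1, "dropout_max in [0,1]")


@dataclass
class DiversityConfig:
    entropy_min_total: int = 10
    entropy_diff: float = 0.1
    fdr: float = 0.05

    def validate(self) -> None:
        _check(self.entropy_min_total >= 0, "entropy_min_total >= 0")
        _check(0 <= self.entropy_diff <= 1, "entropy_diff in [0,1]")
        _check(0 < self.fdr < 1, "fdr in (0,1)")


@dataclass
class DTUConfig:
    dif_min: float = 0.1
    fdr: float = 0.05
    min_if_cells: int = 10
    min_total: int = 10
    n_perm: int = 1000

    def validate(self) -> None:
        _check(0 <= self.dif_min <= 1, "dif_min in [0,1]")
        _check(0 < self.fdr < 1, "fdr in (0,1)")
        _check(self.min_if_cells >= 1, "min_if_cells >= 1")
        _check(self.n_perm >= 1, "n_perm >= 1")


@dataclass
class ScoringConfig:
    r_max: int = 1500

    def validate(self) -> None:
        _check(self.r_max >= 1, "r_max >= 1")


@dataclass
class KNNConfig:
    k: int = 10
    n_components: int = 50

    def validate(self) -> None:
        _check(self.k >= 1, "k >= 1")
        _check(self.n_components >= 1, "n_components >= 1")


@dataclass
class RunConfig:
    qc: QCConfig = field(default_factory=QCConfig)
    de: DEConfig = field(default_factory=DEConfig)
    diversity: DiversityConfig = field(default_factory=DiversityConfig)
    dtu: DTUConfig = field(default_factory=DTUConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    knn: KNNConfig = field(default_factory=KNNConfig)
    seed: int = 0

    def validate(self) -> None:
        for f in fields(self):
            sub = getattr(self, f.name)
            if hasattr(sub, "validate"):
                sub.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = {}
        sections = {f.name: f for f in fields(cls)}
        for name, val in d.items():
            if name not in sections:
                raise ValueError(f"unknown configuration section {name!r}")
            f = sections[name]
            if name == "seed":
                kw[name] = int(val)
            else:
                kw[name] = f.default_factory()  # type: ignore[misc]
                for k, v in val.items():
                    if not hasattr(kw[name], k):
                        raise ValueError(f"unknown option {name}.{k}")
                    setattr(kw[name], k, v)
        cfg = cls(**kw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_seed(seed: int, stage: str) -> int:
    """Deterministically fan a global seed out to a named pipeline stage."""
    return int(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31))
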