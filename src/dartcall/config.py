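"""Run configuration: published defaults, YAML loading, validation.

Precedence is CLI flags > config file > defaults; every override is echoed
to the log so a run manifest can be reconstructed from the log alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, asdict

import yaml

from .sites import CallParams

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable thresholds of both workflows.

    Site-calling defaults are the published cascade (50 reads, 3 edited,
    1-95 %C2U, 1.25-fold vs each KO, 2 replicates, 1.5-fold confidence
    ratio, 5 kb 3'UTR extension); localization defaults are the published
    enrichment thresholds (1.5-fold, KCl 2-fold, FDR 0.05, baseMean 10,
    FPKM 5).
    """

    # site calling
    min_coverage: int = 50
    min_edited: int = 3
    min_rate_pct: float = 1.0
    max_rate_pct: float = 95.0
    fold_vs_each_control: float = 1.25
    min_replicates: int = 2
    high_conf_fold: float = 1.5
    min_control_coverage: int = 10
    utr3_extension_bp: int = 5000
    # pileup
    min_mapq: int = 10
    min_baseq: int = 20
    strandedness: str = "reverse"
    # localization
    enrich_fold: float = 1.5
    kcl_fold: float = 2.0
    fdr: float = 0.05
    base_mean_min: float = 10.0
    fpkm_min: float = 5.0
    mito_chroms: tuple[str, ...] = ("chrM", "MT")
    # reproducibility
    seed: int = 0

    def call_params(self) -> CallParams:
        return CallParams(
            min_coverage=self.min_coverage,
            min_edited=self.min_edited,
            min_rate_pct=self.min_rate_pct,
            max_rate_pct=self.max_rate_pct,
            fold_vs_each_control=self.fold_vs_each_control,
            min_replicates=self.min_replicates,
            high_conf_fold=self.high_conf_fold,
            min_control_coverage=self.min_control_coverage,
        )

    def validate(self) -> None:
        self.call_params().validate()
        if self.strandedness not in ("forward", "reverse", "unstranded"):
            raise ValueError(f"bad strandedness {self.strandedness!r}")
        if self.utr3_extension_bp < 0:
            raise ValueError("utr3_extension_bp must be non-negative")
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr must be in (0, 1]")
        if self.enrich_fold < 1 or self.kcl_fold < 1:
            raise ValueError("fold thresholds must be >= 1")

    @classmethod
    def load(cls, yaml_path=None, **overrides) -> "RunConfig":
        """Build a config from optional YAML plus keyword overrides."""
        values = {}
        if yaml_path is not None:
            with open(yaml_path) as fh:
                doc = yaml.safe_load(fh) or {}
            if not isinstance(doc, dict):
                raise ValueError("config file must be a flat key-value document")
            values.update(doc)
        values.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        defaults = cls()
        for k, v in values.items():
            if getattr(defaults, k) != v:
                log.info("config override: %s = %r", k, v)
        if "mito_chroms" in values:
            values["mito_chroms"] = tuple(values["mito_chroms"])
        cfg = cls(**values)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mito_chroms"] = list(d["mito_chroms"])
        return d
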