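"""Run configuration: one master seed plus the study-design constants.

Defaults reproduce the emulated design: four binary traits, 1% pool-merge
threshold, duplicate pools, alpha = 0.05, a family cohort of ~1,402 related
individuals, and a desk-scale panel of 5,000 autosomal variants with
MAF >= 1%.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .exceptions import ConfigError
from .simulate import DEFAULT_PREVALENCES


@dataclass
class RunConfig:
    master_seed: int = 0
    cohort_size: int = 1402
    family_distribution: dict = field(
        default_factory=lambda: {"mean_size": 4.0, "p_extended": 0.3}
    )
    prevalences: tuple = DEFAULT_PREVALENCES
    n_variants: int = 5000
    maf_beta: tuple = (1.0, 3.0)
    causal: dict = field(default_factory=dict)  # variant index -> liability effect
    shared_loading: float = 0.4
    family_variance: float = 0.2
    pool_threshold: float = 0.01
    n_replicates: int = 2
    n_chips: int = 2
    dirichlet_concentration: float = 50.0
    array_sd: float = 0.01
    alpha: float = 0.05
    require_t2d_case: bool = False
    reference: str = "normal"
    write_genotype_vcf: bool = True

    _REQUIRED = ("master_seed", "cohort_size", "n_variants")

    def validate(self) -> "RunConfig":
        checks = [
            ("cohort_size", self.cohort_size >= 10, ">= 10"),
            ("n_variants", self.n_variants >= 1, ">= 1"),
            ("pool_threshold", 0 <= self.pool_threshold < 1, "in [0, 1)"),
            ("n_replicates", self.n_replicates >= 1, ">= 1"),
            ("n_chips", self.n_chips >= 1, ">= 1"),
            ("dirichlet_concentration", self.dirichlet_concentration > 0, "> 0"),
            ("array_sd", self.array_sd >= 0, ">= 0"),
            ("alpha", 0 < self.alpha < 1, "in (0, 1)"),
            ("prevalences", len(self.prevalences) == 4
             and all(0 < p < 1 for p in self.prevalences), "four values in (0, 1)"),
            ("reference", self.reference in ("normal", "t"), "'normal' or 't'"),
        ]
        for name, ok, req in checks:
            if not ok:
                raise ConfigError(f"config field {name!r} must be {req}")
        return self

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["prevalences"] = list(self.prevalences)
        d["maf_beta"] = list(self.maf_beta)
        d["causal"] = {str(k): v for k, v in self.causal.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        missing = [k for k in cls._REQUIRED if k not in d]
        if missing:
            raise ConfigError(f"missing config field(s): {missing}")
        if "prevalences" in d:
            d["prevalences"] = tuple(d["prevalences"])
        if "maf_beta" in d:
            d["maf_beta"] = tuple(d["maf_beta"])
        if "causal" in d:
            d["causal"] = {int(k): float(v) for k, v in dict(d["causal"]).items()}
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
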