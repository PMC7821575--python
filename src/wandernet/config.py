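"""Run configuration: one YAML file drives a reproducible pipeline run."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .exceptions import InvalidParameterError
from .nbs import TAILS


@dataclass
class MFAOptions:
    n_components: int = 3
    scale: bool = True
    nested: bool = True
    n_boot: int = 10_000
    alpha: float = 0.05
    bonferroni: bool = True

    def validate(self):
        if self.n_components < 1:
            raise InvalidParameterError("mfa.n_components must be >= 1")
        if not 0 < self.alpha < 1:
            raise InvalidParameterError("mfa.alpha must be in (0, 1)")
        if self.n_boot < 2:
            raise InvalidParameterError("mfa.n_boot must be >= 2")


@dataclass
class NBSOptions:
    threshold: float = 4.7
    tails: tuple = ("positive", "negative")
    n_perm: int = 5000
    nuisance: str = "subject_indicators"
    component_stat: str = "extent"

    def validate(self):
        if self.threshold <= 0:
            raise InvalidParameterError("nbs.threshold must be positive")
        if self.n_perm < 100:
            raise InvalidParameterError("nbs.n_perm must be >= 100")
        bad = [t for t in self.tails if t not in TAILS]
        if bad:
            raise InvalidParameterError(f"nbs.tails contains invalid entries {bad}")
        if self.nuisance not in ("subject_indicators", "subject_mean"):
            raise InvalidParameterError(f"unknown nbs.nuisance {self.nuisance!r}")
        if self.component_stat not in ("extent", "intensity"):
            raise InvalidParameterError(
                f"unknown nbs.component_stat {self.component_stat!r}"
            )


@dataclass
class RunConfig:
    """Configuration of a simulate -> mfa -> nbs pipeline run.

    Either ``simulate`` parameters (passed to :class:`simulate.SimParams`)
    or input paths (``questionnaire``, ``connectivity_dir``) must be given.
    The global ``seed`` drives every stochastic stage through fixed child
    streams.
    """

    seed: int = 0
    output_dir: str = "wandernet_out"
    simulate: dict = field(default_factory=dict)
    questionnaire: str = None
    connectivity_dir: str = None
    score_component: int = 1
    mfa: MFAOptions = field(default_factory=MFAOptions)
    nbs: NBSOptions = field(default_factory=NBSOptions)

    def validate(self):
        self.mfa.validate()
        self.nbs.validate()
        sim_requested = self.simulate is not None and (
            self.questionnaire is None or self.connectivity_dir is None
        )
        if not sim_requested:
            for p, name in ((self.questionnaire, "questionnaire"),
                            (self.connectivity_dir, "connectivity_dir")):
                if p is not None and not Path(p).exists():
                    raise InvalidParameterError(f"{name} path {p!r} does not exist")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        mfa = MFAOptions(**d.pop("mfa", {}))
        nbs_opts = d.pop("nbs", {})
        if "tails" in nbs_opts:
            nbs_opts["tails"] = tuple(nbs_opts["tails"])
        nbs = NBSOptions(**nbs_opts)
        known = {f for f in cls.__dataclass_fields__ if f not in ("mfa", "nbs")}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config key(s) {sorted(unknown)}")
        return cls(mfa=mfa, nbs=nbs, **d).validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)
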