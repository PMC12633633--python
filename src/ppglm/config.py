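"""Run configuration: a flat YAML mapping with full validation.

Command-line flags override file values; every stochastic run records its
seed in the outputs.  Invalid estimator/link combinations (the polynomial
approximation is derived for the exp link only) are rejected at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml

__all__ = ["RunConfig", "parse_config"]

_ESTIMATORS = ("mc", "pa-c", "pa-d", "db", "hybrid")
_LINKS = ("exp", "softplus")


@dataclass
class RunConfig:
    estimator: str = "mc"
    link: str = "exp"
    basis_kind: str = "gl"
    J: int = 3
    H: float = 0.005
    alpha: float = 2.0
    c: float = 1.5
    M: int | None = None
    n_iter: int = 2000
    lr: float = 1e-2
    ridge: float = 0.0
    seed: int = 0
    bin_ms: float = 0.1
    batch_bins: int = 10_000
    range_mode: str = "mean_centered"
    range_width_hz: float = 5.0

    def __post_init__(self):
        if self.estimator not in _ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.link not in _LINKS:
            raise ValueError(f"unknown link {self.link!r}")
        if self.estimator in ("pa-c", "pa-d", "hybrid") and self.link != "exp":
            raise ValueError(
                f"estimator {self.estimator!r} supports only the exp link "
                f"(got {self.link!r}); use estimator=mc for softplus"
            )
        if self.J < 1 or self.H <= 0:
            raise ValueError("need J >= 1 and H > 0")

    def basis(self):
        from .basis import BasisSet

        return BasisSet(kind=self.basis_kind, J=self.J, H=self.H,
                        alpha=self.alpha, c=self.c)

    def mc_config(self):
        from .mc import MCFitConfig

        return MCFitConfig(M=self.M, n_iter=self.n_iter, lr=self.lr,
                           ridge=self.ridge, seed=self.seed)


def parse_config(path, **overrides) -> RunConfig:
    """Parse a YAML config file; unknown keys raise, overrides win."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a flat key/value mapping")
    known = {f.name for f in fields(RunConfig)}
    for key in doc:
        if key not in known:
            raise ValueError(f"{path}: unknown config key {key!r}")
    doc.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**doc)
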