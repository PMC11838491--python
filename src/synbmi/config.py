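"""Run configuration: defaults, validation, TOML/YAML loading."""

from __future__ import annotations

import dataclasses
import pathlib
from dataclasses import dataclass, field

from .synth import SynthConfig


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    Defaults mirror the study conditions: 20 ms bins, 10 bins (200 ms) of
    decoder history, a 90% VAF rule for synergy counts, 1000-permutation
    significance at alpha 0.05, and chronological 80/20 splits.
    """

    # synthetic session
    synth: SynthConfig = field(default_factory=SynthConfig)
    # signal processing
    sbp_band: tuple = (300.0, 1000.0)
    emg_band: tuple = (100.0, 500.0)
    bin_width: float = 0.020
    sbp_power: str = "abs"
    rms_multiplier: float = -4.5
    min_crossing_rate: float = 1.0
    # decoding
    lags: int = 10
    lambda_grid_min: float = 1e-4
    lambda_grid_max: float = 1e4
    lambda_grid_points: int = 9
    train_frac: float = 0.8
    # dimred
    vaf_threshold: float = 0.90
    aligned_len: int = 40
    nmf_max_iter: int = 300
    nmf_restarts: int = 2
    # stats
    alpha: float = 0.05
    n_perm: int = 1000
    # experiments
    component_fractions: tuple = (0.125, 0.25, 0.5, 0.75, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (0 < self.alpha < 1, "alpha", "must lie in (0, 1)"),
            (self.n_perm >= 100, "n_perm", "must be at least 100"),
            (self.lags >= 1, "lags", "must be at least 1"),
            (0 < self.train_frac < 1, "train_frac",
             "must lie strictly between 0 and 1"),
            (0 < self.vaf_threshold <= 1, "vaf_threshold",
             "must lie in (0, 1]"),
            (self.bin_width > 0, "bin_width", "must be positive"),
            (self.sbp_power in ("abs", "mean_square"), "sbp_power",
             "must be 'abs' or 'mean_square'"),
            (all(0 < f <= 1 for f in self.component_fractions),
             "component_fractions", "must lie in (0, 1]"),
        ]
        for ok, name, msg in checks:
            if not ok:
                raise ConfigError(f"{name}: {msg} (got "
                                  f"{getattr(self, name)!r})")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path) -> RunConfig:
    """Read a RunConfig from a TOML or YAML file (by extension)."""
    path = pathlib.Path(path)
    if path.suffix in (".toml", ".tml"):
        import tomllib
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    elif path.suffix in (".yaml", ".yml"):
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raise ConfigError(f"unknown config format {path.suffix!r}; use "
                          f".toml or .yaml")
    synth_raw = raw.pop("synth", {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    try:
        synth = SynthConfig(**synth_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"synth: {exc}") from exc
    for key in ("component_fractions", "sbp_band", "emg_band"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        return RunConfig(synth=synth, **raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
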