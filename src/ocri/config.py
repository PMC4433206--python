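"""Run configuration: every tunable constant of the pipeline in one place.

The defaults are the method's published constants (amplification weights,
hypothetical component shapes, ploidy windows). Overriding any of them is
legal but is reported by :meth:`RunConfig.changed_fields` so the CLI can log
the deviation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


@dataclasses.dataclass
class RunConfig:
    # --- signal amplification -------------------------------------------
    #: combined diploid+tetraploid weight when all three populations exist
    pair_weight_three: float = 0.9
    #: combined diploid+tetraploid weight when the aneuploid peak is hypothetical
    pair_weight_two: float = 0.995
    #: aneuploid weight in the one- and two-population paths
    r3_floor: float = 0.005
    #: range of the uniform draw for R1 when only a diploid population exists
    r1_range: tuple[float, float] = (0.75, 0.8)
    #: (mean, sd) of the hypothetical tetraploid component
    hypothetical_tetraploid: tuple[float, float] = (2.0, 0.3)
    #: (mean, sd) of the hypothetical aneuploid component
    hypothetical_aneuploid: tuple[float, float] = (2.3, 0.3)

    # --- density estimation / peak identification -----------------------
    grid_step: float = 0.01
    #: minimal peak prominence as a fraction of the maximum density height
    min_prominence: float = 0.005
    bandwidth_floor: float = 1e-3

    # --- population windows ---------------------------------------------
    #: a diploid peak must sit below this DI
    diploid_max: float = 1.5
    #: DI window labelling a secondary peak as tetraploid
    tetraploid_window: tuple[float, float] = (1.5, 2.3)
    #: DI at and above which a cell counts as aneuploid
    aneuploid_threshold: float = 2.3
    #: cells beyond mean + extraction_span * sd are never claimed by a population
    extraction_span: float = 4.0
    #: below this many cells KDE is skipped and windows assign populations
    small_sample_n: int = 10

    # --- reconstruction --------------------------------------------------
    bin_filler: float = 0.0001
    di_clamp: float = 8.0

    # --- simulation -------------------------------------------------------
    cells_range: tuple[int, int] = (1000, 4000)

    # --- risk model -------------------------------------------------------
    #: nine-value geometric cost grid 2^-2 ... 2^6
    cost_grid: tuple[float, ...] = tuple(float(2.0**k) for k in range(-2, 7))
    cv_folds: int = 10
    cv_repeats: int = 5
    scale_floor: float = 1e-8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for field in dataclasses.fields(cls):
            if field.name in raw and isinstance(raw[field.name], list):
                raw[field.name] = tuple(raw[field.name])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def changed_fields(self) -> dict:
        """Fields that deviate from the published defaults."""
        ref = RunConfig()
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) != getattr(ref, f.name)
        }


DEFAULT_CONFIG = RunConfig()
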