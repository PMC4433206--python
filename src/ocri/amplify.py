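"""Signal amplification and 16-bin feature reconstruction.

Aneuploid cells carry the diagnostic signal but are a tiny fraction of a
sample, so their contribution is re-weighted before reconstruction. With
population ratios R1 (diploid), R2 (tetraploid), R3 (aneuploid) and the
constraint R1 + R2 + R3 = 1:

* all three populations observed — R1:R2 is preserved, R1 + R2 = 0.9, so
  the aneuploid weight becomes R3 = 0.1;
* diploid and tetraploid only — R1:R2 preserved, R1 + R2 = 0.995, and a
  hypothetical aneuploid component Norm(2.3, 0.3) takes R3 = 0.005;
* diploid only — R1 ~ Unif[0.75, 0.8], R2 = 0.995 - R1, R3 = 0.005, with
  hypothetical tetraploid Norm(2.0, 0.3) and aneuploid Norm(2.3, 0.3).

The amplified three-Gaussian mixture is then integrated over the 16
half-open DI intervals [0, 0.5), ..., [7.5, 8.0]; mass beyond DI 8 is
clamped into the last bin, and any bin below 0.0001 is set to the 0.0001
filler. Interval probability masses (not point densities) are used so that
rows are comparable across cases and sum to ~1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import norm

from .config import DEFAULT_CONFIG, RunConfig
from .decompose import DecompositionResult, decompose
from .exceptions import ValidationError
from .io import BIN_EDGES, DICase

__all__ = [
    "AmplifiedComponent",
    "AmplifiedMixture",
    "FeatureVector",
    "amplify",
    "reconstruct",
    "edtar_transform",
    "transform_cohort",
]


@dataclasses.dataclass(frozen=True)
class AmplifiedComponent:
    kind: str  # diploid | tetraploid | aneuploid
    mean: float
    sd: float
    weight: float
    observed: bool  # False for hypothetical components


@dataclasses.dataclass(frozen=True)
class AmplifiedMixture:
    """Exactly three weighted Gaussian components after amplification."""

    components: tuple[AmplifiedComponent, AmplifiedComponent, AmplifiedComponent]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.components) != 3:
            raise ValidationError("amplified mixture needs exactly 3 components")
        weights = [c.weight for c in self.components]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError(f"R1+R2+R3 must equal 1, got {sum(weights)!r}")
        if any(w <= 0 for w in weights):
            raise ValidationError("all amplified weights must be positive")
        means = [c.mean for c in self.components]
        if not (means[0] < means[1] < means[2]):
            raise ValidationError(
                f"component means must be ordered diploid < tetraploid < "
                f"aneuploid, got {means}"
            )

    @property
    def weights(self) -> tuple[float, float, float]:
        return tuple(c.weight for c in self.components)  # type: ignore[return-value]


@dataclasses.dataclass
class FeatureVector:
    """16 non-negative interval masses over DI [0, 8]; the model input."""

    bins: np.ndarray
    case_id: str
    label: str | None = None

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (16,):
            raise ValidationError(f"feature vector must have 16 bins, got {self.bins.shape}")
        if np.min(self.bins) < 0.0001 - 1e-12:
            raise ValidationError("every bin must be >= 0.0001")


def _observed(pop, kind: str) -> AmplifiedComponent | None:
    if pop is None:
        return None
    # a zero spread (degenerate population) still needs a usable shape
    sd = pop.sd if pop.sd > 1e-6 else 1e-3
    return AmplifiedComponent(kind, pop.mean, sd, weight=np.nan, observed=True)


def amplify(
    dec: DecompositionResult,
    seed: int | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> AmplifiedMixture:
    """Apply the three-case amplification rules to a decomposition."""
    if not dec.populations:
        raise ValidationError(f"case {dec.case_id!r}: no populations to amplify")
    rng = np.random.default_rng(seed)

    diploid = _observed(dec.population("diploid"), "diploid")
    tetraploid = _observed(dec.population("tetraploid"), "tetraploid")
    aneuploid = _observed(dec.population("aneuploid"), "aneuploid")
    if diploid is None:
        raise ValidationError(f"case {dec.case_id!r}: no diploid population")

    r_diploid = dec.population("diploid").ratio
    hyp_tet = AmplifiedComponent(
        "tetraploid", *config.hypothetical_tetraploid, weight=np.nan, observed=False
    )
    hyp_aneu = AmplifiedComponent(
        "aneuploid", *config.hypothetical_aneuploid, weight=np.nan, observed=False
    )

    if aneuploid is not None:
        # amplified path: the aneuploid signal takes 1 - 0.9 = 0.1
        pair = config.pair_weight_three
        if tetraploid is not None:
            r_tet = dec.population("tetraploid").ratio
            r1 = pair * r_diploid / (r_diploid + r_tet)
            r2 = pair - r1
        else:
            # diploid + aneuploid without a tetraploid peak: R1 drawn as in
            # the diploid-only rule, hypothetical tetraploid fills the rest
            r1 = float(rng.uniform(*config.r1_range))
            r2 = pair - r1
            tetraploid = hyp_tet
        r3 = 1.0 - pair
    elif tetraploid is not None:
        pair = config.pair_weight_two
        r_tet = dec.population("tetraploid").ratio
        r1 = pair * r_diploid / (r_diploid + r_tet)
        r2 = pair - r1
        r3 = config.r3_floor
        aneuploid = hyp_aneu
    else:
        r1 = float(rng.uniform(*config.r1_range))
        r2 = config.pair_weight_two - r1
        r3 = 1.0 - r1 - r2  # = 1 - 0.995 = 0.005
        tetraploid = hyp_tet
        aneuploid = hyp_aneu

    components = tuple(
        dataclasses.replace(comp, weight=w)
        for comp, w in zip((diploid, tetraploid, aneuploid), (r1, r2, r3))
    )
    return AmplifiedMixture(components=components, seed=seed)


def reconstruct(
    mix: AmplifiedMixture,
    case_id: str = "case",
    label: str | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> FeatureVector:
    """Integrate the amplified mixture over the 16 DI intervals.

    Bin value = probability mass of the weighted three-Gaussian mixture on
    the interval; mass below 0 folds into the first bin and mass beyond the
    DI clamp (8) folds into the last; bins below the filler are set to it.
    """
    edges = BIN_EDGES
    masses = np.zeros(len(edges) - 1)
    for comp in mix.components:
        cdf = norm.cdf(edges, loc=comp.mean, scale=comp.sd)
        masses += comp.weight * np.diff(cdf)
        masses[0] += comp.weight * cdf[0]  # below-zero mass
        masses[-1] += comp.weight * norm.sf(
            config.di_clamp, loc=comp.mean, scale=comp.sd
        )
    masses = np.maximum(masses, config.bin_filler)
    return FeatureVector(bins=masses, case_id=case_id, label=label)


def edtar_transform(
    case: DICase,
    seed: int | None = None,
    bandwidth: float | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> FeatureVector:
    """Full per-case transform: decompose -> amplify -> reconstruct."""
    dec = decompose(case, bandwidth=bandwidth, config=config)
    mix = amplify(dec, seed=seed, config=config)
    return reconstruct(mix, case_id=case.case_id, label=case.label, config=config)


def transform_cohort(
    cases,
    seed: int | None = None,
    config: RunConfig = DEFAULT_CONFIG,
):
    """Transform every case; returns (feature vectors, unanalyzable case ids).

    Per-case seeds derive deterministically from the cohort seed and the
    case's position, so single cases are reproducible.
    """
    from .exceptions import UnanalyzableCaseError
    from .synthetic import case_seed

    vectors: list[FeatureVector] = []
    skipped: list[str] = []
    for index, case in enumerate(cases):
        sub_seed = case_seed(seed, index) if seed is not None else None
        try:
            vectors.append(edtar_transform(case, seed=sub_seed, config=config))
        except UnanalyzableCaseError:
            skipped.append(case.case_id)
    return vectors, skipped
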