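"""Synthetic DNA-index (DI) cytometry.

DNA image cytometry of Feulgen-stained exfoliated oral mucosa cells yields,
per nucleus, a DNA index: the ratio of integrated optical density to the
diploid reference (DI 1 = 2N, DI 2 = 4N). A sample is well described by a
Gaussian mixture: a dominant diploid population near DI 1, a small
tetraploid population near DI 2, and — in dysplastic or malignant lesions —
an aneuploid fraction at DI >= 2.3.

This module draws per-case DI samples from such mixtures so the whole
pipeline is testable without patient data. The reference three-population
mixture (diploid mu=1.001 sigma=0.19, tetraploid mu=2.002 sigma=0.25,
aneuploid mu=2.300 sigma=0.5, mixed 0.893:0.092:0.005) reproduces a typical
OSCC-adjacent sample; the case profiles operationalize typical normal, oral
leukoplakia (OLK) and OSCC ploidy patterns.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .exceptions import EmptyCohortError, ValidationError
from .io import DICase

__all__ = [
    "MixtureComponent",
    "MixtureSpec",
    "CaseProfile",
    "reference_mixture",
    "normal_profile",
    "olk_profile",
    "oscc_profile",
    "default_profiles",
    "simulate_case",
    "simulate_cohort",
    "case_seed",
]


@dataclasses.dataclass(frozen=True)
class MixtureComponent:
    """One Gaussian cell population: DI mean, DI sd, mixture weight."""

    mean: float
    sd: float
    weight: float
    kind: str = "other"  # diploid | tetraploid | aneuploid | other


@dataclasses.dataclass(frozen=True)
class MixtureSpec:
    """A per-case generating mixture plus sample size and seed."""

    components: tuple[MixtureComponent, ...]
    n_cells: int
    seed: int

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError("mixture needs at least one component")
        weights = np.array([c.weight for c in self.components])
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"component weights must sum to 1, got {weights.sum()!r}"
            )
        if any(c.sd <= 0 for c in self.components):
            raise ValidationError("component sd must be positive")
        if any(c.mean <= 0 for c in self.components):
            raise ValidationError("component means must be positive")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")

    @property
    def mean(self) -> float:
        """Closed-form mixture mean, sum(w_i * mu_i)."""
        return float(sum(c.weight * c.mean for c in self.components))

    def tail_mass(self, threshold: float) -> float:
        """Mixture probability of DI >= threshold (normal CDF closed form)."""
        from scipy.stats import norm

        return float(
            sum(c.weight * norm.sf(threshold, c.mean, c.sd) for c in self.components)
        )


@dataclasses.dataclass(frozen=True)
class CaseProfile:
    """A named mixture template for one diagnostic group."""

    name: str  # normal | olk | oscc
    components: tuple[MixtureComponent, ...]

    def __post_init__(self) -> None:
        aneuploid_w = self.aneuploid_weight
        if self.name == "normal" and aneuploid_w > 0.001:
            raise ValidationError(
                f"normal profile aneuploid weight {aneuploid_w} > 0.001"
            )
        if self.name == "oscc" and aneuploid_w < 0.02:
            raise ValidationError(
                f"oscc profile aneuploid weight {aneuploid_w} < 0.02"
            )

    @property
    def aneuploid_weight(self) -> float:
        return float(
            sum(c.weight for c in self.components if c.kind == "aneuploid")
        )

    def spec(self, n_cells: int, seed: int) -> MixtureSpec:
        return MixtureSpec(components=self.components, n_cells=n_cells, seed=seed)


def reference_mixture(n_cells: int = 4000, seed: int = 0) -> MixtureSpec:
    """The reference three-population mixture, ratio 0.893 : 0.092 : 0.005.

    The stated ratio sums to 0.990, so it is normalized to mixture weights.
    """
    total = 0.893 + 0.092 + 0.005
    return MixtureSpec(
        components=(
            MixtureComponent(1.001, 0.19, 0.893 / total, "diploid"),
            MixtureComponent(2.002, 0.25, 0.092 / total, "tetraploid"),
            MixtureComponent(2.300, 0.50, 0.005 / total, "aneuploid"),
        ),
        n_cells=n_cells,
        seed=seed,
    )


def normal_profile(aneuploid_weight: float = 0.0) -> CaseProfile:
    """Healthy mucosa: essentially pure diploid plus a small, tight
    tetraploid fraction (cycling cells); healthy samples carry no
    aneuploid cells, mirroring uniformly negative conventional cytology."""
    components = [
        MixtureComponent(1.001, 0.19, 1.0 - 0.004 - aneuploid_weight, "diploid"),
        MixtureComponent(2.0, 0.12, 0.004, "tetraploid"),
    ]
    if aneuploid_weight > 0:
        components.append(
            MixtureComponent(2.35, 0.30, aneuploid_weight, "aneuploid")
        )
    return CaseProfile(name="normal", components=tuple(components))


def olk_profile() -> CaseProfile:
    """Oral leukoplakia: dominant diploid peak plus satellite peaks near
    DI 1.25, 1.75, 2.22 and 2.74 (a typical multi-peak premalignant pattern)."""
    return CaseProfile(
        name="olk",
        components=(
            MixtureComponent(1.00, 0.19, 0.82, "diploid"),
            MixtureComponent(1.25, 0.12, 0.06, "other"),
            MixtureComponent(1.75, 0.12, 0.06, "tetraploid"),
            MixtureComponent(2.22, 0.12, 0.04, "other"),
            MixtureComponent(2.74, 0.20, 0.02, "aneuploid"),
        ),
    )


def oscc_profile() -> CaseProfile:
    """OSCC: diploid + tetraploid populations and a clear aneuploid burden
    with high-DI peaks (near DI 3.2-4.0)."""
    return CaseProfile(
        name="oscc",
        components=(
            MixtureComponent(1.02, 0.19, 0.78, "diploid"),
            MixtureComponent(1.79, 0.25, 0.15, "tetraploid"),
            MixtureComponent(3.25, 0.30, 0.030, "aneuploid"),
            MixtureComponent(3.57, 0.30, 0.025, "aneuploid"),
            MixtureComponent(3.99, 0.30, 0.015, "aneuploid"),
        ),
    )


def default_profiles() -> dict[str, CaseProfile]:
    return {
        "normal": normal_profile(),
        "olk": olk_profile(),
        "oscc": oscc_profile(),
    }


def simulate_case(
    spec: MixtureSpec, case_id: str = "case", label: str | None = None
) -> DICase:
    """Draw one case from a mixture; negative/zero draws are redrawn.

    DI is a ratio of optical densities and strictly positive; at the
    parameter values in use P(X <= 0) is negligible, so rejection introduces
    no measurable truncation bias. The generating component index of every
    cell is kept on the returned case for ground-truth checks.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components])
    means = np.array([c.mean for c in spec.components])
    sds = np.array([c.sd for c in spec.components])

    comp = rng.choice(len(weights), size=spec.n_cells, p=weights / weights.sum())
    values = rng.normal(means[comp], sds[comp])
    bad = values <= 0
    while bad.any():
        values[bad] = rng.normal(means[comp[bad]], sds[comp[bad]])
        bad = values <= 0
    return DICase(
        case_id=case_id,
        di_values=values,
        label=label,
        true_components=comp,
        seed=spec.seed,
    )


def case_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-case seed derived from (cohort seed, case index)."""
    return int(
        np.random.SeedSequence([int(cohort_seed), int(index)]).generate_state(1)[0]
        % (2**31)
    )


def simulate_cohort(
    n_normal: int,
    n_olk: int,
    n_oscc: int,
    seed: int,
    cells_range: tuple[int, int] = (1000, 4000),
    profiles: dict[str, CaseProfile] | None = None,
) -> list[DICase]:
    """Simulate a labelled cohort; per-case seeds derive from the cohort seed.

    Per-case cell counts are drawn uniformly from ``cells_range`` (the scale
    of a routine brush biopsy, a few thousand measurable nuclei).
    """
    counts = {"normal": n_normal, "olk": n_olk, "oscc": n_oscc}
    if any(v < 0 for v in counts.values()):
        raise ValidationError("cohort counts must be >= 0")
    if sum(counts.values()) == 0:
        raise EmptyCohortError("cohort has zero cases")
    profiles = profiles or default_profiles()
    rng = np.random.default_rng(seed)
    cases: list[DICase] = []
    index = 0
    for label in ("normal", "olk", "oscc"):
        for k in range(counts[label]):
            n_cells = int(rng.integers(cells_range[0], cells_range[1] + 1))
            spec = profiles[label].spec(n_cells=n_cells, seed=case_seed(seed, index))
            cases.append(
                simulate_case(spec, case_id=f"{label}_{k:04d}", label=label)
            )
            index += 1
    return cases


def component_fractions(case: DICase) -> np.ndarray:
    """Empirical ground-truth component fractions of a simulated case."""
    if case.true_components is None:
        raise ValidationError("case carries no ground-truth components")
    counts = np.bincount(case.true_components)
    return counts / counts.sum()
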