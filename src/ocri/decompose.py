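"""Sequential extraction of diploid/tetraploid populations and isolation of
the aneuploid population.

The procedure is geometric, not likelihood-based: the dominant KDE peak
below DI 1.5 is the diploid population; its spread is estimated from the
left flank only (the right flank is contaminated by higher-ploidy cells)
under a half-normal assumption, and the right side is removed by mirroring
the left-side cell counts. A remaining peak in the tetraploid window
[1.5, 2.3) is extracted the same way. Every residual cell at DI >= 2.3 is
the aneuploid population; residual cells below 2.3 are reassigned to the
nearest extracted population so that counts are conserved.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import DEFAULT_CONFIG, RunConfig
from .density import DensityEstimate, Peak, estimate_density, find_density_peaks
from .exceptions import UnanalyzableCaseError, ValidationError
from .io import DICase

__all__ = [
    "PopulationSummary",
    "DecompositionResult",
    "extract_population",
    "decompose",
]


@dataclasses.dataclass
class PopulationSummary:
    """Mean, spread and cell count of one extracted population."""

    kind: str  # diploid | tetraploid | aneuploid
    mean: float
    sd: float
    count: int
    ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0 or self.count < 0 or not (0 <= self.ratio <= 1):
            raise ValidationError(f"invalid population summary: {self}")


@dataclasses.dataclass
class DecompositionResult:
    """Per-case populations plus the summary statistics of the raw data."""

    case_id: str
    populations: list[PopulationSummary]
    n_total: int
    di_mean: float
    di_sd: float
    peak_locations: list[float]
    aneuploid_max_di: float | None = None
    assignments: np.ndarray | None = None  # per-cell population kind
    bandwidth: float | None = None
    label: str | None = None

    def population(self, kind: str) -> PopulationSummary | None:
        for pop in self.populations:
            if pop.kind == kind:
                return pop
        return None

    @property
    def kinds(self) -> list[str]:
        return [p.kind for p in self.populations]


def _half_normal_sd(values: np.ndarray, peak: Peak, center: float) -> float:
    """Spread from the left flank only: sqrt(mean((x - c)^2)) over
    left_bound <= x <= c (half-normal assumption; the right flank is
    contaminated by higher-ploidy cells)."""
    left = values[(values >= peak.left_bound) & (values <= center)]
    if left.size == 0:
        return 0.0
    return float(np.sqrt(np.mean((left - center) ** 2)))


def _extract_indices(
    values: np.ndarray, peak: Peak, span: float = 4.0
) -> tuple[PopulationSummary, np.ndarray]:
    """Indices of the cells claimed by the population under ``peak``.

    The left flank (within the peak's bounds) is taken wholesale; on the
    right, the mirrored expectation is matched by removing the same number
    of cells in order of increasing deviation, so any excess — the cells of
    a higher-ploidy population — survives as residual, as does everything
    beyond the center + span * sd.

    The KDE mode has location error of order the bandwidth, which would
    unbalance the left/right counts; the mirror center is therefore the
    median of the cells inside the peak's support [left_bound, p + 4 sd],
    which balances the two flanks exactly for a symmetric population while
    the reach cap keeps separated higher-ploidy cells out.
    """
    p = float(peak.location)
    if not (values.min() <= p <= values.max()):
        raise ValidationError(
            f"peak at {p} lies outside the data span "
            f"[{values.min()}, {values.max()}]"
        )
    sd0 = _half_normal_sd(values, peak, center=p)
    support = values[
        (values >= peak.left_bound) & (values <= p + span * sd0)
    ]
    center = float(np.median(support)) if support.size else p
    sd = _half_normal_sd(values, peak, center=center)

    left_idx = np.flatnonzero((values >= peak.left_bound) & (values <= center))
    reach = center + span * sd if sd > 0 else center
    right_idx = np.flatnonzero((values > center) & (values <= reach))
    # mirror: keep as many right-side cells as there are left-side cells,
    # closest deviations first
    order = np.argsort(values[right_idx] - center, kind="stable")
    right_idx = right_idx[order[: left_idx.size]]
    taken = np.concatenate([left_idx, right_idx])
    summary = PopulationSummary(
        kind="unlabelled", mean=p, sd=sd, count=int(taken.size)
    )
    return summary, taken


def extract_population(
    values: np.ndarray, peak: Peak, span: float = 4.0
) -> tuple[PopulationSummary, np.ndarray]:
    """Extract the population under ``peak``; returns (summary, residual).

    See :func:`_extract_indices` for the mirror rule. ``span`` bounds the
    population at location + span * sd.
    """
    values = np.asarray(values, dtype=float)
    summary, taken = _extract_indices(values, peak, span=span)
    residual = np.delete(values, taken)
    return summary, residual


def _window_decompose(case: DICase, config: RunConfig) -> DecompositionResult:
    """Small-sample path: fixed ploidy windows instead of KDE."""
    values = case.di_values
    windows = {
        "diploid": (0.0, config.diploid_max),
        "tetraploid": (config.diploid_max, config.aneuploid_threshold),
        "aneuploid": (config.aneuploid_threshold, np.inf),
    }
    assignments = np.empty(values.size, dtype=object)
    populations = []
    for kind, (lo, hi) in windows.items():
        mask = (values >= lo) & (values < hi)
        if not mask.any():
            continue
        assignments[mask] = kind
        sub = values[mask]
        populations.append(
            PopulationSummary(
                kind=kind,
                mean=float(sub.mean()),
                sd=float(sub.std()) if sub.size > 1 else 0.0,
                count=int(mask.sum()),
                ratio=float(mask.sum() / values.size),
            )
        )
    if not any(p.kind == "diploid" for p in populations):
        raise UnanalyzableCaseError(case.case_id, "no cells below the diploid bound")
    aneu = [p for p in populations if p.kind == "aneuploid"]
    return DecompositionResult(
        case_id=case.case_id,
        populations=populations,
        n_total=values.size,
        di_mean=float(values.mean()),
        di_sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        peak_locations=[p.mean for p in populations],
        aneuploid_max_di=float(values.max()) if aneu else None,
        assignments=assignments,
        bandwidth=None,
        label=case.label,
    )


def decompose(
    case: DICase,
    bandwidth: float | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> DecompositionResult:
    """Decompose one case into diploid / tetraploid / aneuploid populations.

    Steps: (a) KDE and peak identification; (b) the dominant peak below
    DI 1.5 is extracted as diploid (a case without one is unanalyzable);
    (c) a remaining peak in [1.5, 2.3) is extracted as tetraploid; (d) all
    residual cells at DI >= 2.3 form the aneuploid population; residual
    cells below 2.3 are reassigned to the nearest population in
    |DI - mean| / sd distance. Counts are conserved exactly.
    """
    values = case.di_values
    if values.size < config.small_sample_n:
        return _window_decompose(case, config)

    dens: DensityEstimate = estimate_density(values, bandwidth=bandwidth, config=config)
    peaks = find_density_peaks(dens, config=config)
    peak_locations = [p.location for p in peaks]

    diploid_candidates = [
        p for p in peaks if p.location < config.diploid_max and p.kind == "mode"
    ]
    if not diploid_candidates:
        raise UnanalyzableCaseError(
            case.case_id, f"no density peak below DI {config.diploid_max}"
        )
    diploid_peak = max(diploid_candidates, key=lambda p: p.height)

    assignments = np.empty(values.size, dtype=object)
    remaining = np.arange(values.size)

    summary, taken_local = _extract_indices(
        values, diploid_peak, span=config.extraction_span
    )
    diploid = dataclasses.replace(summary, kind="diploid")
    assignments[remaining[taken_local]] = "diploid"
    remaining = np.delete(remaining, taken_local)
    populations = [diploid]

    tet_lo, tet_hi = config.tetraploid_window
    tet_candidates = [
        p
        for p in peaks
        if tet_lo <= p.location < tet_hi and p is not diploid_peak
    ]
    if tet_candidates and remaining.size:
        tet_peak = max(tet_candidates, key=lambda p: p.height)
        res_values = values[remaining]
        if res_values.min() <= tet_peak.location <= res_values.max():
            summary, taken_local = _extract_indices(
                res_values, tet_peak, span=config.extraction_span
            )
            if summary.count > 0:
                tetraploid = dataclasses.replace(summary, kind="tetraploid")
                assignments[remaining[taken_local]] = "tetraploid"
                remaining = np.delete(remaining, taken_local)
                populations.append(tetraploid)

    res_values = values[remaining]
    aneu_mask = res_values >= config.aneuploid_threshold
    aneuploid_max = None
    if aneu_mask.any():
        aneu = res_values[aneu_mask]
        populations.append(
            PopulationSummary(
                kind="aneuploid",
                mean=float(aneu.mean()),
                sd=float(aneu.std(ddof=1)) if aneu.size > 1 else 0.0,
                count=int(aneu.size),
            )
        )
        aneuploid_max = float(aneu.max())
        assignments[remaining[aneu_mask]] = "aneuploid"
        remaining = remaining[~aneu_mask]

    # residual cells below the aneuploid threshold: nearest population by
    # standardized distance, so that counts are conserved
    if remaining.size:
        index_of = {p.kind: i for i, p in enumerate(populations)}
        anchors = [
            p for p in populations if p.kind in ("diploid", "tetraploid")
        ] or populations
        res = values[remaining]
        dist = np.vstack(
            [np.abs(res - p.mean) / max(p.sd, 1e-6) for p in anchors]
        )
        nearest = np.argmin(dist, axis=0)
        for j, p in enumerate(anchors):
            extra = int((nearest == j).sum())
            if extra:
                k = index_of[p.kind]
                populations[k] = dataclasses.replace(
                    p, count=p.count + extra
                )
            assignments[remaining[nearest == j]] = p.kind

    populations = [
        dataclasses.replace(p, ratio=p.count / values.size) for p in populations
    ]
    return DecompositionResult(
        case_id=case.case_id,
        populations=populations,
        n_total=int(values.size),
        di_mean=float(values.mean()),
        di_sd=float(values.std(ddof=1)),
        peak_locations=peak_locations,
        aneuploid_max_di=aneuploid_max,
        assignments=assignments,
        bandwidth=dens.bandwidth,
        label=case.label,
    )


def decomposition_table(results: list[DecompositionResult]):
    """Audit table: one row per (case, population)."""
    import pandas as pd

    rows = []
    for res in results:
        for pop in res.populations:
            rows.append(
                {
                    "case_id": res.case_id,
                    "kind": pop.kind,
                    "mean": pop.mean,
                    "sd": pop.sd,
                    "count": pop.count,
                    "ratio": pop.ratio,
                }
            )
    return pd.DataFrame(rows)
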