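"""Sequential population extraction: the geometric mirror rule and windows."""

import numpy as np
import pytest

from ocri.decompose import decompose, extract_population
from ocri.density import Peak, estimate_density, find_density_peaks
from ocri.exceptions import UnanalyzableCaseError, ValidationError
from ocri.io import DICase
from ocri.synthetic import (
    MixtureComponent,
    MixtureSpec,
    reference_mixture,
    simulate_case,
)

SEPARATED = MixtureSpec(
    (
        MixtureComponent(1.0, 0.1, 0.70, "diploid"),
        MixtureComponent(2.0, 0.1, 0.25, "tetraploid"),
        MixtureComponent(3.0, 0.1, 0.05, "aneuploid"),
    ),
    n_cells=2000,
    seed=0,
)


def kde_top_peak(values):
    dens = estimate_density(values)
    return max(find_density_peaks(dens), key=lambda p: p.height)


class TestExtractPopulation:
    def test_pure_normal_extraction(self):
        """On a single Gaussian population the mirror rule should claim
        nearly everything and recover the true spread."""
        for seed in range(20):
            values = np.random.default_rng(seed).normal(1.0, 0.2, 2000)
            values = values[values > 0]
            summary, residual = extract_population(values, kde_top_peak(values))
            assert residual.size <= 0.05 * values.size
            assert 0.17 <= summary.sd <= 0.23

    def test_mixture_residual_fraction(self):
        """Extracting the dominant component leaves the minor one as residual."""
        spec = MixtureSpec(
            (MixtureComponent(1.0, 0.15, 0.9), MixtureComponent(2.0, 0.15, 0.1)),
            n_cells=2000,
            seed=0,
        )
        fractions = []
        for seed in range(5):
            case = simulate_case(
                MixtureSpec(spec.components, spec.n_cells, seed=seed)
            )
            values = case.di_values
            _, residual = extract_population(values, kde_top_peak(values))
            fractions.append(residual.size / values.size)
        assert abs(np.mean(fractions) - 0.1) < 0.03

    def test_mirror_removes_balanced_counts(self):
        values = np.random.default_rng(3).normal(1.0, 0.2, 2000)
        peak = kde_top_peak(values)
        summary, residual = extract_population(values, peak)
        removed = values.size - residual.size
        left = np.count_nonzero(
            (values >= peak.left_bound) & (values <= peak.location)
        )
        right = removed - left
        assert abs(left - right) <= np.sqrt(values.size)

    def test_peak_outside_span_is_contract_error(self):
        values = np.linspace(0.8, 1.2, 100)
        with pytest.raises(ValidationError):
            extract_population(
                values, Peak(location=5.0, height=1.0, prominence=1.0,
                             left_bound=4.5, right_bound=5.5)
            )


class TestDecompose:
    def test_single_population_path(self):
        spec = MixtureSpec(
            (MixtureComponent(1.0, 0.19, 1.0, "diploid"),), n_cells=1500, seed=1
        )
        dec = decompose(simulate_case(spec, case_id="pure"))
        assert dec.kinds == ["diploid"]
        assert dec.populations[0].ratio == pytest.approx(1.0)
        assert dec.aneuploid_max_di is None

    def test_reference_mixture_mean_recovery(self):
        """Recovered diploid and tetraploid means, averaged over seeds, hit
        the generating component means (1.001 and 2.002)."""
        diploid, tetraploid = [], []
        for seed in range(20):
            case = simulate_case(reference_mixture(4000, seed=seed))
            dec = decompose(case)
            diploid.append(dec.population("diploid").mean)
            tet = dec.population("tetraploid")
            if tet is not None:
                tetraploid.append(tet.mean)
        assert abs(np.mean(diploid) - 1.001) <= 0.05
        assert len(tetraploid) >= 15
        assert abs(np.mean(tetraploid) - 2.002) <= 0.08

    def test_aneuploid_count_exact(self):
        """Seven clearly separated high-DI cells survive extraction intact."""
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.uniform(0.9, 1.1, 400), np.full(7, 3.0)])
        dec = decompose(DICase("seven", values))
        assert dec.population("aneuploid").count == 7

    def test_count_conservation(self, small_cohort):
        for case in small_cohort[:8]:
            dec = decompose(case)
            assert sum(p.count for p in dec.populations) == dec.n_total
            assert abs(sum(p.ratio for p in dec.populations) - 1.0) < 1e-6
            assert (dec.assignments != None).all()  # noqa: E711

    def test_summary_statistics_present(self, reference_case):
        dec = decompose(reference_case)
        assert dec.n_total == 4000
        assert dec.di_mean > 0 and dec.di_sd > 0
        assert len(dec.peak_locations) >= 2

    def test_aneuploid_max_di_recorded(self):
        case = simulate_case(MixtureSpec(SEPARATED.components, 2000, seed=6))
        dec = decompose(case)
        assert dec.aneuploid_max_di is not None
        assert dec.aneuploid_max_di == pytest.approx(case.di_values.max())

    def test_ratio_recovery_separated_mixture(self):
        """With >= 4 sd separation each recovered ratio is within 0.05 of
        the generating weight in >= 90% of seeds."""
        truth = {"diploid": 0.70, "tetraploid": 0.25, "aneuploid": 0.05}
        hits = 0
        for seed in range(10):
            case = simulate_case(
                MixtureSpec(SEPARATED.components, 2000, seed=seed)
            )
            dec = decompose(case)
            ok = all(
                dec.population(kind) is not None
                and abs(dec.population(kind).ratio - w) < 0.05
                for kind, w in truth.items()
            )
            hits += ok
        assert hits >= 9

    def test_cell_assignment_matches_ground_truth(self):
        kinds = np.array(["diploid", "tetraploid", "aneuploid"])
        agree = []
        for seed in range(5):
            case = simulate_case(MixtureSpec(SEPARATED.components, 2000, seed=seed))
            dec = decompose(case)
            truth = kinds[case.true_components]
            agree.append(np.mean(dec.assignments == truth))
        assert np.mean(agree) >= 0.90

    def test_duplication_invariance_at_fixed_bandwidth(self):
        case = simulate_case(MixtureSpec(SEPARATED.components, 1000, seed=4))
        doubled = DICase("dup", np.concatenate([case.di_values, case.di_values]))
        dec1 = decompose(case, bandwidth=0.05)
        dec2 = decompose(doubled, bandwidth=0.05)
        r1 = {p.kind: p.ratio for p in dec1.populations}
        r2 = {p.kind: p.ratio for p in dec2.populations}
        assert r1.keys() == r2.keys()
        for kind in r1:
            assert abs(r1[kind] - r2[kind]) < 1e-6

    def test_no_diploid_peak_flagged(self):
        values = np.random.default_rng(5).normal(3.0, 0.2, 500)
        with pytest.raises(UnanalyzableCaseError):
            decompose(DICase("aneu_only", values))

    def test_small_sample_window_path(self):
        dec = decompose(DICase("tiny", np.array([0.9, 1.0, 1.1, 1.9, 2.5])))
        assert dec.population("diploid").count == 3
        assert dec.population("tetraploid").count == 1
        assert dec.population("aneuploid").count == 1
        assert sum(p.count for p in dec.populations) == 5

    def test_small_sample_without_diploid_flagged(self):
        with pytest.raises(UnanalyzableCaseError):
            decompose(DICase("tiny_bad", np.array([2.5, 2.6, 3.0])))
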