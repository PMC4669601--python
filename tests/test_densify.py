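"""Marker insertion machinery: co-occurrence counts, marker generation,
interval selection, the densification loop and thinning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplodense import (
    DensifyConfig,
    HaplotypeDensifier,
    densify,
    generate_marker,
    required_cooccurrences,
    select_interval,
    thin,
)
from haplodense.densify import InsertionError, _eligible_intervals
from haplodense.panel import SIMULATED_PREFIX, PanelError
from haplodense.synthetic import SyntheticSpec, simulate_panel


def brute_force_n11(x_jk: float, x_star: float, rho: float, n: int) -> int:
    """Oracle: search all feasible co-occurrence counts for the one whose
    implied correlation is closest to the target."""
    n1k, n1s = round(n * x_jk), round(n * x_star)
    lo, hi = max(0, n1k + n1s - n), min(n1k, n1s)
    denom = np.sqrt(x_jk * (1 - x_jk) * x_star * (1 - x_star))
    best, best_err = lo, np.inf
    for n11 in range(lo, hi + 1):
        implied = (n11 / n - x_jk * x_star) / denom
        if abs(implied - rho) < best_err:
            best, best_err = n11, abs(implied - rho)
    return best


def implied_corr(n11: int, x_jk: float, x_star: float, n: int) -> float:
    denom = np.sqrt(x_jk * (1 - x_jk) * x_star * (1 - x_star))
    return (n11 / n - x_jk * x_star) / denom


class TestRequiredCooccurrences:
    def test_perfect_correlation_at_half(self):
        assert required_cooccurrences(0.5, 0.5, 1.0, 100) == 50

    @pytest.mark.parametrize("x,xs", [(0.5, 0.5), (0.3, 0.7), (0.2, 0.4)])
    def test_independence_gives_product_term(self, x, xs):
        assert required_cooccurrences(x, xs, 0.0, 100) == round(100 * x * xs)

    def test_worked_example(self):
        # E = sqrt(.24) * sqrt(.21) * 0.5 + 0.12 = 0.23225 -> 23
        assert required_cooccurrences(0.4, 0.3, 0.5, 100) == 23
        assert brute_force_n11(0.4, 0.3, 0.5, 100) == 23

    def test_matches_brute_force_on_sample_grid(self):
        for n in (10, 20):
            for n1k in range(1, n):
                for xs in (0.1, 0.3, 0.5, 0.7, 0.9):
                    for rho in (0.0, 0.5, 1.0):
                        ours = required_cooccurrences(n1k / n, xs, rho, n)
                        oracle = brute_force_n11(n1k / n, xs, rho, n)
                        e_ours = abs(implied_corr(ours, n1k / n, xs, n) - rho)
                        e_orac = abs(implied_corr(oracle, n1k / n, xs, n) - rho)
                        # equal up to rounding ties (equal implied error)
                        assert e_ours == pytest.approx(e_orac, abs=1e-9)

    @given(
        st.integers(10, 300),
        st.floats(0.05, 0.95),
        st.floats(0.05, 0.95),
        st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_always_feasible(self, n, x, xs, rho):
        n11 = required_cooccurrences(x, xs, rho, n)
        n1k, n1s = round(n * x), round(n * xs)
        assert max(0, n1k + n1s - n) <= n11 <= min(n1k, n1s)


class TestGenerateMarker:
    def test_ones_count_preserved_and_n11_achieved(self, rng):
        left = (rng.random(100) < 0.4).astype(np.uint8)
        for _ in range(50):
            col, n11, x_tilde = generate_marker(left, 0.3, 0.6, rng)
            assert col.sum() == round(100 * x_tilde)
            assert int(np.sum((col == 1) & (left == 1))) == n11

    def test_full_correlation_copies_left_when_counts_match(self, rng):
        left = np.zeros(40, dtype=np.uint8)
        left[:16] = 1  # frequency 0.4
        for _ in range(200):
            col, n11, x_tilde = generate_marker(left, 0.4, 1.0, rng)
            if round(40 * x_tilde) == 16:  # counts happen to coincide
                np.testing.assert_array_equal(col, left)
                break
        else:
            pytest.fail("never drew a matching ones-count")

    def test_zero_correlation_hits_independence_count(self, rng):
        left = np.zeros(200, dtype=np.uint8)
        left[:100] = 1
        col, n11, x_tilde = generate_marker(left, 0.5, 0.0, rng)
        assert n11 == round(200 * 0.5 * x_tilde)

    def test_monte_carlo_correlation_calibration(self):
        """Mean achieved |Pearson r| over replicates sits near the target."""
        rng = np.random.default_rng(99)
        left = np.zeros(200, dtype=np.uint8)
        left[:100] = 1
        achieved = []
        for _ in range(1000):
            col, *_ = generate_marker(left, 0.5, 0.6, rng)
            achieved.append(abs(np.corrcoef(left, col)[0, 1]))
        assert np.mean(achieved) == pytest.approx(0.6, abs=0.05)

    def test_monomorphic_anchor_rejected(self, rng):
        with pytest.raises(ValueError, match="monomorphic"):
            generate_marker(np.zeros(50, dtype=np.uint8), 0.5, 0.5, rng)


class TestSelectInterval:
    def test_single_candidate(self, rng, toy):
        left, right = select_interval(toy.map, "1", 100.0, rng)
        assert (left, right) in {("c1_m1", "c1_m2"), ("c1_m2", "c1_m3"), ("c1_m3", "c1_m4")}

    def test_long_interval_never_selected(self, rng):
        pos = np.array([0.0, 10.0, 30.0, 5030.0])
        elig = _eligible_intervals(pos, 1000.0)
        np.testing.assert_array_equal(elig, [0, 1])

    def test_equal_intervals_selected_uniformly(self):
        rng = np.random.default_rng(5)
        pos = np.array([0.0, 10.0, 20.0, 30.0])
        counts = np.zeros(3)
        for _ in range(30_000):
            elig = _eligible_intervals(pos, 100.0)
            counts[int(rng.choice(elig))] += 1
        np.testing.assert_allclose(counts / 30_000, 1 / 3, atol=0.02)

    def test_exhaustion_error(self, rng, toy):
        with pytest.raises(InsertionError, match="no interval"):
            select_interval(toy.map, "1", 0.001, rng)


@pytest.fixture(scope="module")
def dense_input():
    spec = SyntheticSpec(
        n_haplotypes=100, chromosomes=(("1", 10_000.0, 100), ("2", 10_000.0, 100)),
        seed=21,
    )
    return simulate_panel(spec)


class TestDensify:
    def test_target_at_current_count_is_identity(self, dense_input):
        cfg = DensifyConfig(target_min_markers=dense_input.n_markers, seed=1)
        out, sims = densify(dense_input, cfg)
        assert sims == []
        np.testing.assert_array_equal(out.alleles, dense_input.alleles)

    def test_densified_panel_contract(self, dense_input):
        cfg = DensifyConfig(
            target_min_markers=260, batch_size=30, seed=7, maf_limit=0.05
        )
        out, sims = densify(dense_input, cfg)
        assert out.n_markers >= 260
        assert len(sims) == out.n_markers - dense_input.n_markers
        # originals bit-identical, in order
        orig_ids = list(dense_input.map.marker_ids)
        keep = [i for i, m in enumerate(out.map.marker_ids) if m in set(orig_ids)]
        assert [out.map.marker_ids[i] for i in keep] == orig_ids
        np.testing.assert_array_equal(out.alleles[:, keep], dense_input.alleles)
        # every simulated marker respects the MAF floor and carries the prefix
        for s in sims:
            maf = min(s.allele_vector.mean(), 1 - s.allele_vector.mean())
            assert maf >= 0.05
            assert s.marker_id.startswith(SIMULATED_PREFIX)
        # positions strictly increasing per chromosome (new ones inside gaps)
        for chrom in out.chromosomes:
            assert np.all(np.diff(out.map.positions(chrom)) > 0)

    def test_same_seed_bit_identical(self, dense_input):
        cfg = DensifyConfig(target_min_markers=240, batch_size=40, seed=3)
        out1, _ = densify(dense_input, cfg)
        out2, _ = densify(dense_input, cfg)
        np.testing.assert_array_equal(out1.alleles, out2.alleles)
        assert list(out1.map.marker_ids) == list(out2.map.marker_ids)
        np.testing.assert_array_equal(out1.map.positions_kb, out2.map.positions_kb)

    def test_sklearn_param_interface(self, dense_input):
        dens = HaplotypeDensifier(target_min_markers=210, random_state=2)
        assert dens.get_params()["target_min_markers"] == 210
        dens.set_params(batch_size=25).fit(dense_input)
        assert set(dens.beta_models_) == {"1", "2"}
        out = dens.transform(dense_input)
        assert out.n_markers >= 210

    def test_config_validation(self):
        with pytest.raises(ValueError, match="exactly one"):
            DensifyConfig(target_min_markers=10, target_max_markers=5)
        with pytest.raises(ValueError, match="exactly one"):
            DensifyConfig()
        with pytest.raises(ValueError, match="maf_limit"):
            DensifyConfig(target_min_markers=10, maf_limit=0.6)


class TestThin:
    def test_identity_at_current_count(self, dense_input):
        out = thin(dense_input, dense_input.n_markers, 0)
        np.testing.assert_array_equal(out.alleles, dense_input.alleles)

    def test_subset_and_count(self, dense_input):
        out = thin(dense_input, 150, 4)
        assert out.n_markers == 150
        assert set(out.map.marker_ids) <= set(dense_input.map.marker_ids)
        # surviving columns unchanged
        pos = {m: i for i, m in enumerate(dense_input.map.marker_ids)}
        idx = [pos[m] for m in out.map.marker_ids]
        np.testing.assert_array_equal(out.alleles, dense_input.alleles[:, idx])

    def test_same_seed_same_subset(self, dense_input):
        a = thin(dense_input, 120, 9)
        b = thin(dense_input, 120, 9)
        assert list(a.map.marker_ids) == list(b.map.marker_ids)

    def test_floor_of_two_markers_per_chromosome(self, dense_input):
        with pytest.raises(PanelError, match="fewer than 2"):
            thin(dense_input, 3, 0)
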