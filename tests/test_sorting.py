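"""Fluorescence gating: quantile gates, exceedance curves, composition."""

import numpy as np
import pandas as pd
import pytest

from dropscreen import simulate as sim
from dropscreen import sorting as srt


class TestTopFractionGate:
    def test_exact_count_on_distinct_values(self):
        rng = np.random.default_rng(0)
        x = rng.permutation(np.arange(1000, dtype=float) + 1)
        gate, idx = srt.top_fraction_gate(x, 0.01)
        assert gate.selected_count == 10
        assert sorted(x[idx]) == list(np.arange(991.0, 1001.0))

    def test_all_ties_select_nothing_flagged(self):
        gate, idx = srt.top_fraction_gate(np.full(100, 5.0), 0.01)
        assert gate.selected_count == 0
        assert gate.degenerate

    def test_never_selects_more_than_requested(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(3, 1, 5000)
        gate, _ = srt.top_fraction_gate(x, 0.01)
        assert gate.selected_count / gate.n_total <= 0.01 + 1 / gate.n_total

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(3, 1, 2000)
        _, idx_raw = srt.top_fraction_gate(x, 0.05)
        _, idx_log = srt.top_fraction_gate(np.log(x), 0.05)
        assert np.array_equal(np.sort(idx_raw), np.sort(idx_log))

    def test_empty_and_bad_q_raise(self):
        with pytest.raises(ValueError):
            srt.top_fraction_gate([], 0.01)
        with pytest.raises(ValueError):
            srt.top_fraction_gate([1.0, 2.0], 1.5)

    def test_large_population_selects_close_to_q(self, strains):
        scn = sim.ScreenScenario(
            n_droplets=200_000, lambdas={"P_mexicana": 0.1}, seed=23
        )
        table = sim.generate_screen_population(scn, list(strains.values()))
        gate, _ = srt.top_fraction_gate(table["intensity"].to_numpy(), 0.01)
        assert gate.selected_fraction == pytest.approx(0.01, abs=0.0005)


class TestFractionExceeding:
    def test_boundary_thresholds(self):
        x = np.array([10.0, 20.0, 30.0])
        assert srt.fraction_exceeding(x, [0.0])[0] == 1.0
        assert srt.fraction_exceeding(x, [100.0])[0] == 0.0

    def test_non_increasing_in_threshold(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(3, 1.2, 10_000)
        props = srt.fraction_exceeding(x, [1000, 2000, 3000, 4000, 5000])
        assert np.all(np.diff(props) <= 0)

    def test_unsorted_thresholds_raise(self):
        with pytest.raises(ValueError):
            srt.fraction_exceeding([1.0], [5.0, 1.0])

    def test_non_decreasing_in_culture_time(self, strains):
        """Longer culture produces more fluorescence, hence higher exceedance."""
        props = []
        for t_h in (24.0, 48.0, 72.0):
            scn = sim.ScreenScenario(
                n_droplets=5000, lambdas={"P_mexicana": 0.3},
                culture_time_h=t_h, seed=24,
            )
            tab = sim.generate_screen_population(scn, list(strains.values()))
            props.append(
                srt.fraction_exceeding(tab["intensity"].to_numpy(), [1000.0])[0]
            )
        assert props[0] <= props[1] <= props[2]


class TestHistogram:
    def test_empty_population(self):
        counts, edges = srt.intensity_histogram([], 10)
        assert counts.size == 0 and edges.size == 0

    def test_counts_conserve_n(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(2, 1, 5000)
        counts, _ = srt.intensity_histogram(x, 40, log_axis=True)
        assert counts.sum() == 5000
        counts_lin, _ = srt.intensity_histogram(x, 17, log_axis=False)
        assert counts_lin.sum() == 5000

    def test_single_value_single_bin(self):
        counts, _ = srt.intensity_histogram(np.full(50, 7.0), 10)
        assert counts.sum() == 50
        assert (counts > 0).sum() == 1

    def test_nonpositive_with_log_axis_raises(self):
        with pytest.raises(ValueError):
            srt.intensity_histogram([0.0, 1.0], 10, log_axis=True)

    def test_empty_droplet_population_peaks_in_10_20_band(self, strains):
        """Baseline fluorescence of cell-free droplets peaks at 10-20."""
        scn = sim.ScreenScenario(
            n_droplets=50_000, lambdas={"E_coli": 0.0}, seed=25
        )
        tab = sim.generate_screen_population(scn, list(strains.values()))
        counts, edges = srt.intensity_histogram(
            tab["intensity"].to_numpy(), 50, log_axis=True
        )
        mode = int(np.argmax(counts))
        center = np.sqrt(edges[mode] * edges[mode + 1])
        assert 10.0 <= center <= 20.0


@pytest.fixture(scope="module")
def mixed_table(strains):
    scn = sim.ScreenScenario(
        n_droplets=30_000,
        lambdas={"P_mexicana": 0.250, "E_coli": 0.173},
        culture_time_h=24.0,
        seed=26,
    )
    return sim.generate_screen_population(scn, list(strains.values()))


class TestGateComposition:
    def test_empty_gate_gives_zero_selected(self, mixed_table):
        comp = srt.gate_composition(mixed_table, np.array([], dtype=int))
        assert (comp["n_selected"] == 0).all()
        assert comp["n_total"].sum() == len(mixed_table)

    def test_single_strain_table_has_no_mixed_class(self, strains):
        scn = sim.ScreenScenario(n_droplets=5000, lambdas={"E_coli": 0.5}, seed=27)
        tab = sim.generate_screen_population(scn, list(strains.values()))
        comp = srt.gate_composition(tab, np.arange(len(tab)))
        assert "mixed" not in set(comp["content"])

    def test_low_band_gate_isolates_low_activity_strain(self, mixed_table):
        """A gate on the low-fluorescence band captures only the weak
        protease producer: the high producer's droplets all fluoresce
        above the band."""
        x = mixed_table["intensity"].to_numpy()
        low_band = np.flatnonzero((x > 80.0) & (x < 250.0))
        assert low_band.size > 0
        comp = srt.gate_composition(mixed_table, low_band).set_index("content")
        assert comp.loc["only_E_coli", "n_selected"] > 0
        for cls in ("only_P_mexicana", "mixed"):
            if cls in comp.index:
                assert comp.loc[cls, "n_selected"] == 0

    def test_missing_strain_columns_raise(self):
        with pytest.raises(ValueError):
            srt.gate_composition(
                pd.DataFrame({"intensity": [1.0, 2.0]}), np.array([0])
            )

    def test_gated_enrichment_of_high_activity_strain(self, mixed_table):
        """Top-gate enrichment: the strong producer is over-represented
        among sorted droplets relative to the whole population."""
        x = mixed_table["intensity"].to_numpy()
        _, idx = srt.top_fraction_gate(x, 0.05)
        has_pm = mixed_table["n_P_mexicana"].to_numpy() > 0
        pre_freq = has_pm.mean()
        post_freq = has_pm[idx].mean()
        assert post_freq >= pre_freq
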