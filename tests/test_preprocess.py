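"""Background correction, filtering, M/A ratios, LOWESS, replicate averaging."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_scan
from toxarray.exceptions import (
    DegenerateDataError,
    EmptyResultError,
    ValidationError,
)
from toxarray.preprocess import (
    average_replicates,
    compute_ratios,
    correct_background,
    filter_spots,
    lowess_normalize,
    qc_report,
    run_preprocessing,
)
from toxarray.simulate import SimulationConfig, simulate_experiment


class TestBackgroundCorrection:
    def test_subtraction(self):
        scan = correct_background(
            make_scan([("s1", "GA", 100.0, 40.0, 200.0, 50.0, "OK")])
        )
        assert scan.data.loc[0, "s1"] == 60.0
        assert scan.data.loc[0, "s2"] == 150.0

    def test_nonpositive_flagged_not_dropped(self):
        scan = correct_background(
            make_scan([
                ("s1", "GA", 30.0, 50.0, 90.0, 10.0, "OK"),
                ("s2", "GB", 90.0, 10.0, 90.0, 10.0, "OK"),
            ])
        )
        assert len(scan) == 2
        assert scan.data.loc[0, "flag"] == "BAD"
        assert scan.data.loc[0, "flag_reason"] == "nonpositive"
        assert scan.data.loc[1, "flag"] == "OK"

    def test_zero_background_is_identity(self):
        scan = make_scan([("s1", "GA", 100.0, 0.0, 200.0, 0.0, "OK")])
        out = correct_background(scan)
        assert out.data.loc[0, "s1"] == 100.0
        assert out.data.loc[0, "flag"] == "OK"
        assert out.provenance  # audit note present


class TestFilterSpots:
    def test_counts_by_reason(self):
        rows = [(f"s{i}", f"G{i}", 100.0, 10.0, 100.0, 10.0, "OK")
                for i in range(9)]
        rows.append(("s9", "G9", 100.0, 10.0, 100.0, 10.0, "BAD"))
        out, report = filter_spots(correct_background(make_scan(rows)))
        assert len(out) == 9
        assert report.flagged == 1
        assert report.low_snr == 0
        assert report.pass_fraction == pytest.approx(0.9)

    def test_snr_threshold_matches_brute_force(self, rng):
        rows = []
        for i in range(200):
            bg1, bg2 = rng.uniform(5, 50, 2)
            fg1 = bg1 * rng.uniform(0.5, 4.0)
            fg2 = bg2 * rng.uniform(0.5, 4.0)
            rows.append((f"s{i}", f"G{i}", fg1, bg1, fg2, bg2, "OK"))
        scan = correct_background(make_scan(rows))
        out, _ = filter_spots(scan, min_snr=1.5)
        expected = {
            r[0] for r in rows
            if min(r[2] / max(r[3], 1), r[4] / max(r[5], 1)) >= 1.5
            and r[2] - r[3] > 0 and r[4] - r[5] > 0
        }
        assert set(out.data["spot_id"]) == expected

    def test_everything_removed_raises(self):
        scan = make_scan([("s1", "GA", 10.0, 10.0, 10.0, 10.0, "BAD")])
        with pytest.raises(EmptyResultError):
            filter_spots(correct_background(scan))


class TestComputeRatios:
    @pytest.mark.parametrize(
        "s1, s2, m", [(100.0, 100.0, 0.0), (50.0, 200.0, 2.0), (200.0, 50.0, -2.0)],
    )
    def test_log_ratio_arithmetic(self, s1, s2, m):
        scan = correct_background(
            make_scan([("s1", "GA", s1, 0.0, s2, 0.0, "OK")])
        )
        rec = compute_ratios(scan)
        assert rec.loc[0, "M"] == pytest.approx(m)
        assert rec.loc[0, "A"] == pytest.approx((np.log2(s1) + np.log2(s2)) / 2)

    def test_dye_swap_antisymmetry(self):
        rows = [("s1", "GA", 50.0, 0.0, 200.0, 0.0, "OK")]
        std = compute_ratios(correct_background(make_scan(rows)))
        swapped_rows = [("s1", "GA", 200.0, 0.0, 50.0, 0.0, "OK")]
        swp = compute_ratios(
            correct_background(make_scan(swapped_rows, dye_orientation="swapped"))
        )
        assert std.loc[0, "M"] == pytest.approx(swp.loc[0, "M"])

    def test_nonpositive_signal_is_contract_error(self):
        scan = correct_background(
            make_scan([("s1", "GA", 10.0, 50.0, 100.0, 0.0, "OK")])
        )
        with pytest.raises(ValidationError, match="filter_spots"):
            compute_ratios(scan)


def _ratio_frame(A, M):
    return pd.DataFrame({
        "gene": [f"G{i}" for i in range(len(A))],
        "A": A, "M": M, "array_id": "a1",
        "spot_id": [f"s{i}" for i in range(len(A))],
    })


class TestLowess:
    def test_zero_ratio_stays_zero(self, rng):
        A = rng.uniform(6, 14, 200)
        out, fit = lowess_normalize(_ratio_frame(A, np.zeros(200)))
        np.testing.assert_allclose(out["M"], 0.0, atol=1e-12)

    def test_constant_offset_removed(self, rng):
        A = rng.uniform(6, 14, 200)
        out, _ = lowess_normalize(_ratio_frame(A, np.full(200, 0.8)))
        np.testing.assert_allclose(out["M"], 0.0, atol=1e-6)

    def test_small_input_falls_back_to_median_centering(self, rng, caplog):
        A = rng.uniform(6, 14, 20)
        M = rng.normal(0.5, 0.1, 20)
        with caplog.at_level("WARNING"):
            out, _ = lowess_normalize(_ratio_frame(A, M))
        np.testing.assert_allclose(out["M"], M - np.median(M))
        assert any("median-centering" in r.message for r in caplog.records)

    def test_constant_A_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            lowess_normalize(_ratio_frame(np.full(60, 8.0), np.zeros(60)))

    def test_planted_cubic_bias_removed(self):
        """With noise off, normalized M matches true log2FC away from the
        intensity extremes."""
        cfg = SimulationConfig(
            n_genes=2000, n_arrays=1, prop_de=0.1,
            noise_sd_at_low_A=0.0, noise_sd_at_high_A=0.0,
            prop_bad_spots=0.0, seed=0,
        )
        scans, truth = simulate_experiment(cfg)
        scan, _ = filter_spots(correct_background(scans[0]))
        out, _ = lowess_normalize(compute_ratios(scan))
        lfc = truth.set_index("gene")["true_log2fc"]
        resid = out["M"].to_numpy() - lfc.loc[out["gene"]].to_numpy()
        A = out["A"].to_numpy()
        lo, hi = np.quantile(A, [0.02, 0.98])
        inner = (A >= lo) & (A <= hi)
        assert np.abs(resid[inner]).max() < 0.05


class TestAverageReplicates:
    def test_duplicate_spot_mean(self):
        df = _ratio_frame([8.0, 8.0], [1.0, 3.0])
        df["gene"] = "GA"
        out = average_replicates([df])
        assert out.loc[0, "R"] == pytest.approx(2.0)
        assert out.loc[0, "n_spots"] == 2

    def test_mean_of_array_means(self):
        a1 = _ratio_frame([8.0], [1.0]); a1["gene"] = "GA"
        a2 = _ratio_frame([8.0], [2.0]); a2["gene"] = "GA"
        out = average_replicates([a1, a2])
        assert out.loc[0, "R"] == pytest.approx(1.5)
        assert out.loc[0, "n_arrays"] == 2

    def test_matches_two_stage_brute_force(self, rng):
        arrays = []
        for a in range(3):
            n = 60
            genes = rng.choice([f"G{i}" for i in range(20)], n)
            df = _ratio_frame(rng.uniform(6, 14, n), rng.normal(0, 1, n))
            df["gene"] = genes
            arrays.append(df)
        out = average_replicates(arrays).set_index("gene")
        for gene in out.index:
            per_array = [
                df.loc[df["gene"] == gene, "M"].mean()
                for df in arrays if (df["gene"] == gene).any()
            ]
            assert out.loc[gene, "R"] == pytest.approx(np.mean(per_array))

    def test_min_arrays_drops_and_reports(self):
        a1 = _ratio_frame([8.0, 9.0], [1.0, 2.0]); a1["gene"] = ["GA", "GB"]
        a2 = _ratio_frame([8.0], [1.0]); a2["gene"] = "GA"
        out = average_replicates([a1, a2], min_arrays=2)
        assert list(out["gene"]) == ["GA"]
        assert out.attrs["dropped_genes"] == ["GB"]


class TestQC:
    def test_identical_arrays_correlate_perfectly(self, rng):
        df = _ratio_frame(rng.uniform(6, 14, 100), rng.normal(0, 1, 100))
        qc = qc_report([df, df.assign(array_id="a2")])
        assert qc.array_reproducibility == pytest.approx(1.0)
        assert qc.verdicts["array_r"] is True

    def test_independent_arrays_fail_reproducibility(self, rng):
        a = _ratio_frame(rng.uniform(6, 14, 1000), rng.normal(0, 1, 1000))
        b = a.assign(M=rng.normal(0, 1, 1000), array_id="a2")
        qc = qc_report([a, b])
        assert abs(qc.array_reproducibility) < 0.1
        assert qc.verdicts["array_r"] is False

    def test_single_array_reports_not_applicable(self, rng):
        df = _ratio_frame(rng.uniform(6, 14, 50), rng.normal(0, 1, 50))
        qc = qc_report([df])
        assert qc.array_reproducibility is None
        assert qc.verdicts["array_r"] is None


class TestPipelineInvariants:
    def test_spot_order_invariance(self, small_experiment, rng):
        scans, _ = small_experiment
        gene_a, _ = run_preprocessing(scans)
        shuffled = []
        for scan in scans:
            s = scan.copy()
            s.data = s.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
            shuffled.append(s)
        gene_b, _ = run_preprocessing(shuffled)
        pd.testing.assert_frame_equal(
            gene_a.sort_values("gene").reset_index(drop=True),
            gene_b.sort_values("gene").reset_index(drop=True),
        )

    def test_normalization_reduces_injected_bias(self, small_config):
        scans, _ = simulate_experiment(small_config)
        scan, _ = filter_spots(correct_background(scans[0]))
        raw = compute_ratios(scan)
        norm, _ = lowess_normalize(raw)
        # within central A windows, normalized M is closer to zero on average
        A = raw["A"].to_numpy()
        lo, hi = np.quantile(A, [0.1, 0.9])
        inner = (A >= lo) & (A <= hi)
        assert (
            abs(norm["M"].to_numpy()[inner].mean())
            <= abs(raw["M"].to_numpy()[inner]).mean()
        )
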