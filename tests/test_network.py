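import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernet import (
    ExpressionMatrix,
    PartialCorrelation,
    PerSampleStat,
    SelectionThresholds,
    Triplet,
    TripletStatRecord,
    partial_correlation,
    partial_correlation_pvalue,
    patient_network,
    pearson,
    perturb_cohort,
    perturb_one_sample,
    read_stat_records,
    reference_network,
    write_stat_records,
    ztest_select,
    ztest_statistics,
)
from oracles import residual_partial_correlation

from cernet.errors import (
    DegenerateInputError,
    GeneLookupError,
    InsufficientSamplesError,
    SampleLookupError,
)


class TestPearson:
    def test_self_correlation(self, rng):
        x = rng.normal(size=10)
        assert pearson(x, x) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        assert pearson(np.array([1.0, 2, 3]), np.array([3.0, 2, 1])) == pytest.approx(-1.0)

    def test_matches_definitional_oracle(self, rng):
        x, y = rng.normal(size=(2, 20))
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / (np.sqrt((xc**2).sum()) * np.sqrt((yc**2).sum()))
        assert pearson(x, y) == pytest.approx(expected, abs=1e-14)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson(np.ones(5), np.arange(5.0))

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientSamplesError):
            pearson(np.array([1.0, 2]), np.array([2.0, 1]))


class TestPartialCorrelation:
    def test_orthogonal_conditioner_reduces_to_pearson(self, rng):
        # orthogonalize z against x and y so PCC(x,z) = PCC(y,z) = 0 exactly
        x, y, z0 = rng.normal(size=(3, 40))
        B = np.column_stack([np.ones(40), x - x.mean(), y - y.mean()])
        z = z0 - B @ np.linalg.lstsq(B, z0, rcond=None)[0]
        assert partial_correlation(x, y, z) == pytest.approx(pearson(x, y), abs=1e-10)

    def test_identical_x_y_gives_one(self, rng):
        z = rng.normal(size=30)
        x = 0.6 * z + rng.normal(size=30)
        assert partial_correlation(x, x, z) == pytest.approx(1.0)

    def test_matches_regression_residual_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 101))
            x, y, z = rng.normal(size=(3, n))
            assert partial_correlation(x, y, z) == pytest.approx(
                residual_partial_correlation(x, y, z), abs=1e-10
            )

    def test_symmetric_in_x_and_y(self, rng):
        x, y, z = rng.normal(size=(3, 25))
        assert partial_correlation(x, y, z) == pytest.approx(partial_correlation(y, x, z), abs=1e-14)

    @given(
        a=st.floats(0.1, 5.0), b=st.floats(-3.0, 3.0),
        c=st.floats(0.1, 5.0), d=st.floats(-3.0, 3.0),
    )
    @settings(max_examples=40, derandomize=True)
    def test_affine_invariance_positive_slopes(self, a, b, c, d):
        rng = np.random.default_rng(5)
        x, y, z = rng.normal(size=(3, 20))
        base = partial_correlation(x, y, z)
        assert partial_correlation(a * x + b, y, z) == pytest.approx(base, abs=1e-9)
        assert partial_correlation(x, a * y + b, z) == pytest.approx(base, abs=1e-9)
        assert partial_correlation(x, y, c * z + d) == pytest.approx(base, abs=1e-9)
        assert partial_correlation(-a * x + b, y, z) == pytest.approx(-base, abs=1e-9)

    def test_collinear_conditioner_rejected(self, rng):
        z = rng.normal(size=20)
        with pytest.raises(DegenerateInputError):
            partial_correlation(2.0 * z + 1.0, rng.normal(size=20), z)


class TestPartialCorrelationPvalue:
    def test_null_center(self):
        assert partial_correlation_pvalue(0.0, 30) == pytest.approx(1.0)

    @pytest.mark.parametrize("rho", [1.0, -1.0])
    def test_boundary(self, rho):
        assert partial_correlation_pvalue(rho, 10) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(InsufficientSamplesError):
            partial_correlation_pvalue(0.5, 3)

    def test_matches_null_simulation_oracle(self):
        # Monte-Carlo null: partial correlation of i.i.d. Gaussian triples at
        # n = 30; the t-based p-value is exact for Gaussian data, so the tail
        # frequency of |rho_null| >= 0.5 must agree within Monte-Carlo error.
        rng = np.random.default_rng(77)
        n, reps = 30, 120_000
        sims = np.empty(reps)
        for start in range(0, reps, 20_000):
            block = min(20_000, reps - start)
            x, y, z = rng.standard_normal((3, block, n))
            zc = z - z.mean(1, keepdims=True)
            zn = zc / np.linalg.norm(zc, axis=1, keepdims=True)
            rx = x - x.mean(1, keepdims=True)
            ry = y - y.mean(1, keepdims=True)
            rx -= (rx * zn).sum(1, keepdims=True) * zn
            ry -= (ry * zn).sum(1, keepdims=True) * zn
            sims[start:start + block] = (rx * ry).sum(1) / (
                np.linalg.norm(rx, axis=1) * np.linalg.norm(ry, axis=1)
            )
        p_mc = float((np.abs(sims) >= 0.5).mean())
        p_t = partial_correlation_pvalue(0.5, n)
        mc_sd = np.sqrt(p_t * (1 - p_t) / reps)
        assert abs(p_mc - p_t) < 4 * mc_sd + 1e-4


def _matrix_from_rows(rows: dict[str, np.ndarray], n_normal: int) -> ExpressionMatrix:
    values = pd.DataFrame(rows).T
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    classes = pd.Series(
        ["normal"] * n_normal + ["tumor"] * (values.shape[1] - n_normal),
        index=values.columns,
    )
    return ExpressionMatrix(values, classes)


class TestReferenceNetwork:
    def test_planted_correlation_recovered(self, rng):
        n = 40
        z = rng.normal(size=n)
        y = rng.normal(size=n)
        x = 2.0 * y + 0.1 * rng.normal(size=n)
        frame = pd.DataFrame({"L": x, "M": z, "G": y}).T
        frame.columns = [f"s{i}" for i in range(n)]
        ref = reference_network(frame, {Triplet("L", "M", "G")})
        rho = ref.correlations[Triplet("L", "M", "G")].rho
        assert rho > 0.9

    def test_constant_mirna_row_excluded(self, rng):
        frame = pd.DataFrame(
            {"L": rng.normal(size=10), "M": np.ones(10), "G": rng.normal(size=10)}
        ).T
        frame.columns = [f"s{i}" for i in range(10)]
        ref = reference_network(frame, {Triplet("L", "M", "G")})
        assert not ref.correlations
        assert "variance" in ref.excluded[Triplet("L", "M", "G")]

    def test_elementwise_oracle(self, demo_cohort, demo_triplets):
        _, cohort = demo_cohort
        normal = np.log2(cohort.expression.normal + 1.0)
        ref = reference_network(normal, demo_triplets)
        for t in list(sorted(demo_triplets))[:10]:
            expected = partial_correlation(
                normal.loc[t.lncrna].to_numpy(),
                normal.loc[t.mrna].to_numpy(),
                normal.loc[t.mirna].to_numpy(),
            )
            assert ref.correlations[t].rho == pytest.approx(expected, abs=1e-12)

    def test_missing_gene_reported(self, rng):
        frame = pd.DataFrame({"L": rng.normal(size=8), "M": rng.normal(size=8)}).T
        frame.columns = [f"s{i}" for i in range(8)]
        with pytest.raises(GeneLookupError, match="G"):
            reference_network(frame, {Triplet("L", "M", "G")})


class TestPerturbation:
    def test_appending_mean_sample_gives_zero_delta(self, rng):
        n = 20
        rows = {g: rng.normal(loc=5, size=n) for g in ("L", "M", "G")}
        frame = pd.DataFrame(rows).T
        frame.columns = [f"s{i}" for i in range(n)]
        t = Triplet("L", "M", "G")
        ref = reference_network(frame, {t})
        mean_sample = frame.mean(axis=1)  # leaves all centered moments intact
        out = perturb_one_sample(frame, mean_sample, {t}, ref)
        assert out[t].delta_rho == pytest.approx(0.0, abs=1e-12)

    def test_delta_rho_nonnegative_everywhere(self, demo_records):
        records, _ = demo_records
        for rec in records.values():
            for st_ in rec.per_sample.values():
                assert st_.delta_rho >= 0.0

    def test_cohort_matches_single_sample_recomputation(self, demo_cohort, demo_triplets, demo_records):
        _, cohort = demo_cohort
        records, _ = demo_records
        mat = np.log2(cohort.expression.values + 1.0)
        normal = mat.loc[:, cohort.expression.sample_class == "normal"]
        sample_id = sorted(cohort.expression.tumor.columns)[3]
        for t in list(sorted(demo_triplets))[:8]:
            cols = lambda g: np.append(normal.loc[g].to_numpy(), mat.loc[g, sample_id])
            rho1 = partial_correlation(cols(t.lncrna), cols(t.mrna), cols(t.mirna))
            rec = records[t].per_sample[sample_id]
            assert rec.rho_pert.rho == pytest.approx(rho1, abs=1e-10)
            assert rec.delta_rho == pytest.approx(abs(rho1 - records[t].rho_ref.rho), abs=1e-10)

    def test_delta_rho_symmetric_under_lnc_mrna_exchange(self, demo_cohort):
        _, cohort = demo_cohort
        t = cohort.planted[0].triplet
        swapped = Triplet(t.mrna, t.mirna, t.lncrna)
        records, _ = perturb_cohort(cohort.expression, {t, swapped})
        for sid in records[t].per_sample:
            assert records[t].per_sample[sid].delta_rho == pytest.approx(
                records[swapped].per_sample[sid].delta_rho, abs=1e-12
            )

    def test_stat_records_roundtrip(self, tmp_path, demo_records):
        records, _ = demo_records
        p = tmp_path / "records.tsv"
        write_stat_records(p, records)
        back = read_stat_records(p)
        assert set(back) == set(records)
        t = next(iter(records))
        sid = next(iter(records[t].per_sample))
        assert back[t].per_sample[sid].delta_rho == pytest.approx(
            records[t].per_sample[sid].delta_rho, abs=1e-9
        )


def _record(triplet, deltas, passes=None, rho_ref=0.9):
    passes = [True] * len(deltas) if passes is None else passes
    rec = TripletStatRecord(triplet, PartialCorrelation(rho_ref, 30, 1e-8))
    for i, (d, ok) in enumerate(zip(deltas, passes)):
        rec.per_sample[f"t{i}"] = PerSampleStat(
            rho_pert=PartialCorrelation(rho_ref - d, 31, 1e-8), delta_rho=d, passes_edge_filter=ok
        )
    return rec


class TestZtestSelect:
    def test_all_zero_delta_not_selected(self):
        rec = _record(Triplet("L", "M", "G"), [0.0] * 10)
        assert ztest_select([rec]) == set()

    def test_overwhelming_signal_selected(self, rng):
        deltas = rng.normal(0.5, 0.05, size=50).clip(min=0)
        rec = _record(Triplet("L", "M", "G"), list(deltas))
        assert ztest_select([rec]) == {Triplet("L", "M", "G")}

    def test_insufficient_passing_samples_dropped(self):
        rec = _record(Triplet("L", "M", "G"), [0.5, 0.4, 0.45], passes=[True, True, False])
        df = ztest_statistics([rec], SelectionThresholds(min_samples=3))
        assert not df.loc[0, "selected"]
        assert df.loc[0, "flag"] == "insufficient passing samples"
        # with the edge filter disabled all three samples pool in
        df2 = ztest_statistics([rec], SelectionThresholds(min_samples=3, use_edge_filter=False))
        assert df2.loc[0, "m"] == 3

    def test_degenerate_sd_kept_and_flagged(self):
        rec = _record(Triplet("L", "M", "G"), [0.3] * 5)
        df = ztest_statistics([rec])
        assert df.loc[0, "selected"]
        assert df.loc[0, "flag"] == "degenerate-sd"
        assert np.isinf(df.loc[0, "z"])

    def test_matches_raw_matrix_recomputation(self, demo_cohort, demo_triplets, demo_records):
        # end-to-end oracle: recompute every z from the raw expression matrix
        _, cohort = demo_cohort
        records, _ = demo_records
        thresholds = SelectionThresholds()
        mat = np.log2(cohort.expression.values + 1.0)
        normal = mat.loc[:, cohort.expression.sample_class == "normal"]
        tumor_ids = sorted(c for c in mat.columns if c.startswith("T"))
        expected_sel = set()
        from scipy import stats as sps
        for t in demo_triplets:
            deltas = []
            xn = normal.loc[t.lncrna].to_numpy()
            yn = normal.loc[t.mrna].to_numpy()
            zn = normal.loc[t.mirna].to_numpy()
            rho_n = partial_correlation(xn, yn, zn)
            for sid in tumor_ids:
                x1 = np.append(xn, mat.loc[t.lncrna, sid])
                y1 = np.append(yn, mat.loc[t.mrna, sid])
                z1 = np.append(zn, mat.loc[t.mirna, sid])
                rho1 = partial_correlation(x1, y1, z1)
                p1 = partial_correlation_pvalue(rho1, len(x1))
                if abs(rho1) > thresholds.threshold_abs and p1 < thresholds.threshold_p:
                    deltas.append(abs(rho1 - rho_n))
            if len(deltas) < thresholds.min_samples:
                continue
            arr = np.asarray(deltas)
            sd = arr.std(ddof=1)
            if sd == 0:
                if arr.mean() > 0:
                    expected_sel.add(t)
                continue
            z = arr.mean() / (sd / np.sqrt(len(arr)))
            if 2 * sps.norm.sf(abs(z)) < thresholds.ztest_alpha:
                expected_sel.add(t)
        assert ztest_select(records, thresholds) == expected_sel

    def test_planted_triplets_recovered(self, demo_cohort, demo_records):
        _, cohort = demo_cohort
        records, _ = demo_records
        selected = ztest_select(records)
        planted = {p.triplet for p in cohort.planted}
        assert planted <= selected
        assert len(selected - planted) <= 0.1 * max(len(selected), 1)


class TestPatientNetwork:
    def test_edges_equal_external_filtering(self, demo_records):
        records, _ = demo_records
        sid = next(iter(next(iter(records.values())).per_sample))
        pn = patient_network(records, sid)
        expected = {
            t: rec.per_sample[sid].delta_rho
            for t, rec in records.items()
            if rec.per_sample[sid].passes_edge_filter
        }
        assert pn.edges == expected

    def test_unknown_sample_rejected(self, demo_records):
        records, _ = demo_records
        with pytest.raises(SampleLookupError):
            patient_network(records, "no-such-sample")

    def test_all_filters_failing_gives_empty_network(self):
        rec = _record(Triplet("L", "M", "G"), [0.1, 0.2], passes=[False, False])
        with pytest.warns(UserWarning, match="empty"):
            pn = patient_network({Triplet("L", "M", "G"): rec}, "t0")
        assert pn.edges == {}
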