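import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntekinetics.data import (
    EXACT_BINNING,
    PERMISSIVE_BINNING,
    DomainError,
    LetBinError,
    SchemaError,
    bin_let,
    export,
    ingest,
    process_records,
    screen_predictors,
    transform_response,
)

CSV_HEADER = "subject_id,ion,energy_mev_n,let_kev_um,dose_gy,time_months,f_nov\n"


def make_csv(tmp_path, rows, name="d.csv"):
    path = tmp_path / name
    path.write_text(CSV_HEADER + "\n".join(rows) + "\n")
    return path


class TestTransformResponse:
    @pytest.mark.parametrize(
        "f_nov,expected",
        [(1.0, 0.0), (0.5, math.log(2)), (math.exp(-1), 1.0)],
    )
    def test_known_values(self, f_nov, expected):
        assert transform_response(f_nov) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5, float("nan")])
    def test_domain_errors_identify_offender(self, bad):
        with pytest.raises(DomainError):
            transform_response(bad)

    @given(st.floats(min_value=0.0, max_value=30.0))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_with_exponential_is_identity(self, r):
        assert transform_response(math.exp(-r)) == pytest.approx(r, abs=1e-9)

    def test_monotone_decreasing(self):
        f = np.linspace(0.05, 1.0, 50)
        assert np.all(np.diff(transform_response(f)) < 0)


class TestBinLet:
    @pytest.mark.parametrize(
        "let,dose,expected",
        [
            (0.22, 0.1, "L"),
            (14.0, 0.5, "M"),
            (45.0, 1.0, "H"),
            (150.0, 0.05, "VH"),
            (0.0, 0.0, "SHAM"),
            (150.0, 0.0, "SHAM"),  # dose 0 overrides any LET
        ],
    )
    def test_exact_binning(self, let, dose, expected):
        assert bin_let(let, dose, EXACT_BINNING) == expected

    def test_unassignable_let_raises(self):
        with pytest.raises(LetBinError):
            bin_let(70.0, 0.1, EXACT_BINNING)

    def test_permissive_binning_is_total_on_nonnegative_let(self):
        for let in (0.0, 3.0, 20.0, 70.0, 500.0):
            assert bin_let(let, 0.1, PERMISSIVE_BINNING) in "L M H VH".split()

    def test_negative_let_rejected(self):
        with pytest.raises(DomainError):
            bin_let(-1.0, 0.1)


class TestIngest:
    def test_well_formed_rows_all_accepted(self, tmp_path):
        path = make_csv(
            tmp_path,
            [
                "r1,H,1000,0.22,0.1,3,0.6",
                "r2,Fe,600,150,0.05,3,0.5",
                "r3,sham,,0,0,9,0.7",
            ],
        )
        result = ingest(path)
        assert result.n_accepted == 3 and result.n_rejected == 0
        assert list(result.samples["let_category"]) == ["L", "VH", "SHAM"]
        assert result.samples["response"].iloc[2] == pytest.approx(-math.log(0.7))

    def test_f_nov_zero_rejected_without_clip(self, tmp_path):
        path = make_csv(tmp_path, ["r1,H,1000,0.22,0.1,3,0.0"])
        result = ingest(path)
        assert result.n_accepted == 0
        assert "f_nov" in result.rejections[0][1]

    def test_f_nov_zero_clipped_to_epsilon_when_enabled(self, tmp_path):
        path = make_csv(tmp_path, ["r1,H,1000,0.22,0.1,3,0.0"])
        result = ingest(path, clip_f_nov=True, epsilon=1e-3)
        assert result.n_accepted == 1
        assert result.samples["response"].iloc[0] == pytest.approx(-math.log(1e-3))

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,ion\nr1,H\n")
        with pytest.raises(SchemaError):
            ingest(path)

    def test_unparseable_numeric_rejected_row_level(self, tmp_path):
        path = make_csv(
            tmp_path,
            ["r1,H,1000,0.22,oops,3,0.6", "r2,H,1000,0.22,0.1,3,0.6"],
        )
        result = ingest(path)
        assert result.n_accepted == 1
        assert "unparseable" in result.rejections[0][1]

    def test_missing_energy_ok_for_sham_only(self, tmp_path):
        path = make_csv(
            tmp_path,
            ["r1,sham,,0,0,3,0.7", "r2,H,,0.22,0.1,3,0.6"],
        )
        result = ingest(path)
        assert result.n_accepted == 1
        assert "missing energy" in result.rejections[0][1]

    def test_accepted_plus_rejected_equals_input(self, tmp_path):
        rows = [
            "r1,H,1000,0.22,0.1,3,0.6",
            "r2,H,1000,70,0.1,3,0.6",  # unassignable LET
            "r3,H,1000,0.22,-1,3,0.6",  # negative dose
            "r4,H,1000,0.22,0.1,3,1.2",  # f_nov > 1
        ]
        result = ingest(make_csv(tmp_path, rows))
        assert result.n_accepted + result.n_rejected == len(rows)

    def test_export_reingest_idempotent(self, tmp_path):
        path = make_csv(
            tmp_path,
            ["r1,H,1000,0.22,0.1,3,0.637", "r2,sham,,0,0,9,0.71"],
        )
        first = ingest(path).samples
        out1 = tmp_path / "out1.csv"
        export(first, out1)
        second = ingest(out1).samples
        out2 = tmp_path / "out2.csv"
        export(second, out2)
        assert out1.read_text() == out2.read_text()


class TestScreenPredictors:
    def test_perfect_monotone_relation_gives_rho_one(self):
        df = pd.DataFrame(
            {
                "dose_gy": np.linspace(0, 2, 30),
                "let_kev_um": np.ones(30),
                "time_months": np.arange(30) % 3,
                "response": np.linspace(0, 2, 30) ** 2,  # monotone in dose
            }
        )
        out = screen_predictors(df)
        rho = out.set_index("predictor").loc["dose_gy", "rho"]
        assert rho == pytest.approx(1.0)

    def test_independent_predictor_has_small_rho(self):
        rng = np.random.default_rng(0)
        n = 10_000
        for seed in range(3):
            r = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "dose_gy": r.random(n),
                    "let_kev_um": r.random(n),
                    "time_months": r.random(n),
                    "response": r.random(n),
                }
            )
            out = screen_predictors(df)
            assert (out["rho"].abs() < 0.05).all()

    def test_constant_predictor_reported_undefined(self):
        df = pd.DataFrame(
            {
                "dose_gy": [1.0, 1.0, 1.0, 1.0],
                "let_kev_um": [1, 2, 3, 4],
                "time_months": [1, 2, 1, 2],
                "response": [0.1, 0.2, 0.3, 0.4],
            }
        )
        out = screen_predictors(df).set_index("predictor")
        assert np.isnan(out.loc["dose_gy", "rho"])
        assert "constant" in out.loc["dose_gy", "note"]

    def test_too_few_samples_raises(self):
        df = pd.DataFrame(
            {"dose_gy": [1, 2], "let_kev_um": [1, 2], "time_months": [1, 2], "response": [1, 2]}
        )
        with pytest.raises(ValueError):
            screen_predictors(df)
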