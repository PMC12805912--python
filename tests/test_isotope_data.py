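"""Record IO, validation and within-tissue z-scoring."""

import math

import numpy as np
import pytest

from nichepart import (
    IsotopeRecord,
    default_study_design,
    read_isotope_table,
    simulate_isotopes,
    standardize,
    write_isotope_table,
)
from nichepart.errors import (
    DegenerateTissueError,
    ParseError,
    SchemaError,
    ValidationError,
)
from nichepart.isotope_data import validate_records


def rec(ind, tissue="plasma", d13C=-15.0, d15N=17.0, species="a",
        season="breeding", campaign="c1"):
    return IsotopeRecord(ind, species, season, campaign, tissue, d13C, d15N)


class TestReaderWriter:
    def test_round_trip_preserves_every_field(self, tmp_path):
        records = [
            rec("i1", d13C=-14.123456789, d15N=17.5),
            rec("i2", d13C=-15.0, d15N=16.25),
            rec("i3", tissue="body_feather", d13C=-16.5, d15N=18.125),
        ]
        path = tmp_path / "iso.csv"
        write_isotope_table(records, str(path))
        back = read_isotope_table(str(path))
        assert back == records

    def test_tab_delimited_accepted(self, tmp_path):
        records = [rec("i1"), rec("i2", tissue="body_feather")]
        path = tmp_path / "iso.tsv"
        write_isotope_table(records, str(path), delimiter="\t")
        assert read_isotope_table(str(path)) == records

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("individual_id,species,season,campaign,tissue,d13C\n")
        with pytest.raises(SchemaError, match="d15N"):
            read_isotope_table(str(path))

    def test_non_numeric_isotope_cites_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "individual_id,species,season,campaign,tissue,d13C,d15N\n"
            "i1,a,breeding,c1,plasma,-15.0,17.0\n"
            "i2,a,breeding,c1,plasma,NA,17.0\n"
        )
        with pytest.raises(ParseError, match="row 2"):
            read_isotope_table(str(path))

    def test_duplicate_key_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            validate_records([rec("i1"), rec("i1")])

    def test_non_finite_value_rejected(self):
        with pytest.raises(ValidationError, match="non-finite"):
            validate_records([rec("i1", d13C=math.nan)])

    def test_generated_default_design_row_count(self, tmp_path):
        truths = default_study_design()
        records = simulate_isotopes(truths, seed=0)
        expected = sum(t.n_individuals * len(t.tissue_offsets) for t in truths)
        assert len(records) == expected
        assert len({r.individual_id for r in records}) == 111
        path = tmp_path / "sim.csv"
        write_isotope_table(records, str(path))
        assert len(read_isotope_table(str(path))) == expected


class TestStandardize:
    def test_symmetric_triple_maps_to_unit_z(self):
        records = [
            rec("i1", d13C=-14.0, d15N=16.0),
            rec("i2", d13C=-15.0, d15N=17.0),
            rec("i3", d13C=-16.0, d15N=18.0),
        ]
        ds = standardize(records)
        z13 = [r.z13C for r in ds.records]
        z15 = [r.z15N for r in ds.records]
        assert z13 == pytest.approx([1.0, 0.0, -1.0])
        assert z15 == pytest.approx([-1.0, 0.0, 1.0])

    def test_pooled_moments_per_tissue(self):
        records = simulate_isotopes(default_study_design(), seed=3)
        ds = standardize(records)
        df = ds.to_frame()
        for _, grp in df.groupby("tissue"):
            for col in ("z13C", "z15N"):
                assert abs(grp[col].mean()) < 1e-10
                assert abs(grp[col].std(ddof=1) - 1.0) < 1e-10

    def test_stored_table_reproduces_transform(self):
        records = simulate_isotopes(default_study_design(), seed=4)
        ds = standardize(records)
        again = ds.apply(records)
        assert again == ds.records

    def test_idempotent_within_tolerance(self):
        records = simulate_isotopes(default_study_design(), seed=5)
        ds = standardize(records)
        as_raw = [
            IsotopeRecord(r.individual_id, r.species, r.season, r.campaign,
                          r.tissue, r.z13C, r.z15N)
            for r in ds.records
        ]
        ds2 = standardize(as_raw)
        for r1, r2 in zip(ds.records, ds2.records):
            assert abs(r1.z13C - r2.z13C) < 1e-10
            assert abs(r1.z15N - r2.z15N) < 1e-10

    def test_species_mean_contrast_scales_as_delta_over_sd(self):
        # two species with tissue means differing by delta, common SD s
        rng = np.random.default_rng(11)
        delta, s = 2.0, 0.5
        records = []
        for i in range(200):
            records.append(rec(f"a{i}", species="a",
                               d13C=float(rng.normal(-15, s)),
                               d15N=float(rng.normal(17, s))))
            records.append(rec(f"b{i}", species="b",
                               d13C=float(rng.normal(-15 + delta, s)),
                               d15N=float(rng.normal(17, s))))
        ds = standardize(records)
        df = ds.to_frame()
        raw_a = np.mean([r.d13C for r in records if r.species == "a"])
        raw_b = np.mean([r.d13C for r in records if r.species == "b"])
        pooled_sd = np.std([r.d13C for r in records], ddof=1)
        observed = (
            df[df.species == "b"].z13C.mean() - df[df.species == "a"].z13C.mean()
        )
        # affine transform: z-scale contrast is the raw contrast over pooled SD
        assert observed == pytest.approx((raw_b - raw_a) / pooled_sd, rel=1e-9)
        # and the empirical contrast matches the planted delta
        assert raw_b - raw_a == pytest.approx(delta, abs=0.15)

    def test_single_record_tissue_is_degenerate(self):
        records = [rec("i1"), rec("i2"), rec("i3", tissue="body_feather")]
        with pytest.raises(DegenerateTissueError, match="body_feather"):
            standardize(records)

    def test_zero_variance_tissue_is_degenerate(self):
        records = [rec("i1", d13C=-15.0), rec("i2", d13C=-15.0, d15N=17.0)]
        records[1] = IsotopeRecord("i2", "a", "breeding", "c1", "plasma",
                                   -15.0, 17.0)
        records[0] = IsotopeRecord("i1", "a", "breeding", "c1", "plasma",
                                   -15.0, 17.0)
        with pytest.raises(DegenerateTissueError):
            standardize(records)

    def test_per_season_flag_fits_one_transform_per_tissue_season(self):
        records = []
        for season, shift in (("breeding", 0.0), ("non_breeding", 3.0)):
            for i in range(5):
                records.append(
                    IsotopeRecord(f"{season}{i}", "a", season, "c1", "plasma",
                                  -15.0 + shift + i * 0.1, 17.0 + i * 0.1)
                )
        ds = standardize(records, per_season=True)
        df = ds.to_frame()
        for _, grp in df.groupby(["tissue", "season"]):
            assert abs(grp.z13C.mean()) < 1e-10
        # default pooling preserves the seasonal contrast instead
        ds_pooled = standardize(records)
        dfp = ds_pooled.to_frame()
        seasonal_gap = (
            dfp[dfp.season == "non_breeding"].z13C.mean()
            - dfp[dfp.season == "breeding"].z13C.mean()
        )
        assert seasonal_gap > 1.0
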