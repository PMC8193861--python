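"""I/O round trips, censoring tokens, dialects and metadata validation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryomir.errors import (
    FormatError,
    IntegrityError,
    RowParseError,
    ValidationError,
)
from embryomir.qpcr_io import (
    PANEL_A,
    PANEL_B,
    ArrayDialect,
    AssayMeasurement,
    SampleMeta,
    VolumeModel,
    canonical_mirna_id,
    parse_array_export,
    parse_assay_table,
    parse_sample_meta,
    write_array_export,
    write_assay_table,
    write_results,
    write_sample_meta,
)
from embryomir.simulate import SimConfig, simulate_array_screen, simulate_experiment


# ---------------------------------------------------------------- domain types


def test_measurement_invariants():
    with pytest.raises(ValidationError):
        AssayMeasurement("", "s", 20.0)
    with pytest.raises(ValidationError):
        AssayMeasurement("miR-1", "s", -3.0)
    with pytest.raises(ValidationError):
        AssayMeasurement("miR-1", "s", 20.0, delta_rn=-0.1)
    m = AssayMeasurement("miR-1", "s", None, 0.02)
    assert m.censored


def test_sample_meta_vocabulary():
    with pytest.raises(ValidationError):
        SampleMeta("s1", "plasma")
    with pytest.raises(ValidationError):
        SampleMeta("s1", "cohort_lysate", replicate=0)
    with pytest.raises(ValidationError):
        SampleMeta("s1", "cohort_lysate", cohort_size=0)
    assert SampleMeta("s1", "conditioned_media", stage="blastocyst").group == "blastocyst"
    assert SampleMeta("s1", "conditioned_media", stage="blastocyst",
                      treatment="rhein").group == "rhein"


def test_volume_model_derived_equivalent():
    vm = VolumeModel()
    # 15/(15+15) * 2.5 uL of media per data point; droplet scale 20/1.25 = 16
    assert vm.media_equivalent_per_datapoint_ul == pytest.approx(1.25)
    assert vm.scale_media == pytest.approx(16.0)
    assert vm.scale_lysate == pytest.approx(1.1)
    with pytest.raises(ValidationError):
        VolumeModel(droplet_volume_ul=0)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("mmu-miR-294-3p", "miR-294-3p"),
        ("  mir-294-3p ", "miR-294-3p"),
        ("hsa-miR-372", "miR-372"),
        ("miR-191-5p", "miR-191-5p"),
    ],
)
def test_canonical_mirna_id(raw, expected):
    assert canonical_mirna_id(raw) == expected


def test_panel_membership():
    assert len(PANEL_A.members) == 5 and len(PANEL_B.members) == 5
    assert "miR-191-5p" in PANEL_A.members
    assert "miR-294-3p" in PANEL_B.members


# ---------------------------------------------------------------- array export


def test_array_export_round_trip(tmp_path):
    screen = simulate_array_screen(SimConfig(seed=2), n_targets=50,
                                   planted_counts={"undetected": 30,
                                                   "conditioned_exclusive_strict": 20})
    path = write_array_export(screen.array_conditioned, tmp_path / "a.csv")
    back = parse_array_export(path, sample_id="array_conditioned")
    assert back == screen.array_conditioned  # censoring flags included


def test_array_export_row_count_and_censoring(tmp_path):
    p = tmp_path / "x.csv"
    p.write_text(
        "Well,Target Name,CT,Delta Rn\n"
        "1,mmu-miR-294-3p,28.5,1.2\n"
        "2,mmu-miR-1a,Undetermined,0.02\n"
        "3,mmu-miR-2,41.0,0.9\n"
    )
    recs = parse_array_export(p)
    assert len(recs) == 3
    assert recs[0].ct == pytest.approx(28.5) and recs[0].mirna_id == "miR-294-3p"
    assert recs[1].censored
    assert recs[2].censored  # at/past the 40-cycle limit


def test_array_export_missing_drn_column(tmp_path):
    p = tmp_path / "x.csv"
    p.write_text("Well,Target Name,CT\n1,miR-1,20.0\n")
    with pytest.raises(FormatError, match="Delta Rn"):
        parse_array_export(p)
    # a dialect that does not require dRn accepts the same file
    recs = parse_array_export(p, ArrayDialect(drn_col=None))
    assert recs[0].delta_rn is None


def test_array_export_bad_ct_reports_row(tmp_path):
    p = tmp_path / "x.csv"
    p.write_text("Well,Target Name,CT,Delta Rn\n1,miR-1,oops,1.0\n2,miR-2,20,1.0\n")
    with pytest.raises(RowParseError, match="row 0"):
        parse_array_export(p)
    recs, errors = parse_array_export(p, errors="collect")
    # no row silently dropped: records + reported errors = data rows
    assert len(recs) + len(errors) == 2


# ---------------------------------------------------------------- assay tables


def test_assay_table_fixture_dimensions(tmp_path):
    """10 panel miRNAs x 4 sample types x 3 replicates -> 120 rows, 12 metas."""
    mirnas = PANEL_A.members + PANEL_B.members
    measurements, metas = [], []
    for stype in ("cohort_lysate", "conditioned_media", "blank_media", "water"):
        for rep in (1, 2, 3):
            sid = f"{stype}_r{rep}"
            metas.append(SampleMeta(sid, stype, stage="blastocyst", replicate=rep))
            for m in mirnas:
                measurements.append(AssayMeasurement(m, sid, 25.0))
    apath = write_assay_table(measurements, tmp_path / "a.tsv")
    mpath = write_sample_meta(metas, tmp_path / "m.tsv")
    ms, sm = parse_assay_table(apath, mpath)
    assert len(ms) == 120 and len(sm) == 12


def test_assay_table_duplicate_pair_rejected(tmp_path):
    p = tmp_path / "a.tsv"
    p.write_text(
        "mirna_id\tsample_id\tct\n"
        "miR-294-3p\trep1-lysate\t22.0\n"
        "miR-294-3p\trep1-lysate\t23.0\n"
    )
    with pytest.raises(IntegrityError, match="duplicate"):
        parse_assay_table(p)


def test_assay_table_empty_file(tmp_path):
    p = tmp_path / "a.tsv"
    p.write_text("")
    ms, sm = parse_assay_table(p)
    assert ms == [] and sm == []


def test_assay_table_unknown_sample_type(tmp_path):
    a = tmp_path / "a.tsv"
    a.write_text("mirna_id\tsample_id\tct\nmiR-1\ts1\t20\n")
    m = tmp_path / "m.tsv"
    m.write_text("sample_id\tsample_type\ns1\tserum\n")
    with pytest.raises(ValidationError, match="sample_type"):
        parse_assay_table(a, m)


def test_simulated_dataset_round_trip(tmp_path, noise_free_dataset):
    """write -> parse yields identical measurements, censoring flags included."""
    paths = noise_free_dataset.to_files(tmp_path)
    ms, sm = parse_assay_table(paths["assays"], paths["sample_meta"])
    assert ms == noise_free_dataset.measurements
    assert sm == noise_free_dataset.metas


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    cts=st.lists(
        st.one_of(st.none(), st.floats(min_value=5.0, max_value=39.9)),
        min_size=1,
        max_size=12,
    )
)
def test_round_trip_property_arbitrary_ct(tmp_path_factory, cts):
    tmp = tmp_path_factory.mktemp("rt")
    measurements = [
        AssayMeasurement(f"miR-{i}", "s1", ct) for i, ct in enumerate(cts)
    ]
    path = write_assay_table(measurements, tmp / "a.tsv")
    back, _ = parse_assay_table(path)
    assert back == measurements


# ---------------------------------------------------------------- results


def test_write_results_round_trip(tmp_path, noise_free_dataset):
    from embryomir.qpcr_io import read_result_table
    from embryomir.quantify import build_expression_profiles

    prof = build_expression_profiles(
        noise_free_dataset.measurements, noise_free_dataset.metas
    )
    paths = write_results({"expression_profiles": prof.data}, tmp_path / "out",
                          metadata={"seed": 11})
    back = read_result_table(paths["expression_profiles"])
    assert (back["rq"] == prof.data["rq"]).all()  # bit-exact float round trip
    assert (tmp_path / "out" / "run_metadata.json").exists()


def test_write_results_missing_dir_no_create(tmp_path):
    import pandas as pd

    with pytest.raises(IOError):
        write_results({"t": pd.DataFrame({"a": [1]})}, tmp_path / "nope",
                      create_dirs=False)


def test_sample_meta_duplicate_ids(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("sample_id\tsample_type\ns1\twater\ns1\twater\n")
    with pytest.raises(IntegrityError):
        parse_sample_meta(p)
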