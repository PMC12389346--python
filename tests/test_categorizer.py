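"""Binning schemes, composite indices, excipient indicator and the 27-feature row."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budcast import (
    FEATURE_COLUMNS,
    SCHEMES,
    assign_class,
    delta_report,
    encode_excipients,
    featurize,
    molecular_structure_class,
    molecule_class,
    storage_class,
)
from budcast.categorizer import PACKAGING_CLASS, BinningScheme


def brute_force_class(value: float, scheme: BinningScheme) -> int:
    """Independent oracle: linear scan over explicit bin edges."""
    edges = scheme.edges()
    for k, edge in enumerate(edges, start=1):
        if value < edge:
            return k
    return scheme.class_count


class TestAssignClass:
    @pytest.mark.parametrize(
        "scheme, value, expected",
        [
            ("mw", 94.12, 2),       # verified against the edge-scan oracle
            ("logp", -10.5, 1),     # below the lowest bound
            ("logp", 13.0, 46),     # above the highest bound
            ("temperature", 25.0, 10),
            ("content", 4.0, 1),
            ("rb", 0, 1), ("rb", 2, 1), ("rb", 3, 2), ("rb", 5, 2), ("rb", 21, 8),
        ],
    )
    def test_examples(self, scheme, value, expected):
        assert assign_class(value, SCHEMES[scheme]) == expected
        assert brute_force_class(value, SCHEMES[scheme]) == expected

    def test_non_finite_rejected(self):
        for bad in (float("nan"), float("inf")):
            with pytest.raises(ValueError, match="finite"):
                assign_class(bad, SCHEMES["mw"])

    @pytest.mark.parametrize("name", list(SCHEMES))
    def test_partition_and_monotonicity_against_brute_force(self, name):
        # dense grid spanning [lower - 3 step, upper + 3 step]
        s = SCHEMES[name]
        lo = s.lower_open_bound - 3 * s.step
        hi = s.lower_open_bound + s.step * (s.class_count + 1)
        grid = np.linspace(lo, hi, 2001)
        classes = [assign_class(v, s) for v in grid]
        assert classes == [brute_force_class(v, s) for v in grid]
        assert all(1 <= c <= s.class_count for c in classes)
        assert all(b >= a for a, b in zip(classes, classes[1:])), "monotone non-decreasing"
        assert classes[0] == 1 and classes[-1] == s.class_count

    def test_scheme_cardinalities(self):
        expected = {
            "mw": 25, "logp": 46, "rb": 8, "ps": 21,
            "hbd": 8, "hba": 8, "ar": 8, "content": 10, "temperature": 15,
        }
        assert {k: s.class_count for k, s in SCHEMES.items()} == expected
        assert len([p for p in PACKAGING_CLASS if p is not None]) == 3


class TestExcipientIndicator:
    def test_printed_examples(self):
        assert encode_excipients({"lactose"}) == (1, 0, 0, 0, 0, 0, 0)
        assert encode_excipients({"lactose", "cellulose"}) == (1, 0, 1, 0, 0, 0, 0)
        assert encode_excipients(set()) == (0, 0, 0, 0, 0, 0, 0)

    def test_order_insensitive_and_sum(self):
        a = encode_excipients(["lactose", "silica"])
        b = encode_excipients(["silica", "lactose"])
        assert a == b
        assert sum(a) == 2
        assert encode_excipients(["mannitol", "mannitol"]) == encode_excipients(["mannitol"])

    def test_reserved_position_zero_and_unknown_rejected(self):
        for combo in (set(), {"hpmc"}, {"sucrose", "silica"}):
            assert encode_excipients(combo)[6] == 0
        with pytest.raises(ValueError, match="lactulose"):
            encode_excipients({"lactulose"})


class TestCompositeIndices:
    @pytest.mark.parametrize(
        "api_name, mc, msc",
        [
            ("Melatonin", 31, 6),
            ("Menadione", 30, 4),
            ("Captopril", 29, 6),
            ("4-Aminopyridine", 24, 4),
            ("Clonidine hydrochloride", 33, 5),
            ("Midazolam Hydrochloride", 38, 6),
        ],
    )
    def test_consistent_rows_match_printed_values(self, dataset, api_name, mc, msc):
        api = dataset.apis[api_name]
        assert molecule_class(api) == mc
        assert molecular_structure_class(api) == msc

    def test_composite_conservation_on_all_fixture_rows(self, dataset, features):
        for _, row in features.iterrows():
            assert row["mc"] == row["mw_class"] + row["logp_class"] + row["rb_class"]
            assert row["msc"] == (
                row["ps_class"] + row["hbd_class"] + row["hba_class"] + row["ar_class"]
            )
            assert row["storage_class"] == (
                row["packaging_class"] + row["content_class"] + row["temperature_class"]
            )

    def test_delta_report_covers_every_api(self, dataset):
        report = delta_report(dataset)
        assert len(report) == 22
        consistent = report[report["api"] == "Melatonin"].iloc[0]
        assert consistent["mc_delta"] == 0 and consistent["msc_delta"] == 0
        # at least one printed value disagrees with the convention — reported, not hidden
        assert (report["mc_delta"].abs() + report["msc_delta"].abs()).max() > 0


class TestStorageClass:
    @pytest.mark.parametrize(
        "packaging, content, temp, expected",
        [
            ("glass", 4.0, 25.0, 12),   # 1 + 1 + 10
            ("glass", 5.0, -20.0, 3),   # 1 + 1 + 1
            (None, None, 25.0, 10),     # unknowns contribute 0
            ("paper", 95.0, 50.0, 28),  # 3 + 10 + 15
        ],
    )
    def test_examples(self, packaging, content, temp, expected):
        assert storage_class(packaging, content, temp) == expected

    def test_unknown_packaging_rejected(self):
        with pytest.raises(ValueError, match="packaging"):
            storage_class("tin", 5.0, 25.0)


class TestFeaturize:
    def test_feature_count_is_27(self, features):
        assert len(FEATURE_COLUMNS) == 27
        assert list(features.columns) == list(FEATURE_COLUMNS) + ["bud_days"]

    def test_melatonin_hpmc_row(self, dataset):
        rec = next(
            r for r in dataset.records
            if r.api_name == "Melatonin" and "hpmc" in r.excipients
        )
        row = featurize(rec, dataset)
        assert row["excipient_vector"] == "1000010"
        assert row["mc"] == 31 and row["msc"] == 6
        assert row["packaging_class"] == 1  # glass
        assert row["bud_days"] == 90

    def test_label_codes_follow_first_appearance(self, features, dataset):
        assert features["name_code"].iloc[0] == 0  # first API in file order
        # codes are dense integers starting at 0
        codes = sorted(features["name_code"].unique())
        assert codes == list(range(len(codes)))

    def test_excipient_order_irrelevant(self, dataset):
        from budcast.amf_db import StabilityRecord

        a = StabilityRecord("Melatonin", "lactose", "silica", "glass", 1.0, 5.0, 25.0, 90.0)
        b = StabilityRecord("Melatonin", "silica", "lactose", "glass", 1.0, 5.0, 25.0, 90.0)
        ra, rb = featurize(a, dataset), featurize(b, dataset)
        assert ra["excipient_vector"] == rb["excipient_vector"]


@settings(max_examples=200, deadline=None)
@given(
    value=st.floats(min_value=-1e4, max_value=1e4, allow_nan=False),
    name=st.sampled_from(sorted(SCHEMES)),
)
def test_every_real_value_gets_exactly_one_class(value, name):
    s = SCHEMES[name]
    c = assign_class(value, s)
    assert 1 <= c <= s.class_count
    assert c == brute_force_class(value, s)
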