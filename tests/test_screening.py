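"""Suspect matching, the filter cascade, and conjugate searches."""

import itertools

import numpy as np
import pytest

from wwscreen.registry import SuspectEntry, default_adducts
from wwscreen.screening import (
    CRITERIA,
    FilterReport,
    diagnostic_fragment_search,
    filter_cascade,
    match_suspects,
    neutral_loss_search,
    ppm_error,
)

from conftest import make_component, make_hit, tiny_ms2

MH_ONLY = [a for a in default_adducts("positive") if a.label == "[M+H]+"]


class TestPpmError:
    def test_five_ppm(self):
        assert ppm_error(242.11877, 242.11756) == pytest.approx(5.00, abs=0.01)

    def test_identity(self):
        assert ppm_error(242.11756, 242.11756) == 0.0

    def test_sign(self):
        assert ppm_error(242.117, 242.118) < 0

    def test_invalid_expected(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)


class TestMatchSuspects:
    def test_exact_match(self):
        comp = make_component(mz=242.11756)
        suspect = SuspectEntry("mefenamic_acid", "C15H15NO2")
        hits = match_suspects([comp], [suspect], MH_ONLY)
        assert len(hits) == 1
        assert hits[0].ppm_error == pytest.approx(0.0, abs=0.05)

    def test_off_mass_no_match(self):
        comp = make_component(mz=242.13000)  # ~51 ppm away
        suspect = SuspectEntry("mefenamic_acid", "C15H15NO2")
        assert match_suspects([comp], [suspect], MH_ONLY) == []

    def test_isobars_both_kept(self):
        comp = make_component(mz=242.11756)
        isobar = SuspectEntry("isobar", "C15H15NO2")
        suspect = SuspectEntry("mefenamic_acid", "C15H15NO2")
        hits = match_suspects([comp], [suspect, isobar], MH_ONLY)
        assert {h.suspect.name for h in hits} == {"mefenamic_acid", "isobar"}

    def test_decoy_within_tolerance_matches(self, demo_dataset, demo_result):
        """Isobaric decoys are picked up by exact mass (and must be caught
        later by RT/MS2 evidence, not here)."""
        gt = demo_dataset.ground_truth.compounds
        decoys = gt[gt.kind == "decoy"]
        found = sum(
            any(
                abs(h.component.mz - d.mz_mh) / d.mz_mh * 1e6 <= 6.0
                and abs(h.component.rt - d.true_rt) <= 0.3
                for h in demo_result.hits
            )
            for d in decoys.itertuples()
        )
        assert found == len(decoys)


def _cascade_fixture():
    """10 hits: 2 sub-intensity, 1 early RT, 3 without MS2, 1
    blank-dominated, 3 clean."""
    ms2 = tiny_ms2()
    hits = []
    samples = {"S1": 5e5, "S2": 4e5}
    for _ in range(2):  # sub-intensity
        hits.append(make_hit(sample_intensity={"S1": 5e4, "S2": 2e4}, ms2=ms2))
    hits.append(make_hit(rt=2.0, sample_intensity=samples, ms2=ms2))  # dead time
    for _ in range(3):  # no MS2
        hits.append(make_hit(sample_intensity=samples, ms2=None))
    blank_hit = make_hit(
        sample_intensity={"S1": 5e5, "S2": 4e5, "B1": 3e5}, ms2=ms2
    )
    hits.append(blank_hit)  # blank-dominated (blank*10 >= sample mean)
    for _ in range(3):  # clean
        hits.append(make_hit(sample_intensity=samples, ms2=ms2))
    return hits


class TestFilterCascade:
    def test_constructed_fixture_accounting(self):
        hits = _cascade_fixture()
        retained, report = filter_cascade(
            hits, sample_ids=["S1", "S2"], blank_ids=["B1"]
        )
        assert len(retained) == 3
        assert report.removed_per_criterion == {
            "intensity": 2, "peak_shape": 0, "ms2": 3, "background": 1, "rt": 1,
        }
        assert report.input_count == 10

    def test_all_clean_identity(self):
        ms2 = tiny_ms2()
        hits = [make_hit(ms2=ms2, sample_intensity={"S1": 5e5}) for _ in range(4)]
        retained, report = filter_cascade(hits, sample_ids=["S1"])
        assert len(retained) == 4
        assert sum(report.removed_per_criterion.values()) == 0

    def test_empty_input(self):
        retained, report = filter_cascade([], sample_ids=["S1"])
        assert retained == []
        assert report.input_count == 0

    def test_removal_reason_set_iff_failed(self):
        hits = _cascade_fixture()
        filter_cascade(hits, sample_ids=["S1", "S2"], blank_ids=["B1"])
        for hit in hits:
            assert (hit.removal_reason is not None) == (not hit.passed_filters)

    def test_conservation_on_random_inputs(self):
        rng = np.random.default_rng(11)
        ms2 = tiny_ms2()
        for _ in range(200):
            n = int(rng.integers(0, 20))
            hits = [
                make_hit(
                    rt=float(rng.uniform(0, 34)),
                    sample_intensity={
                        "S1": float(rng.uniform(1e3, 1e6)),
                        "B1": float(rng.uniform(0, 5e5)),
                    },
                    peak_rating=float(rng.uniform(0, 10)),
                    ms2=ms2 if rng.random() < 0.6 else None,
                )
                for _ in range(n)
            ]
            retained, report = filter_cascade(
                hits, sample_ids=["S1"], blank_ids=["B1"]
            )
            assert report.input_count == len(hits)
            assert report.retained_count + sum(
                report.removed_per_criterion.values()
            ) == len(hits)

    def test_retained_set_invariant_under_order_permutation(self):
        rng = np.random.default_rng(12)
        ms2 = tiny_ms2()
        hits = [
            make_hit(
                rt=float(rng.uniform(0, 34)),
                sample_intensity={
                    "S1": float(rng.uniform(1e3, 1e6)),
                    "B1": float(rng.uniform(0, 5e5)),
                },
                peak_rating=float(rng.uniform(0, 10)),
                ms2=ms2 if rng.random() < 0.6 else None,
            )
            for _ in range(30)
        ]
        reference = None
        for order in itertools.permutations(CRITERIA):
            retained, _ = filter_cascade(
                hits, sample_ids=["S1"], blank_ids=["B1"], order=order
            )
            ids = {id(h) for h in retained}
            if reference is None:
                reference = ids
            assert ids == reference

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            filter_cascade([], sample_ids=["S1"], order=("intensity",))

    def test_report_validates_conservation(self):
        with pytest.raises(ValueError):
            FilterReport(input_count=5, removed_per_criterion={"rt": 1},
                         retained_count=5)


class TestConjugateSearches:
    def test_glucuronide_neutral_loss(self):
        sp = tiny_ms2("glu", 300.0, peaks=[(123.96791, 10.0)])
        flags = neutral_loss_search([sp])
        assert flags["glu"] == ["glucuronide"]

    def test_sulfate_neutral_loss(self):
        sp = tiny_ms2("sul", 300.0, peaks=[(220.04319, 10.0)])
        assert neutral_loss_search([sp])["sul"] == ["sulfate"]

    def test_no_qualifying_fragment(self):
        sp = tiny_ms2("none", 300.0, peaks=[(150.0, 10.0)])
        assert neutral_loss_search([sp])["none"] == []

    def test_diagnostic_fragment_hit_within_tolerance(self):
        sp = tiny_ms2("d", 351.0, peaks=[(175.0253, 5.0)])
        sp.polarity = "negative"
        assert diagnostic_fragment_search([sp])["d"] == ["glucuronide"]

    def test_diagnostic_empty_peaks_no_flag(self):
        sp = tiny_ms2("e", 351.0, peaks=[(120.0, 1.0)])
        assert diagnostic_fragment_search([sp])["e"] == []

    def test_zero_tolerance_exact_grid(self):
        sp = tiny_ms2("z", 400.0, peaks=[(175.024814, 2.0)])
        flags = diagnostic_fragment_search([sp], tol_da=0.0)
        assert flags["z"] == ["glucuronide"]
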