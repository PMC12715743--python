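"""DDA/DIA precursor prioritization on simulated ground truth."""

from dataclasses import replace

import numpy as np
import pytest

from dfiscreen.chem import ppm_error
from dfiscreen.screen import (
    PrecursorCandidate,
    ScreenParams,
    export_inclusion_list,
    screen_dda,
    screen_dia,
)
from dfiscreen.simulate import (
    CompoundSpec,
    default_matrix,
    generate_run,
    specs_from_standards,
)

WINDOW = (5.0, 9.0)


@pytest.fixture(scope="module")
def dda_pair(registry):
    specs = specs_from_standards(["MeP", "EtP", "PrP"], 25.0)
    run, truth = generate_run(specs, mode="DDA", seed=11, rt_window=WINDOW,
                              registry=registry)
    blank, _ = generate_run([], mode="DDA", seed=12, rt_window=WINDOW,
                            registry=registry)
    return run, blank, truth


def _recovered(candidates, mz, rt, rt_tol=0.2):
    return any(
        abs(ppm_error(c.mz, mz)) <= 5 and abs(c.rt - rt) <= rt_tol
        for c in candidates
    )


class TestScreenDda:
    def test_recovers_spiked_parabens(self, dda_pair, registry, params):
        run, blank, truth = dda_pair
        cands = screen_dda(run, [blank], registry, params)
        for entry in truth.entries:
            assert entry.expected_candidate
            assert _recovered(cands, entry.mz, entry.rt), entry.name
        for c in cands:
            assert c.n_matched >= params.min_diagnostic_ions
            assert c.blank_ratio_observed >= params.blank_ratio
            assert c.formula_candidates

    def test_class_call_and_formula(self, dda_pair, registry, params):
        run, blank, _ = dda_pair
        cands = screen_dda(run, [blank], registry, params)
        mep = next(c for c in cands if abs(ppm_error(c.mz, 151.0395)) <= 5)
        assert mep.class_call == "paraben"
        assert mep.formula_candidates[0].formula.hill() == "C8H8O3"
        # MeP's applicable set lacks the heterolytic branch: 5 ions, not 7
        assert mep.n_matched == 5

    def test_blank_screened_against_itself_is_empty(self, registry, params):
        blank, _ = generate_run([], mode="DDA", seed=13, rt_window=WINDOW,
                                registry=registry)
        assert screen_dda(blank, [blank], registry, params) == []

    def test_three_ion_precursor_excluded(self, registry, params):
        """A compound yielding only three diagnostic ions fails the >=4 rule."""
        profile = {
            20.0: {"A1": 0.6, "A2": 0.3, "B1": 0.2},
            40.0: {"A1": 0.3, "A2": 0.2, "B1": 0.4},
        }
        spec = CompoundSpec(
            name="EtP-sparse", formula="C9H10O3", rt=6.9,
            compound_class="paraben", concentration=25.0,
            fragment_profile=profile,
        )
        run, _ = generate_run([spec], mode="DDA", seed=14, rt_window=WINDOW,
                              registry=registry)
        blank, _ = generate_run([], mode="DDA", seed=15, rt_window=WINDOW,
                                registry=registry)
        assert screen_dda(run, [blank], registry, params) == []

    def test_interference_channels_rejected(self, dda_pair, registry, params):
        # benzophenone-like channels (91.0184 only) are in the matrix and
        # trigger MS2, yet never survive the >= 4-ion rule
        run, blank, truth = dda_pair
        cands = screen_dda(run, [blank], registry, params)
        truth_mzs = [e.mz for e in truth.entries]
        for c in cands:
            assert any(abs(ppm_error(c.mz, mz)) <= 5 for mz in truth_mzs)

    def test_min_ions_monotonicity(self, dda_pair, registry, params):
        """Raising min_diagnostic_ions never adds candidates."""
        run, blank, _ = dda_pair
        loose = screen_dda(run, [blank], registry, params)
        strict = screen_dda(
            run, [blank], registry, replace(params, min_diagnostic_ions=6)
        )
        loose_keys = {(round(c.mz, 3), round(c.rt, 2)) for c in loose}
        strict_keys = {(round(c.mz, 3), round(c.rt, 2)) for c in strict}
        assert strict_keys <= loose_keys

    def test_blank_ratio_monotonicity(self, dda_pair, registry, params):
        """Lowering the blank-ratio threshold never removes candidates."""
        run, blank, _ = dda_pair
        base = screen_dda(run, [blank], registry, params)
        lax = screen_dda(run, [blank], registry, replace(params, blank_ratio=1.5))
        base_keys = {(round(c.mz, 3), round(c.rt, 2)) for c in base}
        lax_keys = {(round(c.mz, 3), round(c.rt, 2)) for c in lax}
        assert base_keys <= lax_keys

    def test_non_dda_input_rejected(self, registry, params):
        run, _ = generate_run([], mode="DIA", seed=16, rt_window=(0, 1),
                              registry=registry)
        with pytest.raises(ValueError, match="DDA"):
            screen_dda(run, [run], registry, params)

    def test_requires_blank(self, dda_pair, registry, params):
        run, _, _ = dda_pair
        with pytest.raises(ValueError, match="blank"):
            screen_dda(run, [], registry, params)


@pytest.fixture(scope="module")
def dia_pair(registry):
    specs = specs_from_standards(["MeP", "EtP", "PrP"], 25.0)
    run, truth = generate_run(specs, mode="DIA", seed=21, rt_window=WINDOW,
                              registry=registry)
    blank, _ = generate_run([], mode="DIA", seed=22, rt_window=WINDOW,
                            registry=registry)
    return run, blank, truth


class TestScreenDia:
    def test_accepts_monotone_precursors(self, dia_pair, registry, params):
        run, blank, truth = dia_pair
        cands = screen_dia(run, [blank], registry, params)
        for entry in truth.entries:
            assert _recovered(cands, entry.mz, entry.rt), entry.name

    def test_rejects_non_monotone_ce_series(self, registry, params):
        specs = specs_from_standards(["PrP"], 25.0)
        bad = replace(
            specs_from_standards(["MeP"], 25.0)[0],
            name="MeP-nonmono",
            survival={10.0: 0.6, 20.0: 0.7, 40.0: 0.1},
        )
        run, _ = generate_run(specs + [bad], mode="DIA", seed=23,
                              rt_window=WINDOW, registry=registry)
        blank, _ = generate_run([], mode="DIA", seed=24, rt_window=WINDOW,
                                registry=registry)
        cands = screen_dia(run, [blank], registry, params)
        assert _recovered(cands, specs[0].mz, specs[0].rt)
        assert not any(abs(ppm_error(c.mz, bad.mz)) <= 5 for c in cands)

    def test_rejects_below_intensity_floor(self, registry, params):
        # 1 ng/mL -> apex ~3.4e4, below the 1e5 CE-0 floor
        weak = specs_from_standards(["EtP"], 1.0)
        run, _ = generate_run(weak, mode="DIA", seed=25, rt_window=WINDOW,
                              registry=registry)
        blank, _ = generate_run([], mode="DIA", seed=26, rt_window=WINDOW,
                                registry=registry)
        assert screen_dia(run, [blank], registry, params) == []

    def test_dda_dia_concordance(self, registry, params):
        """The same analyte simulated in both modes yields candidates at the
        same m/z (+-5 ppm) and retention time."""
        specs = specs_from_standards(["EtP"], 25.0)
        dda, _ = generate_run(specs, mode="DDA", seed=27, rt_window=WINDOW,
                              registry=registry)
        dia, _ = generate_run(specs, mode="DIA", seed=28, rt_window=WINDOW,
                              registry=registry)
        blank_dda, _ = generate_run([], mode="DDA", seed=29, rt_window=WINDOW,
                                    registry=registry)
        blank_dia, _ = generate_run([], mode="DIA", seed=30, rt_window=WINDOW,
                                    registry=registry)
        c_dda = screen_dda(dda, [blank_dda], registry, params)
        c_dia = screen_dia(dia, [blank_dia], registry, params)
        assert len(c_dda) == len(c_dia) == 1
        assert abs(ppm_error(c_dda[0].mz, c_dia[0].mz)) <= 5
        assert abs(c_dda[0].rt - c_dia[0].rt) <= params.coelution_window


def test_screen_dia_rejects_dda_input(registry, params):
    run, _ = generate_run([], mode="DDA", seed=31, rt_window=(0, 1),
                          registry=registry)
    with pytest.raises(ValueError, match="DIA"):
        screen_dia(run, [run], registry, params)


class TestInclusionList:
    def _candidate(self, mz, rt):
        return PrecursorCandidate(
            mz=mz, rt=rt, matched_ions=[], n_matched=4,
            blank_ratio_observed=float("inf"), formula_candidates=[],
            class_call="paraben", source="DDA",
        )

    def test_window_arithmetic(self):
        frame = export_inclusion_list([self._candidate(151.0395, 6.20)])
        row = frame.iloc[0]
        assert row["mz"] == 151.0395
        assert row["rt_start"] == pytest.approx(6.00)
        assert row["rt_end"] == pytest.approx(6.40)

    def test_empty_list_gives_header_only(self):
        frame = export_inclusion_list([])
        assert len(frame) == 0
        assert list(frame.columns) == ["mz", "rt_start", "rt_end"]

    def test_shared_mz_distinct_rt_not_merged(self):
        frame = export_inclusion_list(
            [self._candidate(151.0395, 3.0), self._candidate(151.0395, 8.0)]
        )
        assert len(frame) == 2


class TestScreenParams:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ScreenParams(min_diagnostic_ions=0)
        with pytest.raises(ValueError):
            ScreenParams(blank_ratio=-1.0)
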