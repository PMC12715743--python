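"""Phase II conjugate screening and hydrolysis-comparison speciation."""

import math

import numpy as np
import pytest

from dfiscreen.compounds import get_standard
from dfiscreen.conjugates import (
    VERDICT_ABSENT,
    VERDICT_CONJUGATED,
    VERDICT_FREE,
    VERDICT_PARTIAL,
    compare_hydrolysis,
    screen_conjugates,
)
from dfiscreen.msio import Spectrum, SpectrumRun
from dfiscreen.simulate import CompoundSpec, generate_run, specs_from_standards


def _sulfate_spec(name, conc=25.0, rt=None):
    s = get_standard(name)
    return CompoundSpec(
        name=f"{name}-sulfate",
        formula=s.formula,
        rt=rt if rt is not None else max(1.2, s.rt - 1.5),
        compound_class=s.compound_class,
        concentration=conc,
        conjugate="sulfate",
        base_name=name,
    )


class TestScreenConjugates:
    def test_mep_sulfate_hit(self, registry, params):
        spec = _sulfate_spec("MeP", rt=4.4)
        run, _ = generate_run([spec], mode="DDA", seed=41, rt_window=(3.5, 5.5),
                              registry=registry)
        hits = screen_conjugates(run, registry, [get_standard("MeP")], params)
        assert len(hits) == 1
        h = hits[0]
        assert h.conjugation == "sulfate"
        assert h.target == "MeP"
        assert abs(h.precursor_mz - 230.9963) < 0.01
        assert h.n_evidence >= 3
        assert "SO3-." in h.evidence

    def test_4hb_sulfate_hit(self, registry, params):
        spec = _sulfate_spec("4-HB", rt=2.3)
        run, _ = generate_run([spec], mode="DDA", seed=42, rt_window=(1.5, 3.2),
                              registry=registry)
        hits = screen_conjugates(run, registry, [get_standard("4-HB")], params)
        assert len(hits) == 1
        assert hits[0].target == "4-HB"
        assert abs(hits[0].precursor_mz - 216.9807) < 0.01
        # the acid's phenolate daughter is part of the evidence
        assert "B1" in hits[0].evidence

    def test_mass_linkage_within_5ppm(self, registry, params):
        from dfiscreen.chem import ppm_error
        from dfiscreen.fragments import conjugate_mass

        spec = _sulfate_spec("EtP", rt=5.0)
        run, _ = generate_run([spec], mode="DDA", seed=43, rt_window=(4.2, 5.8),
                              registry=registry)
        hits = screen_conjugates(run, registry, [get_standard("EtP")], params)
        expected = conjugate_mass(get_standard("EtP").neutral, "sulfate")
        assert hits and abs(ppm_error(hits[0].precursor_mz, expected)) <= 5

    def test_precursor_without_free_fragment_is_no_hit(self, registry, params):
        """A precursor at the conjugate mass whose MS2 lacks the free-form
        ion is not evidence of a conjugate."""
        spectra = [Spectrum(0, 1, 1.0, [230.9963], [5e5])]
        for j, ce in enumerate((10.0, 20.0, 40.0)):
            spectra.append(
                Spectrum(j + 1, 2, 1.0 + (j + 1) * 1e-3,
                         [79.9568, 96.9596], [2e4, 1e4],
                         collision_energy=ce, acquisition="ddMS2",
                         precursor_mz=230.9963, isolation_width=1.5)
            )
        run = SpectrumRun(spectra, mode="DDA")
        assert screen_conjugates(run, registry, [get_standard("MeP")], params) == []

    def test_no_false_sulfate_hits_without_sulfates(self, registry, params):
        """Free-compound runs never produce sulfate (or glucuronide) hits."""
        targets = [get_standard(n) for n in ("MeP", "EtP", "PrP")]
        for seed in range(44, 50):
            specs = specs_from_standards(["MeP", "EtP", "PrP"], 25.0)
            run, _ = generate_run(specs, mode="DDA", seed=seed,
                                  rt_window=(5.0, 9.0), registry=registry)
            assert screen_conjugates(run, registry, targets, params) == []

    def test_non_dda_rejected(self, registry, params):
        run, _ = generate_run([], mode="DIA", seed=50, rt_window=(0, 1),
                              registry=registry)
        with pytest.raises(ValueError, match="DDA"):
            screen_conjugates(run, registry, [get_standard("MeP")], params)


@pytest.fixture(scope="module")
def runs(registry):
    window = (5.0, 7.7)
    free_high = specs_from_standards(["MeP", "EtP"], 25.0)
    free_low = specs_from_standards(["MeP"], 2.0)
    hyd, _ = generate_run(free_high, mode="DDA", seed=51,
                          rt_window=window, registry=registry)
    # unhydrolyzed: MeP mostly conjugated (low free), EtP absent
    unhyd, _ = generate_run(free_low, mode="DDA", seed=52,
                            rt_window=window, registry=registry)
    return hyd, unhyd


class TestCompareHydrolysis:
    def test_fold_gain_with_hit_is_predominantly_conjugated(self, runs, registry):
        hyd, unhyd = runs
        targets = [get_standard("MeP")]
        from dfiscreen.conjugates import ConjugateHit

        hit = ConjugateHit("sulfate", 230.9963, 4.4, "MeP", 151.0395,
                           ("[M-H]- MeP", "SO3-."), 2)
        report = compare_hydrolysis(hyd, unhyd, targets, [hit])
        row = report.set_index("target").loc["MeP"]
        assert row["fold_change"] >= 5
        assert row["verdict"] == VERDICT_CONJUGATED

    def test_absent_before_hydrolysis_with_hit(self, runs, registry):
        hyd, unhyd = runs
        targets = [get_standard("EtP")]
        from dfiscreen.conjugates import ConjugateHit

        hit = ConjugateHit("sulfate", 245.0120, 5.4, "EtP", 165.0552,
                           ("[M-H]- EtP", "SO3-."), 2)
        report = compare_hydrolysis(hyd, unhyd, targets, [hit])
        row = report.set_index("target").loc["EtP"]
        assert math.isinf(row["fold_change"])
        assert row["verdict"] == VERDICT_CONJUGATED

    def test_identical_runs_no_hit_is_predominantly_free(self, registry):
        specs = specs_from_standards(["MeP"], 25.0)
        run, _ = generate_run(specs, mode="DDA", seed=53, rt_window=(5.0, 6.8),
                              registry=registry)
        report = compare_hydrolysis(run, run, [get_standard("MeP")], [])
        assert report.iloc[0]["verdict"] == VERDICT_FREE
        assert report.iloc[0]["fold_change"] == pytest.approx(1.0)

    def test_absent_everywhere_is_not_detected(self, registry):
        blank, _ = generate_run([], mode="DDA", seed=54, rt_window=(5.0, 6.8),
                                registry=registry)
        report = compare_hydrolysis(blank, blank, [get_standard("MeP")], [])
        assert report.iloc[0]["verdict"] == VERDICT_ABSENT

    def test_moderate_gain_with_hit_is_partial(self, registry):
        window = (5.0, 6.8)
        hyd, _ = generate_run(specs_from_standards(["MeP"], 25.0), mode="DDA",
                              seed=55, rt_window=window, registry=registry)
        unhyd, _ = generate_run(specs_from_standards(["MeP"], 10.0), mode="DDA",
                                seed=56, rt_window=window, registry=registry)
        from dfiscreen.conjugates import ConjugateHit

        hit = ConjugateHit("sulfate", 230.9963, 4.4, "MeP", 151.0395,
                           ("[M-H]- MeP", "SO3-."), 2)
        report = compare_hydrolysis(hyd, unhyd, [get_standard("MeP")], [hit])
        assert report.iloc[0]["verdict"] == VERDICT_PARTIAL
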