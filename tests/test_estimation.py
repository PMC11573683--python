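"""Parameter estimation: proteome fractions, imputation, unit conversion,
specific activities, pathway molecular weights, correlated-protein selection."""

import numpy as np
import pytest

import atpmax as am
from atpmax.estimation import (
    EnzymeSlot,
    PathwayDefinition,
    PhysiologyMeasurement,
    ProteinEntry,
    ProteomicsSample,
)


def make_sample(sample_id, signals, complex_map=None, mito=(), mws=None):
    """signals: protein_id -> signal or None."""
    complex_map = complex_map or {}
    mws = mws or {}
    entries = [
        ProteinEntry(
            protein_id=pid,
            ms_signal=sig,
            molecular_weight=mws.get(pid, 50.0),
            complex_id=complex_map.get(pid, (None, 1.0))[0],
            subunit_stoichiometry=complex_map.get(pid, (None, 1.0))[1],
            is_mitochondrial=pid in mito,
        )
        for pid, sig in signals.items()
    ]
    return ProteomicsSample(sample_id, tuple(entries))


def single_protein_pathway(*pids):
    return PathwayDefinition("p", tuple(EnzymeSlot(p, (p,)) for p in pids))


class TestProteomeFraction:
    def test_signal_share_is_mass_share(self):
        s = make_sample("s1", {"a": 10.0, "b": 40.0, "c": 50.0})
        assert am.proteome_fraction(s, single_protein_pathway("a")) == pytest.approx(0.10)

    def test_whole_proteome_normalizes_to_one(self):
        s = make_sample("s1", {"a": 10.0, "b": 40.0, "c": 50.0})
        assert am.proteome_fraction(s, single_protein_pathway("a", "b", "c")) == 1.0

    def test_missing_signals_count_as_absent(self):
        s = make_sample("s1", {"a": 10.0, "b": None, "c": 90.0})
        assert am.proteome_fraction(s, single_protein_pathway("a", "b")) == pytest.approx(0.1)

    def test_zero_noise_synthetic_recovers_truth_exactly(self, yeast_truth_config):
        samples, _ = am.generate_proteomics(yeast_truth_config)
        defs = am.default_pathway_definitions()
        for s in samples:
            assert am.proteome_fraction(s, defs["glycolysis"]) == pytest.approx(0.05, abs=1e-12)
            assert am.proteome_fraction(s, defs["respiration"]) == pytest.approx(0.10, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            am.proteome_fraction(ProteomicsSample("s", ()), single_protein_pathway("a"))


class TestImputation:
    def test_missing_subunit_imputed_from_complex_partner(self):
        # A present (MW 100, stoich 1, signal 50); B missing everywhere
        # (MW 50, stoich 2) -> imputed to 50/(100*1) * (50*2) = 50
        cx = {"A": ("C1", 1.0), "B": ("C1", 2.0)}
        mws = {"A": 100.0, "B": 50.0}
        samples = [
            make_sample(f"s{i}", {"A": 50.0, "B": None, "X": 100.0}, cx, mws=mws)
            for i in range(5)
        ]
        out = am.impute_etc_subunits(samples)
        for s in out:
            assert s.entry("B").ms_signal == pytest.approx(50.0)
            assert s.entry("A").ms_signal == 50.0  # untouched
            assert s.entry("X").ms_signal == 100.0

    def test_no_missing_values_identity(self):
        cx = {"A": ("C1", 1.0), "B": ("C1", 1.0)}
        samples = [make_sample(f"s{i}", {"A": 10.0, "B": 20.0}, cx) for i in range(4)]
        out = am.impute_etc_subunits(samples)
        for before, after in zip(samples, out):
            for e_b, e_a in zip(before.entries, after.entries):
                assert e_b.ms_signal == e_a.ms_signal

    def test_threshold_is_strict_at_twenty_percent(self):
        cx = {"A": ("C1", 1.0), "B": ("C1", 1.0)}
        # B missing in exactly 1 of 5 samples (20%): left as missing
        samples = [
            make_sample(f"s{i}", {"A": 10.0, "B": None if i == 0 else 20.0}, cx)
            for i in range(5)
        ]
        out = am.impute_etc_subunits(samples)
        assert out[0].entry("B").ms_signal is None
        # missing in 2 of 5 (40%): imputed
        samples = [
            make_sample(f"s{i}", {"A": 10.0, "B": None if i < 2 else 20.0}, cx)
            for i in range(5)
        ]
        out = am.impute_etc_subunits(samples)
        assert out[0].entry("B").ms_signal is not None

    def test_fully_missing_complex_skipped_with_warning(self, caplog):
        cx = {"A": ("C1", 1.0), "B": ("C1", 1.0)}
        samples = [make_sample(f"s{i}", {"A": None, "B": None, "X": 5.0}, cx) for i in range(4)]
        with caplog.at_level("WARNING"):
            out = am.impute_etc_subunits(samples)
        assert "skipped" in caplog.text
        assert out[0].entry("A").ms_signal is None

    def test_never_negative_never_touches_observed(self, yeast_truth_config):
        import dataclasses
        cfg = dataclasses.replace(yeast_truth_config, noise_cv=0.1, missing_rate_etc=0.4, seed=7)
        samples, _ = am.generate_proteomics(cfg)
        out = am.impute_etc_subunits(samples)
        for before, after in zip(samples, out):
            for e_b, e_a in zip(before.entries, after.entries):
                if e_b.ms_signal is not None:
                    assert e_a.ms_signal == e_b.ms_signal
                elif e_a.ms_signal is not None:
                    assert e_a.ms_signal >= 0


class TestUnitConversion:
    def test_od600_conversion_reproduces_published_activities(self):
        # 750 and 390 mM OD600^-1 h^-1 at 192.5 mg protein/L -> 65 and 34
        m750 = PhysiologyMeasurement(
            "ecoli", "ref", "acetate", 750.0, "mM/OD600/h",
            metadata={"mg_protein_per_l_od": 192.5},
        )
        m390 = PhysiologyMeasurement(
            "ecoli", "ref", "OCR", 390.0, "mM/OD600/h",
            metadata={"mg_protein_per_l_od": 192.5},
        )
        assert round(am.convert_to_canonical(m750)) == 65
        assert round(am.convert_to_canonical(m390)) == 34

    def test_gcdw_conversion(self):
        m = PhysiologyMeasurement(
            "ecoli", "s", "acetate", 11.0, "mmol/gCDW/h",
            metadata={"protein_per_gcdw": 0.55},
        )
        # mmol/gCDW == umol/mgCDW; / 0.55 g protein per gCDW / 60 min
        assert am.convert_to_canonical(m) == pytest.approx(11.0 / 0.55 / 60.0)

    def test_per_cell_conversion(self):
        m = PhysiologyMeasurement(
            "mammalian", "s", "lactate", 9.0, "umol/1e6cells/h",
            metadata={"pg_protein_per_cell": 300.0},
        )
        # 1e6 cells at 300 pg = 0.3 mg protein
        assert am.convert_to_canonical(m) == pytest.approx(9.0 / 0.3 / 60.0)

    def test_canonical_passthrough_and_zero(self):
        m = PhysiologyMeasurement("yeast", "s", "ethanol", 0.37, "umol/mgProtein/min")
        assert am.convert_to_canonical(m) == 0.37
        z = PhysiologyMeasurement("yeast", "s", "ethanol", 0.0, "mmol/gCDW/h",
                                  metadata={"protein_per_gcdw": 0.44})
        assert am.convert_to_canonical(z) == 0.0

    def test_linearity(self):
        meta = {"protein_per_gcdw": 0.44}
        f = lambda x: am.convert_to_canonical(
            PhysiologyMeasurement("yeast", "s", "ethanol", x, "mmol/gCDW/h", metadata=meta)
        )
        assert f(3.0 * 2.5) == pytest.approx(2.5 * f(3.0), rel=1e-12)

    def test_missing_metadata_named_in_error(self):
        m = PhysiologyMeasurement("ecoli", "s", "OCR", 1.0, "mM/OD600/h", metadata={})
        with pytest.raises(ValueError, match="mg_protein_per_l_od"):
            am.convert_to_canonical(m)

    def test_unknown_unit_rejected_at_construction(self):
        with pytest.raises(ValueError, match="unit"):
            PhysiologyMeasurement("ecoli", "s", "OCR", 1.0, "furlongs/fortnight")


class TestSpecificActivity:
    def test_rate_over_fraction(self):
        assert am.specific_activity(0.1, 0.05) == pytest.approx(2.0)
        assert am.specific_activity(0.0, 0.3) == 0.0

    def test_nonpositive_fraction_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            am.specific_activity(0.1, 0.0)


class TestPathwayMolecularWeight:
    def test_single_enzyme_with_stoichiometry(self):
        pd_ = PathwayDefinition("p", (EnzymeSlot("e", ("a",), stoichiometry=2.0),))
        assert am.pathway_molecular_weight(pd_, {"a": 100.0}) == 200.0

    def test_isoforms_averaged(self):
        pd_ = PathwayDefinition("p", (EnzymeSlot("e", ("a", "b")),))
        assert am.pathway_molecular_weight(pd_, {"a": 90.0, "b": 110.0}) == 100.0

    def test_complex_subunits_weighted_by_stoichiometry(self):
        pd_ = PathwayDefinition(
            "p",
            (
                EnzymeSlot("e1", ("a", "b"), stoichiometry=2.0),
                EnzymeSlot("cx", (), subunits=(("s", 4.0),)),
            ),
        )
        mw = {"a": 90.0, "b": 110.0, "s": 50.0}
        assert am.pathway_molecular_weight(pd_, mw) == 400.0

    def test_unresolvable_ids_listed(self):
        pd_ = PathwayDefinition("p", (EnzymeSlot("e", ("a", "zzz")),))
        with pytest.raises(KeyError, match="zzz"):
            am.pathway_molecular_weight(pd_, {"a": 1.0})


class TestCorrelatedMitoSelection:
    def _samples(self, extra_signals):
        """5 samples; core respiration protein R with varying abundance."""
        out = []
        for i in range(5):
            signals = {"R": 10.0 * (i + 1), "BG": 100.0}
            for pid, series in extra_signals.items():
                signals[pid] = series[i]
            out.append(make_sample(f"s{i}", signals, mito=set(extra_signals)))
        return out

    def test_proportional_protein_included(self):
        samples = self._samples({"M1": [1, 2, 3, 4, 5]})
        core = single_protein_pathway("R")
        ext = am.select_correlated_mito(samples, core)
        assert "M1" in ext.protein_ids()

    def test_anticorrelated_protein_excluded(self):
        samples = self._samples({"M1": [5, 4, 3, 2, 1]})
        ext = am.select_correlated_mito(samples, single_protein_pathway("R"))
        assert "M1" not in ext.protein_ids()

    def test_too_few_samples_rejected(self):
        samples = self._samples({"M1": [1, 2, 3, 4, 5]})[:3]
        with pytest.raises(ValueError, match="4 samples"):
            am.select_correlated_mito(samples, single_protein_pathway("R"))

    def test_false_inclusion_controlled_under_null(self):
        # 300 independent-noise mitochondrial proteins, 10 samples, no true
        # correlate: BH at 5% keeps the false-inclusion fraction below 5%
        rng = np.random.default_rng(0)
        n_proteins, n_samples = 300, 10
        noise = rng.lognormal(0, 1, size=(n_proteins, n_samples))
        samples = []
        for j in range(n_samples):
            signals = {"R": float(rng.lognormal(2, 0.5))}
            for i in range(n_proteins):
                signals[f"M{i:03d}"] = float(noise[i, j])
            samples.append(
                make_sample(f"s{j}", signals, mito={f"M{i:03d}" for i in range(n_proteins)})
            )
        ext = am.select_correlated_mito(samples, single_protein_pathway("R"))
        n_included = len(ext.protein_ids()) - 1
        assert n_included / n_proteins <= 0.05


class TestEstimateAll:
    def test_zero_noise_exact_recovery(self, yeast_truth_config):
        samples, _ = am.generate_proteomics(yeast_truth_config)
        meas, _ = am.generate_physiology(yeast_truth_config)
        est, model = am.estimate_all(
            samples, meas, am.default_pathway_definitions(), "yeast"
        )
        assert est["phi_glyc"].value == pytest.approx(0.05, rel=1e-9)
        assert est["phi_resp"].value == pytest.approx(0.10, rel=1e-9)
        assert est["phi_total_atp"].value == pytest.approx(0.15, rel=1e-9)
        assert est["vmax_glyc"].value == pytest.approx(3.75, rel=1e-9)
        assert est["vmax_resp"].value == pytest.approx(0.2875, rel=1e-9)
        assert model.phi_total_atp == pytest.approx(0.15, rel=1e-9)
        assert model["fermentation"].atp_yield == 2
        assert model["respiration"].atp_yield == 16

    def test_noisy_recovery_within_five_percent(self, yeast_truth_config):
        import dataclasses
        cfg = dataclasses.replace(
            yeast_truth_config, noise_cv=0.10, seed=11,
            unit_mix={"umol/mgProtein/min": 0.3, "mmol/gCDW/h": 0.4, "mM/OD600/h": 0.3},
        )
        samples, _ = am.generate_proteomics(cfg)
        meas, _ = am.generate_physiology(cfg)
        est, _ = am.estimate_all(samples, meas, am.default_pathway_definitions(), "yeast")
        truth = {"phi_total_atp": 0.15, "vmax_glyc": 3.75, "vmax_resp": 0.2875,
                 "gamma_glyc": 2.0, "gamma_resp": 16.0}
        for name, true_val in truth.items():
            assert abs(est[name].value - true_val) / true_val <= 0.05

    def test_fccp_minus_antimycin_defines_max_respiration(self):
        cfg = am.SyntheticConfig(
            true_phi={"glycolysis": 0.06, "respiration": 0.04},
            true_vmax={"glycolysis": 2.8, "respiration": 0.075},
            true_gamma={"glycolysis": 2, "respiration": 24},
            organism="mammalian", noise_cv=0.0, seed=0,
        )
        samples, _ = am.generate_proteomics(cfg)
        meas, _ = am.generate_physiology(cfg)
        assert any(m.treatment == "FCCP" for m in meas)
        assert any(m.treatment == "antimycin" for m in meas)
        est, _ = am.estimate_all(samples, meas, am.default_pathway_definitions(), "mammalian")
        # the non-mitochondrial offset present in both FCCP and antimycin
        # records cancels exactly at zero noise
        assert est["vmax_resp"].value == pytest.approx(0.075, rel=1e-9)

    def test_missing_condition_class_named_in_error(self, yeast_truth_config):
        samples, _ = am.generate_proteomics(yeast_truth_config)
        meas, _ = am.generate_physiology(yeast_truth_config)
        only_glyc = [m for m in meas if m.kind != "OCR"]
        with pytest.raises(ValueError, match="respiration-maximizing"):
            am.estimate_all(samples, only_glyc, am.default_pathway_definitions(), "yeast")
        only_resp = [m for m in meas if m.kind == "OCR"]
        with pytest.raises(ValueError, match="glycolysis-maximizing"):
            am.estimate_all(samples, only_resp, am.default_pathway_definitions(), "yeast")

    def test_ecoli_atp_rate_ordering_reproduced(self):
        # fermentation < respiration < Pta-AckA in specific activity of ATP
        # production, as estimated for E. coli
        cfg = am.SyntheticConfig(
            true_phi={"glycolysis": 0.045, "pta_acka": 0.01, "respiration": 0.06},
            true_vmax={"glycolysis": 9.18, "pta_acka": 35.0, "respiration": 1.7},
            true_gamma={"glycolysis": 2, "pta_acka": 10, "respiration": 20},
            organism="ecoli", noise_cv=0.05, seed=2,
        )
        samples, _ = am.generate_proteomics(cfg)
        meas, _ = am.generate_physiology(cfg)
        est, model = am.estimate_all(
            samples, meas, am.default_pathway_definitions(include_pta=True), "ecoli"
        )
        gv = {p.name: p.atp_specific_activity for p in model.pathways}
        assert gv["fermentation"] < gv["respiration"] < gv["pta_acka"]
        # phi_total counts the shared glycolytic enzymes once
        assert est["phi_total_atp"].value < est["phi_glyc"].value + est["phi_pta"].value + est["phi_resp"].value


class TestParamEstimate:
    def test_point_must_be_mean_of_sources(self):
        with pytest.raises(ValueError, match="mean"):
            am.ParamEstimate("x", 1.0, "u", sources=(1.0, 3.0))
        est = am.ParamEstimate("x", 2.0, "u", sources=(1.0, 3.0))
        assert est.n_sources == 2
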