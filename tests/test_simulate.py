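"""Synthetic-data generators: planted structure and determinism."""

import numpy as np
import pytest

from trflp.insilico import HAEIII, MCRA_REV, MLAS, MSPI, extract_amplicon, predict_trf
from trflp.simulate import (Coupling, StudyDesign, TaxonSpec, default_couplings,
                            default_taxon_panel, generate_community_series,
                            generate_process_parameters,
                            generate_reference_sequences,
                            simulate_peak_tables, simulate_study)


class TestTaxonPanel:
    def test_panel_has_one_collision_pair(self):
        specs = default_taxon_panel()
        hae = sorted(s.haeIII_trf for s in specs)
        close = [(a, b) for a, b in zip(hae, hae[1:]) if b - a <= 2]
        assert close == [(175, 176)]
        msp = sorted(s.mspI_trf for s in specs)
        assert all(b - a >= 5 for a, b in zip(msp, msp[1:]))

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="sizing window"):
            TaxonSpec("x", 40, 200)


class TestReferenceSequences:
    def test_round_trip_trfs(self):
        specs = default_taxon_panel()
        records = generate_reference_sequences(specs, seed=3)
        for spec, rec in zip(specs, records):
            amp = extract_amplicon(str(rec.seq), MLAS, MCRA_REV)
            assert predict_trf(amp, HAEIII).length_bp == spec.haeIII_trf
            assert predict_trf(amp, MSPI).length_bp == spec.mspI_trf

    def test_infeasible_spec_rejected(self):
        # a 500 bp T-RF would place the cut site beyond the far primer
        with pytest.raises(ValueError, match="primer region"):
            generate_reference_sequences([TaxonSpec("x", 500, 200)],
                                         amplicon_len=520, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            generate_reference_sequences([TaxonSpec("x", 200, 201)], seed=0)

    def test_deterministic(self):
        a = generate_reference_sequences(default_taxon_panel()[:3], seed=9)
        b = generate_reference_sequences(default_taxon_panel()[:3], seed=9)
        assert [str(r.seq) for r in a] == [str(r.seq) for r in b]
        c = generate_reference_sequences(default_taxon_panel()[:3], seed=10)
        assert [str(r.seq) for r in a] != [str(r.seq) for r in c]


class TestCommunitySeries:
    def truth(self, seed=4):
        design = StudyDesign(couplings=default_couplings())
        labels = [s.taxon_label for s in default_taxon_panel()]
        return generate_community_series(design, labels, seed=seed), design

    def test_rows_sum_to_one(self):
        truth, _ = self.truth()
        np.testing.assert_allclose(truth.composition.sum(axis=1), 1.0, atol=1e-12)

    def test_dominated_reactor_every_timepoint(self):
        truth, _ = self.truth()
        dom = truth.composition.loc[["R1T1", "R1T2", "R1T3"]]
        assert (dom.max(axis=1) >= 0.9).all()
        # minor taxa in the dominated reactor stay below the 1% reporting line
        assert (dom.drop(columns=[dom.iloc[0].idxmax()]).max(axis=1) < 0.01).all()

    def test_floor_keeps_every_taxon_detectable(self):
        truth, _ = self.truth()
        assert truth.composition.to_numpy().min() > 0.002
        assert (truth.composition.max(axis=0) >= 0.01).all()

    def test_distinct_seeds_distinct_compositions(self):
        a, _ = self.truth(seed=1)
        b, _ = self.truth(seed=2)
        assert not a.composition.equals(b.composition)

    def test_design_sample_ids(self):
        truth, design = self.truth()
        assert list(truth.composition.index) == design.sample_ids
        assert len(design.sample_ids) == 33


class TestProcessParameters:
    def test_noiseless_coupling_gives_perfect_rank_correlation(self):
        truth, design = TestCommunitySeries().truth()
        table = generate_process_parameters(truth, design, noise_sd=0.0, seed=1)
        for c in design.couplings:
            rho = truth.composition[c.taxon_label].corr(table[c.parameter],
                                                        method="spearman")
            assert rho == pytest.approx(float(c.sign), abs=1e-12)

    def test_realized_couplings_recorded_in_plausible_band(self):
        hits = 0
        for seed in range(20):
            design = StudyDesign(couplings=default_couplings())
            labels = [s.taxon_label for s in default_taxon_panel()]
            truth = generate_community_series(design, labels, seed=seed)
            generate_process_parameters(truth, design, seed=seed + 1000)
            rhos = [truth.realized_couplings[f"{c.taxon_label}~{c.parameter}"] * c.sign
                    for c in design.couplings]
            hits += sum(0.6 < r < 0.95 for r in rhos)
        assert hits >= 0.8 * 20 * 5

    def test_parameter_ranges_respected(self):
        truth, design = TestCommunitySeries().truth()
        table = generate_process_parameters(truth, design, seed=2)
        assert table["pH"].between(6.8, 8.2).all()
        assert table["TAN"].between(1.0, 6.0).all()

    def test_conflicting_couplings_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            StudyDesign(couplings=(Coupling("a", "TAN", 1, 0.8),
                                   Coupling("b", "TAN", -1, 0.8)))
        with pytest.raises(ValueError, match="schema"):
            StudyDesign(couplings=(Coupling("a", "notaparam", 1, 0.8),))


class TestPeakTables:
    def test_structure_and_determinism(self):
        truth, specs, refdb, tables = simulate_study(seed=5)
        assert len(tables) == 33 * 2 * 3
        _, _, _, tables2 = simulate_study(seed=5)
        assert all(
            [(p.size_bp, p.area) for p in a.peaks] ==
            [(p.size_bp, p.area) for p in b.peaks]
            for a, b in zip(tables, tables2))

    def test_noiseless_tables_have_exact_sizes(self):
        truth, specs, refdb, tables = simulate_study(seed=5, sizing_sd=0.0,
                                                     n_noise_peaks=0)
        trf = {(t.taxon_label, e): v for t in refdb
               for e, v in t.trf_by_enzyme.items()}
        expected = {float(v) for v in trf.values()}
        for t in tables[:12]:
            assert {p.size_bp for p in t.peaks} <= expected

    def test_noise_peak_areas_bounded(self):
        truth, specs, refdb, tables = simulate_study(seed=6)
        for t in tables[:6]:
            areas = sorted(p.area for p in t.peaks)
            top = areas[-1]
            # 30 noise peaks all at most 0.5% of the largest true peak
            assert sum(1 for a in areas if a <= 0.005 * top) >= 30

    def test_invalid_noise_settings(self):
        truth, specs, refdb, _ = simulate_study(seed=1)
        with pytest.raises(ValueError):
            simulate_peak_tables(truth, refdb, sizing_sd=-0.1)
        with pytest.raises(ValueError):
            simulate_peak_tables(truth, refdb, noise_area_frac=0.2)
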