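import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet import io
from cernet.simulate import (SimulationConfig, SyntheticTruth,
                             generate_annotation, generate_clinical,
                             generate_expression, generate_gene_sets,
                             generate_qpcr, generate_sequences,
                             required_marker_separation)
from cernet.targets import MatureMiRNA, TranscriptSeq, find_seed_matches
from oracles import naive_seed_scan


class TestConfigValidation:
    def test_rejects_bad_fractions_and_auc(self):
        with pytest.raises(ValueError, match="frac_de"):
            SimulationConfig(frac_de=1.0)
        with pytest.raises(ValueError, match="biomarker_auc"):
            SimulationConfig(biomarker_auc=1.0)
        with pytest.raises(ValueError, match="biomarker_auc"):
            SimulationConfig(biomarker_auc=0.3)
        with pytest.raises(ValueError, match="clinical_r"):
            SimulationConfig(clinical_r={"lactate": -1.5})

    def test_rejects_non_finite_values(self):
        with pytest.raises(ValueError, match="finite"):
            SimulationConfig(planted_log2fc=float("nan"))
        with pytest.raises(ValueError, match="finite"):
            SimulationConfig(noise_sd=float("inf"))

    def test_rejects_infeasible_triad_count(self):
        with pytest.raises(ValueError, match="n_triads"):
            SimulationConfig(n_mirna=50, n_lncrna=50, n_mrna=50,
                             frac_de=0.1, n_triads=20)

    def test_rejects_window_exceeding_chromosome(self):
        with pytest.raises(ValueError, match="cis_window"):
            SimulationConfig(cis_window=20_000_000)

    def test_frac_de_zero_allowed_with_no_triads(self):
        cfg = SimulationConfig(frac_de=0.0, n_triads=0)
        _, _, _, truth = generate_expression(cfg)
        assert truth.de_features == {}
        assert truth.triads == []


class TestGenerateExpression:
    def test_planted_fold_change_recovered_without_noise(self):
        cfg = SimulationConfig(seed=2, n_mirna=30, n_lncrna=40, n_mrna=60,
                               frac_de=0.2, planted_log2fc=1.0, noise_sd=0.0,
                               n_triads=0, n_case=5, n_control=5)
        mirna, _, _, truth = generate_expression(cfg)
        up = [f for f, d in truth.de_features.items()
              if d == "up" and f.startswith("miR")]
        assert up
        case = mirna.values.loc[up, mirna.case_samples].mean(axis=1)
        control = mirna.values.loc[up, mirna.control_samples].mean(axis=1)
        assert np.allclose(case / control, 2.0)

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(seed=7, n_mirna=20, n_lncrna=30, n_mrna=50,
                               frac_de=0.2, n_triads=3, n_case=4, n_control=4)
        a = generate_expression(cfg)
        b = generate_expression(cfg)
        for x, y in zip(a[:3], b[:3]):
            assert x.values.equals(y.values)
        assert a[3].de_features == b[3].de_features
        assert a[3].triads == b[3].triads

    def test_triad_directions_opposed(self, default_sim):
        _, _, _, _, truth = default_sim
        for l, m, g in truth.triads:
            assert truth.de_features[m] != truth.de_features[l]
            assert truth.de_features[l] == truth.de_features[g]

    def test_values_positive_and_groups_labelled(self, default_sim):
        _, mirna, lnc, mrna, _ = default_sim
        for mat in (mirna, lnc, mrna):
            assert (mat.values.to_numpy() > 0).all()
            assert len(mat.case_samples) == 20 and len(mat.control_samples) == 20


class TestGenerateSequences:
    def test_planted_edges_have_strong_sites(self, default_sim, default_sim_sequences):
        _, _, _, _, truth = default_sim
        mirs, utrs, lncs = default_sim_sequences
        targets = {**utrs, **lncs}
        for l, m, g in truth.triads[:20]:
            for tid in (l, g):
                sites = naive_seed_scan(mirs[m], targets[tid])
                assert any(t in ("8mer", "7mer-m8") for t, _, _ in sites)

    def test_non_edges_have_no_strong_sites(self, default_sim, default_sim_sequences):
        _, _, _, _, truth = default_sim
        mirs, utrs, lncs = default_sim_sequences
        edges = {(m, t) for l, m, g in truth.triads for t in (l, g)}
        rng = np.random.default_rng(0)
        mir_ids = sorted(mirs)
        targets = {**utrs, **lncs}
        target_ids = sorted(targets)
        checked = 0
        while checked < 300:
            m = mir_ids[rng.integers(len(mir_ids))]
            t = target_ids[rng.integers(len(target_ids))]
            if (m, t) in edges:
                continue
            sites = find_seed_matches(
                MatureMiRNA(m, mirs[m]),
                TranscriptSeq(t, "utr3" if t.startswith("gene") else "lncrna",
                              targets[t]))
            assert not any(s.site_type in ("8mer", "7mer-m8") for s in sites)
            checked += 1

    def test_recorded_intervals_match_sequences(self, default_sim, default_sim_sequences):
        _, _, _, _, truth = default_sim
        mirs, utrs, lncs = default_sim_sequences
        targets = {**utrs, **lncs}
        from cernet.targets import reverse_complement
        assert truth.planted_sites
        for m, t, (start, end) in truth.planted_sites:
            site = targets[t][start:end]
            rc7 = reverse_complement(mirs[m][1:8])
            assert site == rc7 or site == rc7 + "A"

    def test_no_triads_means_unconstrained_sequences(self):
        cfg = SimulationConfig(seed=9, n_mirna=10, n_lncrna=10, n_mrna=10,
                               frac_de=0.0, n_triads=0, utr_length=60,
                               lnc_length=80, n_case=3, n_control=3)
        _, _, _, truth = generate_expression(cfg)
        mirs, utrs, lncs = generate_sequences(cfg, truth)
        assert len(mirs) == 10 and len(utrs) == 10 and len(lncs) == 10
        assert truth.planted_sites == []


class TestGenerateAnnotation:
    def test_cis_fraction_one_places_all_pairs_in_window(self):
        cfg = SimulationConfig(seed=4, n_mirna=30, n_lncrna=50, n_mrna=80,
                               frac_de=0.2, n_triads=10, cis_fraction=1.0,
                               n_case=4, n_control=4)
        _, _, _, truth = generate_expression(cfg)
        bed = generate_annotation(truth, cfg).set_index("name")
        for l, _, g in truth.triads:
            assert bed.loc[l, "chrom"] == bed.loc[g, "chrom"]
            gap = max(bed.loc[l, "start"], bed.loc[g, "start"]) - \
                min(bed.loc[l, "end"], bed.loc[g, "end"])
            assert max(0, gap) <= cfg.cis_window

    def test_cis_fraction_zero_separates_chromosomes(self):
        cfg = SimulationConfig(seed=4, n_mirna=30, n_lncrna=50, n_mrna=80,
                               frac_de=0.2, n_triads=10, cis_fraction=0.0,
                               n_case=4, n_control=4)
        _, _, _, truth = generate_expression(cfg)
        bed = generate_annotation(truth, cfg).set_index("name")
        for l, _, g in truth.triads:
            assert bed.loc[l, "chrom"] != bed.loc[g, "chrom"]

    def test_bed_round_trip_identity(self, tmp_path):
        cfg = SimulationConfig(seed=4, n_mirna=10, n_lncrna=15, n_mrna=20,
                               frac_de=0.2, n_triads=3, n_case=3, n_control=3)
        _, _, _, truth = generate_expression(cfg)
        bed = generate_annotation(truth, cfg)
        io.write_bed(bed, tmp_path / "a.bed")
        back = io.read_bed(tmp_path / "a.bed")
        pd.testing.assert_frame_equal(bed, back)
        io.write_bed(back, tmp_path / "b.bed")
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()
        assert (bed["start"] < bed["end"]).all()


class TestGenerateQpcr:
    @staticmethod
    def config(**kw):
        base = dict(seed=5, n_mirna=30, n_lncrna=40, n_mrna=60, frac_de=0.2,
                    n_triads=5, n_case=8, n_control=8)
        base.update(kw)
        return SimulationConfig(**base)

    def test_reference_genes_group_invariant(self):
        cfg = self.config(ct_noise_sd=0.0)
        _, _, _, truth = generate_expression(cfg)
        ct = generate_qpcr(truth, cfg)
        for ref in ("U6", "GAPDH", "cel-miR-39"):
            sub = ct[ct["gene"] == ref]
            gapdh = ct[ct["gene"] == "GAPDH"]
            merged = sub.merge(gapdh, on=["sample", "group", "replicate"],
                               suffixes=("", "_ref"))
            dct = merged["ct"] - merged["ct_ref"]
            case = dct[merged["group"] == "case"].mean()
            control = dct[merged["group"] == "control"].mean()
            assert case == pytest.approx(control, abs=1e-9)

    def test_triplicates_emitted(self):
        cfg = self.config()
        _, _, _, truth = generate_expression(cfg)
        ct = generate_qpcr(truth, cfg)
        counts = ct.groupby(["sample", "gene"])["replicate"].count()
        assert (counts == 3).all()

    def test_replicate_spread_matches_noise_sd(self):
        cfg = self.config(ct_noise_sd=0.2, n_case=30, n_control=30)
        _, _, _, truth = generate_expression(cfg)
        ct = generate_qpcr(truth, cfg, n_replicates=12)
        # pooled within-(sample, gene) variance over ~10k residuals
        var = ct.groupby(["sample", "gene"])["ct"].var(ddof=1)
        assert ct.shape[0] >= 10_000
        assert np.sqrt(var.mean()) == pytest.approx(0.2, rel=0.05)


class TestGenerateClinical:
    def test_auc_half_means_identical_distributions(self):
        cfg = SimulationConfig(seed=6, n_case=400, n_control=400,
                               n_mirna=30, n_lncrna=40, n_mrna=60,
                               frac_de=0.1, n_triads=0, biomarker_auc=0.5)
        table = generate_clinical(cfg)
        case = table.loc[table["group"] == "case", "serum_marker"]
        control = table.loc[table["group"] == "control", "serum_marker"]
        ks = stats.ks_2samp(case, control)
        assert ks.pvalue > 0.01

    def test_required_separation_inverts_auc(self):
        # independent numerical inversion of Phi(delta / sqrt(2)) = 0.879
        from scipy.optimize import brentq
        expected = brentq(lambda d: stats.norm.cdf(d / np.sqrt(2)) - 0.879, 0, 10,
                          xtol=1e-12)
        assert expected == pytest.approx(1.653, abs=2e-3)  # printed-precision check
        assert required_marker_separation(0.879) == pytest.approx(expected, abs=1e-9)
        # forward check: Phi(delta / sqrt(2)) returns the AUC
        delta = required_marker_separation(0.75)
        assert stats.norm.cdf(delta / np.sqrt(2)) == pytest.approx(0.75)

    def test_zero_clinical_r_gives_null_correlation(self):
        n = 500
        cfg = SimulationConfig(seed=8, n_case=n, n_control=n,
                               n_mirna=30, n_lncrna=40, n_mrna=60,
                               frac_de=0.1, n_triads=0,
                               clinical_r={"lactate": 0.0})
        table = generate_clinical(cfg)
        r = stats.spearmanr(table["serum_marker"], table["lactate"]).statistic
        assert abs(r) < 3.0 / np.sqrt(2 * n)

    def test_truth_records_parameters(self):
        cfg = SimulationConfig(seed=6, n_mirna=30, n_lncrna=40, n_mrna=60,
                               frac_de=0.1, n_triads=0)
        truth = SyntheticTruth()
        generate_clinical(cfg, truth)
        assert truth.biomarker_params["target_auc"] == cfg.biomarker_auc
        assert truth.planted_correlations == cfg.clinical_r


def test_gene_sets_cover_universe_and_seed_de_terms(default_sim):
    cfg, _, _, _, truth = default_sim
    terms = generate_gene_sets(truth, cfg)
    assert len(terms) == 60
    universe = {g for _, (_, members) in terms.items() for g in members}
    assert universe <= set(f"gene-{i:04d}" for i in range(1, cfg.n_mrna + 1))
    de_mrna = {f for f in truth.de_features if f.startswith("gene")}
    first = terms["BP:T0001"][1]
    assert len(set(first) & de_mrna) >= 3


def test_truth_json_round_trip(tmp_path, default_sim):
    _, _, _, _, truth = default_sim
    truth.to_json(tmp_path / "truth.json")
    back = SyntheticTruth.from_json(tmp_path / "truth.json")
    assert back.de_features == truth.de_features
    assert back.triads == truth.triads
    assert back.planted_sites == truth.planted_sites
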