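"""Synthetic-data generators: determinism, ground truth, round trips."""

import numpy as np
import pytest

from phytoscreen.annotate import annotate
from phytoscreen.fate import summarize
from phytoscreen.simulate import (
    DTASimConfig,
    FateSimConfig,
    SpectrumSimConfig,
    bayes_auroc,
    dta_records_to_frame,
    rule_label,
    simulate_dta,
    simulate_presence,
    simulate_spectra,
    simulate_spectrum,
    write_spectra_mgf,
    PHARMACOPHORE_TOKEN,
    PROTEIN_MOTIF,
)


class TestSimulateSpectrum:
    def test_noiseless_emodin_contains_reference_ladder(self, library):
        rec = next(r for r in library if r.name == "emodin")
        sp, gt = simulate_spectrum(
            rec, SpectrumSimConfig(ppm_sigma=0.0, decoy_fraction=0.0, seed=0)
        )
        mzs = np.array([m for m, _ in sp.peaks])
        for obs in (269.0455, 241.0506, 225.0557, 197.0608, 210.0328):
            assert np.min(np.abs(mzs - obs)) < 5e-3
        assert gt.decoy_mzs == ()

    def test_decoy_count_roughly_binomial(self, library):
        rec = next(r for r in library if r.name == "rutin")
        cfg = SpectrumSimConfig(ppm_sigma=2.0, decoy_fraction=0.3, seed=0)
        rng = np.random.default_rng(5)
        counts = []
        for _ in range(200):
            sp, gt = simulate_spectrum(rec, cfg, rng=rng)
            n_true = len(gt.true_peaks)
            counts.append(len(gt.decoy_mzs) / n_true)
        # decoys/true ratio averages f/(1-f) = 3/7
        assert np.mean(counts) == pytest.approx(3 / 7, abs=0.08)

    def test_decoys_at_least_20ppm_from_true_peaks(self, library):
        rec = next(r for r in library if r.name == "rutin")
        sp, gt = simulate_spectrum(
            rec, SpectrumSimConfig(ppm_sigma=0.0, decoy_fraction=0.4, seed=2)
        )
        true = np.array([m for m, _ in gt.true_peaks])
        for d in gt.decoy_mzs:
            assert np.min(np.abs(d - true) / true) * 1e6 >= 20.0

    def test_seeded_mgf_byte_identical(self, tmp_path, library):
        cfg = SpectrumSimConfig(seed=42)
        out1, out2 = tmp_path / "a.mgf", tmp_path / "b.mgf"
        write_spectra_mgf([s for s, _ in simulate_spectra(library, 20, cfg)], out1)
        write_spectra_mgf([s for s, _ in simulate_spectra(library, 20, cfg)], out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_round_trip_every_compound_top1_score1(self, library):
        """Noise- and decoy-free spectra must rank their source compound
        first with class score 1.0 for every fixture compound."""
        cfg = SpectrumSimConfig(ppm_sigma=0.0, decoy_fraction=0.0, seed=1)
        for rec in library:
            sp, _ = simulate_spectrum(rec, cfg)
            res = annotate(sp, library)
            assert res[0].compound.name == rec.name
            assert res[0].class_score == 1.0


class TestSimulatePresence:
    def test_point_mass_all_present(self):
        probs = [0.0] * 64
        probs[63] = 1.0
        pm, tallies = simulate_presence(
            FateSimConfig(n_compounds=30, pattern_probs=probs, seed=0)
        )
        assert summarize(pm)["absorbed"] == 30
        assert tallies == {63: 30}

    def test_point_mass_gastric_absent(self):
        probs = [0.0] * 64
        probs[0] = 1.0
        pm, _ = simulate_presence(
            FateSimConfig(n_compounds=10, pattern_probs=probs, seed=0)
        )
        rep = summarize(pm)
        assert rep["site_flags"]["degraded_in_stomach"] == 10
        assert rep["absorbed"] == 0

    def test_mixture_tallies_within_3_sigma(self):
        probs = np.zeros(64)
        probs[63], probs[0], probs[32] = 0.5, 0.3, 0.2
        cfg = FateSimConfig(n_compounds=10_000, pattern_probs=probs.tolist(), seed=3)
        _, tallies = simulate_presence(cfg)
        for code, p in ((63, 0.5), (0, 0.3), (32, 0.2)):
            sigma = np.sqrt(10_000 * p * (1 - p))
            assert abs(tallies.get(code, 0) - 10_000 * p) <= 3 * sigma

    def test_tallies_match_summary_exactly(self):
        probs = np.zeros(64)
        probs[63], probs[0] = 0.7, 0.3
        cfg = FateSimConfig(n_compounds=500, pattern_probs=probs.tolist(), seed=9)
        pm, tallies = simulate_presence(cfg)
        rep = summarize(pm)
        assert rep["absorbed"] == tallies.get(63, 0)
        assert rep["site_flags"]["degraded_in_stomach"] == tallies.get(0, 0)

    def test_bad_probability_vector(self):
        with pytest.raises(ValueError):
            FateSimConfig(pattern_probs=[0.5] * 64)


class TestSimulateDta:
    def test_label_follows_rule_xor_noise(self):
        recs, _ = simulate_dta(DTASimConfig(n_pairs=300, label_noise=0.0, seed=4))
        for r in recs:
            assert r.label == rule_label(r)

    def test_noise_free_bayes_auroc_is_one(self):
        _, bayes = simulate_dta(DTASimConfig(n_pairs=100, label_noise=0.0, seed=4))
        assert bayes == 1.0

    def test_label_prevalence_near_balance(self):
        cfg = DTASimConfig(n_pairs=4000, label_noise=0.05, class_balance=0.13, seed=8)
        recs, _ = simulate_dta(cfg)
        prevalence = np.mean([r.label for r in recs])
        assert prevalence == pytest.approx(0.13, abs=3 * np.sqrt(0.13 * 0.87 / 4000))

    def test_bayes_formula_matches_enumeration(self):
        # brute-force AUROC of the rule-bit scorer under XOR label noise
        eps, pi, n = 0.1, 0.3, 200_000
        rng = np.random.default_rng(0)
        rule = rng.random(n) < pi
        label = rule ^ (rng.random(n) < eps)
        score = rule.astype(float)
        pos, neg = score[label == 1], score[label == 0]
        # Mann-Whitney with tie correction on binary scores
        gt = np.mean(pos[:, None] > neg[None, :500]) + 0.5 * np.mean(
            pos[:, None] == neg[None, :500]
        )
        assert bayes_auroc(eps, pi) == pytest.approx(gt, abs=0.01)

    def test_seeded_csv_identical(self, tmp_path):
        cfg = DTASimConfig(n_pairs=50, seed=6)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        dta_records_to_frame(simulate_dta(cfg)[0]).to_csv(a, index=False)
        dta_records_to_frame(simulate_dta(cfg)[0]).to_csv(b, index=False)
        assert a.read_bytes() == b.read_bytes()

    def test_molecules_parse_and_motifs_planted_exactly(self):
        from rdkit import Chem

        recs, _ = simulate_dta(DTASimConfig(n_pairs=100, label_noise=0.0, seed=2))
        for r in recs:
            assert Chem.MolFromSmiles(r.smiles) is not None
            has_pharm = PHARMACOPHORE_TOKEN in r.smiles
            has_motif = PROTEIN_MOTIF in r.sequence
            assert r.label == int(has_pharm and has_motif)
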