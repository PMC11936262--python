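"""Synthetic corpus generator: planted truth, observations, scores, fixtures."""

import json
from pathlib import Path

import numpy as np
import pytest

from misscan import (
    HARD_MISSING,
    LABEL_NAMES,
    MODELED,
    SOFT_MISSING,
    ConfigurationError,
    GeneratorConfig,
    classify_residues,
    generate_corpus,
    generate_truth,
    simulate_observations,
    simulate_scores,
    write_fixture_set,
)
from misscan.synthetic import DEFAULT_SCORE_PARAMS


def small_config(**kwargs) -> GeneratorConfig:
    base = dict(n_proteins=10, length_range=(60, 120), seed=42)
    base.update(kwargs)
    return GeneratorConfig(**base)


class TestGenerateTruth:
    def test_degenerate_weights_give_all_modeled(self):
        truths = generate_truth(small_config(class_weights=(1.0, 0.0, 0.0)))
        for _, labels, regions in truths:
            assert (labels.labels == MODELED).all()
            assert len(regions) == 0

    def test_forced_short_mix_gives_only_short_regions(self):
        truths = generate_truth(small_config(short_long_mix=1.0, n_proteins=30))
        regions = [r for _, _, rs in truths for r in rs]
        assert regions, "expected some hard-missing regions"
        assert all(r.length_class == "short" for r in regions)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_truth(small_config(class_weights=(0.5, 0.5, 0.5)))

    def test_empty_length_range_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_truth(small_config(length_range=(50, 10)))

    def test_reproducible_given_seed(self):
        a = generate_truth(small_config())
        b = generate_truth(small_config())
        for (sa, la, _), (sb, lb, _) in zip(a, b):
            assert sa == sb
            assert (la.labels == lb.labels).all()

    def test_hard_regions_separated_by_modeled(self):
        for _, labels, regions in generate_truth(small_config(n_proteins=40)):
            vec = labels.labels
            for r in regions:
                if r.start > 1:
                    assert vec[r.start - 2] == MODELED
                if r.end < vec.size:
                    assert vec[r.end] == MODELED

    def test_kesp_enrichment_in_hard_missing(self):
        """Pooled K+E+S+P frequency among hard-missing positions exceeds the
        modeled-position frequency over 100 proteins (direct counting)."""
        truths = generate_truth(GeneratorConfig(n_proteins=100, seed=5))
        counts = {MODELED: [0, 0], HARD_MISSING: [0, 0]}  # [KESP, total]
        for seq, labels, _ in truths:
            for aa, code in zip(seq, labels.labels):
                if code in counts:
                    counts[code][0] += aa in "KESP"
                    counts[code][1] += 1
        freq_hard = counts[HARD_MISSING][0] / counts[HARD_MISSING][1]
        freq_mod = counts[MODELED][0] / counts[MODELED][1]
        assert freq_hard > freq_mod


class TestSimulateObservations:
    def test_all_modeled_truth_gives_all_present_masks(self):
        from misscan import ResidueLabels

        truth = ResidueLabels(np.zeros(5, dtype=np.int8), n_entries_used=2)
        observations = simulate_observations(truth, 3, 0.5, seed=0)
        assert len(observations) == 3
        assert all(o.presence.all() for o in observations)

    def test_two_entries_force_soft_recoverability(self):
        from misscan import ResidueLabels

        truth = ResidueLabels(
            np.array([MODELED, SOFT_MISSING, HARD_MISSING], dtype=np.int8), n_entries_used=2
        )
        observations = simulate_observations(truth, 2, 0.5, seed=3)
        col = np.array([o.presence for o in observations])
        assert col[:, 0].all()
        assert not col[:, 2].any()
        assert col[:, 1].sum() == 1  # present exactly once

    def test_zero_entries_rejected(self):
        from misscan import ResidueLabels

        truth = ResidueLabels(np.zeros(3, dtype=np.int8), n_entries_used=2)
        with pytest.raises(ValueError):
            simulate_observations(truth, 0, 0.5, seed=0)

    def test_single_entry_with_soft_truth_rejected(self):
        from misscan import ResidueLabels

        truth = ResidueLabels(np.array([SOFT_MISSING], dtype=np.int8), n_entries_used=2)
        with pytest.raises(ValueError, match="single entry"):
            simulate_observations(truth, 1, 0.5, seed=0)
        # but allowed when recoverability is explicitly waived
        observations = simulate_observations(truth, 1, 0.5, seed=0, require_recoverable=False)
        assert len(observations) == 1

    def test_round_trip_recovery(self):
        """classify(simulate(truth)) == truth for 200 random proteins."""
        truths = generate_truth(GeneratorConfig(n_proteins=200, length_range=(30, 150), seed=9))
        rng = np.random.default_rng(10)
        for _, labels, _ in truths:
            n_entries = int(rng.integers(2, 7))
            observations = simulate_observations(labels, n_entries, 0.5, int(rng.integers(2**31)))
            recovered = classify_residues(observations)
            assert (recovered.labels == labels.labels).all()


class TestSimulateScores:
    def test_class_medians_near_reference_values(self, default_corpus):
        pooled = {name: ([], []) for name in LABEL_NAMES}
        for rec in default_corpus:
            for code, name in enumerate(LABEL_NAMES):
                sel = rec.labels.labels == code
                pooled[name][0].append(rec.tracks.plddt[sel])
                pooled[name][1].append(rec.tracks.iupred[sel])
        med = {
            name: (
                float(np.median(np.concatenate(p))),
                float(np.median(np.concatenate(i))),
            )
            for name, (p, i) in pooled.items()
        }
        assert med["modeled"][0] == pytest.approx(97.1, abs=3)
        assert med["hard_missing"][0] == pytest.approx(55.5, abs=5)
        assert med["modeled"][1] == pytest.approx(0.2, abs=0.05)

    def test_score_separation_ordering(self, default_corpus):
        means = {name: [] for name in LABEL_NAMES}
        for rec in default_corpus:
            for code, name in enumerate(LABEL_NAMES):
                sel = rec.labels.labels == code
                if sel.any():
                    means[name].append(rec.tracks.plddt[sel])
        m = {name: float(np.concatenate(v).mean()) for name, v in means.items()}
        assert m["modeled"] > m["soft_missing"] > m["hard_missing"]

    def test_zero_variance_window_one_is_exact(self):
        from misscan import ResidueLabels

        truth = ResidueLabels(np.zeros(20, dtype=np.int8), n_entries_used=2)
        params = {
            "plddt": {"modeled": (97.1, 0.0), "soft_missing": (84.4, 0.0), "hard_missing": (55.5, 0.0)},
            "iupred": {"modeled": (0.2, 0.0), "soft_missing": (0.29, 0.0), "hard_missing": (0.38, 0.0)},
        }
        tracks = simulate_scores(truth, params, smoothing_window=1, seed=0)
        assert (tracks.plddt == 97.1).all()
        assert (tracks.iupred == 0.2).all()

    def test_invalid_window_rejected(self):
        from misscan import ResidueLabels

        truth = ResidueLabels(np.zeros(5, dtype=np.int8), n_entries_used=2)
        with pytest.raises(ValueError):
            simulate_scores(truth, DEFAULT_SCORE_PARAMS, smoothing_window=0, seed=0)

    def test_tracks_within_legal_ranges(self, default_corpus):
        for rec in default_corpus:
            assert rec.tracks.plddt.min() >= 0 and rec.tracks.plddt.max() <= 100
            assert rec.tracks.iupred.min() >= 0 and rec.tracks.iupred.max() <= 1


class TestWriteFixtureSet:
    def test_manifest_lists_expected_files(self, tmp_path):
        corpus = generate_corpus(small_config(n_proteins=1, n_entries_range=(2, 2)))
        manifest = write_fixture_set(corpus, tmp_path)
        (entry,) = manifest["proteins"]
        assert len(entry["entries"]) == 2
        assert entry["model"] and entry["iupred"] and entry["fasta"]
        assert (tmp_path / "manifest.json").exists()

    def test_empty_protein_list_gives_empty_manifest(self, tmp_path):
        manifest = write_fixture_set([], tmp_path / "empty")
        assert manifest["proteins"] == []
        assert list((tmp_path / "empty").glob("*.pdb")) == []

    def test_identical_seeds_give_byte_identical_fixtures(self, tmp_path):
        for name in ("a", "b"):
            write_fixture_set(generate_corpus(small_config(n_proteins=3)), tmp_path / name)
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes()

    def test_manifest_truth_labels_match_memory(self, tmp_path):
        corpus = generate_corpus(small_config(n_proteins=2))
        write_fixture_set(corpus, tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        for rec, entry in zip(corpus, manifest["proteins"]):
            assert entry["truth_labels"] == rec.labels.names()
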