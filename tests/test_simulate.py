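"""Synthetic catalog, truth table and tag-library generation."""

import math

import numpy as np
import pandas as pd
import pytest

from tagdge.errors import ConfigError, SimulationError
from tagdge.reference import extract_canonical_tag
from tagdge.simulate import (
    DEFAULT_DE_DESIGN,
    SimulationConfig,
    generate_catalog,
    generate_truth,
    simulate_library,
)


def cfg(**kwargs) -> SimulationConfig:
    base = dict(
        n_genes=150,
        gene_length_range=(100, 600),
        library_sizes=(50_000,) * 4,
        error_rate=0.0,
        frac_no_catg=0.1,
        seed=3,
    )
    base.update(kwargs)
    return SimulationConfig(**base)


class TestGenerateCatalog:
    def test_single_gene_has_catg(self):
        cat = generate_catalog(cfg(n_genes=1, frac_no_catg=0.0))
        [(gene, seq)] = list(cat.items())
        assert extract_canonical_tag(seq) is not None

    def test_exact_no_catg_count(self):
        cat = generate_catalog(cfg(n_genes=100, frac_no_catg=0.1))
        n_without = sum(1 for _g, s in cat.items() if "CATG" not in s)
        assert n_without == 10

    def test_every_other_gene_has_eligible_site(self):
        cat = generate_catalog(cfg(n_genes=100, frac_no_catg=0.1))
        n_with = sum(1 for _g, s in cat.items() if extract_canonical_tag(s) is not None)
        assert n_with == 90

    def test_lengths_within_range(self):
        c = cfg(gene_length_range=(100, 200))
        cat = generate_catalog(c)
        assert all(100 <= len(s) <= 200 for _g, s in cat.items())

    def test_deterministic_given_seed(self):
        c = cfg(seed=99)
        cat1 = generate_catalog(c)
        cat2 = generate_catalog(cfg(seed=99))
        assert dict(cat1.items()) == dict(cat2.items())

    def test_invalid_length_range_rejected(self):
        with pytest.raises(ConfigError):
            generate_catalog(cfg(gene_length_range=(500, 100)))
        with pytest.raises(ConfigError):
            generate_catalog(cfg(gene_length_range=(10, 100)))


class TestGenerateTruth:
    def test_zero_design_all_none_single_abundance_vector(self):
        c = cfg(de_design={"up2-4": 0.0}, stage_specific_frac=0.0)
        truth = generate_truth(c, generate_catalog(c))
        assert (truth.labels == "none").all().all()
        for s in truth.stages[1:]:
            pd.testing.assert_series_equal(
                truth.abundance[s], truth.abundance[truth.stages[0]], check_names=False
            )

    def test_abundances_sum_to_one(self, small_config, small_catalog, small_truth):
        sums = small_truth.abundance.sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_up8_fold_at_least_8_prenormalization(self, small_truth):
        for t in ("T1", "T2", "T3"):
            genes = small_truth.labels.index[small_truth.labels[t] == "up8+"]
            folds = small_truth.designed_fold.loc[genes, t]
            assert (folds >= 8).all() and (folds < 16).all()

    def test_all_designed_folds_inside_class_intervals(self, small_truth):
        intervals = {
            "up2-4": (2, 4), "up4-8": (4, 8), "up8+": (8, 16),
            "down2-4": (0.25, 0.5), "down4-8": (0.125, 0.25), "down8+": (1 / 16, 0.125),
        }
        for t in ("T1", "T2", "T3"):
            for cls, (lo, hi) in intervals.items():
                genes = small_truth.labels.index[small_truth.labels[t] == cls]
                folds = small_truth.designed_fold.loc[genes, t]
                assert ((folds >= lo) & (folds < hi)).all(), (t, cls)

    def test_label_tallies_match_config_bookkeeping(self):
        """Exact bookkeeping oracle: floor(fraction*n) per designed class plus
        the on/off labels induced by stage-specific genes."""
        c = cfg(n_genes=400, stage_specific_frac=0.05, seed=21)
        truth = generate_truth(c, generate_catalog(c))
        design = c.per_transition_design()
        n_ss = math.floor(c.stage_specific_frac * c.n_genes)
        per_stage = [n_ss // 4 + (1 if s < n_ss % 4 else 0) for s in range(4)]
        for t_idx, t in enumerate(("T1", "T2", "T3")):
            tallies = truth.labels[t].value_counts()
            for cls in ("up2-4", "up4-8", "up8+", "down2-4", "down4-8", "down8+"):
                expected = math.floor(design[t][cls] * c.n_genes)
                assert tallies.get(cls, 0) == expected, (t, cls)
            # stage-specific genes of the later stage add "on" labels,
            # those of the earlier stage add "off" labels
            exp_on = math.floor(design[t]["on"] * c.n_genes) + per_stage[t_idx + 1]
            exp_off = math.floor(design[t]["off"] * c.n_genes) + per_stage[t_idx]
            assert tallies.get("on", 0) == exp_on, t
            assert tallies.get("off", 0) == exp_off, t

    def test_on_gene_zero_before_positive_after(self, small_truth):
        for t_idx, t in enumerate(("T1", "T2", "T3")):
            genes = small_truth.labels.index[small_truth.labels[t] == "on"]
            earlier = small_truth.stages[t_idx]
            later = small_truth.stages[t_idx + 1]
            assert (small_truth.abundance.loc[genes, earlier] == 0).all()
            assert (small_truth.abundance.loc[genes, later] > 0).all()

    def test_design_fractions_summing_to_one_rejected(self):
        with pytest.raises(ConfigError):
            cfg(de_design={"up2-4": 0.6, "down2-4": 0.4}).validate()

    def test_deterministic(self):
        c = cfg(seed=77)
        cat = generate_catalog(c)
        t1 = generate_truth(c, cat)
        t2 = generate_truth(c, cat)
        pd.testing.assert_frame_equal(t1.abundance, t2.abundance)
        pd.testing.assert_frame_equal(t1.labels, t2.labels)


class TestSimulateLibrary:
    def test_single_source_no_error_identical_reads(self):
        c = cfg(n_genes=1, frac_no_catg=0.0, de_design={}, stage_specific_frac=0.0)
        cat = generate_catalog(c)
        truth = generate_truth(c, cat)
        reads = simulate_library(cat, truth, "BU", 1000, 0.0, seed=5)
        tag = extract_canonical_tag(cat[cat.gene_ids[0]])
        assert len(reads) == 1000
        assert set(reads) == {tag}

    def test_deterministic_given_seed(self, small_catalog, small_truth):
        r1 = simulate_library(small_catalog, small_truth, "EG", 5000, 0.01, seed=9)
        r2 = simulate_library(small_catalog, small_truth, "EG", 5000, 0.01, seed=9)
        assert np.array_equal(r1.sequences, r2.sequences)

    def test_error_free_frequencies_converge_to_truth(self):
        """Multinomial sampling: max |freq - p| < 5e-3 at 1e6 draws, 10 seeds."""
        c = cfg(n_genes=200, frac_no_catg=0.0, seed=13)
        cat = generate_catalog(c)
        truth = generate_truth(c, cat)
        p = truth.abundance["BU"]
        expressed = p[p > 0]
        rng_seeds = range(10)
        for s in rng_seeds:
            counts = np.random.default_rng(s).multinomial(1_000_000, expressed.to_numpy())
            freqs = counts / 1_000_000
            assert np.max(np.abs(freqs - expressed.to_numpy())) < 5e-3

    def test_substitution_rate_matches_closed_form(self, small_catalog, small_truth):
        """P(>=1 substitution in a 21-mer) = 1 - (1-e)^21 ~ 0.190 at e=0.01."""
        size = 100_000
        clean = simulate_library(small_catalog, small_truth, "BU", size, 0.0, seed=40)
        noisy = simulate_library(small_catalog, small_truth, "BU", size, 0.01, seed=40)
        # same seed: the multinomial draw is identical, reads align one-to-one
        changed = np.mean(clean.sequences != noisy.sequences)
        expected = 1 - 0.99**21
        assert abs(changed - expected) < 0.01

    def test_expressed_gene_without_tag_raises(self):
        from tagdge.reference import GeneCatalog
        from tagdge.simulate import TruthTable

        cat = GeneCatalog([("g0", "ACGT" * 30)])  # no CATG... may contain? ensure below
        assert extract_canonical_tag(cat["g0"]) is None
        truth = TruthTable(
            abundance=pd.DataFrame(
                {"BU": [1.0], "EG": [1.0], "EL": [1.0], "MA": [1.0]}, index=["g0"]
            ),
            labels=pd.DataFrame("none", index=["g0"], columns=["T1", "T2", "T3"]),
            designed_fold=pd.DataFrame(np.nan, index=["g0"], columns=["T1", "T2", "T3"]),
        )
        with pytest.raises(SimulationError, match="g0"):
            simulate_library(cat, truth, "BU", 10, 0.0, seed=1)
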