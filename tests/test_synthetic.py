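"""Synthetic corpus generation and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from caspcons import ortholog, sites, synthetic
from caspcons.synthetic import SyntheticConfig, generate_corpus, recover_parameters


def zero_noise_config(**overrides):
    base = dict(
        seed=2,
        n_sites=5,
        n_species_per_class={"Mammalia": 5, "Aves": 5},
        octamer_sub_rate={"Mammalia": 0.0, "Aves": 0.0},
        flank_sub_rate={"Mammalia": 0.0, "Aves": 0.0},
        p1_retention_prob=1.0,
        p1_to_E_prob=0.0,
        gap_at_p1_prob=0.0,
        hit_dropout_prob=0.0,
        multi_hit_prob=0.0,
        p1prime_resample_prob=0.0,
        n_poor_species=0,
        subject_flank_extra_max=4,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


class TestDeterminism:
    def test_same_seed_same_corpus(self):
        c1 = generate_corpus(SyntheticConfig(seed=3, n_sites=4,
                                             n_species_per_class={"Mammalia": 6, "Aves": 4}))
        c2 = generate_corpus(SyntheticConfig(seed=3, n_sites=4,
                                             n_species_per_class={"Mammalia": 6, "Aves": 4}))
        pd.testing.assert_frame_equal(c1.hits, c2.hits)
        pd.testing.assert_frame_equal(c1.truth_hits, c2.truth_hits)
        assert c1.proteome == c2.proteome

    def test_written_files_are_byte_identical(self, tmp_path):
        cfg = dict(seed=4, n_sites=3, n_species_per_class={"Mammalia": 4, "Aves": 3})
        generate_corpus(SyntheticConfig(**cfg)).write(tmp_path / "a")
        generate_corpus(SyntheticConfig(**cfg)).write(tmp_path / "b")
        for name in ("proteins.fasta", "hits.tsv", "q3.tsv", "lineage.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        c1 = generate_corpus(SyntheticConfig(seed=1, n_sites=3,
                                             n_species_per_class={"Mammalia": 4}))
        c2 = generate_corpus(SyntheticConfig(seed=2, n_sites=3,
                                             n_species_per_class={"Mammalia": 4}))
        assert not c1.hits.equals(c2.hits)


class TestDegenerateLimits:
    def test_zero_noise_gives_perfect_conservation(self):
        corpus = generate_corpus(zero_noise_config())
        site_list, _ = sites.load_sites(corpus.catalogue, corpus.proteome)
        best = ortholog.best_hit_per_species(corpus.hits)
        ann = ortholog.annotate_hits(site_list, best, corpus.lineage)
        assert (ann["octamer_hd"] == 0).all()
        assert (ann["p1_residue"] == "D").all()

    def test_zero_noise_recovery_error_is_zero(self):
        corpus = generate_corpus(zero_noise_config(
            p1_retention_prob=1.0, destab_p1prime_fraction=0.0))
        site_list, _ = sites.load_sites(corpus.catalogue, corpus.proteome)
        best = ortholog.best_hit_per_species(corpus.hits)
        ann = ortholog.annotate_hits(site_list, best, corpus.lineage)
        rep = recover_parameters(corpus, ann).set_index("parameter")
        assert rep.loc["p1_d_fraction", "abs_error"] == 0.0
        assert rep.loc["octamer_hd_anchoring_error", "abs_error"] == 0.0


class TestConfigValidation:
    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_corpus(SyntheticConfig(p1_retention_prob=1.5))

    def test_p1_categories_must_fit_in_unit_interval(self):
        with pytest.raises(ValueError):
            generate_corpus(SyntheticConfig(p1_retention_prob=0.9, p1_to_E_prob=0.2))

    def test_missing_class_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_corpus(
                SyntheticConfig(n_species_per_class={"Mammalia": 3, "Squamata": 3})
            )


class TestCorpusShape:
    def test_proteome_sizes_straddle_threshold(self, small_corpus):
        universe = ortholog.filter_species(small_corpus.proteome_sizes)
        sizes = small_corpus.proteome_sizes
        assert 0 < len(universe) < len(sizes)
        # the sparse-proteome species are exactly the filtered ones
        poor = set(sizes.loc[sizes["n_proteins"] <= 8000, "taxon_id"])
        assert poor.isdisjoint(universe)
        assert len(poor) == small_corpus.config.n_poor_species

    def test_hit_table_is_valid_pipeline_input(self, small_corpus, tmp_path):
        paths = small_corpus.write(tmp_path)
        hits = ortholog.read_hit_table(paths["hits"])
        assert {"site_id", "taxon_id", "evalue", "sseq"} <= set(hits.columns)
        best = ortholog.best_hit_per_species(hits)
        # best-hit selection keeps at most one row per (site, species)
        assert not best.duplicated(["site_id", "taxon_id"]).any()

    def test_duplicate_hits_lose_to_primary(self, small_corpus):
        best = ortholog.best_hit_per_species(small_corpus.hits)
        group_min = small_corpus.hits.groupby(["site_id", "taxon_id"])["evalue"].min()
        chosen = best.set_index(["site_id", "taxon_id"])["evalue"]
        assert (chosen == group_min.loc[chosen.index]).all()

    def test_q3_strings_are_valid(self, small_corpus):
        assert (small_corpus.q3["q3"].str.len() == 60).all()
        assert set("".join(small_corpus.q3["q3"])) <= set("HEC")


def _class_tree(lineage, species):
    """Planted two-level hierarchy: species join within their class, then
    classes join at the root."""
    import numpy as np

    from caspcons.clustering import Dendrogram

    cls = dict(zip(lineage["species_name"], lineage["class_label"]))
    n = len(species)
    index = {s: i for i, s in enumerate(species)}
    rows, roots, nid = [], [], n
    for c in sorted({cls[s] for s in species}):
        members = [index[s] for s in sorted(x for x in species if cls[x] == c)]
        cur, size = members[0], 1
        for m in members[1:]:
            size += 1
            rows.append([cur, m, 1.0, size])
            cur, nid = nid, nid + 1
        roots.append((cur, size))
    cur, size = roots[0]
    for other, osize in roots[1:]:
        size += osize
        rows.append([cur, other, 2.0, size])
        cur, nid = nid, nid + 1
    return Dendrogram(linkage=np.array(rows), labels=species)


class TestClassStructureRecovery:
    def test_clustering_separates_divergence_classes(self):
        """Class-structured substitution rates with a shared ancestor
        component let hierarchical clustering recover the planted classes
        (Baker's Gamma vs the planted class hierarchy above 0.8)."""
        from caspcons import clustering

        cfg = SyntheticConfig(
            seed=21,
            n_sites=30,
            n_species_per_class={"Mammalia": 20, "Actinopterygii": 20},
            octamer_sub_rate={"Mammalia": 0.03, "Actinopterygii": 0.20},
            flank_sub_rate={"Mammalia": 0.04, "Actinopterygii": 0.25},
            n_poor_species=0,
            p1prime_resample_prob=0.0,
            class_shared_fraction=0.7,
        )
        corpus = generate_corpus(cfg)
        site_list, _ = sites.load_sites(corpus.catalogue, corpus.proteome)
        ann = ortholog.annotate_hits(
            site_list, ortholog.best_hit_per_species(corpus.hits), corpus.lineage
        )
        matrix = clustering.build_species_matrix(
            ann, sorted(ann["site_id"].unique()), mode="window"
        )
        dend = clustering.cluster_species(matrix)
        planted = _class_tree(corpus.lineage, dend.labels)
        assert clustering.bakers_gamma(dend, planted) > 0.8


class TestParameterRecovery:
    def test_recovery_on_small_corpus_is_close(self, small_run):
        corpus = small_run["corpus"]
        ann = small_run["outputs"]["annotated_hits"]
        rep = recover_parameters(corpus, ann, corpus.q3).set_index("parameter")
        # ~550 hits: binomial noise only, anchored without error
        assert rep.loc["octamer_hd_anchoring_error", "abs_error"] == 0.0
        assert rep.loc["p1_d_fraction", "abs_error"] < 0.05
        assert rep.loc["destab_fraction", "abs_error"] < 0.08
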