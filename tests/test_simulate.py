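import math
from collections import Counter

import numpy as np
import pytest

from polyvalent._errors import ConfigError, UsageError
from polyvalent.architectures import write_architecture_table
from polyvalent.cooccurrence import (
    conditional_cooccurrence,
    domain_prevalence,
    prevalence_by_class,
)
from polyvalent.motifs import default_motifs, scan_sequence
from polyvalent.neighborhoods import classify_context
from polyvalent.simulate import (
    ConditionalRule,
    GeneratorConfig,
    MarginalRule,
    build_class_pools,
    config_for_conditional,
    config_for_marginal,
    generate_corpus,
    generate_motif_sequence,
    neighborhoods_as_annotation,
)


class TestConfigValidation:
    def test_defaults_valid(self):
        GeneratorConfig().validate()

    def test_bad_mixture(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(class_mixture=(("conjugative", 0.6), ("phage", 0.6),
                                           ("host", 0.2))).validate()

    def test_bad_probability(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(marginals=(MarginalRule("any", "MPTase", 1.2),)).validate()

    def test_duplicate_rules(self):
        m = MarginalRule("any", "MPTase", 0.3)
        with pytest.raises(ConfigError):
            GeneratorConfig(marginals=(m, m)).validate()
        c = ConditionalRule("any", "A", "B", 0.3)
        with pytest.raises(ConfigError):
            GeneratorConfig(conditionals=(c, c)).validate()

    def test_bad_scope(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(marginals=(MarginalRule("plasmidoid", "MPTase", 0.3),)).validate()


class TestCorpusGeneration:
    def test_empty_corpus(self):
        corpus = generate_corpus(GeneratorConfig(n_proteins=0))
        assert len(corpus.table) == 0 and corpus.neighborhoods == []

    def test_determinism_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(n_proteins=300, seed=5)
        t1, t2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_architecture_table(generate_corpus(cfg).table, t1)
        write_architecture_table(generate_corpus(cfg).table, t2)
        assert t1.read_bytes() == t2.read_bytes()

    def test_different_seeds_differ(self):
        a = generate_corpus(GeneratorConfig(n_proteins=200, seed=1)).table
        b = generate_corpus(GeneratorConfig(n_proteins=200, seed=2)).table
        assert any(
            pa.domain_ids != pb.domain_ids for pa, pb in zip(a, b)
        )

    def test_domain_count_range(self, small_corpus):
        ns = [len(p.hits) for p in small_corpus.table]
        assert min(ns) >= 2 and max(ns) <= 15
        # the length model concentrates mass at two or three domains
        assert sum(1 for k in ns if k <= 3) / len(ns) > 0.75

    def test_all_domains_resolve_against_catalog(self, small_corpus, catalog):
        for p in small_corpus.table:
            assert all(d in catalog for d in p.domain_ids)

    def test_conjugative_ardcn_is_n_terminal(self, small_corpus):
        for p in small_corpus.table:
            if p.element_class == "conjugative" and "ArdC-N" in p.domain_ids:
                assert p.domain_ids[0] == "ArdC-N"

    def test_mixture_recovery(self):
        corpus = generate_corpus(GeneratorConfig(n_proteins=10_000, seed=3,
                                                 with_neighborhoods=False))
        frac = sum(p.element_class == "conjugative" for p in corpus.table) / 10_000
        se = math.sqrt(0.4 * 0.6 / 10_000)
        assert abs(frac - 0.40) <= 3 * se


class TestPlantedMarkers:
    def test_marker_planting_matches_class(self, small_corpus):
        truth = {p.protein_id: p.element_class for p in small_corpus.table}
        for nb in small_corpus.neighborhoods:
            cls = truth[nb.anchor_gene_id.removesuffix("_anchor")]
            call = classify_context(nb)
            assert call.element_class == cls

    def test_tag_noise_can_flip_host_calls(self):
        corpus = generate_corpus(GeneratorConfig(n_proteins=400, seed=9, tag_noise=0.5))
        truth = {p.protein_id: p.element_class for p in corpus.table}
        flipped = sum(
            classify_context(nb).element_class
            != truth[nb.anchor_gene_id.removesuffix("_anchor")]
            for nb in corpus.neighborhoods
        )
        assert flipped > 0

    def test_annotation_view(self, small_corpus):
        ann = neighborhoods_as_annotation(small_corpus)
        assert len(ann) == len(small_corpus.neighborhoods)


class TestClassPools:
    def test_pool_overlap_exact_at_pool_level(self, catalog):
        cfg = GeneratorConfig()
        pools = build_class_pools(catalog, cfg)
        a, b = set(pools["conjugative"]), set(pools["phage"])
        iou = len(a & b) / len(a | b)
        target = round(cfg.class_domain_overlap * len(a | b)) / len(a | b)
        assert iou == pytest.approx(target)

    def test_rule_domains_excluded_from_pools(self, catalog):
        pools = build_class_pools(catalog, GeneratorConfig())
        assert "MPTase" not in pools["conjugative"] + pools["phage"]


class TestParameterRecovery:
    """Each generator probability is recovered by its estimator within
    3 binomial standard errors, across several seeds."""

    N = 4000

    def se(self, p, n):
        return 100 * math.sqrt(p * (1 - p) / n)

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_marginal(self, seed):
        corpus = generate_corpus(config_for_marginal("MPTase", 0.36, n=self.N, seed=seed))
        got = domain_prevalence(corpus.table, "MPTase")
        assert abs(got - 36.0) <= 3 * self.se(0.36, self.N)

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_conditional(self, seed):
        corpus = generate_corpus(
            config_for_conditional("ArdC-N", "MPTase", 0.70, 0.30, n=self.N, seed=seed)
        )
        got = conditional_cooccurrence(corpus.table, "ArdC-N", "MPTase")
        n_carriers = sum(1 for p in corpus.table if "ArdC-N" in p.domain_ids)
        assert abs(got - 70.0) <= 3 * self.se(0.70, n_carriers)

    def test_class_conditional_rule_overrides_any_marginal(self):
        cfg = GeneratorConfig(
            n_proteins=self.N, seed=4, with_neighborhoods=False,
            marginals=(MarginalRule("conjugative", "ArdC-N", 0.93),
                       MarginalRule("any", "ArdC-N", 0.26)),
            conditionals=(),
        )
        corpus = generate_corpus(cfg)
        conj = prevalence_by_class(corpus.table, "ArdC-N", "conjugative")
        phage = prevalence_by_class(corpus.table, "ArdC-N", "phage")
        n_conj = sum(p.element_class == "conjugative" for p in corpus.table)
        n_phage = sum(p.element_class == "phage" for p in corpus.table)
        assert abs(conj - 93.0) <= 3 * self.se(0.93, n_conj)
        assert abs(phage - 26.0) <= 3 * self.se(0.26, n_phage)
        assert corpus.reconciliation  # the skipped any-rule is logged


class TestMotifSequences:
    def test_planted_motif_found(self):
        seq = generate_motif_sequence("HEXXH", 50, 10, seed=2)
        pats = [m for m in default_motifs() if m.motif_id == "HEXXH"]
        assert 10 in [m.start for m in scan_sequence(seq, pats)]

    def test_bounds_error(self):
        with pytest.raises(UsageError):
            generate_motif_sequence("HEXXH", 4, 1, seed=0)

    def test_unknown_motif(self):
        with pytest.raises(KeyError):
            generate_motif_sequence("NOPE", 50, 10, seed=0)

    def test_seeds_change_background_not_plant(self):
        a = generate_motif_sequence("DD", 30, 5, seed=1)
        b = generate_motif_sequence("DD", 30, 5, seed=2)
        assert a != b
        assert a[4:6] == b[4:6] == "DD"
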