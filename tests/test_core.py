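import numpy as np
import pandas as pd
import pytest

import toascore as ts
from conftest import make_profile, score_fixture, small_config
from helpers_naive import naive_profile
from toascore.annotation import SnpAnnotationHit
from toascore.core import (
    WeightTable,
    build_credible_set_99,
    compute_toa,
    max_ppa_differential,
    snp_tissue_vector,
    ssd,
    weighted_toa,
)
from toascore.io import CredibleSet, ValidationError, Variant

TISSUES = ("islet", "adipose", "liver", "muscle")


def hit(annotation, tissues, genes=()):
    return SnpAnnotationHit(
        snp_id="rs1",
        annotation=annotation,
        tissues_hit=frozenset(tissues),
        gene_ids=tuple(genes),
    )


class TestWeights:
    @pytest.mark.parametrize(
        "log2fe, expected", [(0.0, 1.0), (-1.0, 0.5), (2.84, 2 ** 2.84)]
    )
    def test_exponentiation(self, log2fe, expected):
        wt = WeightTable.from_log2fe({("Enh", "islet"): log2fe})
        assert wt["Enh", "islet"] == pytest.approx(expected)
        if log2fe == 2.84:  # the strongest single annotation in the study
            assert wt["Enh", "islet"] == pytest.approx(7.16, abs=0.01)

    def test_missing_pair_listed(self):
        with pytest.raises(ValidationError, match="missing"):
            WeightTable.from_log2fe(
                {("Enh", "islet"): 1.0},
                annotations=["Enh"],
                tissues=["islet", "liver"],
            )

    def test_cds_weight_tissue_invariant(self):
        wt = WeightTable.from_log2fe({("Enh", "islet"): 1.0}, cds_log2fe=2.59)
        assert wt["CDS", "islet"] == wt["CDS", "liver"] == pytest.approx(2 ** 2.59)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValidationError):
            WeightTable({("Enh", "islet"): 0.0})


class TestSnpVector:
    def test_single_tissue_hit(self):
        wt = WeightTable({("Enh", "islet"): 2.0})
        v = snp_tissue_vector([hit("Enh", ["islet"])], wt, None, TISSUES)
        np.testing.assert_allclose(v.scores, [2, 0, 0, 0])

    def test_shared_hit_splits_by_tissue_count(self):
        wt = WeightTable({("Enh", "islet"): 4.0, ("Enh", "muscle"): 2.0})
        v = snp_tissue_vector(
            [hit("Enh", ["islet", "muscle"])], wt, None, TISSUES
        )
        np.testing.assert_allclose(v.scores, [2, 0, 0, 1])

    def test_cds_hit_distributes_by_ess(self):
        wt = WeightTable({("Enh", "islet"): 1.0}, cds_weight=6.0)
        ess = pd.DataFrame(
            [[0.6, 0.3, 0.1, 0.0]], index=["G"], columns=list(TISSUES)
        )
        v = snp_tissue_vector([hit("CDS", [], ["G"])], wt, ess, TISSUES)
        np.testing.assert_allclose(v.scores, [3.6, 1.8, 0.6, 0.0])
        assert v.cds_total == pytest.approx(6.0)

    def test_unknown_gene_contributes_nothing(self):
        wt = WeightTable({("Enh", "islet"): 1.0}, cds_weight=6.0)
        ess = pd.DataFrame(
            [[1.0, 0, 0, 0]], index=["KNOWN"], columns=list(TISSUES)
        )
        v = snp_tissue_vector([hit("CDS", [], ["NOVEL"])], wt, ess, TISSUES)
        assert v.total == 0.0

    def test_unweighted_annotation_raises(self):
        wt = WeightTable({("Enh", "islet"): 1.0})
        with pytest.raises(KeyError, match="Tss"):
            snp_tissue_vector([hit("Tss", ["islet"])], wt, None, TISSUES)


def vec(scores, snp_id="rs1", cds_total=0.0):
    return ts.SnpTissueVector(
        snp_id=snp_id, tissues=TISSUES, scores=np.array(scores, float),
        cds_total=cds_total,
    )


class TestComputeToa:
    def test_single_snp_full_ppa(self):
        cs = CredibleSet("s1", [Variant("rs1", "chr1", 10, 1.0)])
        p = compute_toa(cs, {"rs1": vec([2, 0, 0, 0])}, TISSUES)
        assert p.tau["islet"] == pytest.approx(1.0)
        assert p.unclassified == 0.0

    def test_unannotated_snp_feeds_unclassified(self):
        cs = CredibleSet(
            "s1",
            [Variant("rs1", "chr1", 10, 0.6), Variant("rs2", "chr1", 20, 0.4)],
        )
        vectors = {"rs1": vec([5, 0, 0, 0]), "rs2": vec([0, 0, 0, 0], "rs2")}
        p = compute_toa(cs, vectors, TISSUES)
        assert p.tau["islet"] == pytest.approx(0.6)
        assert p.unclassified == pytest.approx(0.4)

    def test_conservation_random_vectors(self):
        rng = np.random.default_rng(2)
        ppas = rng.dirichlet(np.ones(50))
        variants = [
            Variant(f"rs{i}", "chr1", i + 1, float(p))
            for i, p in enumerate(ppas)
        ]
        cs = CredibleSet("s1", variants)
        vectors = {
            f"rs{i}": vec(rng.exponential(1, 4) * (rng.random() > 0.3),
                          f"rs{i}")
            for i in range(50)
        }
        p = compute_toa(cs, vectors, TISSUES)
        assert sum(p.tau.values()) + p.unclassified == pytest.approx(
            cs.cumulative_ppa, abs=1e-9
        )


class TestWeightedToa:
    def test_scaling(self):
        p = make_profile({"islet": 0.5, "adipose": 0.0, "liver": 0.0,
                          "muscle": 0.0})
        w = weighted_toa(p, beta=0.1, se=0.05)
        assert w.omega["islet"] == pytest.approx(1.0)

    def test_zero_beta_zero_omega(self):
        p = make_profile({"islet": 0.5, "liver": 0.2})
        w = weighted_toa(p, beta=0.0, se=0.05)
        assert all(v == 0.0 for v in w.omega.values())

    def test_doubling_se_halves_omega(self):
        p = make_profile({"islet": 0.5, "liver": 0.2})
        w1 = weighted_toa(p, 0.1, 0.05)
        w2 = weighted_toa(p, 0.1, 0.10)
        for t in w1.omega:
            assert w2.omega[t] == pytest.approx(w1.omega[t] / 2)

    def test_missing_beta_raises(self):
        p = make_profile({"islet": 0.5})
        with pytest.raises(ValidationError):
            weighted_toa(p, None, 0.05)


class TestSsd:
    @pytest.mark.parametrize(
        "tau, expected",
        [
            ({"islet": 0.25, "adipose": 0.25, "liver": 0.25, "muscle": 0.25}, 0.0),
            ({"islet": 1.0, "adipose": 0.0, "liver": 0.0, "muscle": 0.0}, 3.0),
            ({"islet": 0.5, "adipose": 0.5, "liver": 0.0, "muscle": 0.0}, 1.0),
        ],
    )
    def test_pairwise_enumeration(self, tau, expected):
        # expected values from enumerating the six unordered tissue pairs
        p = make_profile(tau)
        assert ssd(p) == pytest.approx(expected)


class TestCredibleSet99:
    @pytest.mark.parametrize(
        "ppas, n_kept",
        [
            ([0.7, 0.25, 0.04, 0.01], 3),
            ([1.0], 1),
            ([0.5, 0.5], 2),
        ],
    )
    def test_minimal_prefix(self, ppas, n_kept):
        snps = [(f"rs{i}", p) for i, p in enumerate(ppas)]
        kept = build_credible_set_99(snps)
        assert len(kept) == n_kept
        assert sum(p for _, p in kept) >= 0.99

    def test_short_total_retains_all(self, caplog):
        kept = build_credible_set_99([("a", 0.4), ("b", 0.3)])
        assert len(kept) == 2

    def test_ties_break_lexicographically(self):
        kept = build_credible_set_99([("z", 0.5), ("a", 0.5)])
        assert [s for s, _ in kept] == ["a", "z"]


class TestMaxPpaDifferential:
    def test_examples(self):
        assert max_ppa_differential({"s": 0.8}, {"s": 0.5}) == {"s": pytest.approx(0.3)}
        same = {"a": 0.4, "b": 0.9}
        assert all(
            v == 0.0 for v in max_ppa_differential(same, dict(same)).values()
        )

    def test_vector_case_elementwise(self):
        rng = np.random.default_rng(3)
        scheme = {f"s{i}": float(x) for i, x in enumerate(rng.random(20))}
        null = {f"s{i}": float(x) for i, x in enumerate(rng.random(20))}
        diff = max_ppa_differential(scheme, null)
        for k in scheme:
            assert diff[k] == pytest.approx(scheme[k] - null[k])

    def test_key_mismatch_raises(self):
        with pytest.raises(ValidationError, match="keys"):
            max_ppa_differential({"a": 1.0}, {"b": 1.0})


class TestPipelineProperties:
    def test_oracle_equivalence_small_fixtures(self):
        """Vectorised pipeline equals the naive per-SNP double loop."""
        for seed in range(4):
            fx = ts.generate_fixture(small_config(seed + 100))
            profiles, ess, weights = score_fixture(fx)
            wmap = {
                (a, t): weights[a, t]
                for a in fx.included_states
                for t in fx.tissues
            }
            for cs, prof in zip(fx.credible_sets, profiles):
                tau, U, coding = naive_profile(
                    cs, fx.state_maps, fx.cds, ess, wmap,
                    weights.cds_weight, list(fx.tissues), fx.included_states,
                )
                np.testing.assert_allclose(
                    [prof.tau[t] for t in fx.tissues], tau, atol=1e-12
                )
                assert prof.unclassified == pytest.approx(max(U, 0), abs=1e-9)
                assert prof.coding_score == pytest.approx(coding, abs=1e-12)

    def test_global_weight_scale_invariance(self):
        fx = ts.generate_fixture(small_config(7))
        profiles, ess, weights = score_fixture(fx)
        for k in (0.1, 10.0):
            scaled = ts.score_signals(
                fx.credible_sets, fx.state_maps, weights.scaled(k), ess=ess,
                cds=fx.cds, included_states=fx.included_states,
                tissues=list(fx.tissues),
            )
            for a, b in zip(profiles, scaled):
                for t in fx.tissues:
                    assert b.tau[t] == pytest.approx(a.tau[t], rel=1e-12,
                                                     abs=1e-15)

    def test_single_tissue_degeneracy(self):
        """With one tissue, tau equals the cumulative PPA of annotated SNPs."""
        fx = ts.generate_fixture(
            small_config(9, n_tissues=1, fraction_shared_elements=0.0)
        )
        profiles, ess, weights = score_fixture(fx)
        from toascore.annotation import SnpAnnotator, partition_states

        annot = SnpAnnotator(
            partition_states(fx.state_maps), cds=fx.cds,
            included_states=fx.included_states,
        )
        t = fx.tissues[0]
        for cs, prof in zip(fx.credible_sets, profiles):
            annotated_ppa = sum(
                v.ppa
                for v in cs.variants
                if any(
                    h.annotation != "CDS" or
                    # a CDS-only SNP still counts when its gene is expressed
                    (ess.loc[list(h.gene_ids)].to_numpy().sum() > 0
                     if set(h.gene_ids) <= set(ess.index) else False)
                    for h in annot.annotate(v)
                )
            )
            assert prof.tau[t] == pytest.approx(annotated_ppa, abs=1e-9)

    def test_raising_one_tissue_weight_never_lowers_its_tau(self):
        fx = ts.generate_fixture(small_config(13))
        profiles, ess, weights = score_fixture(fx)
        bumped = {
            (a, t): weights[a, t] * (3.0 if t == "islet" else 1.0)
            for a in fx.included_states
            for t in fx.tissues
        }
        new = ts.score_signals(
            fx.credible_sets, fx.state_maps,
            WeightTable(bumped, weights.cds_weight), ess=ess, cds=fx.cds,
            included_states=fx.included_states, tissues=list(fx.tissues),
        )
        for a, b in zip(profiles, new):
            assert b.tau["islet"] >= a.tau["islet"] - 1e-12
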