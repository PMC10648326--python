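import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

from her2mbc import expression_profile as ep
from her2mbc.her2_calling import DegenerateInputError
from her2mbc.io_formats import ExpressionMatrix


def matrix_from_log2(genes, samples, log2_values, chrom=None):
    chrom = chrom or {g: "1" for g in genes}
    return ExpressionMatrix(
        genes=list(genes), samples=list(samples),
        values=np.maximum(2.0 ** np.asarray(log2_values, float) - 1.0, 0.0),
        gene_chrom=chrom,
    )


# ---------------------------------------------------------------------------
# groups
# ---------------------------------------------------------------------------

def test_four_group_labels():
    groups = ep.make_four_groups(
        {"a": "positive", "b": "positive", "c": "negative", "d": "negative"},
        {"a": True, "b": False, "c": True, "d": False},
    )
    assert groups.to_dict() == {"a": "HER2+/prior", "b": "HER2+/naive",
                                "c": "HER2-/prior", "d": "HER2-/naive"}


def test_missing_label_excluded():
    groups = ep.make_four_groups({"a": "positive", "b": "positive"}, {"a": True})
    assert list(groups.index) == ["a"]


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------

def planted_matrix(rng, n_per_group=40, shift=3.0, chrom_effect="5"):
    groups = np.repeat(list(ep.GROUP_LABELS), n_per_group)
    n = len(groups)
    samples = [f"S{i}" for i in range(n)]
    effect = 6.0 + np.where(groups == "HER2+/prior", shift, 0.0) + rng.normal(0, 1, n)
    eff17 = 6.0 + np.where(groups == "HER2+/naive", shift, 0.0) + rng.normal(0, 1, n)
    null = 6.0 + rng.normal(0, 1, n)
    m = matrix_from_log2(
        ["eff", "eff17", "null"], samples, np.vstack([effect, eff17, null]),
        chrom={"eff": chrom_effect, "eff17": "17", "null": "2"},
    )
    return m, pd.Series(groups, index=samples)


def test_planted_effect_gene_selected(rng):
    m, groups = planted_matrix(rng)
    res = ep.select_her2_genes(m, groups)
    assert res.frame.loc["eff", "selected"]
    assert not res.frame.loc["null", "selected"]
    assert res.frame.loc["null", "exclusion_reason"] == "p_above_threshold"


def test_chr17_gene_never_selected(rng):
    m, groups = planted_matrix(rng)
    res = ep.select_her2_genes(m, groups)
    assert not res.frame.loc["eff17", "selected"]
    assert res.frame.loc["eff17", "exclusion_reason"] == "chr17"


def test_constant_gene_not_selected(rng):
    groups = pd.Series(np.repeat(list(ep.GROUP_LABELS), 5),
                       index=[f"S{i}" for i in range(20)])
    m = matrix_from_log2(["flat"], groups.index, [np.full(20, 4.0)])
    res = ep.select_her2_genes(m, groups)
    assert not res.frame.loc["flat", "selected"]
    assert np.isnan(res.frame.loc["flat", "p"])


def test_three_group_cohort_still_runs(rng, caplog):
    """A cohort missing one HER2 x therapy combination degrades to a
    3-group Kruskal-Wallis with a warning, matching a direct 3-group test."""
    import logging
    from scipy.stats import kruskal

    groups = np.repeat(["HER2+/prior", "HER2+/naive", "HER2-/naive"], 30)
    samples = [f"S{i}" for i in range(90)]
    vals = 5.0 + np.where(groups == "HER2+/prior", 2.5, 0.0) + rng.normal(0, 1, 90)
    m = matrix_from_log2(["g"], samples, [vals], chrom={"g": "3"})
    with caplog.at_level(logging.WARNING):
        res = ep.select_her2_genes(m, pd.Series(groups, index=samples))
    assert any("3 of 4" in r.message for r in caplog.records)
    log2v = np.log2(m.values[0] + 1)
    oracle = kruskal(*[log2v[groups == g] for g in np.unique(groups)]).pvalue
    # selection works on the raw (monotone-transform-invariant) ranks
    assert res.frame.loc["g", "p"] == pytest.approx(oracle)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def two_block_matrix(rng, n_genes=30, n_per=10):
    samples = [f"A{i}" for i in range(n_per)] + [f"B{i}" for i in range(n_per)]
    block = np.zeros((n_genes, 2 * n_per))
    block[: n_genes // 2, :n_per] = 4.0
    block[n_genes // 2:, n_per:] = 4.0
    vals = 6.0 + block + rng.normal(0, 0.3, size=block.shape)
    genes = [f"G{i}" for i in range(n_genes)]
    return matrix_from_log2(genes, samples, vals), samples, n_per


def test_separable_groups_cluster_exactly(rng):
    m, samples, n_per = two_block_matrix(rng)
    res = ep.cluster_on_profile(m, m.genes, k=2)
    truth = [0] * n_per + [1] * n_per
    assert adjusted_rand_score(truth, res.labels.loc[samples]) == 1.0


def test_cluster_labels_invariant_to_sample_order(rng):
    m, samples, n_per = two_block_matrix(rng)
    perm = rng.permutation(len(samples))
    m2 = ExpressionMatrix(
        genes=list(m.genes), samples=[samples[i] for i in perm],
        values=m.values[:, perm], gene_chrom=dict(m.gene_chrom))
    res1 = ep.cluster_on_profile(m, m.genes, k=2)
    res2 = ep.cluster_on_profile(m2, m.genes, k=2)
    common = res1.labels.index
    assert adjusted_rand_score(res1.labels.loc[common], res2.labels.loc[common]) == 1.0


def test_cluster_invariant_to_per_gene_shift(rng):
    m, samples, n_per = two_block_matrix(rng)
    # adding a constant per gene is removed by median centring of log2 values
    log2 = np.log2(m.values + 1.0) + rng.uniform(1, 3, size=(len(m.genes), 1))
    m2 = matrix_from_log2(m.genes, samples, log2)
    res1 = ep.cluster_on_profile(m, m.genes, k=2)
    res2 = ep.cluster_on_profile(m2, m.genes, k=2)
    assert adjusted_rand_score(res1.labels, res2.labels.loc[res1.labels.index]) == 1.0


def test_duplicate_sample_joins_first(rng):
    m, samples, _ = two_block_matrix(rng)
    dup_vals = np.hstack([m.values, m.values[:, :1]])
    m2 = ExpressionMatrix(genes=list(m.genes), samples=samples + ["A0_copy"],
                          values=dup_vals, gene_chrom=dict(m.gene_chrom))
    res = ep.cluster_on_profile(m2, m2.genes, k=2)
    first_merge = res.linkage_matrix[0]
    idx = {s: i for i, s in enumerate(res.samples)}
    assert {int(first_merge[0]), int(first_merge[1])} == {idx["A0"], idx["A0_copy"]}
    assert first_merge[2] == pytest.approx(0.0, abs=1e-12)


def test_too_few_genes_errors(rng):
    m, *_ = two_block_matrix(rng)
    with pytest.raises(ValueError):
        ep.cluster_on_profile(m, m.genes[:1], k=2)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_enrichment_matches_hypergeometric_oracle():
    """Cluster of 116 samples in a cohort of 366 holding 47 of 49 positives."""
    n, cluster_size, K, k_in = 366, 116, 49, 47
    labels = pd.Series([1] * cluster_size + [2] * (n - cluster_size),
                       index=[f"S{i}" for i in range(n)])
    ann = pd.Series([True] * k_in + [False] * (cluster_size - k_in)
                    + [True] * (K - k_in) + [False] * (n - cluster_size - (K - k_in)),
                    index=labels.index)
    res = ep.cluster_enrichment(labels, ann)
    observed = hypergeom.pmf(k_in, n, K, cluster_size)
    oracle = sum(
        p for k in range(max(0, cluster_size + K - n), min(K, cluster_size) + 1)
        if (p := hypergeom.pmf(k, n, K, cluster_size)) <= observed * (1 + 1e-9)
    )
    assert res.loc[1, "p"] == pytest.approx(oracle, rel=1e-9)
    assert res.loc[1, "p"] < 1e-20  # massively enriched, as the table implies


def test_enrichment_constant_annotation(caplog):
    import logging
    labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
    ann = pd.Series([True] * 4, index=list("abcd"))
    with caplog.at_level(logging.WARNING):
        res = ep.cluster_enrichment(labels, ann)
    assert (res["p"] == 1.0).all()


def test_enrichment_multicategory_uses_chi2(rng):
    labels = pd.Series(rng.integers(1, 3, 60), index=[f"S{i}" for i in range(60)])
    ann = pd.Series(rng.choice(["x", "y", "z"], 60), index=labels.index)
    res = ep.cluster_enrichment(labels, ann)
    assert set(res["test"]) == {"chi2"}


# ---------------------------------------------------------------------------
# signature scores and classification
# ---------------------------------------------------------------------------

def test_single_gene_score_is_centred_value(rng):
    vals = rng.uniform(2, 9, size=(1, 11))
    m = matrix_from_log2(["g"], [f"S{i}" for i in range(11)], vals)
    score = ep.score_signature(m, ["g"])
    log2 = np.log2(m.values[0] + 1)
    np.testing.assert_allclose(score.values, log2 - np.median(log2), atol=1e-12)


def test_median_sample_scores_zero(rng):
    n = 11
    vals = rng.uniform(2, 9, size=(5, n))
    vals[:, 0] = np.median(vals, axis=1)  # sample 0 sits at every gene median
    m = matrix_from_log2([f"g{i}" for i in range(5)], [f"S{i}" for i in range(n)], vals)
    assert ep.score_signature(m, list(m.genes))["S0"] == pytest.approx(0.0, abs=1e-12)


def test_score_ignores_genes_outside_set(rng):
    vals = rng.uniform(2, 9, size=(6, 15))
    genes = [f"g{i}" for i in range(6)]
    samples = [f"S{i}" for i in range(15)]
    m_all = matrix_from_log2(genes, samples, vals)
    m_sub = matrix_from_log2(genes[:3], samples, vals[:3])
    s1 = ep.score_signature(m_all, genes[:3])
    s2 = ep.score_signature(m_sub, genes[:3])
    np.testing.assert_allclose(s1.values, s2.values, atol=1e-12)


def test_zero_intersection_names_missing_genes(rng):
    m = matrix_from_log2(["g1"], ["S0"] * 0 + [f"S{i}" for i in range(3)],
                         rng.uniform(1, 5, size=(1, 3)))
    with pytest.raises(KeyError, match="MISSING"):
        ep.score_signature(m, ["MISSING1", "MISSING2"])


def test_esr1_bimodal_classification(rng):
    n = 200
    high = rng.random(n) < 0.6
    log2 = np.where(high, rng.normal(8, 0.8, n), rng.normal(3, 0.8, n))
    m = matrix_from_log2(["ESR1"], [f"S{i}" for i in range(n)], [log2],
                         chrom={"ESR1": "6"})
    cls = ep.classify_esr1(m)
    agree = ((cls == "high") == pd.Series(high, index=cls.index)).mean()
    assert agree >= 0.98


def test_esr1_constant_refused():
    m = matrix_from_log2(["ESR1"], [f"S{i}" for i in range(30)],
                         [np.full(30, 5.0)], chrom={"ESR1": "6"})
    with pytest.raises(DegenerateInputError):
        ep.classify_esr1(m)


def test_meta_er_mapping():
    er = pd.Series({"a": "positive", "b": "positive", "c": "negative",
                    "d": "negative", "e": "unknown"})
    cls = pd.Series({"a": "low", "b": "high", "c": "high", "d": "low", "e": "low"})
    status = ep.meta_er_status(er, cls)
    assert status.to_dict() == {"a": "pos_to_low", "b": "concordant_pos",
                                "c": "neg_to_high", "d": "concordant_neg"}
    assert "e" not in status.index  # unknown ER omitted


def test_mapk_high_strict_median(rng):
    scores = pd.Series([1.0, 2.0, 2.0, 3.0, 4.0, 5.0],
                       index=[f"S{i}" for i in range(6)])
    high = ep.mapk_high(scores)
    med = sorted(scores)[len(scores) // 2 - 1:len(scores) // 2 + 1]
    oracle = scores > np.mean(med)  # brute-force median
    assert high.equals(oracle)
    assert not high["S1"] and not high["S2"]  # at/below the median is not high
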