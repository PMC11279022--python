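"""diversity_ordination: alpha metrics, rarefaction, Bray-Curtis, NMDS, PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from leafendo.diversity import (
    alpha_diversity,
    bray_curtis,
    nmds,
    permanova,
    rarefaction_curve,
    rarefy,
    richness,
    shannon,
)
from leafendo.tables import SampleMetadata

from conftest import make_table


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def test_richness_counts_nonzero():
    assert richness([0, 3, 0, 1, 2]) == 3


def test_shannon_uniform_closed_form():
    # k equally abundant taxa -> H = ln k
    for k in (2, 4, 7):
        assert shannon([10] * k) == pytest.approx(np.log(k))


def test_shannon_single_taxon_zero():
    assert shannon([0, 42, 0]) == pytest.approx(0.0)


def test_shannon_two_to_one_closed_form():
    p = np.array([2 / 3, 1 / 3])
    assert shannon([20, 10]) == pytest.approx(float(-(p * np.log(p)).sum()))


def test_shannon_all_zero_errors():
    with pytest.raises(ValueError, match="all-zero"):
        shannon([0, 0])


def test_alpha_diversity_table_and_contrasts():
    t = make_table([[10, 10, 1, 1], [10, 10, 1, 1], [0, 0, 18, 18]])
    meta = SampleMetadata({"s0": "HL", "s1": "HL", "s2": "NL", "s3": "NL"})
    res = alpha_diversity(t, meta, method="wilcoxon")
    assert list(res.per_sample.index) == ["s0", "s1", "s2", "s3"]
    assert res.per_sample.loc["s0", "richness"] == 2
    assert res.per_sample.loc["s2", "richness"] == 3
    assert set(res.contrasts) == {"richness", "shannon"}
    for stat, p in res.contrasts.values():
        assert 0 < p <= 1


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def test_rarefy_preserves_depth_and_support():
    t = make_table(np.random.default_rng(0).integers(0, 30, size=(15, 4)) + 1)
    depth = int(t.library_sizes.min())
    r = rarefy(t, depth, seed=3)
    assert (r.library_sizes == depth).all()
    assert (r.counts <= t.counts).all()


def test_rarefy_depth_too_large_errors():
    t = make_table([[3, 3], [2, 2]])
    with pytest.raises(ValueError, match="depth exceeds"):
        rarefy(t, 6)


def test_rarefaction_exact_hypergeometric_oracle():
    # counts (4, 2, 1), depth 3: E[S] = 3 - [C(3,3)+C(5,3)+C(6,3)]/C(7,3)
    #                                 = 3 - (1 + 10 + 20)/35 = 3 - 31/35
    out = rarefaction_curve([4, 2, 1], [3])
    assert out[0] == pytest.approx(3 - 31 / 35)


def test_rarefaction_endpoints_and_monotone():
    c = [9, 5, 3, 1]
    depths = list(range(0, 19))
    out = rarefaction_curve(c, depths)
    assert out[0] == pytest.approx(0.0)
    assert out[-1] == pytest.approx(4.0)
    assert (np.diff(out) >= -1e-12).all()


def test_rarefaction_monte_carlo_agrees_with_exact():
    c = [20, 10, 5, 2]
    exact = rarefaction_curve(c, [10])
    mc = rarefaction_curve(c, [10], reps=400, seed=0)
    assert mc[0] == pytest.approx(exact[0], abs=0.1)


def test_rarefaction_depth_validation():
    with pytest.raises(ValueError, match="depths"):
        rarefaction_curve([2, 2], [5])


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def test_bray_curtis_closed_forms():
    t = make_table([[10, 0, 5], [0, 10, 5]])
    d = bray_curtis(t)
    assert d.loc["s0", "s1"] == pytest.approx(1.0)  # disjoint
    assert d.loc["s0", "s0"] == pytest.approx(0.0)
    # (10,0) vs (5,5): 1 - 2*min_sum/total = 1 - 2*5/20 = 0.5
    assert d.loc["s0", "s2"] == pytest.approx(0.5)
    assert np.allclose(d.to_numpy(), d.to_numpy().T)


def test_bray_curtis_scale_sensitivity_oracle():
    # depth-doubling changes BC; verify against the definition directly
    x, y = np.array([3.0, 1.0, 0.0]), np.array([2.0, 2.0, 2.0])
    t = make_table(np.column_stack([x, y]).astype(int))
    expect = np.abs(x - y).sum() / (x + y).sum()
    assert bray_curtis(t).loc["s0", "s1"] == pytest.approx(expect)


def test_bray_curtis_needs_two_samples():
    with pytest.raises(ValueError, match=">= 2 samples"):
        bray_curtis(make_table([[3], [1]]))


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def test_nmds_recovers_embeddable_configuration():
    # 4 points on a line; their distances embed perfectly in k=2 -> stress ~ 0
    pts = np.array([[0.0], [1.0], [2.0], [4.0]])
    d = np.abs(pts - pts.T)
    res = nmds(d, k=2, seed=0)
    assert res.stress < 0.01
    assert res.coordinates.shape == (4, 2)
    assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-8)


def test_nmds_equilateral_preserves_rank_order():
    d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    res = nmds(d, k=2, seed=1)
    emb = res.coordinates.to_numpy()
    pair = lambda i, j: np.linalg.norm(emb[i] - emb[j])
    ds = [pair(0, 1), pair(0, 2), pair(1, 2)]
    assert res.stress < 0.05
    assert max(ds) / min(ds) < 1.3  # near-equilateral output


def test_nmds_dataframe_labels_and_validation():
    d = pd.DataFrame(
        [[0, 1, 2], [1, 0, 1], [2, 1, 0]],
        index=list("abc"),
        columns=list("abc"),
        dtype=float,
    )
    res = nmds(d, k=1, seed=0)
    assert list(res.coordinates.index) == ["a", "b", "c"]
    with pytest.raises(ValueError):
        nmds(d.iloc[:2, :2], k=1)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _brute_force_permanova_p(d2, labels):
    """Exhaustive pseudo-F permutation p over all relabelings (add-one form
    is not used here: full enumeration includes the identity)."""
    n = len(d2)

    def f_of(lab):
        lab = np.asarray(lab)
        iu = np.triu_indices(n, k=1)
        ss_total = d2[iu].sum() / n
        ssw = 0.0
        for g in set(lab):
            m = lab == g
            sub = d2[np.ix_(m, m)]
            ssw += sub[np.triu_indices(m.sum(), k=1)].sum() / m.sum()
        a = len(set(lab))
        return ((ss_total - ssw) / (a - 1)) / (ssw / (n - a)), ss_total, ssw

    f_obs = f_of(labels)[0]
    ge = tot = 0
    for perm in itertools.permutations(labels):
        tot += 1
        if f_of(perm)[0] >= f_obs - 1e-12:
            ge += 1
    return f_obs, ge / tot


def test_permanova_matches_exhaustive_six_samples():
    rng = np.random.default_rng(7)
    x = np.vstack([rng.normal(0, 1, (3, 4)), rng.normal(2, 1, (3, 4))])
    from scipy.spatial.distance import pdist, squareform

    dm = squareform(pdist(x))
    labels = np.array(["A"] * 3 + ["B"] * 3)
    res = permanova(dm, labels, n_permutations=9999, seed=0)
    f_exact, p_exact = _brute_force_permanova_p(dm**2, labels)
    assert res.pseudo_F == pytest.approx(f_exact, rel=1e-10)
    # sampled add-one p vs exhaustive proportion: generous MC tolerance
    assert res.p == pytest.approx(p_exact, abs=0.02)


def test_permanova_strong_separation_minimal_p():
    d = np.ones((6, 6)) - np.eye(6)
    d[np.ix_([0, 1, 2], [0, 1, 2])] *= 0.01
    d[np.ix_([3, 4, 5], [3, 4, 5])] *= 0.01
    labels = np.array(["A"] * 3 + ["B"] * 3)
    res = permanova(d, labels, n_permutations=999, seed=0)
    # only relabelings equivalent to the true split attain F_obs:
    # 2 / C(6,3) = 0.1 exhaustively; sampled add-one p lands near that
    assert res.pseudo_F > 100
    assert res.p <= 0.15


def test_permanova_r2_plus_f_consistency():
    rng = np.random.default_rng(8)
    from scipy.spatial.distance import pdist, squareform

    x = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(1.5, 1, (5, 3))])
    dm = squareform(pdist(x))
    labels = np.array(["A"] * 5 + ["B"] * 5)
    res = permanova(dm, labels, n_permutations=99, seed=1)
    # F = (R2/(a-1)) / ((1-R2)/(n-a)) must hold identically
    n, a = 10, 2
    f_from_r2 = (res.R2 / (a - 1)) / ((1 - res.R2) / (n - a))
    assert res.pseudo_F == pytest.approx(f_from_r2, rel=1e-10)
    assert 0 < res.R2 < 1


def test_permanova_invariant_to_sample_reordering():
    rng = np.random.default_rng(9)
    from scipy.spatial.distance import pdist, squareform

    x = np.vstack([rng.normal(0, 1, (4, 3)), rng.normal(1, 1, (4, 3))])
    dm = squareform(pdist(x))
    labels = np.array(["A"] * 4 + ["B"] * 4)
    res = permanova(dm, labels, n_permutations=499, seed=0)
    perm = rng.permutation(8)
    res2 = permanova(dm[np.ix_(perm, perm)], labels[perm], n_permutations=499, seed=0)
    assert res2.pseudo_F == pytest.approx(res.pseudo_F, rel=1e-10)
    assert res2.R2 == pytest.approx(res.R2, rel=1e-10)
    assert abs(res2.p - res.p) <= 0.05


def test_permanova_validation():
    d = np.zeros((4, 4))
    with pytest.raises(ValueError, match=">= 2 groups"):
        permanova(d, np.array(["A"] * 4), n_permutations=9)
    with pytest.raises(ValueError, match=">= 2 samples"):
        permanova(d, np.array(["A", "A", "A", "B"]), n_permutations=9)


def test_permanova_dataframe_with_metadata(small_dataset):
    table, groups, _ = small_dataset
    d = bray_curtis(table)
    res = permanova(d, groups, n_permutations=99, seed=0)
    assert res.n_permutations == 99
    assert 1 / 100 <= res.p <= 1


def test_nmds_stress_not_worse_than_metric_seed():
    # the optimiser includes a start at the classical (metric) MDS
    # configuration, so the returned stress can never exceed that
    # configuration's own stress-1
    rng = np.random.default_rng(11)
    x = rng.standard_normal((8, 3))
    from scipy.spatial.distance import pdist, squareform

    dm = squareform(pdist(x))
    res = nmds(dm, k=2, seed=0)

    from leafendo.diversity import _stress1

    n = len(dm)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:2]
    init = v[:, idx] * np.sqrt(np.maximum(w[idx], 0))
    assert res.stress <= _stress1(init, dm) + 1e-9


def test_permanova_matches_skbio():
    # independent cross-check against scikit-bio's implementation
    from skbio import DistanceMatrix
    from skbio.stats.distance import permanova as skbio_permanova

    rng = np.random.default_rng(12)
    from scipy.spatial.distance import pdist, squareform

    x = np.vstack([rng.normal(0, 1, (5, 4)), rng.normal(1, 1, (5, 4))])
    dm = squareform(pdist(x))
    labels = np.array(["A"] * 5 + ["B"] * 5)
    ours = permanova(dm, labels, n_permutations=999, seed=0)
    ids = [f"s{i}" for i in range(10)]
    ref = skbio_permanova(DistanceMatrix(dm, ids), list(labels), permutations=999)
    assert ours.pseudo_F == pytest.approx(float(ref["test statistic"]), rel=1e-9)
    assert abs(ours.p - float(ref["p-value"])) <= 0.05
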