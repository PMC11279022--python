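"""Alpha diversity, rarefaction, Bray-Curtis distances, NMDS, PERMANOVA.

Alpha diversity (observed ASV richness and the natural-log Shannon index) is
computed per sample and contrasted between health groups.  Community
structure is compared on Bray-Curtis dissimilarities via non-metric
multidimensional scaling (NMDS, Kruskal stress-1) and one-way PERMANOVA
(Anderson's distance-based pseudo-F with label-permutation p-values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from sklearn.manifold import MDS

from .tables import CountTable, SampleMetadata, group_contrast_test

__all__ = [
    "AlphaResult",
    "OrdinationResult",
    "PermanovaResult",
    "richness",
    "shannon",
    "alpha_diversity",
    "rarefy",
    "rarefaction_curve",
    "bray_curtis",
    "nmds",
    "permanova",
]


@dataclass(frozen=True)
class AlphaResult:
    """Per-sample alpha diversity plus between-group contrasts."""

    per_sample: pd.DataFrame  # index sample_id; columns richness, shannon, group
    contrasts: dict[str, tuple[float, float]]  # metric -> (statistic, p)


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k, centred
    stress: float  # Kruskal stress-1
    k: int
    converged: bool


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int


def richness(counts: np.ndarray) -> int:
    """Observed richness: number of taxa with nonzero count."""
    return int(np.count_nonzero(np.asarray(counts)))


def shannon(counts: np.ndarray) -> float:
    """Shannon index H = -sum p ln p (natural log); zero counts contribute 0."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def rarefy(t: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement."""
    if (t.library_sizes < depth).any():
        raise ValueError("rarefaction depth exceeds a library size")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(t.counts)
    for j in range(t.n_samples):
        pool = np.repeat(np.arange(t.n_taxa), t.counts[:, j])
        pick = rng.choice(pool, size=depth, replace=False)
        out[:, j] = np.bincount(pick, minlength=t.n_taxa)
    return CountTable(t.taxon_ids, t.sample_ids, out, t.kingdom)


def alpha_diversity(
    t: CountTable,
    groups: SampleMetadata | None = None,
    method: str = "t_test",
    rarefy_to_min: bool = False,
    seed: int = 0,
) -> AlphaResult:
    """Richness and Shannon per sample, with optional group contrasts.

    Counts are used as-is by default; ``rarefy_to_min=True`` first
    subsamples every library to the smallest library size.
    """
    tt = rarefy(t, int(t.library_sizes.min()), seed) if rarefy_to_min else t
    rows = {
        s: {"richness": richness(tt.counts[:, j]), "shannon": shannon(tt.counts[:, j])}
        for j, s in enumerate(tt.sample_ids)
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    contrasts: dict[str, tuple[float, float]] = {}
    if groups is not None:
        df["group"] = [groups.group_of(s) for s in df.index]
        split = groups.split(tt.sample_ids)
        (g1, s1), (g2, s2) = sorted(split.items())
        for metric in ("richness", "shannon"):
            contrasts[metric] = group_contrast_test(
                df.loc[s1, metric], df.loc[s2, metric], method=method
            )
    return AlphaResult(per_sample=df, contrasts=contrasts)


def rarefaction_curve(
    counts: np.ndarray,
    depths: np.ndarray | list[int],
    reps: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Expected richness at each subsampling depth.

    By default the exact hypergeometric expectation is used:
    ``E[S(d)] = S - sum_i C(T - n_i, d) / C(T, d)`` with ``T`` the sample
    total and ``n_i`` the taxon counts; it is deterministic and monotone in
    depth.  Passing ``reps > 0`` switches to Monte-Carlo subsampling.
    """
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    total = int(c.sum())
    depths = np.asarray(depths, dtype=np.int64)
    if (depths > total).any() or (depths < 0).any():
        raise ValueError("depths must lie in [0, sample total]")
    if reps > 0:
        rng = np.random.default_rng(seed)
        pool = np.repeat(np.arange(len(c)), c)
        out = np.empty(len(depths))
        for k, d in enumerate(depths):
            hits = [
                np.unique(rng.choice(pool, size=d, replace=False)).size
                for _ in range(reps)
            ]
            out[k] = float(np.mean(hits))
        return out

    def log_comb(a: np.ndarray, b: int) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(len(depths))
    for k, d in enumerate(depths):
        ok = (total - c) >= d
        miss = np.zeros(len(c))
        miss[ok] = np.exp(log_comb(total - c[ok].astype(float), int(d)) - log_comb(np.float64(total), int(d)))
        out[k] = len(c) - miss.sum()
    return out


def bray_curtis(t: CountTable) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity matrix between samples."""
    if t.n_samples < 2:
        raise ValueError("need >= 2 samples")
    d = squareform(pdist(t.counts.T.astype(float), metric="braycurtis"))
    return pd.DataFrame(d, index=list(t.sample_ids), columns=list(t.sample_ids))


def _stress1(coords: np.ndarray, d: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against target dissimilarities."""
    from scipy.stats import rankdata
    from sklearn.isotonic import IsotonicRegression

    iu = np.triu_indices(len(d), k=1)
    dis = d[iu]
    emb = squareform(pdist(coords))[iu]
    iso = IsotonicRegression()
    fitted = iso.fit_transform(rankdata(dis), emb)
    denom = (emb**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((emb - fitted) ** 2).sum() / denom))


def nmds(
    d: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_starts: int = 4,
    seed: int = 0,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Runs SMACOF with isotonic regression from ``n_starts`` random starts plus
    one start at the classical (metric) MDS configuration, and returns the
    lowest-stress solution with centred coordinates.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        dm = d.to_numpy(dtype=float)
    else:
        dm = np.asarray(d, dtype=float)
        labels = [f"s{i}" for i in range(len(dm))]
    n = len(dm)
    if k < 1 or n < 3:
        raise ValueError("need k >= 1 and >= 3 samples")

    def fit(init: np.ndarray | None, rs: int) -> tuple[np.ndarray, float]:
        model = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            init="random",
            n_init=1 if init is not None else n_starts,
            random_state=rs,
            max_iter=max_iter,
            normalized_stress=True,
            eps=1e-9,
        )
        coords = model.fit_transform(dm, init=init)
        return coords, float(model.stress_)

    best_coords, best_stress = fit(None, seed)

    # classical-MDS start: double-centred eigendecomposition of -D^2/2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:k]
    init = v[:, idx] * np.sqrt(np.maximum(w[idx], 0))
    coords2, stress2 = fit(init, seed)
    if stress2 < best_stress:
        best_coords, best_stress = coords2, stress2

    best_coords = best_coords - best_coords.mean(axis=0)
    converged = bool(np.isfinite(best_stress))
    return OrdinationResult(
        coordinates=pd.DataFrame(
            best_coords, index=labels, columns=[f"NMDS{i + 1}" for i in range(k)]
        ),
        stress=best_stress,
        k=k,
        converged=converged,
    )


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from a squared distance matrix and labels."""
    n = len(d2)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        mask = labels == g
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(mask.sum(), k=1)].sum() / mask.sum()
    return ss_total, ss_within


def permanova(
    d: pd.DataFrame | np.ndarray,
    groups: SampleMetadata | np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Pseudo-F follows the distance-based sum-of-squares partition
    (SS_total from all squared pairwise distances / N; SS_within from
    within-group squared distances / group size).  The p-value permutes
    group labels with the add-one convention.
    """
    if isinstance(d, pd.DataFrame):
        labels = (
            groups.labels_for(list(d.index))
            if isinstance(groups, SampleMetadata)
            else np.asarray(groups)
        )
        dm = d.to_numpy(dtype=float)
    else:
        dm = np.asarray(d, dtype=float)
        labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 samples")
    n = len(dm)
    a = len(uniq)
    d2 = dm**2

    ss_total, ss_within = _permanova_ss(d2, labels)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        sst, ssw = _permanova_ss(d2, perm)
        f_perm = ((sst - ssw) / (a - 1)) / (ssw / (n - a))
        if f_perm >= f_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_F=float(f_obs), R2=float(r2), p=float(p), n_permutations=n_permutations
    )
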