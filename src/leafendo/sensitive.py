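"""Health-sensitive ASV detection.

Two complementary screens are intersected:

* **Differential abundance** — per-taxon negative-binomial generalised
  linear models with effective-library offsets (library size x TMM factor),
  a likelihood-ratio test of the group effect against chi-square(1), and
  Benjamini-Hochberg FDR control.
* **Indicator species analysis** — the group-size-corrected IndVal
  (``sqrt(specificity x fidelity)``) with a label-permutation test on the
  max-over-groups statistic.

Taxa significant by both (default q < 0.05 and permutation p < 0.05) are
flagged as health-sensitive ASVs (hsASVs), with the enriched group assigned
from the indicator side and checked for agreement with the fold-change sign.

TMM (trimmed mean of M-values) normalisation follows the standard
construction: a reference library chosen by the upper-quartile criterion,
M- and A-values doubly trimmed (30% / 5%), precision-weighted averaging,
and factors rescaled to geometric mean 1.  CPM values are counts scaled by
the effective library size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import CountTable, SampleMetadata

__all__ = [
    "NormalizedTable",
    "DifferentialResult",
    "IndicatorResult",
    "HsASVReport",
    "tmm_normalize",
    "nb_lrt_differential",
    "indval",
    "identify_hsasvs",
]


@dataclass(frozen=True)
class NormalizedTable:
    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    cpm: np.ndarray  # taxa x samples, counts per million of effective library
    tmm_factors: np.ndarray  # per-sample, geometric mean 1
    library_sizes: np.ndarray

    @property
    def effective_libsizes(self) -> np.ndarray:
        return self.library_sizes * self.tmm_factors

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cpm, index=list(self.taxon_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class DifferentialResult:
    """Per-taxon NB likelihood-ratio test results (NaN rows = untested)."""

    table: pd.DataFrame  # index taxon_id; log2fc, lrt, p, q, tested

    def significant(self, q_threshold: float = 0.05) -> pd.Index:
        t = self.table
        return t.index[(t["tested"]) & (t["q"] < q_threshold)]


@dataclass(frozen=True)
class IndicatorResult:
    """Per-taxon IndVal statistics: A, B per group, IndVal, best group, p."""

    table: pd.DataFrame  # index taxon_id; columns A_<g>, B_<g>, indval, group, p
    n_permutations: int

    def significant(self, p_threshold: float = 0.05) -> pd.Index:
        return self.table.index[self.table["p"] < p_threshold]


@dataclass(frozen=True)
class HsASVReport:
    table: pd.DataFrame  # log2fc, q, indval, indval_p, hs_flag, assigned_group

    @property
    def hsasvs(self) -> pd.Index:
        return self.table.index[self.table["hs_flag"]]


# ---------------------------------------------------------------------------
# TMM / CPM
# ---------------------------------------------------------------------------

def _tmm_factor_pair(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2**)."""
    shared = (obs > 0) & (ref > 0)
    if not shared.any():
        warnings.warn("library shares no nonzero taxa with reference; factor = 1")
        return 1.0
    po = obs[shared] / lib_obs
    pr = ref[shared] / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic (delta-method) variance of M; weights are its reciprocal
    w = (
        (lib_obs - obs[shared]) / (lib_obs * obs[shared])
        + (lib_ref - ref[shared]) / (lib_ref * ref[shared])
    )
    if len(m) == 1:
        return float(2 ** m[0])
    mlo, mhi = np.quantile(m, [trim_m, 1 - trim_m])
    alo, ahi = np.quantile(a, [trim_a, 1 - trim_a])
    keep = (m >= mlo) & (m <= mhi) & (a >= alo) & (a <= ahi)
    if not keep.any():
        keep = np.ones_like(keep)
    f = (m[keep] / w[keep]).sum() / (1.0 / w[keep]).sum()
    return float(2**f)


def tmm_normalize(
    t: CountTable, trim_M: float = 0.30, trim_A: float = 0.05
) -> NormalizedTable:
    """Trimmed-mean-of-M normalisation factors and CPM matrix.

    The reference sample is the library whose 75th-percentile count fraction
    is closest to the mean of those fractions across libraries.  Factors are
    rescaled to geometric mean 1; ``CPM_ij = counts_ij / (libsize_j *
    factor_j) * 1e6``.
    """
    if t.n_samples < 2:
        raise ValueError("TMM needs >= 2 samples")
    counts = t.counts.astype(float)
    libs = counts.sum(axis=0)
    q75 = np.array(
        [np.quantile(counts[counts[:, j] > 0, j], 0.75) for j in range(t.n_samples)]
    ) / libs
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = counts[:, ref_idx]
    factors = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_factor_pair(
                counts[:, j], ref, libs[j], libs[ref_idx], trim_M, trim_A
            )
            for j in range(t.n_samples)
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    cpm = counts / (libs * factors) * 1e6
    return NormalizedTable(
        taxon_ids=t.taxon_ids,
        sample_ids=t.sample_ids,
        cpm=cpm,
        tmm_factors=factors,
        library_sizes=libs,
    )


# ---------------------------------------------------------------------------
# NB likelihood-ratio differential abundance
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rowwise NB log-likelihood (phi = dispersion; variance mu + phi mu^2)."""
    phi = np.maximum(phi, 1e-10)[:, None]
    r = 1.0 / phi
    return (
        stats.nbinom.logpmf(y, r, r / (r + np.maximum(mu, 1e-300)))
    ).sum(axis=1)


def _fit_nb_means(
    y: np.ndarray, offs: np.ndarray, phi: np.ndarray, n_iter: int = 50
) -> np.ndarray:
    """Vectorised Newton fit of a single intercept per taxon on the log link.

    ``mu_ij = exp(beta_i + offs_j)``.  Returns the fitted mean matrix.
    Score and information for NB with log link: sum (y-mu)/(1+phi mu) and
    sum mu/(1+phi mu).
    """
    with np.errstate(divide="ignore"):
        beta = np.log(
            np.maximum(y.sum(axis=1), 0.5) / np.exp(offs).sum()
        )
    phi_col = phi[:, None]
    for _ in range(n_iter):
        mu = np.exp(beta[:, None] + offs[None, :])
        denom = 1.0 + phi_col * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5, 5)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.exp(beta[:, None] + offs[None, :])


def _shrunk_dispersion(
    y: np.ndarray,
    offs: np.ndarray,
    group_masks: list[np.ndarray],
    prior_df: float,
    n_bins: int = 10,
) -> np.ndarray:
    """Empirical-Bayes dispersion: per-taxon moments shrunk toward a trend.

    Per taxon, the dispersion solves the Pearson moment (estimating)
    equation ``sum (y - mu)^2 / (mu + phi mu^2) = n - p`` — the Pearson
    chi-square statistic matched to its residual degrees of freedom, the
    classic pseudo-likelihood moment estimator for the negative binomial.
    Means are refitted under the current dispersion for three rounds.  The
    variance weighting matters on heavy-tailed count rows, where the
    unweighted moment ratio badly underestimates the dispersion.  Taxa
    underdispersed even at ``phi = 0`` keep their (negative) unweighted
    moment value.  Raw estimates are averaged within mean-abundance bins to
    form the trended dispersion, and each taxon is shrunk toward its bin
    trend with ``prior_df`` pseudo-samples of prior weight:
    ``phi = (df * phi_hat + prior_df * trend) / (df + prior_df)``.
    """
    n_taxa, n_samples = y.shape
    n_params = len(group_masks)
    resid_df = n_samples - n_params
    if resid_df <= 0:
        raise ValueError("not enough samples to estimate dispersion")

    def pearson(mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
        v = mu + phi[:, None] * mu**2
        return ((y - mu) ** 2 / np.maximum(v, 1e-300)).sum(axis=1)

    phi_raw = np.zeros(n_taxa)
    for _ in range(3):
        mu = np.empty_like(y)
        phi_fit = np.maximum(phi_raw, 0.0)
        for mask in group_masks:
            mu[:, mask] = _fit_nb_means(y[:, mask], offs[mask], phi_fit, n_iter=25)
        # Pearson X^2(phi) is monotone decreasing in phi; solve X^2 = df by
        # bisection per taxon.  Taxa underdispersed even at phi = 0 keep their
        # (negative) unweighted moment value so the bin trend stays unbiased.
        under = pearson(mu, np.zeros(n_taxa)) <= resid_df
        lo = np.full(n_taxa, 1e-8)
        hi = np.full(n_taxa, 100.0)
        for _ in range(50):
            mid = np.sqrt(lo * hi)
            too_big = pearson(mu, mid) > resid_df
            lo = np.where(too_big, mid, lo)
            hi = np.where(too_big, hi, mid)
        phi_raw = np.sqrt(lo * hi)
        if under.any():
            num = ((y - mu) ** 2 - mu).sum(axis=1)
            den = np.maximum((mu**2).sum(axis=1), 1e-300)
            phi_raw[under] = (num / den * (n_samples / resid_df))[under]

    mean_ab = (y / np.exp(offs)).mean(axis=1)
    order = np.argsort(mean_ab)
    bins = np.array_split(order, max(1, min(n_bins, n_taxa // 20 or 1)))
    trend = np.empty(n_taxa)
    for idx in bins:
        trend[idx] = phi_raw[idx].mean()
    trend = np.maximum(trend, 0.0)

    shrunk = (resid_df * phi_raw + prior_df * trend) / (resid_df + prior_df)
    return np.maximum(shrunk, 1e-8)


def nb_lrt_differential(
    t: CountTable,
    groups: SampleMetadata,
    norm: NormalizedTable | None = None,
    prior_df: float = 10.0,
) -> DifferentialResult:
    """Negative-binomial likelihood-ratio test of the health-group effect.

    Per taxon, an NB model with log link and effective-library offsets is
    fitted under the null (common abundance) and the full model (one mean
    per group); the likelihood ratio is referred to chi-square(1), and
    p-values are BH-adjusted across tested taxa.  Dispersions are per-taxon
    method-of-moments estimates (df-corrected) moderated toward an
    abundance-binned trend with ``prior_df`` pseudo-samples of prior weight
    (empirical-Bayes shrinkage in the edgeR spirit).

    Taxa that are all-zero are excluded and marked untested.
    """
    if norm is None:
        norm = tmm_normalize(t)
    labels = groups.labels_for(t.sample_ids)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("differential test requires exactly 2 groups")
    for g in uniq:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g} has < 2 samples")

    y = t.counts.astype(float)
    tested = y.sum(axis=1) > 0
    offs = np.log(norm.effective_libsizes)

    yt = y[tested]
    n_t = yt.shape[0]
    mask1 = labels == uniq[0]
    mask2 = ~mask1

    # --- moderated dispersion, then fit means and form the LRT.
    # Moments are taken around the null (common-mean) fit: any between-group
    # difference a taxon shows is charged to its dispersion, so chance group
    # splits of heavy-tailed null taxa inflate phi rather than the LRT.
    all_mask = np.ones(len(labels), dtype=bool)
    phi = _shrunk_dispersion(yt, offs, [all_mask], prior_df)
    mu_full = np.empty_like(yt)
    mu_full[:, mask1] = _fit_nb_means(yt[:, mask1], offs[mask1], phi)
    mu_full[:, mask2] = _fit_nb_means(yt[:, mask2], offs[mask2], phi)
    mu_null = _fit_nb_means(yt, offs, phi)
    ll_full = _nb_loglik(yt, mu_full, phi)
    ll_null = _nb_loglik(yt, mu_null, phi)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)

    # log2 fold change NL-ish (second group) over first, on offset scale
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = (mu_full[:, mask1] / np.exp(offs[mask1])).mean(axis=1)
        m2 = (mu_full[:, mask2] / np.exp(offs[mask2])).mean(axis=1)
        log2fc = np.log2((m2 + 1e-12) / (m1 + 1e-12))

    q = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        index=list(t.taxon_ids),
        data={
            "log2fc": np.nan,
            "lrt": np.nan,
            "p": np.nan,
            "q": np.nan,
            "tested": tested,
        },
    )
    table.loc[tested, "log2fc"] = log2fc
    table.loc[tested, "lrt"] = lrt
    table.loc[tested, "p"] = p
    table.loc[tested, "q"] = q
    table.attrs["groups"] = (str(uniq[0]), str(uniq[1]))
    return DifferentialResult(table=table)


# ---------------------------------------------------------------------------
# IndVal
# ---------------------------------------------------------------------------

def indval(
    t: CountTable,
    groups: SampleMetadata,
    n_perm: int = 9999,
    seed: int = 0,
) -> IndicatorResult:
    """Group-size-corrected indicator value analysis (IndVal.g).

    Specificity ``A_g`` is the group mean of within-sample relative counts
    divided by the sum of those group means; fidelity ``B_g`` is the
    occurrence fraction within the group.  The test statistic is the
    max-over-groups ``sqrt(A_g B_g)``; its null distribution comes from
    label permutations (add-one p-value convention).
    """
    labels = groups.labels_for(t.sample_ids)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("IndVal requires >= 2 groups")
    rel = t.counts / t.counts.sum(axis=0, keepdims=True)
    present = (t.counts > 0).astype(float)
    nonzero = t.counts.sum(axis=1) > 0

    masks = np.stack([(labels == g).astype(float) for g in uniq])  # G x S
    sizes = masks.sum(axis=1)

    def stat_components(mask_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        means = rel @ mask_mat.T / sizes  # taxa x G
        a = means / np.maximum(means.sum(axis=1, keepdims=True), 1e-300)
        b = present @ mask_mat.T / sizes
        return a, b

    a_obs, b_obs = stat_components(masks)
    iv = np.sqrt(a_obs * b_obs)
    best = np.argmax(iv, axis=1)
    obs = iv[np.arange(len(iv)), best]

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(obs))
    chunk = 256
    done = 0
    while done < n_perm:
        b_n = min(chunk, n_perm - done)
        # stack permuted indicator matrices for one GEMM per component
        perm_masks = np.empty((b_n * len(uniq), t.n_samples))
        for r in range(b_n):
            pl = rng.permutation(labels)
            for gi, g in enumerate(uniq):
                perm_masks[r * len(uniq) + gi] = pl == g
        sizes_rep = np.tile(sizes, b_n)
        means = rel @ perm_masks.T / sizes_rep
        occ = present @ perm_masks.T / sizes_rep
        means = means.reshape(t.n_taxa, b_n, len(uniq))
        occ = occ.reshape(t.n_taxa, b_n, len(uniq))
        a = means / np.maximum(means.sum(axis=2, keepdims=True), 1e-300)
        stat = np.sqrt(a * occ).max(axis=2)  # taxa x b_n
        hits += (stat >= obs[:, None] - 1e-12).sum(axis=1)
        done += b_n
    p = (hits + 1) / (n_perm + 1)

    data = {"indval": obs, "group": [str(uniq[i]) for i in best], "p": p}
    for gi, g in enumerate(uniq):
        data[f"A_{g}"] = a_obs[:, gi]
        data[f"B_{g}"] = b_obs[:, gi]
    table = pd.DataFrame(index=list(t.taxon_ids), data=data)
    table = table[nonzero]
    return IndicatorResult(table=table, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# hsASV intersection
# ---------------------------------------------------------------------------

def identify_hsasvs(
    d: DifferentialResult,
    i: IndicatorResult,
    q_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> HsASVReport:
    """Health-sensitive ASVs: significant by *both* screens.

    ``hs_flag = (q < q_threshold) and (indicator p < p_threshold)``.  The
    assigned group is the indicator's best group; when it disagrees with the
    sign of the fold change the taxon is flagged discordant (assigned group
    ``"discordant"``) but keeps its hs_flag.
    """
    dt = d.table
    it = i.table
    idx = dt.index.intersection(it.index)
    g1, g2 = dt.attrs.get("groups", ("HL", "NL"))
    out = pd.DataFrame(index=idx)
    out["log2fc"] = dt.loc[idx, "log2fc"]
    out["q"] = dt.loc[idx, "q"]
    out["indval"] = it.loc[idx, "indval"]
    out["indval_p"] = it.loc[idx, "p"]
    out["indicator_group"] = it.loc[idx, "group"]
    diff_sig = dt.loc[idx, "tested"] & (dt.loc[idx, "q"] < q_threshold)
    ind_sig = it.loc[idx, "p"] < p_threshold
    out["hs_flag"] = (diff_sig & ind_sig).to_numpy()

    # enrichment direction from the fold change: positive log2fc favours g2
    fc_group = np.where(out["log2fc"] > 0, g2, g1)
    assigned = np.where(
        out["indicator_group"].to_numpy() == fc_group, fc_group, "discordant"
    )
    out["assigned_group"] = np.where(out["hs_flag"], assigned, "")
    return HsASVReport(table=out)
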