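"""Stochastic-vs-deterministic community assembly inference.

Three complementary lines of evidence:

* **Levins' niche breadth** ``B_j = 1 / sum_i P_ij^2`` with ``P_ij`` the
  proportion of taxon j's reads found in community i; a perfect generalist
  spread evenly over N communities has B = N, a single-site specialist has
  B = 1.  Community breadth is the mean B over taxa present in a sample.

* **Sloan's neutral community model (NCM)** relating a taxon's occurrence
  frequency across local communities to its mean relative abundance through
  a migration rate ``m``: ``freq(p) = 1 - BetaCDF(d; N m p, N m (1 - p))``
  with ``N`` the mean library size and ``d`` the detection limit (1/N).
  The fit is bounded 1-D least squares over log m with a multi-start grid;
  a 95% Wilson binomial envelope around the fitted curve partitions taxa
  into above / within / below the neutral prediction, and a bootstrap over
  taxa gives the confidence interval for m.

* **C-score null models**: the checkerboard score (mean checkerboard units
  over taxon pairs of the presence/absence matrix) compared with a
  sequential-swap null distribution that preserves row and column sums; the
  standardised effect size SES = (observed - null mean) / null sd, with
  SES > 2 indicating segregation and SES < -2 aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .tables import CountTable, SampleMetadata, group_contrast_test

__all__ = [
    "NicheBreadthResult",
    "NCMFit",
    "CScoreResult",
    "levins_breadth",
    "ncm_fit",
    "c_score",
    "sequential_swap_null",
]


# ---------------------------------------------------------------------------
# Levins' niche breadth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NicheBreadthResult:
    per_taxon: pd.Series  # B_j indexed by taxon
    per_sample: pd.Series  # community breadth indexed by sample
    contrast: tuple[float, float] | None  # (Wilcoxon statistic, p) if groups given


def levins_breadth(
    t: CountTable,
    groups: SampleMetadata | None = None,
    use_relative: bool = False,
) -> NicheBreadthResult:
    """Levins' B per taxon and mean community breadth per sample.

    ``P_ij`` is taxon j's count in sample i divided by its total over
    samples (so each taxon's proportions sum to 1 and B is scale-invariant
    per taxon).  With ``use_relative=True`` counts are first converted to
    within-sample relative abundances.  Community breadth averages B over
    taxa with nonzero count in the sample; with metadata, community breadths
    are contrasted between groups by the Wilcoxon rank-sum test.
    """
    x = t.counts.astype(float)
    if use_relative:
        x = x / x.sum(axis=0, keepdims=True)
    totals = x.sum(axis=1)
    keep = totals > 0
    p = x[keep] / totals[keep, None]
    b = 1.0 / (p**2).sum(axis=1)
    taxa = [tid for tid, k in zip(t.taxon_ids, keep) if k]
    per_taxon = pd.Series(b, index=taxa, name="B")

    present = t.counts[keep] > 0
    community = np.array(
        [b[present[:, j]].mean() if present[:, j].any() else np.nan
         for j in range(t.n_samples)]
    )
    per_sample = pd.Series(community, index=list(t.sample_ids), name="community_breadth")

    contrast = None
    if groups is not None:
        split = groups.split(t.sample_ids)
        (g1, s1), (g2, s2) = sorted(split.items())
        contrast = group_contrast_test(
            per_sample[s1].dropna(), per_sample[s2].dropna(), method="wilcoxon"
        )
    return NicheBreadthResult(per_taxon=per_taxon, per_sample=per_sample, contrast=contrast)


# ---------------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NCMFit:
    m: float
    N_comm: float
    R2: float
    d: float
    m_ci: tuple[float, float] | None
    per_taxon: pd.DataFrame  # p, freq, predicted, lower, upper, partition
    n_bootstrap: int

    @property
    def partition_counts(self) -> dict[str, int]:
        return self.per_taxon["partition"].value_counts().to_dict()


def _ncm_predict(p: np.ndarray, m: float, n_comm: float, d: float) -> np.ndarray:
    a = np.maximum(n_comm * m * p, 1e-12)
    b = np.maximum(n_comm * m * (1.0 - p), 1e-12)
    return stats.beta.sf(d, a, b)


def _fit_m(
    p: np.ndarray, freq: np.ndarray, n_comm: float, d: float
) -> tuple[float, float]:
    """Least-squares m on a log grid multi-start; returns (m, sse)."""

    def sse(log_m: float) -> float:
        resid = freq - _ncm_predict(p, float(np.exp(log_m)), n_comm, d)
        return float((resid**2).sum())

    best_m, best_sse = None, np.inf
    grid = np.log(np.logspace(-4, 0, 9))
    for lo, hi in zip(grid[:-1], grid[1:]):
        res = optimize.minimize_scalar(
            sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
        )
        if res.fun < best_sse:
            best_sse = float(res.fun)
            best_m = float(np.exp(res.x))
    if best_m is None or not np.isfinite(best_sse):
        raise RuntimeError("NCM fit failed to converge on the multi-start grid")
    return best_m, best_sse


def ncm_fit(
    t: CountTable,
    n_bootstrap: int = 1000,
    seed: int = 0,
    detection_limit: float | None = None,
) -> NCMFit:
    """Fit Sloan's neutral model to occurrence frequency vs mean abundance.

    ``p_j`` is the mean within-sample relative abundance of taxon j,
    ``freq_j`` its occurrence fraction over samples, ``N`` the mean library
    size and ``d`` the detection limit (default 1/N).  The 95% envelope uses
    Wilson binomial intervals for the predicted frequency at n = number of
    samples; taxa are classified above/within/below it.  The m confidence
    interval bootstraps taxa (the observations of the fitted curve) with
    replacement.
    """
    counts = t.counts.astype(float)
    n_samples = t.n_samples
    libs = counts.sum(axis=0)
    n_comm = float(libs.mean())
    d = float(detection_limit) if detection_limit is not None else 1.0 / n_comm

    rel = counts / libs
    p = rel.mean(axis=1)
    freq = (counts > 0).mean(axis=1)
    keep = (p > 0) & (freq > 0)
    p, freq = p[keep], freq[keep]
    taxa = [tid for tid, k in zip(t.taxon_ids, keep) if k]
    if np.allclose(freq, 1.0):
        raise ValueError("all taxa occur in every sample: no frequency gradient to fit")

    m_hat, sse = _fit_m(p, freq, n_comm, d)
    pred = _ncm_predict(p, m_hat, n_comm, d)
    ss_tot = float(((freq - freq.mean()) ** 2).sum())
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else np.nan

    lower, upper = proportion_confint(pred * n_samples, n_samples, alpha=0.05, method="wilson")
    partition = np.where(freq > upper, "above", np.where(freq < lower, "below", "within"))

    m_ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_bootstrap)
        n_pts = len(p)
        for b in range(n_bootstrap):
            idx = rng.integers(0, n_pts, size=n_pts)
            try:
                boots[b], _ = _fit_m(p[idx], freq[idx], n_comm, d)
            except RuntimeError:
                boots[b] = np.nan
        ok = boots[np.isfinite(boots)]
        if len(ok):
            m_ci = (float(np.quantile(ok, 0.025)), float(np.quantile(ok, 0.975)))

    per_taxon = pd.DataFrame(
        {
            "p": p,
            "freq": freq,
            "predicted": pred,
            "lower": lower,
            "upper": upper,
            "partition": partition,
        },
        index=taxa,
    )
    return NCMFit(
        m=m_hat, N_comm=n_comm, R2=float(r2), d=d, m_ci=m_ci,
        per_taxon=per_taxon, n_bootstrap=n_bootstrap,
    )


# ---------------------------------------------------------------------------
# C-score and sequential-swap null model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CScoreResult:
    c_obs: float
    null_mean: float
    null_sd: float
    ses: float | None
    n_sim: int
    burn_in: int


def c_score(pa: np.ndarray) -> float:
    """Checkerboard score: mean checkerboard units over unordered taxon pairs.

    For taxa i, j with row totals R_i, R_j and S_ij shared presences,
    ``CU_ij = (R_i - S_ij)(R_j - S_ij)``.
    """
    a = (np.asarray(pa) > 0).astype(np.int64)
    n_taxa = a.shape[0]
    if n_taxa < 2:
        raise ValueError("C-score needs >= 2 taxa")
    r = a.sum(axis=1)
    s = a @ a.T
    cu = (r[:, None] - s) * (r[None, :] - s)
    iu = np.triu_indices(n_taxa, k=1)
    return float(cu[iu].mean())


def _pair_sum(r: np.ndarray, s: np.ndarray) -> float:
    cu = (r[:, None] - s) * (r[None, :] - s)
    return float(np.triu(cu, k=1).sum())


def _rows_contrib(r: np.ndarray, s: np.ndarray, i: int, j: int) -> float:
    """Sum of checkerboard units over all pairs involving rows i or j."""
    ci = (r[i] - s[i]) * (r - s[i])
    ci[i] = 0
    cj = (r[j] - s[j]) * (r - s[j])
    cj[j] = 0
    cu_ij = (r[i] - s[i, j]) * (r[j] - s[i, j])
    return float(ci.sum() + cj.sum() - cu_ij)


def sequential_swap_null(
    pa: np.ndarray,
    n_sim: int = 30_000,
    burn_in: int = 500,
    seed: int = 0,
    return_null: bool = False,
) -> CScoreResult | tuple[CScoreResult, np.ndarray]:
    """Sequential-swap null distribution of the C-score.

    Starting from the observed matrix, 2x2 checkerboard submatrices at
    random row/column pairs are swapped; row and column sums are invariant.
    After ``burn_in`` attempted swaps the C-score is recorded once per
    attempted swap for ``n_sim`` steps.  SES = (c_obs - mean) / sd of the
    recorded values; SES is None (with sd reported) when the null is
    degenerate.
    """
    a = (np.asarray(pa) > 0).astype(np.int64).copy()
    n_taxa, n_samp = a.shape
    if n_taxa < 2 or n_samp < 2:
        raise ValueError("need >= 2 taxa and >= 2 samples")
    rng = np.random.default_rng(seed)
    r = a.sum(axis=1)
    s = a @ a.T
    n_pairs = n_taxa * (n_taxa - 1) // 2
    total = _pair_sum(r, s)
    c_obs = total / n_pairs

    rows = rng.integers(0, n_taxa, size=2 * (burn_in + n_sim))
    rows2 = rng.integers(0, n_taxa, size=2 * (burn_in + n_sim))
    cols = rng.integers(0, n_samp, size=2 * (burn_in + n_sim))
    cols2 = rng.integers(0, n_samp, size=2 * (burn_in + n_sim))

    null = np.empty(n_sim)
    step = 0
    for t_idx in range(burn_in + n_sim):
        i, j = rows[t_idx], rows2[t_idx]
        x, y = cols[t_idx], cols2[t_idx]
        if i != j and x != y:
            aix, aiy, ajx, ajy = a[i, x], a[i, y], a[j, x], a[j, y]
            checker = (aix == 1 and ajy == 1 and aiy == 0 and ajx == 0) or (
                aix == 0 and ajy == 0 and aiy == 1 and ajx == 1
            )
            if checker:
                # flip the 2x2 submatrix; row/column sums are preserved and
                # only pairs involving rows i or j change their CU
                before = _rows_contrib(r, s, i, j)
                a[i, x], a[i, y] = aiy, aix
                a[j, x], a[j, y] = ajy, ajx
                s[i] = a @ a[i]
                s[j] = a @ a[j]
                s[:, i] = s[i]
                s[:, j] = s[j]
                total += _rows_contrib(r, s, i, j) - before
        if t_idx >= burn_in:
            null[t_idx - burn_in] = total / n_pairs
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    ses = None if null_sd == 0 else float((c_obs - null_mean) / null_sd)
    result = CScoreResult(
        c_obs=c_obs, null_mean=null_mean, null_sd=null_sd,
        ses=ses, n_sim=n_sim, burn_in=burn_in,
    )
    return (result, null) if return_null else result
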