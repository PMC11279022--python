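"""Synthetic ASV tables with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a log-normal metacommunity species-abundance distribution, local
communities assembled neutrally in the sense of Sloan's model (per-taxon
beta-distributed local relative abundances governed by a migration rate
``m``, then multinomial read sampling), a second group perturbed by
deterministic selection and injected differential taxa, and blocks of taxa
whose abundances covary through shared latent log-normal factors.

Because the true migration rate, the true differential set and the true
block memberships are known, every downstream stage — differential
abundance, indicator analysis, network modules, neutral-model fitting —
has a recoverable answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .tables import CountTable, SampleMetadata

__all__ = ["SyntheticSpec", "GroundTruth", "sample_neutral_community", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of one synthetic two-group dataset.

    Defaults mirror the study design being emulated: 2 groups x 20 leaf
    samples, library sizes spread over roughly 5,000-75,000 reads, several
    hundred taxa per kingdom, a neutral healthy-leaf (HL) baseline with
    migration rate ``migration_m``, and a non-healthy-leaf (NL) group
    derived from the *same* metacommunity so that between-group structure
    comes only from the injected effects.

    Parameters
    ----------
    n_taxa:
        Metacommunity richness.
    n_samples_per_group:
        Samples in each of HL and NL.
    reads_per_sample:
        Either a fixed library size or an inclusive ``(lo, hi)`` range from
        which per-sample depths are drawn log-uniformly.
    migration_m:
        Sloan migration rate of the neutral baseline, in (0, 1].
    metacommunity_sigma:
        Log-normal sigma of the metacommunity abundance distribution.
    n_differential, fold_change:
        Number of taxa whose NL metacommunity abundance is multiplied by
        ``fold_change`` (half up, half down) — the ground-truth
        health-sensitive set.
    n_corr_blocks, block_size, block_rho, block_sigma:
        Correlated taxon blocks induced by shared latent log-normal factors
        across samples; ``block_rho`` is the within-block latent correlation
        and ``block_sigma`` the log-scale sd of the factor (0.5 ~ a typical
        1.6-fold co-fluctuation).
    selection_strength:
        Intensity of selection on the NL group: the standard deviation of
        log fitness multipliers, split between a fixed per-taxon component
        (a consistent compositional shift) and a per-sample component
        (environmental-filtering heterogeneity between leaves).  0 disables
        both.
    seed:
        Root seed; generation is fully deterministic given the spec.
    """

    n_taxa: int = 500
    n_samples_per_group: int = 20
    reads_per_sample: int | tuple[int, int] = (5000, 75000)
    migration_m: float = 0.1
    metacommunity_sigma: float = 2.0
    n_differential: int = 20
    fold_change: float = 4.0
    n_corr_blocks: int = 4
    block_size: int = 10
    block_rho: float = 0.7
    block_sigma: float = 0.5
    selection_strength: float = 0.0
    kingdom: Literal["bacteria", "fungi", "unspecified"] = "bacteria"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_differential > self.n_taxa:
            raise ValueError("n_differential exceeds n_taxa")
        if self.n_corr_blocks * self.block_size > self.n_taxa:
            raise ValueError("correlated blocks exceed n_taxa")
        if not 0 < self.migration_m <= 1:
            raise ValueError("migration_m must be in (0, 1]")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if self.fold_change <= 1:
            raise ValueError("fold_change must be > 1")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually injected, keyed by emitted taxon ids."""

    true_differential: dict[str, str]  # taxon_id -> "up_NL" | "down_NL"
    true_blocks: dict[str, int]  # taxon_id -> block index
    true_m: float


def sample_neutral_community(
    meta_p: np.ndarray,
    n_reads: int,
    m: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw one local community under the Sloan neutral model.

    Each taxon's local relative abundance is Beta(N m p, N m (1 - p)) with
    N = ``n_reads``; the vector is renormalised and ``n_reads`` reads are
    drawn multinomially.  Large ``m`` pins local abundances to the
    metacommunity; small ``m`` lets ecological drift dominate, producing the
    occurrence-frequency/abundance relationship the neutral-model fit
    recovers.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    meta_p = np.asarray(meta_p, dtype=float)
    if not np.isclose(meta_p.sum(), 1.0):
        raise ValueError("meta_p must sum to 1")
    if n_reads <= 0 or not 0 < m <= 1:
        raise ValueError("need n_reads > 0 and 0 < m <= 1")
    if (meta_p >= 1.0).any():
        # degenerate single-taxon metacommunity
        out = np.zeros_like(meta_p, dtype=np.int64)
        out[int(np.argmax(meta_p))] = n_reads
        return out
    nm = n_reads * m
    local = rng.beta(np.maximum(nm * meta_p, 1e-12), np.maximum(nm * (1 - meta_p), 1e-12))
    total = local.sum()
    if total == 0:  # pathological underflow; fall back to metacommunity
        local = meta_p.copy()
        total = 1.0
    return rng.multinomial(n_reads, local / total)


def _library_sizes(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.reads_per_sample, (int, np.integer)):
        return np.full(n, int(spec.reads_per_sample), dtype=np.int64)
    lo, hi = spec.reads_per_sample
    # log-uniform depths: sequencing depth varies multiplicatively across libraries
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(np.int64)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[CountTable, SampleMetadata, GroundTruth]:
    """Generate a two-group ASV table plus metadata and ground truth.

    HL samples are plain neutral draws from the metacommunity.  NL samples
    are drawn from a perturbed metacommunity: differential taxa scaled by
    ``fold_change`` (half up, half down), then per-taxon fitness multipliers
    with log-sd ``selection_strength`` (a fixed component shared by every NL
    sample — a consistent selective shift — plus a per-sample component
    modelling filtering that varies between leaves; the latter is what
    weakens the neutral occurrence-frequency signature).  Correlated blocks
    act on both groups through per-sample shared latent factors, so block
    structure is a within-kingdom co-occurrence signal, not a group
    contrast.
    """
    root = np.random.default_rng(spec.seed)
    n = spec.n_taxa

    meta = root.lognormal(mean=0.0, sigma=spec.metacommunity_sigma, size=n)
    meta /= meta.sum()

    # ground-truth assignments drawn once from the root stream; differential
    # taxa come from the upper half of the metacommunity abundance
    # distribution (a fold change below the detection limit is not a
    # recoverable ground truth), and correlated blocks are seeded with the
    # differential taxa first so that network modules rich in
    # health-sensitive taxa are the ground-truth sensitive modules
    candidates = np.flatnonzero(meta >= np.median(meta))
    diff_idx = root.choice(candidates, size=spec.n_differential, replace=False)
    rest = np.setdiff1d(np.arange(n), diff_idx)
    pool = np.concatenate([diff_idx, root.permutation(rest)])
    block_of = np.full(n, -1, dtype=int)
    for b in range(spec.n_corr_blocks):
        members = pool[b * spec.block_size: (b + 1) * spec.block_size]
        block_of[members] = b

    up = diff_idx[: len(diff_idx) // 2]
    down = diff_idx[len(diff_idx) // 2:]
    meta_nl = meta.copy()
    meta_nl[up] *= spec.fold_change
    meta_nl[down] /= spec.fold_change

    # fixed selection component: one fitness vector shared by all NL samples
    sel = spec.selection_strength
    if sel > 0:
        fitness = root.lognormal(0.0, sel / np.sqrt(2), size=n)
        meta_nl = meta_nl * fitness
    meta_nl /= meta_nl.sum()

    n_per = spec.n_samples_per_group
    libs = _library_sizes(spec, 2 * n_per, root)

    sigma_block = spec.block_sigma
    rho = spec.block_rho

    counts = np.zeros((n, 2 * n_per), dtype=np.int64)
    for j in range(2 * n_per):
        # per-sample substream keyed by index: draws are order-independent
        rng_j = np.random.default_rng([spec.seed, j])
        base = meta if j < n_per else meta_nl
        p = base.copy()
        if spec.n_corr_blocks > 0:
            shared = rng_j.standard_normal(spec.n_corr_blocks)
            noise = rng_j.standard_normal(n)
            z = np.zeros(n)
            in_block = block_of >= 0
            z[in_block] = (
                np.sqrt(rho) * shared[block_of[in_block]]
                + np.sqrt(1 - rho) * noise[in_block]
            )
            p = p * np.exp(sigma_block * z)
            p /= p.sum()
        if j >= n_per and sel > 0:
            # per-leaf filtering: fitness varies between NL samples
            p = p * np.exp((sel / np.sqrt(2)) * rng_j.standard_normal(n))
            p /= p.sum()
        counts[:, j] = sample_neutral_community(p, int(libs[j]), spec.migration_m, rng_j)

    taxon_ids = tuple(f"ASV{k + 1:04d}" for k in range(n))
    sample_ids = tuple(
        [f"HL{i + 1:02d}" for i in range(n_per)] + [f"NL{i + 1:02d}" for i in range(n_per)]
    )
    groups = SampleMetadata(
        {s: ("HL" if s.startswith("HL") else "NL") for s in sample_ids}
    )

    # drop taxa never observed (they carry no information downstream)
    seen = counts.sum(axis=1) > 0
    counts = counts[seen]
    kept_ids = tuple(t for t, s in zip(taxon_ids, seen) if s)
    table = CountTable(kept_ids, sample_ids, counts, spec.kingdom)

    truth = GroundTruth(
        true_differential={
            **{taxon_ids[i]: "up_NL" for i in up if seen[i]},
            **{taxon_ids[i]: "down_NL" for i in down if seen[i]},
        },
        true_blocks={
            taxon_ids[i]: int(block_of[i])
            for i in range(n)
            if block_of[i] >= 0 and seen[i]
        },
        true_m=spec.migration_m,
    )
    return table, groups, truth
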