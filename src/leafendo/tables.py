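"""Count-table data model, readers/writers, filtering, and group contrasts.

The universal input downstream is a :class:`CountTable`: an integer matrix of
ASV (amplicon sequence variant) read counts, oriented **taxa x samples**.
Sample metadata maps each sample to one of two leaf-health groups (``HL`` =
healthy leaves, ``NL`` = non-healthy leaves); a taxonomy table stores ranked
lineages for collapsing counts to higher ranks.

Supported on-disk formats are plain TSV (first column taxon_id, header row of
sample ids) and the dense-JSON flavour of the BIOM schema.  Both round-trip
bit-identically for counts and identifier order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountTable",
    "SampleMetadata",
    "TaxonomyTable",
    "CountTableFormatError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "prevalence_filter",
    "relative_abundance_by_rank",
    "group_contrast_test",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

GROUPS = ("HL", "NL")


class CountTableFormatError(ValueError):
    """Raised when an input table violates the count-table contract."""


@dataclass(frozen=True)
class CountTable:
    """Taxa x samples integer count matrix with identifiers.

    Parameters
    ----------
    taxon_ids, sample_ids:
        Ordered, unique identifiers for rows (taxa) and columns (samples).
    counts:
        Non-negative integer array of shape ``(n_taxa, n_samples)``.
    kingdom:
        Which marker the table comes from; ``"bacteria"`` (16S), ``"fungi"``
        (ITS) or ``"unspecified"``.
    """

    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray
    kingdom: Literal["bacteria", "fungi", "unspecified"] = "unspecified"

    def __post_init__(self) -> None:
        taxa = tuple(str(t) for t in self.taxon_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        if len(set(taxa)) != len(taxa):
            raise CountTableFormatError("duplicate taxon identifiers")
        if len(set(samples)) != len(samples):
            raise CountTableFormatError("duplicate sample identifiers")
        counts = np.asarray(self.counts)
        if counts.shape != (len(taxa), len(samples)):
            raise CountTableFormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(taxa)} taxa x {len(samples)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise CountTableFormatError("non-integer counts")
            counts = np.round(counts).astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise CountTableFormatError("negative counts")
        empty = counts.sum(axis=0) == 0
        if empty.any():
            bad = [samples[i] for i in np.flatnonzero(empty)]
            raise CountTableFormatError(f"samples with zero total reads: {bad}")
        if self.kingdom not in ("bacteria", "fungi", "unspecified"):
            raise CountTableFormatError(f"unknown kingdom {self.kingdom!r}")
        object.__setattr__(self, "taxon_ids", taxa)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "counts", counts)
        self.counts.setflags(write=False)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.taxon_ids), columns=list(self.sample_ids)
        )

    def select_taxa(self, keep: Sequence[str] | np.ndarray) -> "CountTable":
        """Subset to the given taxa (mask or id list), keeping sample set."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {t: i for i, t in enumerate(self.taxon_ids)}
            idx = np.array([pos[t] for t in keep], dtype=int)
        return CountTable(
            tuple(self.taxon_ids[i] for i in idx),
            self.sample_ids,
            self.counts[idx],
            self.kingdom,
        )

    def select_samples(self, keep: Sequence[str]) -> "CountTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in keep], dtype=int)
        return CountTable(
            self.taxon_ids,
            tuple(self.sample_ids[i] for i in idx),
            self.counts[:, idx],
            self.kingdom,
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Mapping of sample id -> group label (``HL`` or ``NL``)."""

    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.groups.values()} - set(GROUPS)
        if bad:
            raise CountTableFormatError(f"unknown group labels: {sorted(bad)}")
        object.__setattr__(self, "groups", dict(self.groups))

    def group_of(self, sample_id: str) -> str:
        try:
            return self.groups[sample_id]
        except KeyError:
            raise CountTableFormatError(f"sample {sample_id!r} has no group") from None

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.group_of(s) for s in sample_ids])

    def split(self, sample_ids: Sequence[str]) -> dict[str, list[str]]:
        """Sample ids per group, in table order; both groups must be non-empty."""
        out: dict[str, list[str]] = {}
        for s in sample_ids:
            out.setdefault(self.group_of(s), []).append(s)
        if len(out) < 2:
            raise CountTableFormatError(
                "two-group contrast requires both groups non-empty; "
                f"found only {sorted(out)}"
            )
        return out


@dataclass(frozen=True)
class TaxonomyTable:
    """ASV -> ranked lineage.  Missing ranks resolve to ``"unclassified"``."""

    lineages: Mapping[str, tuple[str, ...]]
    ranks: tuple[str, ...] = RANKS

    def rank_of(self, taxon_id: str, rank: str) -> str:
        if rank not in self.ranks:
            raise KeyError(f"unknown rank {rank!r}; valid: {self.ranks}")
        i = self.ranks.index(rank)
        lineage = self.lineages.get(taxon_id, ())
        if i < len(lineage) and lineage[i]:
            return lineage[i]
        return "unclassified"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_count_table(
    path: str | Path,
    format: Literal["tsv", "biom-json"] = "tsv",
    kingdom: Literal["bacteria", "fungi", "unspecified"] = "unspecified",
) -> CountTable:
    """Read a count table from TSV or dense BIOM-JSON.

    The TSV dialect is: UTF-8, tab-separated, header row of sample ids, first
    column taxon ids, no quoting.  Only the *dense* JSON flavour of BIOM is
    accepted; sparse matrices are rejected with a clear message.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype={0: str})
        counts = df.to_numpy()
        if counts.dtype == object or not np.issubdtype(counts.dtype, np.number):
            raise CountTableFormatError(f"{path}: non-numeric cells in count table")
        return CountTable(
            tuple(str(i) for i in df.index),
            tuple(str(c) for c in df.columns),
            counts,
            kingdom,
        )
    if format == "biom-json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        if doc.get("matrix_type") != "dense":
            raise CountTableFormatError(
                f"{path}: only dense BIOM-JSON is supported "
                f"(matrix_type={doc.get('matrix_type')!r})"
            )
        taxa = tuple(row["id"] for row in doc["rows"])
        samples = tuple(col["id"] for col in doc["columns"])
        counts = np.asarray(doc["data"])
        king = doc.get("comment", "unspecified")
        if king not in ("bacteria", "fungi", "unspecified"):
            king = kingdom
        return CountTable(taxa, samples, counts, king)
    raise ValueError(f"unknown format {format!r}")


def write_count_table(
    t: CountTable, path: str | Path, format: Literal["tsv", "biom-json"] = "tsv"
) -> Path:
    """Write a count table; lossless round-trip with :func:`read_count_table`."""
    path = Path(path)
    if format == "tsv":
        t.to_dataframe().to_csv(path, sep="\t", index_label="taxon_id")
    elif format == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table",
            "generated_by": "leafendo",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [t.n_taxa, t.n_samples],
            "comment": t.kingdom,
            "rows": [{"id": x, "metadata": None} for x in t.taxon_ids],
            "columns": [{"id": x, "metadata": None} for x in t.sample_ids],
            "data": t.counts.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata TSV with columns ``sample_id`` and ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise CountTableFormatError(
            f"{path}: metadata needs columns sample_id and group"
        )
    if df["sample_id"].duplicated().any():
        raise CountTableFormatError(f"{path}: duplicate sample ids in metadata")
    return SampleMetadata(dict(zip(df["sample_id"], df["group"])))


def write_metadata(m: SampleMetadata, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"sample_id": list(m.groups), "group": list(m.groups.values())}
    ).to_csv(path, sep="\t", index=False)
    return path


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read taxonomy TSV: taxon_id <TAB> semicolon-delimited lineage."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    first, second = df.columns[:2]
    lineages = {
        str(t): tuple(part.strip() for part in str(lin).split(";"))
        for t, lin in zip(df[first], df[second])
    }
    return TaxonomyTable(lineages)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"taxon_id": t, "lineage": ";".join(lin)} for t, lin in tax.lineages.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Filtering and summaries
# ---------------------------------------------------------------------------

def prevalence_filter(
    t: CountTable, min_samples: int, min_reads: int
) -> CountTable:
    """Keep taxa observed with >= ``min_reads`` counts in >= ``min_samples`` samples.

    Mirrors the network prefilter used for leaf endophytes: bacteria are kept
    when present in at least 5 samples with at least 2 reads; fungi in at
    least 3 samples with at least 2 reads.  The sample set is unchanged.
    """
    if min_samples < 1 or min_reads < 1:
        raise ValueError("min_samples and min_reads must be >= 1")
    keep = (t.counts >= min_reads).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            f"prevalence filter (min_samples={min_samples}, min_reads={min_reads}) "
            "removed every taxon"
        )
    return t.select_taxa(keep)


def relative_abundance_by_rank(
    t: CountTable,
    tax: TaxonomyTable,
    rank: str,
    groups: SampleMetadata,
) -> pd.DataFrame:
    """Per-group relative abundance of counts collapsed to a taxonomic rank.

    Returns a DataFrame indexed by rank value with one column per group;
    each column sums to 1.
    """
    labels = [tax.rank_of(tid, rank) for tid in t.taxon_ids]
    df = t.to_dataframe()
    df["_rank"] = labels
    collapsed = df.groupby("_rank").sum()
    out = {}
    for g, samples in groups.split(t.sample_ids).items():
        total = collapsed[samples].to_numpy().sum()
        out[g] = collapsed[samples].sum(axis=1) / total
    return pd.DataFrame(out)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided mid-rank rank-sum p by subset-sum enumeration.

    Doubled mid-ranks are integers, so the null distribution of the rank sum
    of group x (all C(n+m, n) equally likely subsets) is built by dynamic
    programming; the two-sided p aggregates both tails at least as far from
    the null mean as observed.  Valid with ties (mid-ranks enter the
    enumeration as-is).
    """
    n, m = len(x), len(y)
    big_n = n + m
    r2 = np.round(stats.rankdata(np.concatenate([x, y])) * 2).astype(np.int64)
    w_obs = int(r2[:n].sum())
    total = int(r2.sum())
    # dp[k, s] = number of k-subsets of the pooled ranks with doubled-rank sum s
    dp = np.zeros((n + 1, total + 1))
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(n, 0, -1):  # descending: each rank used at most once
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[n]
    mean2 = n * (big_n + 1)  # null mean of the doubled rank sum
    dev = abs(w_obs - mean2)
    sums = np.arange(total + 1)
    p = counts[np.abs(sums - mean2) >= dev - 1e-9].sum() / counts.sum()
    return float(min(1.0, p))


def group_contrast_test(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["t_test", "wilcoxon"] = "t_test",
) -> tuple[float, float]:
    """Two-sided two-group contrast: Welch's t-test or Wilcoxon rank-sum.

    Welch's unequal-variance form is used for the t-test.  The rank-sum test
    uses exact mid-rank enumeration when both groups have <= 20 observations
    (valid with ties) and the mid-rank normal approximation for larger
    samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "t_test":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("t-test needs >= 2 observations per group")
        if np.var(x) == 0 and np.var(y) == 0:
            raise ValueError("zero variance in both groups: t-test degenerate")
        res = stats.ttest_ind(x, y, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if method == "wilcoxon":
        if len(x) < 1 or len(y) < 1:
            raise ValueError("rank-sum test needs >= 1 observation per group")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        if max(len(x), len(y)) <= 20:
            return float(res.statistic), _exact_ranksum_p(x, y)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")
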