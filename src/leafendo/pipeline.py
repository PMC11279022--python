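"""End-to-end orchestration: config, staged execution, and run summaries.

The full workflow on one or two kingdom tables:

    prevalence filter -> alpha/beta diversity (+ group tests)
    -> TMM/CPM -> NB-LRT differential + IndVal -> hsASV intersection
    -> meta network + modules + summaries -> per-group networks + topology
    -> niche breadth + NCM + C-score

Every artifact is a TSV/JSON file with a provenance header (config hash,
seed, package version); runs are deterministic given the seed, which fans
out to per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import c_score, levins_breadth, ncm_fit, sequential_swap_null
from .diversity import alpha_diversity, bray_curtis, nmds, permanova
from .networks import (
    build_network,
    greedy_modules,
    module_summary,
    spearman_matrix,
    topology_metrics,
    write_graphml,
)
from .sensitive import identify_hsasvs, indval, nb_lrt_differential, tmm_normalize
from .tables import (
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    prevalence_filter,
    read_count_table,
    read_metadata,
    read_taxonomy,
)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_run"]

log = logging.getLogger("leafendo")

PREVALENCE_DEFAULTS = {"bacteria": (5, 2), "fungi": (3, 2), "unspecified": (5, 2)}
GROUP_R_DEFAULTS = {"bacteria": 0.8, "fungi": 0.7, "unspecified": 0.8}


@dataclass
class PipelineConfig:
    """All thresholds and permutation counts of the workflow.

    Defaults follow the study conventions: prevalence prefilter >=5
    samples with >=2 reads (bacteria) / >=3 with >=2 (fungi); meta-network
    edges at Spearman r > 0.6, p < 0.001; per-group networks at r > 0.8
    (bacteria) / 0.7 (fungi), p < 0.01; hsASV thresholds q < 0.05 and
    indicator p < 0.05; PERMANOVA 999 permutations, IndVal 9999, sequential
    swap 30,000 with 500 burn-in, NCM bootstrap 1000.
    """

    count_tables: dict[str, str] = field(default_factory=dict)  # kingdom -> path
    metadata: str | None = None
    taxonomy: str | None = None
    output_dir: str = "leafendo_run"
    prevalence: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(PREVALENCE_DEFAULTS)
    )
    meta_r_min: float = 0.6
    meta_p_max: float = 0.001
    group_r_min: dict[str, float] = field(default_factory=lambda: dict(GROUP_R_DEFAULTS))
    group_p_max: float = 0.01
    hs_q_threshold: float = 0.05
    hs_p_threshold: float = 0.05
    # differential testing can run on filtered or full tables; default to
    # the prevalence-filtered table
    differential_on_filtered: bool = True
    n_perm_permanova: int = 999
    n_perm_indval: int = 9999
    n_swap: int = 30_000
    swap_burn_in: int = 500
    n_bootstrap: int = 1000
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True, default=list)

    def config_hash(self) -> str:
        # output_dir is a location, not an analytic parameter: two runs of the
        # same analysis into different directories must hash identically.
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        payload = json.dumps(d, indent=2, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed (< 2**31) derived from the root seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _provenance(cfg: PipelineConfig) -> str:
    return f"# leafendo {__version__} | config {cfg.config_hash()} | seed {cfg.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, **fmt) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(cfg))
        df.to_csv(fh, sep="\t", **fmt)


def _write_json(obj: dict, path: Path, cfg: PipelineConfig) -> None:
    payload = {"_provenance": _provenance(cfg).strip("# \n"), **obj}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(
    cfg: PipelineConfig,
    tables: dict[str, CountTable] | None = None,
    groups: SampleMetadata | None = None,
    taxonomy: TaxonomyTable | None = None,
) -> Path:
    """Run every stage and write one report directory.

    Inputs may be passed in-memory or loaded from the paths in ``cfg``.
    Returns the run directory.  A stage failure raises with the stage name;
    artifacts of completed stages are left in place.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json() + "\n")

    if tables is None:
        tables = {
            k: read_count_table(p, format="tsv", kingdom=k)  # type: ignore[arg-type]
            for k, p in cfg.count_tables.items()
        }
    if groups is None:
        if cfg.metadata is None:
            raise ValueError("no sample metadata given")
        groups = read_metadata(cfg.metadata)
    if taxonomy is None and cfg.taxonomy:
        taxonomy = read_taxonomy(cfg.taxonomy)
    if not tables:
        raise ValueError("no count tables given")

    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                log.info("stage %s", name)
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    log.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Timer()

    summary_rows = []
    for kingdom, table in tables.items():
        kdir = out / kingdom
        kdir.mkdir(exist_ok=True)

        with stage(f"{kingdom}:filter"):
            min_s, min_r = cfg.prevalence.get(kingdom, PREVALENCE_DEFAULTS["unspecified"])
            filtered = prevalence_filter(table, min_s, min_r)

        with stage(f"{kingdom}:alpha_beta"):
            alpha = alpha_diversity(table, groups)
            _write_tsv(alpha.per_sample, kdir / "alpha.tsv", cfg, index_label="sample_id")
            dist = bray_curtis(table)
            _write_tsv(dist, kdir / "bray_curtis.tsv", cfg, index_label="sample_id")
            ord_res = nmds(dist, k=2, seed=cfg.stage_seed(f"{kingdom}:nmds"))
            with open(kdir / "nmds.tsv", "w") as fh:
                fh.write(_provenance(cfg))
                fh.write(f"# stress1 {ord_res.stress:.6f}\n")
                ord_res.coordinates.to_csv(fh, sep="\t", index_label="sample_id")
            perm = permanova(
                dist, groups, cfg.n_perm_permanova, cfg.stage_seed(f"{kingdom}:permanova")
            )
            _write_json(
                {
                    "alpha_contrasts": {
                        k: {"statistic": v[0], "p": v[1]} for k, v in alpha.contrasts.items()
                    },
                    "permanova": dataclasses.asdict(perm),
                    "nmds_stress": ord_res.stress,
                },
                kdir / "beta_tests.json",
                cfg,
            )

        with stage(f"{kingdom}:normalize"):
            diff_table = filtered if cfg.differential_on_filtered else table
            norm = tmm_normalize(diff_table)
            _write_tsv(norm.to_dataframe(), kdir / "cpm.tsv", cfg, index_label="taxon_id")

        with stage(f"{kingdom}:hsasv"):
            diff = nb_lrt_differential(diff_table, groups, norm)
            ind = indval(
                diff_table, groups, cfg.n_perm_indval, cfg.stage_seed(f"{kingdom}:indval")
            )
            hs = identify_hsasvs(diff, ind, cfg.hs_q_threshold, cfg.hs_p_threshold)
            _write_tsv(hs.table, kdir / "hsasv.tsv", cfg, index_label="taxon_id")

        with stage(f"{kingdom}:meta_network"):
            r, pmat = spearman_matrix(norm)
            meta_net = build_network(r, pmat, cfg.meta_r_min, cfg.meta_p_max)
            meta_net = (
                greedy_modules(meta_net) if meta_net.n_edges else meta_net
            )
            _write_tsv(meta_net.edge_list(), kdir / "meta_edges.tsv", cfg, index=False)
            write_graphml(meta_net, kdir / "meta_network.graphml")
            metrics = topology_metrics(meta_net)
            if meta_net.n_edges and meta_net.modules:
                msum = module_summary(meta_net, norm, hs, taxonomy, groups)
                _write_tsv(
                    msum.drop(columns=["class_composition"], errors="ignore"),
                    kdir / "modules.tsv",
                    cfg,
                )
            _write_json({"meta_network": metrics}, kdir / "meta_network.json", cfg)

        group_metrics: dict[str, dict] = {}
        assembly_rows: dict[str, dict] = {}
        for g, samples in groups.split(table.sample_ids).items():
            sub_full = table.select_samples(samples)
            with stage(f"{kingdom}:{g}:network"):
                min_s, min_r = cfg.prevalence.get(
                    kingdom, PREVALENCE_DEFAULTS["unspecified"]
                )
                sub = prevalence_filter(sub_full, min_s, min_r)
                sub_norm = tmm_normalize(sub)
                rg, pg = spearman_matrix(sub_norm)
                net = build_network(
                    rg,
                    pg,
                    cfg.group_r_min.get(kingdom, 0.8),
                    cfg.group_p_max,
                )
                net = greedy_modules(net) if net.n_edges else net
                group_metrics[g] = topology_metrics(net)
                _write_tsv(net.edge_list(), kdir / f"network_{g}.tsv", cfg, index=False)

            with stage(f"{kingdom}:{g}:assembly"):
                nb = levins_breadth(sub_full)
                fit = ncm_fit(
                    sub_full,
                    n_bootstrap=cfg.n_bootstrap,
                    seed=cfg.stage_seed(f"{kingdom}:{g}:ncm"),
                )
                _write_tsv(
                    fit.per_taxon, kdir / f"ncm_{g}.tsv", cfg, index_label="taxon_id"
                )
                pa = (sub_full.counts > 0).astype(int)
                cs = sequential_swap_null(
                    pa,
                    n_sim=cfg.n_swap,
                    burn_in=cfg.swap_burn_in,
                    seed=cfg.stage_seed(f"{kingdom}:{g}:cscore"),
                )
                assembly_rows[g] = {
                    "mean_niche_breadth": float(nb.per_sample.mean()),
                    "ncm_m": fit.m,
                    "ncm_R2": fit.R2,
                    "ncm_m_ci": list(fit.m_ci) if fit.m_ci else None,
                    "cscore": dataclasses.asdict(cs),
                }
                _write_tsv(
                    nb.per_sample.to_frame(),
                    kdir / f"niche_breadth_{g}.tsv",
                    cfg,
                    index_label="sample_id",
                )

        _write_json(
            {"group_networks": group_metrics, "assembly": assembly_rows},
            kdir / "group_results.json",
            cfg,
        )
        metrics_rows = [{"network": "meta", **metrics}] + [
            {"network": g, **m} for g, m in sorted(group_metrics.items())
        ]
        _write_tsv(
            pd.DataFrame(metrics_rows), kdir / "network_metrics.tsv", cfg, index=False
        )

        for g in sorted(assembly_rows):
            alpha_g = alpha.per_sample[alpha.per_sample["group"] == g]
            summary_rows.append(
                {
                    "kingdom": kingdom,
                    "group": g,
                    "mean_richness": float(alpha_g["richness"].mean()),
                    "mean_shannon": float(alpha_g["shannon"].mean()),
                    "n_nodes": group_metrics[g]["n_nodes"],
                    "n_edges": group_metrics[g]["n_edges"],
                    "mean_betweenness": group_metrics[g]["mean_betweenness"],
                    "degree_assortativity": group_metrics[g]["degree_assortativity"],
                    "mean_niche_breadth": assembly_rows[g]["mean_niche_breadth"],
                    "ncm_m": assembly_rows[g]["ncm_m"],
                    "ncm_R2": assembly_rows[g]["ncm_R2"],
                    "cscore_ses": assembly_rows[g]["cscore"]["ses"],
                }
            )

    summary = pd.DataFrame(summary_rows)
    _write_tsv(summary, out / "summary.tsv", cfg, index=False)
    _write_json(
        {"stages": list(timings), "status": "complete"}, out / "log.json", cfg
    )
    # wall-clock timings are run metadata, kept apart from the deterministic log
    _write_json({"timings_s": timings}, out / "timings.json", cfg)
    return out


def summarize_run(run_dir: str | Path) -> pd.DataFrame:
    """Load the one-row-per-(kingdom x group) summary of a completed run."""
    path = Path(run_dir) / "summary.tsv"
    if not path.exists():
        missing = [
            str(p)
            for p in [Path(run_dir) / "summary.tsv", Path(run_dir) / "config.json"]
            if not p.exists()
        ]
        raise FileNotFoundError(f"incomplete run directory; missing: {missing}")
    return pd.read_csv(path, sep="\t", comment="#")
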