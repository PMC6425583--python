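"""End-to-end pipeline: expression -> kNN graph -> partition -> abstraction.

`run_pipeline` is the library-level composition used by the CLI, the
benchmark harness and the test suite; `run_paga` / `run_benchmark` wrap it
with file input/output around a validated `RunConfig`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_mutual_info_score

from . import io as pio
from .abstraction import (
    connectivity_directed,
    connectivity_undirected,
    count_inter_edges,
    map_resolutions,
    overlap_fractions,
    spanning_tree,
    threshold_graph,
)
from .embedding import coarse_from_fine, embed_cells, init_fine_from_coarse, layout_paga_graph
from .metrics import geodesic_distances, kl_geo, topology_path_score
from .neighbors import build_knn_graph
from .partition import Partitioning, load_partition, partition_graph
from .preprocess import CountMatrix, PreprocessConfig, compute_representation, preprocess_counts
from .pseudotime import dpt_distance, transition_matrix
from .synthetic import SimulatedDataset, simulate_tree, y_topology, double_branch_topology, linear_topology

logger = logging.getLogger("pagamap")

TOPOLOGY_PRESETS = {
    "linear": lambda: linear_topology(3),
    "single": lambda: linear_topology(1),
    "y": y_topology,
    "double": double_branch_topology,
}


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


@dataclass
class RunConfig:
    """All pipeline parameters as one validated, serializable record."""

    # inputs (exactly one of counts_csv / mtx / rep_csv, or a simulation)
    counts_csv: str | None = None
    mtx: str | None = None
    barcodes: str | None = None
    genes: str | None = None
    rep_csv: str | None = None
    partition_csv: str | None = None
    velocity_tsv: str | None = None
    simulate: str | None = None  # topology preset name
    # simulation parameters
    cells_per_segment: int = 200
    n_genes: int = 50
    noise_sd: float = 0.3
    # preprocessing / representation
    do_preprocess: bool = False
    n_top_genes: int = 1000
    n_comps: int = 10
    # graph
    k: int = 15
    kernel: str = "exponential"
    # partition / abstraction
    resolution: float = 1.0
    threshold: float = 0.01
    null: str = "knn"
    # pseudotime / embedding
    root: int | None = None
    embed_method: str = "force_directed"
    embed_iter: int = 50
    # misc
    seed: int = 0
    out_dir: str = "pagamap_run"
    # benchmark sweep
    sweep_resolutions: tuple = (0.3, 0.5, 1.0, 2.0, 3.0)
    sweep_seeds: tuple = (0, 1, 2, 3)

    def validate(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.kernel not in ("exponential", "adaptive_gaussian", "unit"):
            raise ConfigError(f"unknown kernel {self.kernel!r}")
        if self.resolution <= 0:
            raise ConfigError("resolution must be > 0")
        if not 0 <= self.threshold <= 1:
            raise ConfigError("threshold must lie in [0, 1]")
        if self.simulate is not None and self.simulate not in TOPOLOGY_PRESETS:
            raise ConfigError(f"unknown topology preset {self.simulate!r}; choose from {sorted(TOPOLOGY_PRESETS)}")
        sources = [self.counts_csv, self.mtx, self.rep_csv, self.simulate]
        if sum(s is not None for s in sources) != 1:
            raise ConfigError("exactly one input source required (counts_csv | mtx | rep_csv | simulate)")
        if self.mtx is not None and (self.barcodes is None or self.genes is None):
            raise ConfigError("mtx input requires barcodes and genes files")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat key=value text file; explicit keyword overrides win."""
        values: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        parsed: dict = {}
        for key, val in values.items():
            if key not in fields:
                raise ConfigError(f"unknown config key {key!r}")
            default = getattr(cls(), key)
            if val.lower() in ("none", ""):
                parsed[key] = None
            elif isinstance(default, bool):
                parsed[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int) and not isinstance(default, bool):
                parsed[key] = int(val)
            elif isinstance(default, float):
                parsed[key] = float(val)
            elif isinstance(default, tuple):
                parsed[key] = tuple(float(x) for x in val.split(","))
            else:
                parsed[key] = val
        parsed.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**parsed)


def run_pipeline(
    data,
    k: int = 15,
    kernel: str = "exponential",
    n_comps: int = 10,
    resolution: float = 1.0,
    threshold: float = 0.01,
    null: str = "knn",
    seed: int = 0,
    partition: Partitioning | None = None,
) -> dict:
    """Expression matrix (or SimulatedDataset) -> thresholded abstraction.

    Returns a dict with keys rep, graph, partition, counts, paga (theta at
    threshold 0) and thresholded (kept edge set at ``threshold``).
    """
    if isinstance(data, SimulatedDataset):
        counts = CountMatrix(values=data.expr, cell_ids=data.cell_ids, gene_ids=data.gene_ids)
    elif isinstance(data, CountMatrix):
        counts = data
    else:
        arr = np.asarray(data, dtype=float)
        counts = CountMatrix(
            values=arr,
            cell_ids=[f"cell{i}" for i in range(arr.shape[0])],
            gene_ids=[f"gene{j}" for j in range(arr.shape[1])],
        )
    if n_comps and n_comps < min(counts.n_cells, counts.n_genes):
        rep = compute_representation(counts, n_comps=n_comps, seed=seed)
    else:
        rep = None
    graph = build_knn_graph(rep if rep is not None else counts.values, k=k, kernel=kernel)
    part = partition if partition is not None else partition_graph(graph, resolution=resolution, seed=seed)
    counts_ie = count_inter_edges(graph, part)
    paga = connectivity_undirected(counts_ie, part, k=k, null=null)
    thresholded = threshold_graph(paga, threshold)
    return {
        "counts": counts,
        "rep": rep,
        "graph": graph,
        "partition": part,
        "inter_edges": counts_ie,
        "paga": paga,
        "thresholded": thresholded,
    }


def truth_partition(ds: SimulatedDataset) -> tuple[Partitioning, nx.Graph]:
    """Ground-truth segment labels as a Partitioning plus the matching
    reference graph with nodes re-encoded to the same dense ids."""
    segs = sorted(ds.true_topology.nodes())
    mapping = {s: i for i, s in enumerate(segs)}
    labels = np.array([mapping[b] for b in ds.true_branch], dtype=np.int64)
    ref = nx.relabel_nodes(ds.true_topology, mapping, copy=True)
    return Partitioning(labels=labels, source="external", group_names=[str(s) for s in segs]), ref


def score_vs_truth(result: dict, ds: SimulatedDataset) -> float:
    """Topology path score of a pipeline result against the generator truth.

    Paths are read along the spanning forest of the thresholded
    abstraction (inverse-connectivity MST), the package's canonical
    high-confidence path skeleton.
    """
    tpart, ref = truth_partition(ds)
    frac = overlap_fractions(result["partition"], tpart)
    return topology_path_score(ref, spanning_tree(result["thresholded"]), frac).score


def run_paga(config: RunConfig) -> Path:
    """Full workflow with file outputs; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                if exc is not None:
                    log_lines.append(f"{name}: FAILED after {dt:.2f}s: {exc}")
                    (out / "run.log").write_text("\n".join(log_lines) + "\n")
                    raise StageError(f"stage {name!r} failed: {exc}. Check inputs and parameters for this stage.") from exc
                log_lines.append(f"{name}: ok ({dt:.2f}s)")
                return False

        return _Stage()

    log_lines.append(f"seed={config.seed}")
    (out / "config.txt").write_text(
        "\n".join(f"{k}={'' if v is None else (','.join(map(str, v)) if isinstance(v, tuple) else v)}" for k, v in asdict(config).items()) + "\n"
    )

    ds = None
    with stage("input"):
        if config.simulate is not None:
            ds = simulate_tree(
                TOPOLOGY_PRESETS[config.simulate](),
                cells_per_segment=config.cells_per_segment,
                n_genes=config.n_genes,
                noise_sd=config.noise_sd,
                seed=config.seed,
            )
            counts = CountMatrix(values=ds.expr, cell_ids=ds.cell_ids, gene_ids=ds.gene_ids)
        elif config.counts_csv is not None:
            counts = pio.read_counts_csv(config.counts_csv)
        elif config.mtx is not None:
            counts = pio.read_counts_mtx(config.mtx, config.barcodes, config.genes)
        else:
            rep_df = pio.read_counts_csv(config.rep_csv)
            counts = rep_df  # already a representation-like matrix

    with stage("preprocess"):
        if config.do_preprocess:
            counts = preprocess_counts(counts, PreprocessConfig(n_top_genes=config.n_top_genes))

    with stage("graph"):
        result = run_pipeline(
            counts,
            k=config.k,
            kernel=config.kernel,
            n_comps=config.n_comps,
            resolution=config.resolution,
            threshold=config.threshold,
            null=config.null,
            seed=config.seed,
        )
        if config.partition_csv is not None:
            table = pio.read_partition_csv(config.partition_csv)
            part = load_partition(table, result["graph"])
            result = run_pipeline(
                counts,
                k=config.k,
                kernel=config.kernel,
                n_comps=config.n_comps,
                threshold=config.threshold,
                null=config.null,
                seed=config.seed,
                partition=part,
            )
        pio.write_graph_edges(result["graph"], out / "graph_edges.tsv")
        pio.write_graph_graphml(result["graph"], out / "graph.graphml")
        pio.write_partition_csv(result["partition"], out / "partition.csv", cell_ids=counts.cell_ids)

    with stage("abstraction"):
        thresholded = result["thresholded"]
        if config.velocity_tsv is not None:
            arrows = pio.read_velocity_edges(config.velocity_tsv)
            thresholded = connectivity_directed(arrows, result["partition"], base=thresholded)
        tree = spanning_tree(thresholded)
        pio.write_paga_graphml(thresholded, out / "paga.graphml", tree=tree)
        pio.write_paga_adjacency_csv(thresholded, out / "paga_adjacency.csv")
        pio.write_json(paga_summary_with_config(thresholded, tree, config), out / "paga_summary.json")

    with stage("embedding"):
        coarse = layout_paga_graph(thresholded, seed=config.seed)
        init = init_fine_from_coarse(coarse, result["partition"].labels, seed=config.seed)
        cells = embed_cells(result["graph"], init, method=config.embed_method, n_iter=config.embed_iter, seed=config.seed)
        pio.write_layout_csv(coarse, out / "layout_groups.csv")
        pio.write_layout_csv(
            type(cells)(positions=cells.positions, level="cell", ids=counts.cell_ids), out / "layout_cells.csv"
        )

    if config.root is not None:
        with stage("pseudotime"):
            tm = transition_matrix(result["graph"])
            dpt = dpt_distance(tm, root=config.root, n_comps=config.n_comps)
            pio.write_dpt_csv(dpt, out / "dpt.csv", cell_ids=counts.cell_ids)

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def paga_summary_with_config(paga, tree, config: RunConfig) -> dict:
    s = pio.paga_summary(paga, tree)
    s["config"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()}
    return s


def run_benchmark(config: RunConfig) -> dict:
    """Resolution/seed sweep measuring abstraction robustness.

    For every (resolution, seed) pair the pipeline is run on one simulated
    dataset; the report contains the per-run topology score against the
    generator truth, all pairwise topology scores between runs, and all
    pairwise partition agreements (adjusted mutual information).  The
    headline comparison is median pairwise topology agreement vs median
    pairwise AMI.
    """
    config.validate()
    if config.simulate is None:
        raise ConfigError("benchmark requires a simulated topology (simulate=<preset>)")
    ds = simulate_tree(
        TOPOLOGY_PRESETS[config.simulate](),
        cells_per_segment=config.cells_per_segment,
        n_genes=config.n_genes,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    runs = []
    for res in config.sweep_resolutions:
        for sd in config.sweep_seeds:
            r = run_pipeline(
                ds, k=config.k, kernel=config.kernel, n_comps=config.n_comps,
                resolution=float(res), threshold=config.threshold, null=config.null, seed=int(sd),
            )
            runs.append({"resolution": float(res), "seed": int(sd), "result": r,
                         "n_groups": r["partition"].n_groups, "score_vs_truth": score_vs_truth(r, ds)})
    pair_scores, pair_ami = [], []
    for a in range(len(runs)):
        for b in range(a + 1, len(runs)):
            ra, rb = runs[a]["result"], runs[b]["result"]
            frac = overlap_fractions(rb["partition"], ra["partition"])
            s = topology_path_score(
                spanning_tree(ra["thresholded"]), spanning_tree(rb["thresholded"]), frac
            ).score
            ami = adjusted_mutual_info_score(ra["partition"].labels, rb["partition"].labels)
            pair_scores.append({"run_a": a, "run_b": b, "topology_score": s, "ami": float(ami)})
            pair_ami.append(float(ami))
    report = {
        "runs": [{k: v for k, v in r.items() if k != "result"} for r in runs],
        "pairs": pair_scores,
        "median_pairwise_topology_score": float(np.median([p["topology_score"] for p in pair_scores])) if pair_scores else 1.0,
        "median_pairwise_ami": float(np.median(pair_ami)) if pair_ami else 1.0,
        "median_score_vs_truth": float(np.median([r["score_vs_truth"] for r in runs])),
    }
    return report


def write_benchmark_report(report: dict, out_dir: str | Path) -> Path:
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report["runs"]).to_csv(out / "benchmark_runs.tsv", sep="\t", index=False)
    pd.DataFrame(report["pairs"]).to_csv(out / "benchmark_pairs.tsv", sep="\t", index=False)
    pio.write_json({k: v for k, v in report.items() if k not in ("runs", "pairs")}, out / "benchmark_summary.json")
    return out
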