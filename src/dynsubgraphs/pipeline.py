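"""End-to-end pipeline: simulate -> networks -> decompose -> map -> analyze.

Each stage writes its outputs under the run directory and records a
content hash in the run manifest, so a rerun with the same configuration
and seed reproduces every numeric output bit for bit.  Stage failures
abort the run with the failing stage named; outputs of completed stages
are retained.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment

from . import dynamics as dyn
from . import io as dio
from .coherence import CoherenceConfig
from .networks import concatenate, regress_motion
from .nmf import fit_sparse_nmf, project
from .synthetic import simulate_cohort
from .systems import fold_subgraph, locality_skewness, significant_systems, \
    system_matrix

__all__ = ["PipelineConfig", "run_pipeline", "make_report",
           "match_components"]


@dataclass
class PipelineConfig:
    """Declarative run configuration (one YAML document, flat sections)."""

    out_dir: str = "run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    coherence: dict = field(default_factory=dict)
    nmf: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    partition_path: str | None = None
    cohort_path: str | None = None     # reuse an existing cohort container

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        known = {f_.name for f_ in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)


def match_components(A: np.ndarray, B: np.ndarray):
    """Greedy-optimal matching of component rows of A to rows of B.

    Uses the Hungarian algorithm on the Pearson correlation matrix.
    Returns ``(perm, corrs)`` where ``A[perm[j]]`` matches ``B[j]`` with
    correlation ``corrs[j]``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Az = A - A.mean(axis=1, keepdims=True)
    Bz = B - B.mean(axis=1, keepdims=True)
    An = np.linalg.norm(Az, axis=1)
    Bn = np.linalg.norm(Bz, axis=1)
    denom = np.outer(An, Bn)
    corr = np.where(denom > 0, Az @ Bz.T / np.where(denom > 0, denom, 1.0), 0.0)
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(B.shape[0], dtype=int)
    perm[cols] = rows
    return perm, corr[perm, np.arange(B.shape[0])]


def _content_hash(path: Path) -> str:
    """Deterministic content hash (dataset bytes for HDF5, raw bytes else)."""
    h = hashlib.sha256()
    if path.suffix == ".h5":
        import h5py

        with h5py.File(path, "r") as f:
            names = []
            f.visit(names.append)
            for name in sorted(names):
                obj = f[name]
                h.update(name.encode())
                if isinstance(obj, h5py.Dataset):
                    h.update(np.ascontiguousarray(obj[()]).tobytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def _edge_matrices(cohort, cfg: PipelineConfig):
    """Per-subject edge-time matrices: coherence networks from BOLD-like
    series when present, otherwise the rendered connectivity directly."""
    if cohort.series is not None:
        from .networks import build_multilayer, normalize_layers, unfold

        ccfg = CoherenceConfig(**cfg.coherence)
        return [unfold(normalize_layers(build_multilayer(s, ccfg))).values
                for s in cohort.series]
    if cohort.connectivity is not None:
        return [np.asarray(c) for c in cohort.connectivity]
    raise ValueError("cohort has neither series nor connectivity")


def run_pipeline(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "stages": [], "outputs": {}}
    t0 = time.time()

    def record(stage, paths):
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _content_hash(p)
        manifest["stages"].append({"stage": stage,
                                   "wall_time_s": round(time.time() - t0, 3)})

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - name the failing stage
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e

    # --- simulate ---------------------------------------------------------
    def _simulate():
        if cfg.cohort_path:
            path = Path(cfg.cohort_path)
            if not path.exists():
                raise FileNotFoundError(f"cohort container not found: {path}")
            cohort = dio.load_cohort(path)
        else:
            cohort = simulate_cohort(seed=cfg.seed, **cfg.simulate)
        if cfg.partition_path:
            ppath = Path(cfg.partition_path)
            if not ppath.exists():
                raise FileNotFoundError(f"partition file not found: {ppath}")
            partition = dio.read_partition_tsv(ppath)
        else:
            partition = cohort.partition
        dio.save_cohort(out / "cohort.h5", cohort)
        dio.write_partition_tsv(out / "partition.tsv", partition)
        dio.write_metadata_tsv(out / "metadata.tsv", cohort)
        record("simulate", [out / "cohort.h5", out / "partition.tsv",
                            out / "metadata.tsv"])
        return cohort, partition

    cohort, partition = run_stage("simulate", _simulate)

    # --- build networks ---------------------------------------------------
    def _networks():
        edges = _edge_matrices(cohort, cfg)
        if cohort.motion is not None and np.ptp(cohort.motion) > 0:
            edges = regress_motion(edges, cohort.motion)
        X = concatenate(edges)
        dio.save_cohort_matrix(out / "networks.h5", X, mode="w")
        record("build-networks", [out / "networks.h5"])
        return X

    X = run_stage("build-networks", _networks)

    # --- decompose --------------------------------------------------------
    def _decompose():
        nmf_kwargs = dict(cfg.nmf)
        k = int(nmf_kwargs.pop("k", cohort.ground_truth.k_true))
        res = fit_sparse_nmf(X.values, k=k, **nmf_kwargs)
        dio.save_nmf_result(out / "networks.h5", res)
        record("decompose", [out / "networks.h5"])
        return res

    res = run_stage("decompose", _decompose)

    # --- map systems ------------------------------------------------------
    def _map_systems():
        n_perm = int(cfg.analysis.get("n_perm", 1000))
        alpha = float(cfg.analysis.get("alpha", 0.05))
        sysdir = out / "systems"
        sysdir.mkdir(exist_ok=True)
        paths, sig_tables, skews = [], [], []
        for g in range(res.W.shape[1]):
            V = fold_subgraph(res.W[:, g], partition.n_nodes)
            M = system_matrix(V, partition)
            p = sysdir / f"subgraph_{g + 1}_system_matrix.tsv"
            M.to_frame().to_csv(p, sep="\t")
            paths.append(p)
            skews.append(locality_skewness(M))
            sig = significant_systems(V, partition, n_perm=n_perm,
                                      alpha=alpha, seed=cfg.seed + g)
            sig.insert(0, "subgraph", g + 1)
            sig_tables.append(sig)
        sig_all = pd.concat(sig_tables, ignore_index=True)
        sig_all.to_csv(sysdir / "significance.tsv", sep="\t", index=False)
        pd.DataFrame({"subgraph": np.arange(res.W.shape[1]) + 1,
                      "locality_skewness": skews}).to_csv(
            sysdir / "locality.tsv", sep="\t", index=False)
        paths += [sysdir / "significance.tsv", sysdir / "locality.tsv"]
        record("map-systems", paths)
        return sig_all

    run_stage("map-systems", _map_systems)

    # --- analyze ----------------------------------------------------------
    def _analyze():
        n_bins = int(cfg.analysis.get("n_bins", 10))
        n_perm = int(cfg.analysis.get("n_perm", 1000))
        flex_kind = cfg.analysis.get("flexibility", "entropy")
        adir = out / "dynamics"
        adir.mkdir(exist_ok=True)
        summary = dyn.summarize_dynamics(res.H, X.column_map,
                                         group_labels=cohort.group_labels,
                                         motion=cohort.motion, n_bins=n_bins)
        summary.to_csv(adir / "dynamics.tsv", sep="\t", index=False)

        # identify the learned counterpart of the planted effect subgraph
        # by matching basis columns (edge patterns are the stable signature)
        gt = cohort.ground_truth
        perm, corrs = match_components(res.W.T, gt.basis_true.T)
        effect = int(perm[gt.effect_subgraph])

        results = {"effect_subgraph_learned": effect,
                   "effect_subgraph_match_r": float(
                       corrs[gt.effect_subgraph])}
        rows = []
        sub = summary[summary["subgraph"] == effect]
        for metric in ("standardized_energy", "standardized_entropy"):
            z, p = dyn.group_compare(sub[metric].to_numpy(),
                                     sub["group"].to_numpy(),
                                     group_order=("child", "adult"))
            rows.append({"metric": metric, "z": z, "pvalue": p})
        pd.DataFrame(rows).to_csv(adir / "group_tests.tsv", sep="\t",
                                  index=False)

        r, p = dyn.energy_entropy_relation(summary)
        shuffle = dyn.shuffle_null_correlation(res.H, X.column_map,
                                               n_perm=n_perm, seed=cfg.seed,
                                               n_bins=n_bins)
        results.update({"energy_entropy_r": r, "energy_entropy_p": p,
                        "shuffle_null_p": float(shuffle["pvalue"])})
        if cohort.motion is not None and np.ptp(cohort.motion) > 0:
            mc = dyn.motion_check(summary)
            mc.to_csv(adir / "motion_check.tsv", sep="\t", index=False)
            results["motion_energy_r"] = float(
                mc.loc[mc.metric == "energy", "r"].iloc[0])
            results["motion_entropy_r"] = float(
                mc.loc[mc.metric == "entropy", "r"].iloc[0])
        if cohort.behavior is not None and cohort.age is not None:
            weights = np.stack([
                project(c, res.W, beta=res.beta)[effect]
                for c in _edge_matrices(cohort, cfg)
            ])
            if flex_kind == "entropy":
                flex = dyn.entropy_rows(weights, n_bins=n_bins)
            else:
                flex = np.mean(np.abs(np.diff(weights, axis=1)), axis=1)
            pr, pp = dyn.behavior_association(flex, cohort.behavior,
                                              cohort.age, n_perm=n_perm,
                                              seed=cfg.seed)
            results["behavior_partial_r"] = pr
            results["behavior_p"] = float(pp)
        (adir / "tests.json").write_text(json.dumps(results, indent=2))
        record("analyze", [adir / "dynamics.tsv", adir / "group_tests.tsv",
                           adir / "tests.json"])
        return summary, results

    summary, results = run_stage("analyze", _analyze)

    manifest["results"] = results
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_report(run_dir) -> list:
    """Summary figures and cross-checked tables for a completed run.

    Produces heat maps of the per-subgraph system matrices, the
    energy-entropy scatter (one point per subgraph) and group box
    summaries; numeric table values are re-read from the stage TSVs, so
    the report can never disagree with them.  Degenerate (all-constant)
    metrics are flagged rather than plotted.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    figdir = run_dir / "report"
    figdir.mkdir(exist_ok=True)
    outputs = []

    dyn_path = run_dir / "dynamics" / "dynamics.tsv"
    if not dyn_path.exists():
        raise FileNotFoundError(f"missing upstream output: {dyn_path}")
    summary = pd.read_csv(dyn_path, sep="\t")

    sys_paths = sorted((run_dir / "systems").glob("subgraph_*_system_matrix.tsv"))
    if sys_paths:
        n = len(sys_paths)
        ncols = min(n, 5)
        nrows = -(-n // ncols)
        fig, axes = plt.subplots(nrows, ncols,
                                 figsize=(3 * ncols, 2.6 * nrows),
                                 squeeze=False)
        for ax in axes.ravel():
            ax.axis("off")
        for i, p in enumerate(sys_paths):
            M = pd.read_csv(p, sep="\t", index_col=0)
            ax = axes[i // ncols][i % ncols]
            ax.axis("on")
            im = ax.imshow(M.to_numpy(), cmap="viridis")
            ax.set_title(p.stem.replace("_system_matrix", ""), fontsize=8)
            ax.set_xticks([])
            ax.set_yticks([])
        fig.colorbar(im, ax=axes.ravel().tolist(), shrink=0.7)
        fig.savefig(figdir / "system_matrices.png", dpi=120)
        plt.close(fig)
        outputs.append(figdir / "system_matrices.png")

    per = summary.groupby("subgraph")[["energy", "entropy"]].mean()
    fig, ax = plt.subplots(figsize=(4, 3.2))
    if (per["energy"] > 0).all() and np.ptp(per["entropy"].to_numpy()) > 0:
        ax.scatter(np.log(per["energy"]), per["entropy"])
        for g, row in per.iterrows():
            ax.annotate(str(g + 1), (np.log(row["energy"]), row["entropy"]),
                        fontsize=7)
        ax.set_xlabel("log energy (subgraph mean)")
        ax.set_ylabel("entropy (subgraph mean)")
    else:
        ax.text(0.5, 0.5, "degenerate metrics:\nno variation to plot",
                ha="center", va="center", transform=ax.transAxes)
    fig.tight_layout()
    fig.savefig(figdir / "energy_entropy.png", dpi=120)
    plt.close(fig)
    outputs.append(figdir / "energy_entropy.png")

    if "group" in summary:
        tests_path = run_dir / "dynamics" / "tests.json"
        effect = 0
        if tests_path.exists():
            effect = json.loads(tests_path.read_text()).get(
                "effect_subgraph_learned", 0)
        sub = summary[summary["subgraph"] == effect]
        fig, axes = plt.subplots(1, 2, figsize=(7, 3.2))
        for ax, metric in zip(axes,
                              ("standardized_energy", "standardized_entropy")):
            groups = [g for _, g in sub.groupby("group")[metric]]
            names = [n for n, _ in sub.groupby("group")[metric]]
            if all(np.ptp(g.to_numpy()) == 0 for g in groups):
                ax.text(0.5, 0.5, "degenerate", ha="center", va="center",
                        transform=ax.transAxes)
            else:
                ax.boxplot([g.to_numpy() for g in groups], tick_labels=names)
            ax.set_title(metric, fontsize=9)
        fig.tight_layout()
        fig.savefig(figdir / "group_boxes.png", dpi=120)
        plt.close(fig)
        outputs.append(figdir / "group_boxes.png")

    # round-trip check: table values re-read equal the stage TSV exactly
    check = pd.read_csv(dyn_path, sep="\t")
    if not check.equals(summary):
        raise RuntimeError("report inputs changed while reporting")
    summary.describe().to_csv(figdir / "dynamics_summary.tsv", sep="\t")
    outputs.append(figdir / "dynamics_summary.tsv")
    return outputs
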