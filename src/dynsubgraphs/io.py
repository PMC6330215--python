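"""HDF5 cohort container and TSV tables.

One HDF5 file per cohort holds the generated signals, planted ground
truth, networks and factorization results; partitions and per-subject
metadata travel as TSV so they stay human-readable.

Layout (groups absent when a stage has not run):

    /series                (S, N, n_samples)
    /connectivity          (S, E, T)
    /ground_truth/W        (E, k)       + attrs effect_subgraph, seed, ...
    /ground_truth/H        (S, k, T)
    /partition/labels, /partition/node_to_system
    /metadata/{subject_id, group, age, motion, behavior}
    /X/values, /X/column_subject, /X/column_window
    /nmf/W, /nmf/H, /nmf/objective_trace  + attrs
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .networks import CohortMatrix, edge_index_pairs
from .nmf import NMFResult
from .synthetic import GroundTruth, SyntheticCohort
from .systems import SystemPartition

__all__ = [
    "save_cohort", "load_cohort", "write_partition_tsv", "read_partition_tsv",
    "write_metadata_tsv", "save_cohort_matrix", "load_cohort_matrix",
    "save_nmf_result", "load_nmf_result",
]


def _write_strings(group, name, values):
    group.create_dataset(name, data=np.asarray(values, dtype="S"))


def _read_strings(dset) -> list[str]:
    return [v.decode() for v in dset[()]]


def save_cohort(path, cohort: SyntheticCohort) -> None:
    with h5py.File(path, "w") as f:
        if cohort.series is not None:
            f.create_dataset("series", data=np.stack(cohort.series))
        if cohort.connectivity is not None:
            f.create_dataset("connectivity", data=np.stack(cohort.connectivity))
        gt = cohort.ground_truth
        g = f.create_group("ground_truth")
        g.create_dataset("W", data=gt.basis_true)
        g.create_dataset("H", data=gt.coeffs_true)
        if gt.node_loadings is not None:
            g.create_dataset("node_loadings", data=gt.node_loadings)
        g.attrs["effect_subgraph"] = gt.effect_subgraph
        g.attrs["energy_ratio"] = gt.energy_ratio
        g.attrs["switching_prob"] = gt.switching_prob
        g.attrs["adult_switching_increment"] = gt.adult_switching_increment
        g.attrs["seed"] = gt.seed
        g.attrs["supports"] = str(gt.subgraph_supports)
        if cohort.partition is not None:
            p = f.create_group("partition")
            _write_strings(p, "labels", cohort.partition.labels)
            p.create_dataset("node_to_system",
                             data=cohort.partition.node_to_system)
        m = f.create_group("metadata")
        _write_strings(m, "group", cohort.group_labels)
        for name in ("age", "motion", "behavior"):
            val = getattr(cohort, name)
            if val is not None:
                m.create_dataset(name, data=np.asarray(val, dtype=float))


def load_cohort(path) -> SyntheticCohort:
    with h5py.File(path, "r") as f:
        g = f["ground_truth"]
        groups = np.array(_read_strings(f["metadata"]["group"]))
        partition = None
        if "partition" in f:
            partition = SystemPartition(
                labels=_read_strings(f["partition"]["labels"]),
                node_to_system=f["partition"]["node_to_system"][()])
        gt = GroundTruth(
            basis_true=g["W"][()], coeffs_true=g["H"][()],
            effect_subgraph=int(g.attrs["effect_subgraph"]),
            energy_ratio=float(g.attrs["energy_ratio"]),
            switching_prob=float(g.attrs["switching_prob"]),
            adult_switching_increment=float(
                g.attrs["adult_switching_increment"]),
            seed=int(g.attrs["seed"]),
            node_loadings=(g["node_loadings"][()]
                           if "node_loadings" in g else None),
            group_labels=groups, partition=partition)
        kwargs = {}
        for name in ("age", "motion", "behavior"):
            if name in f["metadata"]:
                kwargs[name] = f["metadata"][name][()]
        return SyntheticCohort(
            partition=partition, group_labels=groups, ground_truth=gt,
            series=(list(f["series"][()]) if "series" in f else None),
            connectivity=(list(f["connectivity"][()])
                          if "connectivity" in f else None),
            **kwargs)


def write_partition_tsv(path, partition: SystemPartition) -> None:
    partition.to_table().to_csv(path, sep="\t", index=False)


def read_partition_tsv(path) -> SystemPartition:
    return SystemPartition.from_table(pd.read_csv(path, sep="\t"))


def write_metadata_tsv(path, cohort: SyntheticCohort) -> None:
    df = pd.DataFrame({
        "subject_id": np.arange(cohort.n_subjects),
        "group": cohort.group_labels,
    })
    for name in ("age", "motion", "behavior"):
        val = getattr(cohort, name)
        if val is not None:
            df[name] = val
    df.to_csv(path, sep="\t", index=False)


def save_cohort_matrix(path, X: CohortMatrix, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        if "X" in f:
            del f["X"]
        g = f.create_group("X")
        g.create_dataset("values", data=X.values)
        g.create_dataset("column_subject",
                         data=X.column_map["subject"].to_numpy())
        g.create_dataset("column_window",
                         data=X.column_map["window"].to_numpy())


def load_cohort_matrix(path) -> CohortMatrix:
    with h5py.File(path, "r") as f:
        g = f["X"]
        values = g["values"][()]
        subj = g["column_subject"][()]
        win = g["column_window"][()]
    column_map = pd.DataFrame({
        "column": np.arange(values.shape[1]),
        "subject": subj,
        "window": win,
    })
    n = int(round((1 + np.sqrt(1 + 8 * values.shape[0])) / 2))
    return CohortMatrix(values=values, column_map=column_map,
                        subject_order=list(pd.unique(subj)),
                        edge_index=edge_index_pairs(n))


def save_nmf_result(path, res: NMFResult, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        if "nmf" in f:
            del f["nmf"]
        g = f.create_group("nmf")
        g.create_dataset("W", data=res.W)
        g.create_dataset("H", data=res.H)
        g.create_dataset("objective_trace", data=res.objective_trace)
        g.attrs["converged"] = res.converged
        g.attrs["n_iter"] = res.n_iter
        g.attrs["eta"] = res.eta
        g.attrs["beta"] = res.beta


def load_nmf_result(path) -> NMFResult:
    with h5py.File(path, "r") as f:
        g = f["nmf"]
        return NMFResult(W=g["W"][()], H=g["H"][()],
                         objective_trace=g["objective_trace"][()],
                         converged=bool(g.attrs["converged"]),
                         n_iter=int(g.attrs["n_iter"]),
                         eta=float(g.attrs["eta"]),
                         beta=float(g.attrs["beta"]))
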