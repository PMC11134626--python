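"""Cohort manifest reading/writing and model archives.

A cohort on disk is a directory with a YAML manifest pointing at four plain
tables:

* ``visits.csv`` — columns ``participant_id, visit_index, <d feature cols>``;
  a participant's highest ``visit_index`` row is the last record, the rest
  form the history. Participant order is first appearance in this file.
* ``snp.csv`` — first column ``snp_id``, then one column per participant.
* ``groups.tsv`` — tab-separated ``snp_id, group_id``.
* ``labels.csv`` — first column ``score_id``, then one column per labeled
  participant.

The manifest also carries a ``modalities`` section mapping modality name to
an inclusive feature-column range. On load, labeled participants are moved
to the front (the internal convention) and the original file order is
recorded on the cohort.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import LongitudinalCohort, ModelState, FitResult

__all__ = ["load_cohort", "save_cohort", "save_model", "load_model"]


def save_cohort(cohort: LongitudinalCohort, outdir: str | os.PathLike,
                manifest_name: str = "manifest.yaml") -> Path:
    """Write a cohort to ``outdir`` in the manifest format; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = cohort.d

    feat_cols = []
    for name, sl in cohort.modality_slices.items():
        feat_cols.extend(f"{name}_{j}" for j in range(sl.stop - sl.start))
    if len(feat_cols) != d:  # slices validated elsewhere; fall back to generic names
        feat_cols = [f"feat_{j}" for j in range(d)]

    rows = []
    for i, pid in enumerate(cohort.ids):
        X = cohort.histories[i]
        for j in range(X.shape[1]):
            rows.append([pid, j, *X[:, j]])
        rows.append([pid, X.shape[1], *cohort.last_records[:, i]])
    visits = pd.DataFrame(rows, columns=["participant_id", "visit_index", *feat_cols])
    visits.to_csv(outdir / "visits.csv", index=False)

    snp_ids = [f"snp_{s}" for s in range(cohort.d_snp)]
    snp = pd.DataFrame(cohort.snp_matrix, columns=cohort.ids)
    snp.insert(0, "snp_id", snp_ids)
    snp.to_csv(outdir / "snp.csv", index=False)

    group_rows = []
    for k, g in enumerate(cohort.snp_groups):
        for s in g:
            group_rows.append([snp_ids[s], f"group_{k}"])
    pd.DataFrame(group_rows, columns=["snp_id", "group_id"]).to_csv(
        outdir / "groups.tsv", sep="\t", index=False
    )

    l = cohort.n_labeled
    labels = pd.DataFrame(cohort.labels, columns=cohort.ids[:l])
    labels.insert(0, "score_id", [f"score_{q}" for q in range(cohort.n_scores)])
    labels.to_csv(outdir / "labels.csv", index=False)

    modalities = {
        name: {"start": sl.start, "stop": sl.stop}
        for name, sl in cohort.modality_slices.items()
    }
    manifest = {
        "visits": "visits.csv",
        "snp": "snp.csv",
        "groups": "groups.tsv",
        "labels": "labels.csv",
        "modalities": modalities,
    }
    path = outdir / manifest_name
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def load_cohort(manifest_path: str | os.PathLike) -> LongitudinalCohort:
    """Read a cohort from a manifest, reordering labeled participants first."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)

    visits = pd.read_csv(base / manifest["visits"], dtype={"participant_id": str})
    feat_cols = [c for c in visits.columns if c not in ("participant_id", "visit_index")]

    snp = pd.read_csv(base / manifest["snp"], dtype={"snp_id": str})
    snp_ids = snp["snp_id"].tolist()
    groups_df = pd.read_csv(base / manifest["groups"], sep="\t", dtype=str)
    labels = pd.read_csv(base / manifest["labels"], dtype={"score_id": str})
    labeled_ids = [c for c in labels.columns if c != "score_id"]

    # participant order: first appearance in visits.csv, labeled first
    file_order = list(dict.fromkeys(visits["participant_id"]))
    labeled_set = set(labeled_ids)
    ordered = [p for p in file_order if p in labeled_set] + [
        p for p in file_order if p not in labeled_set
    ]
    original_order = np.array([file_order.index(p) for p in ordered], dtype=int)

    histories, last_records = [], []
    for pid in ordered:
        block = visits[visits["participant_id"] == pid].sort_values("visit_index")
        mat = block[feat_cols].to_numpy(dtype=float).T  # d x total_visits
        histories.append(mat[:, :-1])
        last_records.append(mat[:, -1])
    last = np.column_stack(last_records)

    snp_matrix = snp[ordered].to_numpy(dtype=float)

    group_of = dict(zip(groups_df["snp_id"], groups_df["group_id"]))
    group_names = list(dict.fromkeys(groups_df["group_id"]))
    snp_groups = [
        np.array([s for s, sid in enumerate(snp_ids) if group_of.get(sid) == gname],
                 dtype=int)
        for gname in group_names
    ]

    label_matrix = labels[[p for p in ordered if p in labeled_set]].to_numpy(dtype=float)

    modality_slices = {
        name: slice(rng["start"], rng["stop"])
        for name, rng in manifest["modalities"].items()
    }
    return LongitudinalCohort(
        histories=histories,
        last_records=last,
        modality_slices=modality_slices,
        snp_matrix=snp_matrix,
        snp_groups=snp_groups,
        labels=label_matrix,
        ids=ordered,
        original_order=original_order,
    )


def save_model(result: FitResult, path: str | os.PathLike) -> None:
    """Save a fit result as a flat ``.npz`` archive (runtime artifact)."""
    st = result.state
    arrays = {
        "H0": st.H0, "G0": st.G0, "H1": st.H1, "G1": st.G1,
        "U": st.U, "F": st.F, "A": st.A,
        "Lambda1": st.Lambda1, "Lambda3": st.Lambda3,
        "mu1": np.array(st.mu1), "mu2": st.mu2,
        "mu3": np.array(st.mu3), "mu4": st.mu4,
        "Z": result.Z,
        "objective_history": np.array(result.objective_history),
        "converged": np.array(result.converged),
        "n_outer": np.array(result.n_outer),
        "n_inner_total": np.array(result.n_inner_total),
    }
    for i, (w, b, l2, l4) in enumerate(zip(st.W, st.B, st.Lambda2, st.Lambda4)):
        arrays[f"W_{i}"] = w
        arrays[f"B_{i}"] = b
        arrays[f"Lambda2_{i}"] = l2
        arrays[f"Lambda4_{i}"] = l4
    np.savez(path, **arrays)


def load_model(path: str | os.PathLike) -> FitResult:
    """Load a fit result saved by :func:`save_model`."""
    with np.load(path) as data:
        n = sum(1 for k in data.files if k.startswith("W_"))
        state = ModelState(
            W=[data[f"W_{i}"] for i in range(n)],
            H0=data["H0"], G0=data["G0"], H1=data["H1"], G1=data["G1"],
            U=data["U"], F=data["F"], A=data["A"],
            B=[data[f"B_{i}"] for i in range(n)],
            Lambda1=data["Lambda1"],
            Lambda2=[data[f"Lambda2_{i}"] for i in range(n)],
            Lambda3=data["Lambda3"],
            Lambda4=[data[f"Lambda4_{i}"] for i in range(n)],
            mu1=float(data["mu1"]), mu2=data["mu2"],
            mu3=float(data["mu3"]), mu4=data["mu4"],
        )
        return FitResult(
            state=state,
            Z=data["Z"],
            objective_history=list(data["objective_history"]),
            residual_history=[],
            converged=bool(data["converged"]),
            n_outer=int(data["n_outer"]),
            n_inner_total=int(data["n_inner_total"]),
        )
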