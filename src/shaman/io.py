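"""Readers, writers, run configuration, and the censoring sweep report.

All interchange formats are plain text: TSV for matrices (nodes as rows,
frames as columns), a one-column TSV for FD series, CSV with a header for
trait tables, two-column TSV for parcel labels, and JSON for configs and
results.  Every result artifact embeds the exact configuration and seed that
produced it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .fc import ParcelTimeseries, censor, meets_minimum

EDGE_ORDER_HEADER = "# edges: row-major upper triangle, 0-based (i<j, i asc then j)"


@dataclass
class RunConfig:
    """Analysis configuration; round-trips exactly through JSON."""

    censor_threshold: float = float("inf")
    min_minutes: float = 8.0
    clamp_frames: int | None = None
    n_perm: int = 1000
    alpha: float = 0.05
    gate: float = 2.0
    seed: int = 0
    trait: str = "trait"
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.censor_threshold <= 0:
            raise ValueError("censor_threshold must be positive")
        if self.min_minutes <= 0 or self.alpha <= 0 or self.gate < 0:
            raise ValueError("thresholds must be positive")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if np.isinf(d["censor_threshold"]):
            d["censor_threshold"] = "inf"
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if d.get("censor_threshold") == "inf":
            d["censor_threshold"] = float("inf")
        return cls(**d)


@dataclass
class CohortManifest:
    """Paths to one cohort's files; every id unique, every file must parse."""

    participant_ids: list[str]
    timeseries_paths: list[Path]
    fd_paths: list[Path]
    run_start_lists: list[list[int]] | None = None
    trait_table: Path | None = None
    parcel_labels: Path | None = None
    tr: float = 0.8

    def __post_init__(self) -> None:
        n = len(self.participant_ids)
        if len(set(self.participant_ids)) != n:
            raise ValueError("duplicate participant ids in manifest")
        if len(self.timeseries_paths) != n or len(self.fd_paths) != n:
            raise ValueError("manifest path lists differ in length")

    @classmethod
    def from_json(cls, path: Path) -> "CohortManifest":
        d = json.loads(Path(path).read_text())
        base = Path(path).parent
        return cls(
            participant_ids=[p["id"] for p in d["participants"]],
            timeseries_paths=[base / p["timeseries"] for p in d["participants"]],
            fd_paths=[base / p["fd"] for p in d["participants"]],
            run_start_lists=[p.get("run_starts", [0]) for p in d["participants"]],
            trait_table=base / d["trait_table"] if d.get("trait_table") else None,
            parcel_labels=base / d["parcel_labels"] if d.get("parcel_labels") else None,
            tr=d.get("tr", 0.8),
        )


def read_timeseries(ts_path: Path, fd_path: Path, run_starts=None,
                    tr: float = 0.8, participant: str = "?") -> ParcelTimeseries:
    data = np.loadtxt(ts_path, ndmin=2)
    fd = np.loadtxt(fd_path, ndmin=1)
    if fd.shape[0] != data.shape[1]:
        raise ValueError(
            f"participant {participant}: FD has {fd.shape[0]} frames but "
            f"timeseries has {data.shape[1]}"
        )
    return ParcelTimeseries(data=data, fd=fd,
                            run_starts=list(run_starts or [0]), tr=tr)


def read_cohort(manifest: CohortManifest) -> tuple[list[ParcelTimeseries], pd.DataFrame | None]:
    """Load every participant in a manifest; fail loudly with the id."""
    dataset = []
    starts = manifest.run_start_lists or [[0]] * len(manifest.participant_ids)
    n_nodes = None
    for pid, tsp, fdp, rs in zip(manifest.participant_ids,
                                 manifest.timeseries_paths,
                                 manifest.fd_paths, starts):
        ts = read_timeseries(tsp, fdp, rs, tr=manifest.tr, participant=pid)
        if n_nodes is None:
            n_nodes = ts.n_nodes
        elif ts.n_nodes != n_nodes:
            raise ValueError(
                f"participant {pid}: {ts.n_nodes} nodes, expected {n_nodes}"
            )
        dataset.append(ts)
    traits = None
    if manifest.trait_table is not None:
        traits = pd.read_csv(manifest.trait_table)
    return dataset, traits


def write_cohort(cohort, out_dir: Path) -> Path:
    """Write a synthetic cohort as delimited text plus a JSON manifest.

    One nodes x frames TSV and one FD column file per participant, a
    cohort-level trait CSV, and a config echo with seed and the
    positive-definiteness shrinkage applied to each basis.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, ts in enumerate(cohort.participants):
        pid = f"sub-{i:04d}"
        np.savetxt(out_dir / f"{pid}_timeseries.tsv", ts.data, delimiter="\t")
        np.savetxt(out_dir / f"{pid}_fd.tsv", ts.fd)
        entries.append({"id": pid, "timeseries": f"{pid}_timeseries.tsv",
                        "fd": f"{pid}_fd.tsv", "run_starts": ts.run_starts})
    pd.DataFrame({
        "participant_id": [e["id"] for e in entries],
        "trait": cohort.trait,
        "w_brain": cohort.design.w_brain,
        "w_motion": cohort.design.w_motion,
    }).to_csv(out_dir / "traits.csv", index=False)
    cfg = dataclasses.asdict(cohort.config)
    cfg["pd_shrinkage"] = {
        cohort.basis_brain.name: cohort.basis_brain.shrinkage_iterations,
        cohort.basis_motion.name: cohort.basis_motion.shrinkage_iterations,
    }
    manifest = {"participants": entries, "trait_table": "traits.csv",
                "tr": 0.8, "config": cfg}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def write_result_json(result, config: RunConfig, path: Path) -> None:
    payload = {
        "omnibus_z": result.omnibus_z, "omnibus_p": result.omnibus_p,
        "over_z": result.over_z, "over_p": result.over_p,
        "under_z": result.under_z, "under_p": result.under_p,
        "n_perm": result.null.n_perm, "alpha": result.alpha,
        "gate": result.gate, "seed": result.seed,
        "config": json.loads(config.to_json()),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_edge_matrix(vec: np.ndarray, n_nodes: int, path: Path) -> None:
    from .fc import vec_to_matrix

    mat = vec_to_matrix(vec, n_nodes)
    with open(path, "w") as fh:
        fh.write(EDGE_ORDER_HEADER + "\n")
        np.savetxt(fh, mat, delimiter="\t")


def write_effect_table(effect, n_nodes: int, path: Path) -> None:
    """Per-edge effect table: edge id, node pair, beta, t, r_effect."""
    from .fc import edge_nodes

    i, j = edge_nodes(n_nodes)
    pd.DataFrame({
        "edge_id": np.arange(i.size),
        "node_i": i,
        "node_j": j,
        "beta": effect.beta,
        "t": effect.t,
        "r_effect": effect.r_effect,
    }).to_csv(path, sep="\t", index=False)


def load_parcel_labels(path: Path | None = None) -> pd.DataFrame:
    """Parcel -> network label table (node_id, network).

    Defaults to the bundled synthetic stand-in for the 333-cortical +
    61-subcortical (394-node) parcellation scheme.
    """
    if path is None:
        ref = resources.files("shaman.data") / "parcel_labels_synthetic_394.tsv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def censoring_sweep(dataset: list[ParcelTimeseries], trait_table: pd.DataFrame,
                    thresholds: list[float], min_minutes: float = 8.0,
                    shift_flag_pct: float = 1.0) -> pd.DataFrame:
    """Participant exclusion and trait-mean shift at each censoring threshold.

    For each threshold: censor frames at FD < threshold, exclude participants
    left with less than ``min_minutes`` of data, and report per-trait mean
    shifts (%) of the surviving sample versus the uncensored sample, flagging
    shifts larger than ``shift_flag_pct`` percent.
    """
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    trait_cols = [c for c in trait_table.columns
                  if trait_table[c].dtype.kind in "if"]
    base_means = trait_table[trait_cols].mean()
    rows = []
    for thr in thresholds:
        included = []
        for k, ts in enumerate(dataset):
            try:
                censored, _ = censor(ts, thr)
            except ValueError:
                continue  # every frame removed
            if meets_minimum(censored, min_minutes):
                included.append(k)
        sub = trait_table.iloc[included]
        for col in trait_cols:
            base = base_means[col]
            shift = np.nan if base == 0 else (sub[col].mean() - base) / abs(base) * 100
            rows.append({
                "threshold_mm": thr,
                "n_included": len(included),
                "n_excluded": len(dataset) - len(included),
                "trait": col,
                "mean_shift_pct": shift,
                "flagged": bool(abs(shift) > shift_flag_pct) if np.isfinite(shift) else False,
            })
    return pd.DataFrame(rows)
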