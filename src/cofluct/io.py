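"""File I/O, configuration, and the end-to-end pipeline driver.

All matrices travel as plain TSV ("." decimal, 0-based indices), configs and
manifests as JSON. One top-level seed in the config; every stage derives its
own seed deterministically by hashing the stage name, so reruns are
byte-identical and single stages are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import clustering, edges, events, structure, synth

logger = logging.getLogger("cofluct")

__all__ = [
    "AnalysisConfig",
    "NodeMetadata",
    "load_dense_matrix",
    "save_dense_matrix",
    "stage_seed",
    "run_pipeline",
    "write_report",
]


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the config seed."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def load_dense_matrix(
    path: str | Path, expected_shape: tuple[int, int] | None = None
) -> tuple[np.ndarray, dict]:
    """Read a rectangular delimited numeric matrix with provenance.

    Raises ``ValueError`` with row/column diagnostics on ragged rows,
    non-numeric cells, or a shape mismatch.
    """
    path = Path(path)
    text = path.read_text()
    rows: list[list[float]] = []
    width = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        cells = line.split("\t") if "\t" in line else line.split()
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValueError(
                f"{path}: ragged row {lineno}: expected {width} columns, got {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            for col, c in enumerate(cells, start=1):
                try:
                    float(c)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell at row {lineno}, column {col}: {c!r}"
                    ) from exc
            raise
    matrix = np.asarray(rows, dtype=float)
    if expected_shape is not None and matrix.shape != tuple(expected_shape):
        raise ValueError(
            f"{path}: shape {matrix.shape} does not match expected {tuple(expected_shape)}"
        )
    provenance = {
        "path": str(path),
        "sha256": hashlib.sha256(text.encode()).hexdigest(),
        "shape": list(matrix.shape),
    }
    return matrix, provenance


def save_dense_matrix(path: str | Path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt="%.17g")


@dataclass
class NodeMetadata:
    node_ids: np.ndarray
    labels: list[str]
    divisions: list[str]
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        if np.unique(self.node_ids).size != self.node_ids.size:
            raise ValueError("node_ids must be unique")


_CONFIG_FIELDS: dict[str, object] = {}


@dataclass
class AnalysisConfig:
    """End-to-end pipeline configuration (strict: unknown keys rejected)."""

    out_dir: str = "out"
    seed: int = 0
    # inputs: either per-subject time-series files, or a synthetic block
    ts_paths: list[str] = field(default_factory=list)
    sc_path: str | None = None
    coords_path: str | None = None
    synthetic: dict | None = None
    n_subjects: int = 1
    # stage parameters
    n_null_runs: int = 100
    q_threshold: float = 0.05
    n_repetitions: int = 100
    n_iter: int = 100
    n_perm: int = 1000
    alpha: float = 0.05
    gammas: list[float] = field(default_factory=lambda: [1.0])
    null_strategy: str = "rotation"

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _analyze_subject(
    ts: edges.ParcelTimeSeries, cfg: AnalysisConfig, subject: str
) -> dict:
    z = edges.standardize_timeseries(ts)
    ets = edges.compute_edge_timeseries(z)
    fc = edges.compute_static_fc(z)
    rms = edges.compute_rms(ets)
    extrema = events.find_local_extrema(rms)
    null = events.build_null_peak_distribution(
        z, n_runs=cfg.n_null_runs, seed=stage_seed(cfg.seed, f"null:{subject}")
    )
    table = events.detect_events(extrema, null, cfg.q_threshold)
    cats = events.categorize_frames(extrema, table, rms.n_frames)
    sim = None
    if table.n_events > 0:
        sim = events.reconstruct_fc_similarity(
            ets, cats, fc,
            n_repetitions=cfg.n_repetitions,
            seed=stage_seed(cfg.seed, f"similarity:{subject}"),
        )
    patterns = [
        edges.frame_pattern(ets, int(f), subject_id=subject) for f in table.event_frames
    ]
    return {
        "z": z, "ets": ets, "fc": fc, "rms": rms, "extrema": extrema,
        "events": table, "categories": cats, "similarity": sim,
        "patterns": patterns,
    }


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every stage, write all intermediates, and return the manifest.

    Events detected per subject are aggregated across subjects before
    clustering; bipartition and null tests run once per centroid of the
    first hierarchy split.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}, "outputs": []}

    def _emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].append(str(path))

    # ------------------------------------------------------------------ inputs
    subjects: dict[str, edges.ParcelTimeSeries] = {}
    sc = None
    coords = None
    truth = None
    if config.synthetic is not None:
        base = synth.SyntheticConfig(**config.synthetic)
        for s in range(config.n_subjects):
            scfg = dataclasses.replace(
                base, seed=stage_seed(config.seed, f"simulate:{s}")
            )
            sc_obj, truth_s = synth.generate_modular_connectome(scfg)
            ts = synth.generate_parcel_timeseries(scfg, truth_s)
            subjects[f"subject{s}"] = ts
            if s == 0:
                sc, coords, truth = sc_obj, truth_s.node_coordinates, truth_s
        _emit("connectome.tsv", lambda p: save_dense_matrix(p, sc.weights))
        _emit("ground_truth.json", lambda p: truth.to_json(p))
    else:
        if not config.ts_paths:
            raise ValueError("config must provide ts_paths or a synthetic block")
        for s, path in enumerate(config.ts_paths):
            mat, _ = load_dense_matrix(path)
            subjects[f"subject{s}"] = edges.ParcelTimeSeries(mat)
        if config.sc_path:
            mat, _ = load_dense_matrix(config.sc_path)
            sc = structure.StructuralConnectome(mat)
        if config.coords_path:
            coords, _ = load_dense_matrix(config.coords_path)

    # --------------------------------------------------------------- per subject
    all_patterns: list[edges.CoFluctuationPattern] = []
    subject_ids: list[str] = []
    per_subject: dict[str, dict] = {}
    for name, ts in subjects.items():
        logger.info("analyzing %s", name)
        res = _analyze_subject(ts, config, name)
        per_subject[name] = res
        all_patterns.extend(res["patterns"])
        subject_ids.extend([name] * len(res["patterns"]))
        _emit(f"{name}_events.tsv", lambda p, r=res: _write_event_table(p, r))
        manifest["stages"][name] = {
            "n_peaks": int(res["extrema"].peak_frames.size),
            "n_events": res["events"].n_events,
            "categories": res["categories"].counts(),
            "similarity": {
                "mean": res["similarity"].mean, "sd": res["similarity"].sd,
            } if res["similarity"] else None,
        }

    # ------------------------------------------------------------------ clustering
    cluster_summary = None
    centroid_results = []
    if len(all_patterns) >= 2:
        ensemble = clustering.PatternEnsemble(all_patterns, subject_ids)
        cm = clustering.concordance_matrix(ensemble)
        hier = clustering.hierarchical_cluster_events(
            cm, n_iter=config.n_iter, n_perm=config.n_perm, alpha=config.alpha,
            seed=stage_seed(config.seed, "cluster"), vectors=ensemble.as_vectors(),
        )
        level = min(1, hier.depth - 1)
        part = hier.levels[level]
        cents = clustering.compute_centroids(ensemble, part)
        _emit("hierarchy.json", lambda p: _write_hierarchy(p, hier, subject_ids))
        for c, cent in enumerate(cents.centroids):
            _emit(f"centroid{c}.tsv", lambda p, m=cent.values: save_dense_matrix(p, m))
        cluster_summary = {
            "level_used": level,
            "n_clusters": part.n_communities,
            "member_counts": cents.member_counts.tolist(),
            "member_fractions": cents.member_fractions.tolist(),
        }
        # ------------------------------------------------------- structure tests
        if sc is not None:
            for c, cent in enumerate(cents.centroids):
                entry: dict = {"cluster": c}
                try:
                    bp = structure.extract_bipartition(
                        cent, gamma=config.gammas[0], n_iter=config.n_iter,
                        seed=stage_seed(config.seed, f"bipartition:{c}"),
                    )
                except structure.NoValidBipartitionError as exc:
                    entry["valid"] = False
                    entry["reason"] = str(exc)
                    centroid_results.append(entry)
                    continue
                entry["valid"] = True
                entry["n_plus"] = bp.n_plus
                entry["n_minus"] = bp.n_minus
                ind = structure.independent_permutation_null(
                    sc, bp, config.n_perm, stage_seed(config.seed, f"indnull:{c}")
                )
                entry["Q_induced"] = ind.Q_induced
                entry["p_independent"] = ind.p_value
                if coords is not None:
                    geo = structure.geometry_preserving_null(
                        sc, bp, coords, config.n_perm, config.null_strategy,
                        stage_seed(config.seed, f"geonull:{c}"),
                    )
                    entry["p_geometry"] = geo.p_value
                _emit(
                    f"bipartition{c}.tsv",
                    lambda p, b=bp: np.savetxt(
                        p, np.column_stack([np.arange(b.labels.size), b.labels]),
                        delimiter="\t", fmt="%d",
                    ),
                )
                centroid_results.append(entry)

    manifest["stages"]["clustering"] = cluster_summary
    manifest["stages"]["structure"] = centroid_results

    # -------------------------------------------------------------------- coupling
    if sc is not None:
        first = next(iter(per_subject.values()))
        coup = structure.coupling_timeseries(first["ets"], sc, first["rms"])
        rho = _spearman(coup.rms, coup.coupling)
        manifest["stages"]["coupling"] = {"spearman_rms_coupling": rho}
        _emit(
            "coupling.tsv",
            lambda p: np.savetxt(
                p, np.column_stack([coup.rms, coup.coupling]), delimiter="\t",
                fmt="%.17g", header="rms\tcoupling", comments="",
            ),
        )

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=_jsonify))
    manifest["outputs"].append(str(manifest_path))
    return manifest


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    from scipy import stats

    return float(stats.spearmanr(a, b).statistic)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_event_table(path: Path, res: dict) -> None:
    table = res["events"]
    cats = res["categories"]
    rms = res["rms"].values
    with open(path, "w") as fh:
        fh.write("frame\trms\tp\tq\tcategory\n")
        for i, fr in enumerate(table.frames):
            fh.write(
                f"{fr}\t{rms[fr]:.17g}\t{table.p_values[i]:.17g}\t"
                f"{table.q_values[i]:.17g}\t{cats.labels[fr]}\n"
            )


def _write_hierarchy(
    path: Path, hier: clustering.HierarchicalPartition, subject_ids: list[str]
) -> None:
    payload = {
        "depth": hier.depth,
        "levels": [
            {
                "assignment": lvl.assignment.tolist(),
                "Q": None if np.isnan(lvl.Q) else float(lvl.Q),
                "q_contributions": [
                    None if np.isnan(q) else float(q) for q in hier.q_contributions[i]
                ],
                "significant": hier.significant[i].tolist(),
            }
            for i, lvl in enumerate(hier.levels)
        ],
        "parent_map": {
            f"{lvl},{comm}": list(parent) for (lvl, comm), parent in hier.parent_map.items()
        },
        "subject_ids": subject_ids,
    }
    path.write_text(json.dumps(payload, indent=2))


def write_report(manifest: dict, path: str | Path | None = None) -> dict:
    """Summary tables recomputed from the manifest's stage records."""
    report: dict = {}
    similarity_rows = []
    for name, stage in manifest["stages"].items():
        if isinstance(stage, dict) and stage.get("similarity"):
            for cat, m in stage["similarity"]["mean"].items():
                similarity_rows.append(
                    {"subject": name, "category": cat, "mean": m,
                     "sd": stage["similarity"]["sd"][cat]}
                )
    report["fc_similarity"] = similarity_rows
    clus = manifest["stages"].get("clustering")
    if clus:
        total = sum(clus["member_counts"])
        report["clusters"] = [
            {"cluster": i, "count": c, "fraction": c / total}
            for i, c in enumerate(clus["member_counts"])
        ]
    else:
        report["clusters"] = "not applicable: no events clustered"
    struct = manifest["stages"].get("structure") or []
    report["induced_modularity"] = [
        {k: e.get(k) for k in ("cluster", "valid", "Q_induced", "p_independent", "p_geometry")}
        for e in struct
    ]
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2, default=_jsonify))
    return report
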