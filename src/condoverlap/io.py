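"""TSV readers/writers, run manifests, and deterministic fixture
generation.

The single interchange dialect is tab-separated text with a header row.
A differential table needs ``feature_id`` and ``p_value`` columns
(``lfc`` and ``stat`` optional); feature maps are two-column TSV;
gene sets are one id per line.  Parsing is locale-independent (dot
decimal separator), scientific notation accepted.
"""

from __future__ import annotations

import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ValidationError
from .overlap import ConditionalOverlapResult, DifferentialTable, SharedFeatureSet
from .rankscan import FeatureMap, RankScanCurve
from .simulation import SimulationConfig, SimulationSummary, simulate_trio

__all__ = [
    "read_differential_table",
    "read_feature_map",
    "read_gene_set",
    "read_simulation_config",
    "write_shared_features",
    "write_overlap_summary",
    "write_rankscan_curve",
    "write_simulation_summary",
    "write_manifest",
    "generate_fixtures",
]

REQUIRED_COLUMNS = ("feature_id", "p_value")
FIXTURE_KINDS = ("null_pair", "enriched_pair", "trio", "geneset")


def read_differential_table(
    path, column_map: Optional[Mapping[str, str]] = None, name: str = ""
) -> DifferentialTable:
    """Load a differential-analysis TSV into a DifferentialTable.

    ``column_map`` renames nonstandard headers (e.g. {"pval":
    "p_value"}).  Rows with unparseable or out-of-range p-values are
    rejected with their line numbers; duplicate ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValidationError(
                f"{path}: required column {col!r} missing (have "
                f"{list(df.columns)})"
            )
    if df.empty:
        raise ValidationError(f"{path}: table has no rows")

    p = pd.to_numeric(df["p_value"], errors="coerce")
    bad = p.isna() | (p < 0) | (p > 1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
        raise ValidationError(
            f"{path}: unparseable or out-of-range p_value on line(s) {lines}"
        )
    ids = df["feature_id"].astype(str)
    if ids.duplicated().any():
        offenders = ids[ids.duplicated()].unique().tolist()[:10]
        raise ValidationError(f"{path}: duplicate feature_id(s): {offenders}")

    kwargs = {}
    for opt in ("lfc", "stat"):
        if opt in df.columns:
            vals = pd.to_numeric(df[opt], errors="coerce")
            if vals.isna().any():
                lines = (df.index[vals.isna()] + 2).tolist()[:10]
                raise ValidationError(
                    f"{path}: unparseable {opt} on line(s) {lines}"
                )
            kwargs[opt] = vals.to_numpy()
    return DifferentialTable.from_arrays(
        ids.to_numpy(), p.to_numpy(), name=name or path.stem, **kwargs
    )


def read_feature_map(path) -> FeatureMap:
    """Two-column (source, target) TSV; a header row is required."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: feature map needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["source", "target"]
    return FeatureMap(df.drop_duplicates().reset_index(drop=True))


def read_gene_set(path) -> list[str]:
    """Plain-text gene set, one id per line; blanks and '#' lines skipped."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    if not ids:
        raise ValidationError(f"{path}: gene set is empty")
    return ids


def read_simulation_config(path) -> SimulationConfig:
    """YAML simulation config; keys mirror SimulationConfig fields."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    valid = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    return SimulationConfig(**raw)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_path, command: str, params: Mapping, input_paths: Sequence = ()
) -> Path:
    """Emit the run manifest (JSON): version, command, full parameters
    including seeds, input digests, timestamp."""
    manifest = {
        "tool": "condoverlap",
        "version": __version__,
        "command": command,
        "argv": sys.argv,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "inputs": {str(p): _sha256(p) for p in input_paths},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    out_path = Path(out_path)
    out_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return out_path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (Path,)):
        return str(v)
    return v


def write_shared_features(shared: SharedFeatureSet, path) -> Path:
    """SharedFeatureSet -> TSV; q-values at 12 significant digits so a
    write/read round trip is faithful.  An empty set yields a
    header-only file."""
    path = Path(path)
    df = shared.to_frame().reset_index()
    df["qvalue"] = df["qvalue"].map(lambda q: f"{q:.12g}")
    df.to_csv(path, sep="\t", index=False)
    return path


def read_shared_features(path, source_experiments: tuple = ()) -> SharedFeatureSet:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    return SharedFeatureSet(
        feature_ids=df["feature_id"].to_numpy(dtype=object),
        qvalues=df["qvalue"].to_numpy(dtype=float) if len(df) else np.empty(0),
        direction_concordant=(
            df["direction_concordant"].to_numpy(dtype=bool)
            if len(df) else np.empty(0, dtype=bool)
        ),
        source_experiments=source_experiments,
    )


def write_overlap_summary(result: ConditionalOverlapResult, path) -> Path:
    """Machine-readable key-value summary of one overlap test."""
    path = Path(path)
    lines = [
        f"n_conditioning\t{result.n_conditioning}",
        f"pi1_given_1\t{result.pi1_given_1:.12g}",
        f"pi1_given_0\t{result.pi1_given_0:.12g}",
        f"estimated_shared_count\t{result.estimated_shared_count}",
        f"n_resamples\t{len(result.null_pi1_samples)}",
        f"empirical_p\t{result.empirical_p:.12g}",
        f"normal_approx_p\t{result.normal_approx_p:.12g}",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_rankscan_curve(curve: RankScanCurve, path) -> Path:
    curve.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")
    return Path(path)


def write_simulation_summary(summary: SimulationSummary, path, per_rep_path=None) -> Path:
    path = Path(path)
    rows = {
        "mean_estimated_overlap_12": summary.mean_estimated_overlap_12,
        "mean_estimated_overlap_123": summary.mean_estimated_overlap_123,
        "mean_naive_intersection_12": summary.mean_naive_intersection_12,
        "mean_naive_intersection_123": summary.mean_naive_intersection_123,
        "mean_fdp_shared_123": summary.mean_fdp_shared_123,
        "n_reps_run": summary.n_reps_run,
        "n_reps_excluded": summary.n_reps_excluded,
    }
    path.write_text(
        "\n".join(f"{k}\t{v:.12g}" if isinstance(v, float) else f"{k}\t{v}"
                  for k, v in rows.items()) + "\n"
    )
    if per_rep_path is not None and summary.per_rep is not None:
        summary.per_rep.to_csv(per_rep_path, sep="\t", float_format="%.12g")
    return path


def _write_table(path, ids, p, lfc) -> None:
    pd.DataFrame({"feature_id": ids, "p_value": p, "lfc": lfc}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def generate_fixtures(kind: str, seed: int, outdir) -> list[Path]:
    """Write a small deterministic dataset exercising one CLI path.

    Kinds: ``null_pair`` (two tables with no shared signal),
    ``enriched_pair`` (experiment-1 hits carry Beta(0.1, 1) p-values in
    experiment 2), ``trio`` (a scaled-down three-experiment simulation:
    one repetition's tables plus a config), ``geneset`` (a table with a
    shifted 75-gene set).  All are synthetic.
    """
    if kind not in FIXTURE_KINDS:
        raise ValidationError(
            f"unknown fixture kind {kind!r}; valid kinds: {FIXTURE_KINDS}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    m = 2_000
    ids = np.array([f"f{i:05d}" for i in range(m)])
    written: list[Path] = []

    if kind == "null_pair":
        # experiment 1 has clear hits, but experiment 2 carries no
        # signal on them: the no-shared-overlap null holds
        n_sig = 100
        p1 = rng.uniform(size=m)
        p1[:n_sig] = rng.uniform(0, 1e-8, n_sig)
        for label, p in (("exp1", p1), ("exp2", rng.uniform(size=m))):
            path = outdir / f"{label}.tsv"
            _write_table(path, ids, p, rng.normal(0, 0.5, m))
            written.append(path)

    elif kind == "enriched_pair":
        # experiment-1 nulls are floored away from 0 so the significant
        # set is exactly the planted block, whose experiment-2 p-values
        # are Beta(0.1, 1)
        n_sig = 200
        p1 = rng.uniform(0.05, 1.0, size=m)
        p1[:n_sig] = rng.uniform(0, 1e-6, n_sig)
        lfc1 = rng.normal(0, 0.5, m)
        lfc1[:n_sig] = np.abs(rng.normal(1.0, 0.3, n_sig))
        p2 = rng.uniform(size=m)
        p2[:n_sig] = rng.beta(0.1, 1.0, n_sig)
        lfc2 = rng.normal(0, 0.5, m)
        lfc2[:n_sig] = np.abs(rng.normal(1.0, 0.3, n_sig))
        for label, p, lfc in (("exp1", p1, lfc1), ("exp2", p2, lfc2)):
            path = outdir / f"{label}.tsv"
            _write_table(path, ids, p, lfc)
            written.append(path)

    elif kind == "trio":
        config = SimulationConfig(
            m=m, n_diff=400, n_shared_12=280, n_shared_123=200,
            n_per_group=25, n_reps=20, seed=seed,
        )
        tables, truth = simulate_trio(config, rep_index=0)
        for t in tables:
            path = outdir / f"{t.name}.tsv"
            _write_table(path, t.feature_ids.to_numpy(),
                         t.p_values.to_numpy(), t.lfc.to_numpy())
            written.append(path)
        truth_path = outdir / "truth.tsv"
        pd.DataFrame(
            truth.differential, columns=["exp1", "exp2", "exp3"],
            index=pd.Index(truth.feature_ids, name="feature_id"),
        ).astype(int).to_csv(truth_path, sep="\t")
        written.append(truth_path)
        config_path = outdir / "config.yaml"
        import yaml

        config_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
        written.append(config_path)

    elif kind == "geneset":
        set_size = 75
        members = rng.choice(m, size=set_size, replace=False)
        p = rng.uniform(size=m)
        p[members] = rng.beta(0.3, 1.0, set_size)
        table_path = outdir / "expression.tsv"
        _write_table(table_path, ids, p, rng.normal(0, 0.5, m))
        written.append(table_path)
        set_path = outdir / "geneset.txt"
        set_path.write_text("\n".join(sorted(ids[members])) + "\n")
        written.append(set_path)

    return written
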