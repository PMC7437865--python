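"""Readers/writers: CSV and ARFF feature tables, results export, replay.

CSV dialect: comma-delimited, UTF-8, header required, label column named
``label`` unless overridden (falling back to the last column).  ARFF goes
through ``scipy.io.arff`` for reading; a minimal writer covers round-trips
(numeric attributes plus one nominal class attribute, which is all the
framework's tables contain).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

from .data import ConfigurationError, FeatureTable
from .loop import RunConfig, RunResult, aggregate_runs


class ParseError(ValueError):
    """Malformed input table; the message names the offending row/column."""


def _frame_to_table(df: pd.DataFrame, label_col: str | None, source: str) -> FeatureTable:
    if df.empty:
        raise ParseError(f"{source}: empty table")
    if label_col is None:
        label_col = "label" if "label" in df.columns else df.columns[-1]
    if label_col not in df.columns:
        raise ParseError(f"{source}: missing label column {label_col!r}")
    labels = df[label_col].astype(str).to_numpy(dtype=object)
    feat_cols = [c for c in df.columns if c != label_col]
    if not feat_cols:
        raise ParseError(f"{source}: no feature columns besides {label_col!r}")
    features = np.empty((len(df), len(feat_cols)))
    for j, col in enumerate(feat_cols):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            raise ParseError(
                f"{source}: non-numeric feature value {df[col].iloc[bad[0]]!r} "
                f"at row {int(bad[0])}, column {col!r}")
        features[:, j] = converted.to_numpy(dtype=float)
    class_names = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    ids = [f"r{i}" for i in range(len(df))]
    return FeatureTable(sample_ids=ids, features=features, labels=labels,
                        class_names=class_names)


def read_table(path, fmt: str | None = None, label_col: str | None = None) -> FeatureTable:
    """Read a CSV or ARFF feature table (format inferred from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "arff" if path.suffix.lower() == ".arff" else "csv"
    if fmt == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            raise ParseError(f"{path}: empty file") from None
        return _frame_to_table(df, label_col, str(path))
    if fmt == "arff":
        data, meta = scipy_arff.loadarff(str(path))
        df = pd.DataFrame(data)
        for col in df.columns:  # nominal attributes arrive as bytes
            if df[col].dtype == object:
                df[col] = df[col].str.decode("utf-8")
        return _frame_to_table(df, label_col, str(path))
    raise ConfigurationError(f"unknown table format {fmt!r}")


def write_table_csv(table: FeatureTable, path) -> None:
    df = pd.DataFrame(table.features, columns=[f"f{j}" for j in range(table.d)])
    df["label"] = table.labels
    df.to_csv(path, index=False)


def write_table_arff(table: FeatureTable, path, relation: str = "dataset") -> None:
    """Minimal ARFF writer: numeric features + one nominal class attribute."""
    lines = [f"@relation {relation}", ""]
    lines += [f"@attribute f{j} numeric" for j in range(table.d)]
    classes = ",".join(str(c) for c in table.class_names)
    lines.append(f"@attribute label {{{classes}}}")
    lines += ["", "@data"]
    for row, lab in zip(table.features, table.labels):
        lines.append(",".join(repr(float(v)) for v in row) + f",{lab}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_results(result: RunResult, out_dir) -> dict[str, Path]:
    """Write curve.csv, runs.csv and config.json; returns the paths.

    ``config.json`` records the fully resolved configuration including each
    repetition's derived seeds, so a run can be replayed bit-identically
    from it alone.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curve_path, runs_path, cfg_path = out / "curve.csv", out / "runs.csv", out / "config.json"

    curve = aggregate_runs(result)
    # timings are non-deterministic; they stay in runs.csv so that curve.csv
    # is byte-reproducible from config.json alone
    curve = curve[["iteration", "mean_acc", "std_acc", "mean_n_labeled",
                   "mean_n_unlabeled", "support"]]
    curve.to_csv(curve_path, index=False, float_format="%.10g")

    rows = [dataclasses.asdict(rec) | {"repetition": rep.repetition}
            for rep in result.repetitions for rec in rep.records]
    pd.DataFrame(rows).to_csv(runs_path, index=False, float_format="%.10g")

    cfg = dataclasses.asdict(result.config)
    cfg["derived_seeds"] = [{"repetition": rep.repetition, "seed": rep.seed,
                             "split_seed": rep.split_seed} for rep in result.repetitions]
    cfg_path.write_text(json.dumps(cfg, indent=2) + "\n", encoding="utf-8")
    return {"curve": curve_path, "runs": runs_path, "config": cfg_path}


def read_config(path) -> RunConfig:
    """Rebuild a RunConfig from an emitted config.json (replay)."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    raw.pop("derived_seeds", None)
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    return RunConfig(**{k: v for k, v in raw.items() if k in fields})
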