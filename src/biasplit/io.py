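"""Cohort CSV and manifest/report JSON serialization.

Cohort files are plain CSV with a ``sample_id`` column followed by one
numeric column per label dimension.  Split manifests are schema-versioned
JSON carrying the per-sample group index plus full provenance (seed,
winning restart, final cost breakdown), so any split is reproducible and
auditable from its manifest alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_synth import Cohort
from .sampler import Assignment

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_manifest",
    "read_manifest",
    "ManifestError",
    "MANIFEST_SCHEMA_VERSION",
]

MANIFEST_SCHEMA_VERSION = 1


class ManifestError(ValueError):
    """Malformed or incompatible manifest file."""


def read_cohort(path: str | Path) -> Cohort:
    """Parse a cohort CSV; duplicate ids and non-numeric labels are
    rejected with the offending ids / row numbers."""
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "sample_id":
        raise ValueError(
            f"{path}: first column must be 'sample_id', got {df.columns[0]!r}"
        )
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sample ids: {sorted(set(dup))}")
    label_cols = list(df.columns[1:])
    if not label_cols:
        raise ValueError(f"{path}: no label columns")
    labels = np.empty((len(df), len(label_cols)))
    for j, col in enumerate(label_cols):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            rows = [i + 2 for i in np.flatnonzero(bad)]  # 1-based incl header
            raise ValueError(
                f"{path}: non-numeric or missing values in column {col!r} "
                f"at line(s) {rows[:10]}"
            )
        labels[:, j] = values.to_numpy()
    return Cohort(ids=tuple(df["sample_id"]), labels=labels, dims=tuple(label_cols))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    df = pd.DataFrame(cohort.labels, columns=list(cohort.dims))
    df.insert(0, "sample_id", list(cohort.ids))
    df.to_csv(path, index=False)


def write_manifest(
    assignment: Assignment,
    path: str | Path,
    cohort_file: str | None = None,
    dims: tuple[str, ...] | None = None,
    config: dict | None = None,
) -> None:
    payload = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "cohort_file": cohort_file,
        "dims": list(dims) if dims else None,
        "n_groups": assignment.n_groups,
        "group_of": dict(assignment.group_of),
        "config": config or {},
        "provenance": _jsonable(assignment.provenance),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_manifest(path: str | Path) -> Assignment:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ManifestError(f"{path}: not valid JSON ({exc})") from exc
    version = payload.get("schema_version")
    if version != MANIFEST_SCHEMA_VERSION:
        raise ManifestError(
            f"{path}: manifest schema version {version!r} not supported "
            f"(expected {MANIFEST_SCHEMA_VERSION})"
        )
    group_of = {str(k): int(v) for k, v in payload["group_of"].items()}
    n_groups = int(payload["n_groups"])
    if group_of and not set(group_of.values()) <= set(range(n_groups)):
        raise ManifestError(f"{path}: group indices outside [0, {n_groups})")
    return Assignment(
        group_of=group_of,
        n_groups=n_groups,
        provenance=payload.get("provenance", {}),
    )


def validate_manifest_covers(assignment: Assignment, cohort: Cohort) -> None:
    missing = sorted(set(cohort.ids) - set(assignment.group_of))
    extra = sorted(set(assignment.group_of) - set(cohort.ids))
    if missing or extra:
        raise ManifestError(
            f"manifest does not cover the cohort exactly "
            f"(missing {missing[:5]}, extra {extra[:5]})"
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
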