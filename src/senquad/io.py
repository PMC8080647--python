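"""TSV/JSON interchange for cohorts, scores and enrichment results.

Dialect: UTF-8 tab-separated files. Expression matrices have gene ids in
the first column and one column per sample; metadata tables are keyed by
``sample_id`` and must carry ``study_id``. Infinite odds ratios serialize as
``Inf``/``0`` and absent values as ``NA``. Output files start with
provenance comment lines (tool version, config hash, seed) so that reruns
with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import IO, Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .quadrant import EnrichmentResult, QuadrantAssignment, or_bar_export
from .scoring import CohortError, ExpressionCohort

__all__ = [
    "read_expression_tsv",
    "read_metadata_tsv",
    "load_cohort",
    "write_cohort",
    "write_score_table",
    "write_enrichment_tsv",
    "write_enrichment_json",
    "provenance_header",
]

NA = "NA"


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples matrix (first column gene id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata keyed by sample_id; requires study_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in df.columns:
        raise CohortError(f"{path}: metadata must have a 'sample_id' column")
    if "study_id" not in df.columns:
        raise CohortError(f"{path}: metadata must have a 'study_id' column")
    df = df.set_index("sample_id")
    for col in ("age",):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def load_cohort(
    expression_path: str | Path, metadata_path: str | Path
) -> ExpressionCohort:
    """Load and align an expression matrix with its metadata."""
    values = read_expression_tsv(expression_path)
    metadata = read_metadata_tsv(metadata_path)
    missing = set(values.columns) - set(metadata.index)
    if missing:
        raise CohortError(
            f"samples without metadata: {sorted(missing)[:5]}"
            f"{'...' if len(missing) > 5 else ''}"
        )
    metadata = metadata.loc[list(values.columns)]
    return ExpressionCohort(values, metadata)


def provenance_header(config: Mapping[str, Any] | None = None,
                      seed: int | None = None) -> str:
    """Deterministic provenance comment block (no timestamps)."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:16]
    lines = [f"# senquad {__version__}", f"# config_sha256 {digest}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    return "\n".join(lines) + "\n"


def _fmt(v: Any) -> str:
    if v is None:
        return NA
    if isinstance(v, float):
        if math.isnan(v):
            return NA
        if math.isinf(v):
            return "Inf" if v > 0 else "-Inf"
        return format(v, ".10g")
    return str(v)


def _write_frame(df: pd.DataFrame, path: str | Path, header: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header)
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_cohort(
    cohort: ExpressionCohort,
    expression_path: str | Path,
    metadata_path: str | Path,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> None:
    header = provenance_header(config, seed)
    values = cohort.values.reset_index(names="gene_id")
    _write_frame(values, expression_path, header)
    meta = cohort.metadata.reset_index(names="sample_id")
    _write_frame(meta, metadata_path, header)


def write_score_table(
    table: pd.DataFrame,
    path: str | Path,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> None:
    header = provenance_header(config, seed)
    coverage = table.attrs.get("coverage", {})
    if coverage:
        header += "".join(
            f"# coverage {name} {cov:.6g}\n" for name, cov in coverage.items()
        )
    _write_frame(table.reset_index(), path, header)


def write_enrichment_tsv(
    results: Sequence[EnrichmentResult],
    path: str | Path,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> None:
    _write_frame(or_bar_export(results), path, provenance_header(config, seed))


def write_enrichment_json(
    results: Sequence[EnrichmentResult],
    path: str | Path,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
) -> None:
    def jsonable(v: float) -> Any:
        if isinstance(v, float):
            if math.isnan(v):
                return None
            if math.isinf(v):
                return "Inf" if v > 0 else "-Inf"
        return v

    records = []
    for r in or_bar_export(results).to_dict(orient="records"):
        records.append({k: jsonable(v) for k, v in r.items()})
    payload = {
        "tool": f"senquad {__version__}",
        "config": dict(config or {}),
        "seed": seed,
        "results": records,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_scatter(
    assignment: QuadrantAssignment,
    groups: pd.Series,
    path: str | Path,
    config: Mapping[str, Any] | None = None,
) -> None:
    from .quadrant import scatter_export

    _write_frame(scatter_export(assignment, groups), path, provenance_header(config))
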