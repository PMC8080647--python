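"""Per-study z-standardization and gene-set mean scoring.

A gene-set score for a sample is the arithmetic mean of the within-study
z-standardized (log2-scale) expression values of the set's member genes.
Standardizing per study before pooling removes platform and batch offsets so
that samples from different studies can share one quadrant analysis; missing
values are omitted rather than imputed.

Also provides the comparative-Ct (ΔΔCt) relative-expression utility used for
qPCR validation against a housekeeping control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genesets import GeneSet, GeneSetRegistry

__all__ = [
    "ExpressionCohort",
    "zstandardize",
    "geneset_score",
    "score_table",
    "ddct_relative_expression",
]

#: Metadata columns recognized downstream (all optional except study_id).
OPTIONAL_METADATA = ("group", "age", "age_decade", "stage", "tissue")


class CohortError(ValueError):
    """Inconsistent expression matrix / metadata."""


@dataclass(frozen=True)
class ExpressionCohort:
    """A log2-scale expression matrix with aligned per-sample metadata.

    Parameters
    ----------
    values
        Genes × samples DataFrame (index = gene ids, columns = sample ids).
        NaN marks missing entries.
    metadata
        One row per sample, indexed by sample id; must contain ``study_id``.
    zscale
        True once the matrix holds within-study z-scores.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    zscale: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise CohortError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise CohortError("duplicate sample ids in expression matrix")
        if "study_id" not in self.metadata.columns:
            raise CohortError("metadata must contain a 'study_id' column")
        if list(self.metadata.index) != list(self.values.columns):
            missing = set(self.values.columns) ^ set(self.metadata.index)
            raise CohortError(
                f"metadata rows must match samples 1:1 (mismatch: {sorted(missing)})"
            )
        if self.metadata["study_id"].isna().any():
            bad = self.metadata.index[self.metadata["study_id"].isna()]
            raise CohortError(f"samples without study_id: {list(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def studies(self) -> list[str]:
        return list(pd.unique(self.metadata["study_id"]))


def zstandardize(cohort: ExpressionCohort, per_study: bool = True) -> ExpressionCohort:
    """Z-standardize each gene within each study stratum.

    For gene g in study s with nonzero variance over non-missing entries,
    z = (x − mean_gs) / sd_gs with the sample standard deviation (ddof=1).
    Zero-variance (gene, study) cells become missing (dropping them avoids
    deflating set scores toward zero) and are reported in a warning; missing
    entries stay missing.

    ``per_study=False`` standardizes over the pooled matrix instead — only
    appropriate when all samples share one platform/normalization.

    Raises
    ------
    CohortError
        If any study stratum has fewer than 2 samples.
    """
    if cohort.zscale:
        warnings.warn("cohort is already z-scale; standardizing again", stacklevel=2)
    strata = (
        cohort.metadata.groupby("study_id", sort=False).groups
        if per_study
        else {"<pooled>": cohort.metadata.index}
    )
    for study, samples in strata.items():
        if len(samples) < 2:
            raise CohortError(
                f"study {study!r} has {len(samples)} sample(s); "
                "need ≥2 to standardize"
            )
    out = pd.DataFrame(
        np.nan, index=cohort.values.index, columns=cohort.values.columns
    )
    degenerate: list[tuple[str, str]] = []
    for study, samples in strata.items():
        block = cohort.values.loc[:, samples]
        mean = block.mean(axis=1, skipna=True)
        sd = block.std(axis=1, ddof=1, skipna=True)
        zero_var = (sd == 0) | sd.isna()
        sd = sd.where(~zero_var)
        out.loc[:, samples] = block.sub(mean, axis=0).div(sd, axis=0)
        for g in block.index[zero_var & block.notna().any(axis=1)]:
            degenerate.append((str(g), str(study)))
    if degenerate:
        preview = ", ".join(f"{g}@{s}" for g, s in degenerate[:5])
        warnings.warn(
            f"{len(degenerate)} zero-variance (gene, study) cells set missing "
            f"(e.g. {preview})",
            stacklevel=2,
        )
    return replace(cohort, values=out, zscale=True)


def geneset_score(
    zcohort: ExpressionCohort,
    gene_set: GeneSet,
    min_coverage: float = 0.5,
) -> tuple[pd.Series, float]:
    """Per-sample mean of the set's available member-gene z-values.

    Returns ``(scores, coverage)`` where coverage = matched member genes /
    set size. Samples with no available member value get NaN. Coverage below
    ``min_coverage`` triggers a warning, not an error; a set matching zero
    matrix genes is an error.
    """
    if not zcohort.zscale:
        warnings.warn(
            f"scoring {gene_set.name!r} on a cohort not marked z-scale",
            stacklevel=2,
        )
    by_upper = {g.upper(): g for g in map(str, zcohort.values.index)}
    matched = [by_upper[s.upper()] for s in gene_set.symbols if s.upper() in by_upper]
    if not matched:
        raise CohortError(
            f"gene set {gene_set.name!r}: none of its {gene_set.size} symbols "
            "are present in the expression matrix"
        )
    coverage = len(matched) / gene_set.size
    if coverage < min_coverage:
        warnings.warn(
            f"gene set {gene_set.name!r}: coverage {coverage:.2f} below "
            f"{min_coverage:.2f} ({len(matched)}/{gene_set.size} genes matched)",
            stacklevel=2,
        )
    scores = zcohort.values.loc[matched].mean(axis=0, skipna=True)
    scores.name = gene_set.name
    return scores, coverage


def score_table(
    zcohort: ExpressionCohort,
    registry: GeneSetRegistry,
    set_names: list[str],
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Score several sets at once; metadata is carried through.

    Returns one row per sample with the metadata columns followed by one
    score column per requested set. Per-set coverage fractions are stored in
    ``result.attrs["coverage"]``. Duplicate requested names collapse to a
    single column with a warning; an unknown name raises KeyError listing the
    available sets.
    """
    unique_names = list(dict.fromkeys(set_names))
    if len(unique_names) < len(set_names):
        warnings.warn("duplicate set names requested; scoring each once", stacklevel=2)
    if not unique_names:
        warnings.warn("no set names requested; returning metadata only", stacklevel=2)
    table = zcohort.metadata.copy()
    table.index.name = "sample_id"
    coverage: dict[str, float] = {}
    for name in unique_names:
        gs = registry.get(name)  # KeyError lists available names
        scores, cov = geneset_score(zcohort, gs, min_coverage=min_coverage)
        table[name] = scores
        coverage[name] = cov
    table.attrs["coverage"] = coverage
    return table


def ddct_relative_expression(
    ct_target_case: float,
    ct_housekeeping_case: float,
    ct_target_control: float,
    ct_housekeeping_control: float,
) -> float:
    """Comparative-Ct fold change 2^(−ΔΔCt) against a housekeeping control.

    ΔΔCt = (Ct_target,case − Ct_hk,case) − (Ct_target,control − Ct_hk,control).
    All Ct values must be finite and positive.
    """
    cts = (
        ct_target_case,
        ct_housekeeping_case,
        ct_target_control,
        ct_housekeeping_control,
    )
    for ct in cts:
        if not math.isfinite(ct) or ct <= 0:
            raise ValueError(f"Ct values must be finite and > 0, got {ct!r}")
    ddct = (ct_target_case - ct_housekeeping_case) - (
        ct_target_control - ct_housekeeping_control
    )
    return float(2.0 ** (-ddct))
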