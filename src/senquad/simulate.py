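"""Synthetic multi-study expression cohorts with senescence structure.

The generator emulates the statistical features the quadrant analysis relies
on, without reproducing any particular real dataset:

* several independent studies, each with balanced senescent / nonsenescent
  groups and its own additive batch shift;
* coordinated downregulation of the TREX/NCT target genes in the senescent
  group (a shift of ``delta`` residual standard deviations);
* upregulation of the senescence markers (CDKN1A/CDKN2A) by ``delta_marker``;
* within-set gene–gene correlation ("multicollinearity") through one latent
  factor per functional category with loading ``rho``.

Gene g in sample i is drawn as::

    x[g,i] = mu_g + b_s(i) + rho * L_g * f_cat(g),i + shift_g(group_i)
             + sigma * sqrt(1 - rho^2) * e[g,i]

with mu_g ~ N(8, 1) baseline log2 abundance, b_s ~ N(0, tau) per study,
f ~ N(0, 1) per (category, sample), L_g = 1 for category members and 0 for
background genes, and e ~ N(0, 1). This is a Gaussian log2-intensity model
(microarray-like); it does not emulate probe-level artifacts, count noise,
or realistic clinical covariates.

``recovery_experiment`` runs the full simulate → score → quadrant-Fisher
pipeline over a parameter grid to measure type-I error, power, and effect
recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSetRegistry, default_registry
from .quadrant import assign_quadrants, contingency, fisher_exact_one_sided
from .scoring import ExpressionCohort, score_table, zstandardize

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "simulate_cohort",
    "recovery_experiment",
]

SENESCENT = "senescent"
NONSENESCENT = "nonsenescent"

#: Functional categories that receive a latent factor and the downregulation.
TARGET_CATEGORIES = ("TREX", "TREX2", "TREXAF", "NPC", "NTR", "RAN")


@dataclass(frozen=True)
class SimulationParams:
    """Generative-model parameters.

    Defaults describe a small multi-study in-vitro compendium: 5 studies of
    6 + 6 samples, a one-residual-sd downregulation of the target machinery
    in senescent samples, matching marker upregulation, moderate within-set
    correlation (rho = 0.5 ⇒ pairwise gene correlation rho² = 0.25 within a
    category), and study batch shifts comparable to the biological signal
    (tau = 1 on the log2 scale).
    """

    n_studies: int = 5
    n_per_group_per_study: int = 6
    n_background_genes: int = 200
    registry: GeneSetRegistry = field(default_factory=default_registry)
    delta: float = 1.0
    delta_marker: float = 1.0
    rho: float = 0.5
    tau: float = 1.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.n_per_group_per_study < 1:
            raise ValueError("counts must be ≥ 1")
        if self.n_background_genes < 1:
            raise ValueError("need ≥1 background gene")
        if self.delta < 0 or self.delta_marker < 0:
            raise ValueError("effect sizes must be ≥ 0")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be ≥ 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def n_samples(self) -> int:
        return self.n_studies * 2 * self.n_per_group_per_study


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside a simulated cohort."""

    samples: pd.DataFrame  # index sample_id; columns study_id, group
    genes: pd.DataFrame  # index gene_id; columns is_target, is_marker, category
    params: SimulationParams


def simulate_cohort(
    params: SimulationParams,
) -> tuple[ExpressionCohort, SyntheticTruth]:
    """Draw one cohort from the generative model; reproducible from the seed."""
    rng = np.random.default_rng(params.seed)
    reg = params.registry

    gene_ids: list[str] = []
    categories: list[str] = []
    for cat in TARGET_CATEGORIES:
        for s in reg[cat].symbols:
            gene_ids.append(s)
            categories.append(cat)
    n_targets = len(gene_ids)
    marker_symbols = list(reg["MARKER"].symbols)
    gene_ids += marker_symbols
    categories += ["MARKER"] * len(marker_symbols)
    width = len(str(params.n_background_genes))
    gene_ids += [f"BG{i:0{width}d}" for i in range(1, params.n_background_genes + 1)]
    categories += ["background"] * params.n_background_genes
    n_genes = len(gene_ids)

    sample_ids: list[str] = []
    study_ids: list[str] = []
    groups: list[str] = []
    for s in range(1, params.n_studies + 1):
        for grp in (SENESCENT, NONSENESCENT):
            for k in range(1, params.n_per_group_per_study + 1):
                sample_ids.append(f"study{s}_{grp[:3]}_{k:02d}")
                study_ids.append(f"study{s}")
                groups.append(grp)
    n_samples = len(sample_ids)

    mu = rng.normal(8.0, 1.0, size=n_genes)
    batch = rng.normal(0.0, params.tau, size=params.n_studies)
    study_index = np.fromiter(
        (int(s[5:]) - 1 for s in study_ids), dtype=int, count=n_samples
    )
    factors = rng.normal(0.0, 1.0, size=(len(TARGET_CATEGORIES), n_samples))
    noise = rng.normal(0.0, 1.0, size=(n_genes, n_samples))

    cat_arr = np.array(categories)
    is_target = np.isin(cat_arr, TARGET_CATEGORIES)
    is_marker = cat_arr == "MARKER"
    is_senescent = np.array([g == SENESCENT for g in groups])

    x = mu[:, None] + batch[study_index][None, :]
    for ci, cat in enumerate(TARGET_CATEGORIES):
        x[cat_arr == cat, :] += params.rho * factors[ci][None, :]
    shift = np.zeros((n_genes, n_samples))
    shift[np.ix_(is_target, is_senescent)] = -params.delta * params.sigma
    shift[np.ix_(is_marker, is_senescent)] = params.delta_marker * params.sigma
    x += shift + params.sigma * math.sqrt(1.0 - params.rho**2) * noise

    values = pd.DataFrame(x, index=gene_ids, columns=sample_ids)
    metadata = pd.DataFrame(
        {"study_id": study_ids, "group": groups}, index=pd.Index(sample_ids)
    )
    metadata.index.name = "sample_id"
    cohort = ExpressionCohort(values, metadata)
    genes = pd.DataFrame(
        {"is_target": is_target, "is_marker": is_marker, "category": categories},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return cohort, SyntheticTruth(metadata.copy(), genes, params)


# ---------------------------------------------------------------------------
# Operating-characteristic harness
# ---------------------------------------------------------------------------


def _hedges_delta(cohort: ExpressionCohort, truth: SyntheticTruth) -> float:
    """Estimate the downregulation shift delta from one cohort.

    Per target gene and study, the standardized group difference uses the
    pooled *within-group* sd with Hedges' small-sample correction
    J = 1 − 3/(4k − 1), k = n1 + n2 − 2, so it is an (almost) unbiased
    estimate of delta·sigma / sqrt(Vw), Vw = rho² + sigma²(1−rho²).
    Rescaling by sqrt(Vw)/sigma returns the per-gene shift in residual-sd
    units, i.e. the generator's delta. (The pipeline's own z-scores divide
    by the pooled over-groups sd instead and are attenuated to
    delta/sqrt(1 + delta²/4); that quantity is reported separately as
    ``mean_score_diff``.)
    """
    p = truth.params
    targets = truth.genes.index[truth.genes["is_target"]]
    values = cohort.values.loc[targets]
    sen = truth.samples["group"] == SENESCENT
    ds: list[float] = []
    for study in truth.samples["study_id"].unique():
        in_study = truth.samples["study_id"] == study
        x1 = values.loc[:, (in_study & sen).to_numpy()].to_numpy()
        x0 = values.loc[:, (in_study & ~sen).to_numpy()].to_numpy()
        n1, n0 = x1.shape[1], x0.shape[1]
        k = n1 + n0 - 2
        if k < 1:
            continue
        sp = np.sqrt(
            ((n1 - 1) * x1.var(axis=1, ddof=1) + (n0 - 1) * x0.var(axis=1, ddof=1))
            / k
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (x1.mean(axis=1) - x0.mean(axis=1)) / sp
        j = 1.0 - 3.0 / (4.0 * k - 1.0)
        ds.extend((j * d[np.isfinite(d)]).tolist())
    if not ds:
        return math.nan
    vw = p.rho**2 + p.sigma**2 * (1.0 - p.rho**2)
    return float(-np.mean(ds) * math.sqrt(vw) / p.sigma)


def _child_seed(base_seed: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(rep,))
    return int(ss.generate_state(1)[0] % (2**31))


def recovery_experiment(
    param_grid: Sequence[SimulationParams],
    n_reps: int,
    alpha: float = 0.05,
    x_set: str = "TREXes",
    y_set: str = "NCTFs",
    target_quadrant: str = "Q3",
    target_group: str = SENESCENT,
) -> pd.DataFrame:
    """Monte-Carlo operating characteristics of the full pipeline.

    For each grid point, ``n_reps`` cohorts are simulated (child seeds
    derived from the point's seed) and pushed through standardization,
    scoring, median-quadrant assignment and the one-sided Fisher test.

    Returns one row per grid point with the Q3 rejection rate (± MC standard
    error), the mean finite conditional-MLE OR and the fraction of infinite
    ORs, the mean senescent-vs-control score difference on the z scale, and
    the within-group-standardized effect estimate ``delta_hat``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be ≥ 1")
    rows = []
    for point in param_grid:
        rejections = 0
        ors: list[float] = []
        diffs: list[float] = []
        delta_hats: list[float] = []
        for rep in range(n_reps):
            p = replace(point, seed=_child_seed(point.seed, rep))
            cohort, truth = simulate_cohort(p)
            delta_hats.append(_hedges_delta(cohort, truth))
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                z = zstandardize(cohort)
                tbl = score_table(z, p.registry, [x_set, y_set])
                assignment = assign_quadrants(tbl[x_set], tbl[y_set])
                ct = contingency(assignment, tbl["group"], target_quadrant,
                                 target_group)
                res = fisher_exact_one_sided(ct, alternative="greater", alpha=alpha)
            if res.p <= alpha:
                rejections += 1
            ors.append(res.or_cmle)
            sen = tbl["group"] == SENESCENT
            d = float(
                (tbl.loc[sen, [x_set, y_set]].mean(axis=0)
                 - tbl.loc[~sen, [x_set, y_set]].mean(axis=0)).mean()
            )
            diffs.append(d)
        rate = rejections / n_reps
        finite = [o for o in ors if math.isfinite(o) and not math.isnan(o)]
        mean_diff = float(np.mean(diffs))
        rows.append(
            {
                "delta": point.delta,
                "n_samples": point.n_samples,
                "n_reps": n_reps,
                "rejection_rate": rate,
                "rejection_se": math.sqrt(rate * (1 - rate) / n_reps),
                "mean_or_finite": float(np.mean(finite)) if finite else math.nan,
                "frac_or_inf": sum(math.isinf(o) for o in ors) / n_reps,
                "mean_score_diff": mean_diff,
                "score_diff_se": float(np.std(diffs, ddof=1) / math.sqrt(n_reps))
                if n_reps > 1
                else math.nan,
                "delta_hat": float(np.mean(delta_hats)),
                "delta_hat_se": float(np.std(delta_hats, ddof=1) / math.sqrt(n_reps))
                if n_reps > 1
                else math.nan,
            }
        )
    return pd.DataFrame(rows)
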