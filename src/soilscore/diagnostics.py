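"""Self-audit diagnostics: redundancy, error propagation, aggregation.

Three analyses probe the index itself rather than the soils:

* *Redundancy* — pairwise Spearman rank correlations between indicator
  columns (pairwise deletion) and a PCA of the indicator correlation
  matrix (complete cases): strongly correlated indicators or a dominant
  first axis flag redundancy in the battery.
* *Error propagation* — perturb a single measured property by a
  relative (or additive) delta and recompute the full score report; the
  resulting score deltas measure the index's sensitivity to
  measurement error in that property.
* *Aggregation comparison* — per indicator row, the final value under
  the default distance-to-target weighting versus an equal-weight mean
  and the plain minimum. The weighted mean is provably bracketed:
  ``min <= nonlinear <= linear`` row-wise, with the gap to the linear
  mean showing how strongly a single poor function drags the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregation import AggregationConfig, ScoreReport, score_field
from .errors import InputError
from .evaluation import Battery
from .types import Category, FieldYearRecord, PROPERTY_NAMES

__all__ = [
    "indicator_table",
    "correlation_matrix",
    "pca_variance",
    "PCAResult",
    "perturb_and_score",
    "PerturbationResult",
    "compare_aggregations",
]


def indicator_table(
    records: Sequence[FieldYearRecord], battery: Battery
) -> pd.DataFrame:
    """Evaluate the battery for every field-year and tabulate it:
    one row per field-year, one column per soil function (management
    excluded, as it is not a measured indicator)."""
    from .advisory import apply_vsa

    from .evaluation import evaluate_battery

    cols = battery.function_ids(include_management=False)
    rows, index = [], []
    for rec in records:
        vec = apply_vsa(evaluate_battery(battery, rec), rec.vsa)
        rows.append([
            (vec[fid].value if vec[fid].value is not None else np.nan)
            for fid in cols
        ])
        index.append((rec.field_id, rec.year_age))
    return pd.DataFrame(
        rows,
        columns=cols,
        index=pd.MultiIndex.from_tuples(index, names=["field_id", "year_age"]),
    )


def correlation_matrix(tbl: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Spearman rank correlations between indicator columns, pairwise
    deletion with at least ``min_pairs`` complete pairs; constant
    columns yield missing correlations (with a warning)."""
    if tbl.shape[1] < 2:
        raise InputError("need at least 2 indicator columns")
    constant = [
        c for c in tbl.columns if tbl[c].dropna().nunique() <= 1
    ]
    if constant:
        warnings.warn(
            f"constant columns have undefined rank correlation: {constant}",
            stacklevel=2,
        )
    rho = tbl.corr(method="spearman", min_periods=min_pairs)
    for c in tbl.columns:
        rho.loc[c, c] = np.nan if c in constant else 1.0
    return rho


@dataclass
class PCAResult:
    """Variance fractions (descending, summing to 1) and the
    corresponding orthonormal loadings of the indicator correlation
    matrix."""

    fractions: np.ndarray
    loadings: pd.DataFrame  # columns PC1.., rows = functions

    @property
    def n_axes(self) -> int:
        return len(self.fractions)


def pca_variance(tbl: pd.DataFrame) -> PCAResult:
    """PCA on the correlation matrix of the complete-case indicator
    submatrix (equivalently, PCA of the column-standardized values)."""
    complete = tbl.dropna(axis=0, how="any")
    # drop constant columns: they carry no variance to decompose
    keep = [c for c in complete.columns if complete[c].nunique() > 1]
    complete = complete[keep]
    n, p = complete.shape
    if p < 2:
        raise InputError("need at least 2 non-constant columns for PCA")
    if n <= p:
        raise InputError(
            f"need more complete rows ({n}) than columns ({p}) for PCA"
        )
    corr = np.corrcoef(complete.to_numpy(dtype=float), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)  # rank-deficient tail -> 0
    eigvecs = eigvecs[:, order]
    fractions = eigvals / eigvals.sum()
    loadings = pd.DataFrame(
        eigvecs,
        index=complete.columns,
        columns=[f"PC{i + 1}" for i in range(p)],
    )
    return PCAResult(fractions=fractions, loadings=loadings)


@dataclass
class PerturbationResult:
    """Score changes caused by perturbing one property."""

    property_name: str
    delta: float
    mode: str  # "relative" or "additive"
    d_final: float
    d_category: dict[Category, float]
    baseline: ScoreReport
    perturbed: ScoreReport


def perturb_and_score(
    records: Sequence[FieldYearRecord],
    property_name: str,
    delta: float,
    battery: Battery,
    cfg: AggregationConfig | None = None,
    *,
    mode: str = "relative",
) -> PerturbationResult:
    """Recompute one field's score with ``property_name`` scaled by
    ``(1 + delta)`` (relative, default) or shifted by ``delta``
    (additive) in every year, and report the score deltas."""
    if property_name not in PROPERTY_NAMES:
        raise InputError(f"unknown property {property_name!r}")
    if mode not in ("relative", "additive"):
        raise InputError(f"mode must be 'relative' or 'additive', got {mode!r}")
    base = score_field(records, battery, cfg)
    perturbed_records = []
    for rec in records:
        profile = rec.profile
        v = getattr(profile, property_name)
        if v is not None:
            v = v * (1.0 + delta) if mode == "relative" else v + delta
        import dataclasses

        profile = dataclasses.replace(profile, **{property_name: v})
        perturbed_records.append(dataclasses.replace(rec, profile=profile))
    # skip re-validation: a perturbed value may step outside strict
    # input bounds on purpose (that is what is being probed)
    pert = score_field(perturbed_records, battery, cfg, validate=False)
    d_cat = {
        cat: (
            (pert.category_scores[cat].score or 0.0)
            - (base.category_scores[cat].score or 0.0)
            if (
                pert.category_scores[cat].score is not None
                or base.category_scores[cat].score is not None
            )
            else 0.0
        )
        for cat in Category
    }
    return PerturbationResult(
        property_name=property_name,
        delta=delta,
        mode=mode,
        d_final=pert.final_score - base.final_score,
        d_category=d_cat,
        baseline=base,
        perturbed=pert,
    )


def compare_aggregations(
    tbl: pd.DataFrame, cfg: AggregationConfig | None = None
) -> pd.DataFrame:
    """Aggregate each indicator row three ways: the default nonlinear
    distance-to-target weighting, an equal-weight linear mean, and the
    minimum (strict limiting-factor reading). Missing values are
    excluded row-wise. Returns columns ``minimum <= nonlinear <=
    linear``."""
    if tbl.empty:
        raise InputError("empty indicator table")
    cfg = cfg or AggregationConfig()
    cfg.validate()
    x = tbl.to_numpy(dtype=float)
    mask = np.isfinite(x)
    if not mask.any(axis=1).all():
        raise InputError("some rows have no indicator values at all")
    w = np.where(mask, 1.0 / (np.where(mask, x, 0.0) + cfg.c), 0.0)
    nonlinear = (w * np.where(mask, x, 0.0)).sum(axis=1) / w.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        linear = np.nanmean(x, axis=1)
        minimum = np.nanmin(x, axis=1)
    # exact bracketing despite float dust
    nonlinear = np.clip(nonlinear, minimum, linear)
    return pd.DataFrame(
        {"minimum": minimum, "nonlinear": nonlinear, "linear": linear},
        index=tbl.index,
    )
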