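"""Covariate screening: pairwise concurvity and univariate deviance ranking.

Concurvity is the nonlinear analogue of collinearity: the degree to which one
covariate's smooth can be reproduced from another covariate's basis.  It is
measured here symmetrically as the larger R-squared obtained when either
covariate (centered) is regressed on the other's smooth basis.  Pairs above a
threshold (default 0.3) are not allowed in the same model; within such a pair
the covariate with the higher deviance explained in a univariate model is
retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BasisError, MissingCovariateError, ScreeningError
from .gam_engine import SmoothSpec, build_basis, select_smoothing

__all__ = [
    "ConcurvityReport",
    "univariate_deviance",
    "pairwise_concurvity",
    "concurvity_report",
    "filter_covariates",
    "screen",
]

DEFAULT_CONCURVITY_THRESHOLD = 0.3


@dataclass
class ConcurvityReport:
    """Symmetric pairwise concurvities among a set of covariates."""

    covariates: list[str]
    values: pd.DataFrame  # square, symmetric, unit diagonal
    threshold: float = DEFAULT_CONCURVITY_THRESHOLD

    def pairs_above_threshold(self) -> list[tuple[str, str, float]]:
        out = []
        for i, a in enumerate(self.covariates):
            for b in self.covariates[i + 1 :]:
                v = float(self.values.loc[a, b])
                if v > self.threshold:
                    out.append((a, b, v))
        return out

    def to_frame(self) -> pd.DataFrame:
        return self.values.copy()


def univariate_deviance(records: pd.DataFrame, covariate: str, *, basis_dim: int = 5) -> float:
    """Deviance-explained fraction of a single-smooth shrinkage-selected GAM."""
    if covariate not in records.columns:
        raise MissingCovariateError(covariate, "univariate screening")
    try:
        fit = select_smoothing(records, [SmoothSpec(covariate, basis_dim=basis_dim)])
    except BasisError as exc:
        raise ScreeningError(str(exc)) from exc
    return fit.deviance_explained


def _basis_r2(target: np.ndarray, basis_block: np.ndarray) -> float:
    """R^2 of regressing the centered target on the basis block (+intercept)."""
    yc = target - target.mean()
    ss_tot = float(yc @ yc)
    if ss_tot <= 0:
        raise ScreeningError("degenerate (constant) covariate in concurvity")
    X = basis_block - basis_block.mean(axis=0)
    coef, *_ = np.linalg.lstsq(X, yc, rcond=None)
    resid = yc - X @ coef
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return float(np.clip(r2, 0.0, 1.0))


def pairwise_concurvity(
    records: pd.DataFrame,
    cov_a: str,
    cov_b: str,
    spec: SmoothSpec | None = None,
) -> float:
    """Symmetric concurvity of two covariates, in [0, 1].

    The larger of the two projection directions: covariate b regressed on the
    smooth basis of a, and vice versa.  Invariant to affine rescaling of
    either covariate (the basis construction is affine-equivariant).
    """
    for c in (cov_a, cov_b):
        if c not in records.columns:
            raise MissingCovariateError(c, "concurvity")
    basis_dim = spec.basis_dim if spec is not None else 5
    a = records[cov_a].to_numpy(dtype=float)
    b = records[cov_b].to_numpy(dtype=float)
    try:
        Ba = build_basis(SmoothSpec(cov_a, basis_dim=basis_dim), a).design_columns
        Bb = build_basis(SmoothSpec(cov_b, basis_dim=basis_dim), b).design_columns
    except BasisError as exc:
        raise ScreeningError(str(exc)) from exc
    return max(_basis_r2(b, Ba), _basis_r2(a, Bb))


def concurvity_report(
    records: pd.DataFrame,
    covariates: list[str],
    *,
    threshold: float = DEFAULT_CONCURVITY_THRESHOLD,
    basis_dim: int = 5,
) -> ConcurvityReport:
    """All pairwise concurvities among the given covariates."""
    k = len(covariates)
    vals = pd.DataFrame(np.eye(k), index=covariates, columns=covariates)
    for i, a in enumerate(covariates):
        for b in covariates[i + 1 :]:
            v = pairwise_concurvity(
                records, a, b, SmoothSpec(a, basis_dim=basis_dim)
            )
            vals.loc[a, b] = v
            vals.loc[b, a] = v
    return ConcurvityReport(covariates=list(covariates), values=vals, threshold=threshold)


def filter_covariates(
    report: ConcurvityReport, univariate_scores: dict[str, float]
) -> list[str]:
    """Resolve concurved pairs, keeping the higher-scoring covariate.

    Pairs above the threshold are resolved highest-concurvity first by
    dropping the member with the lower univariate deviance explained (ties
    broken by keeping the lexicographically smaller name).  The result
    contains no pair above the threshold and is deterministic.
    """
    for c in report.covariates:
        if c not in univariate_scores:
            raise ScreeningError(f"no univariate score for covariate {c!r}")
    retained = set(report.covariates)
    while True:
        pairs = [
            (v, a, b)
            for a, b, v in report.pairs_above_threshold()
            if a in retained and b in retained
        ]
        if not pairs:
            break
        # highest concurvity first; deterministic tie-break on the names
        v, a, b = max(pairs, key=lambda t: (t[0], t[1], t[2]))
        sa, sb = univariate_scores[a], univariate_scores[b]
        if sa > sb:
            drop = b
        elif sb > sa:
            drop = a
        else:
            drop = max(a, b)  # tied scores: keep lexicographically smaller
        retained.discard(drop)
    return [c for c in report.covariates if c in retained]


def screen(
    records: pd.DataFrame,
    covariates: list[str],
    *,
    threshold: float = DEFAULT_CONCURVITY_THRESHOLD,
    basis_dim: int = 5,
) -> tuple[list[str], ConcurvityReport, dict[str, float]]:
    """Full screening pass: concurvity + univariate ranking + filtering.

    Univariate deviances are only fitted when some pair actually exceeds the
    threshold; with no concurved pairs every covariate is retained and the
    scores dict is left empty.
    """
    report = concurvity_report(
        records, covariates, threshold=threshold, basis_dim=basis_dim
    )
    if not report.pairs_above_threshold():
        return list(covariates), report, {}
    scores = {
        c: univariate_deviance(records, c, basis_dim=basis_dim) for c in covariates
    }
    return filter_covariates(report, scores), report, scores
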