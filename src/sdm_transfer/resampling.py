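"""Spatial thinning, balanced down-sampling replicates and fold partitions.

Field surveys record presences and pseudo-absences in encounter order; points
closer than a thinning radius (default 400 m) are reduced to limit spatial
autocorrelation.  Because encounter rates differ between sites, each site's
data are randomly down-sampled (without replacement) to an equal number of
presences and absences, repeatedly, giving replicate balanced datasets; each
replicate carries a class-stratified three-fold partition for cross-validated
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ResamplingError

__all__ = [
    "ReplicateDesign",
    "thin_by_distance",
    "balance_downsample",
    "make_replicates",
    "DEFAULT_THINNING_RADIUS_M",
]

DEFAULT_THINNING_RADIUS_M = 400.0


def thin_by_distance(
    records: pd.DataFrame, radius: float = DEFAULT_THINNING_RADIUS_M
) -> pd.DataFrame:
    """Thin an encounter-ordered survey table.

    A presence within ``radius`` of the previously retained presence is
    dropped (only the initial presence of a cluster is kept); an absence
    within ``radius`` of any retained presence is dropped.  Row order is
    preserved.
    """
    for col in ("x", "y"):
        if col not in records.columns or records[col].isna().any():
            raise ResamplingError("thinning requires complete x/y coordinates")
    xy = records[["x", "y"]].to_numpy(dtype=float)
    resp = records["response"].to_numpy()
    keep_presence = np.zeros(len(records), dtype=bool)
    last_kept: np.ndarray | None = None
    for i in np.flatnonzero(resp == 1):
        if last_kept is None or np.hypot(*(xy[i] - last_kept)) >= radius:
            keep_presence[i] = True
            last_kept = xy[i]
    kept_xy = xy[keep_presence]
    keep = keep_presence.copy()
    for i in np.flatnonzero(resp == 0):
        if kept_xy.size == 0 or np.hypot(
            kept_xy[:, 0] - xy[i, 0], kept_xy[:, 1] - xy[i, 1]
        ).min() >= radius:
            keep[i] = True
    return records.loc[keep].copy()


def balance_downsample(records: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Down-sample the majority class (without replacement) to the minority size.

    Every minority-class record is kept; the result is a subset of the input
    with original row order preserved.
    """
    resp = records["response"].to_numpy()
    n_pres = int((resp == 1).sum())
    n_abs = int((resp == 0).sum())
    if n_pres == 0 or n_abs == 0:
        raise ResamplingError("both classes must be non-empty for balancing")
    rng = np.random.default_rng(seed)
    if n_pres == n_abs:
        return records.copy()
    minority = 1 if n_pres < n_abs else 0
    n_min = min(n_pres, n_abs)
    maj_pos = np.flatnonzero(resp != minority)
    sampled = rng.choice(maj_pos, size=n_min, replace=False)
    keep = np.zeros(len(records), dtype=bool)
    keep[resp == minority] = True
    keep[sampled] = True
    return records.loc[keep].copy()


def _near_equal_counts(total: int, k: int) -> np.ndarray:
    base = total // k
    out = np.full(k, base)
    out[: total % k] += 1
    return out


def _stratified_folds(resp: np.ndarray, k: int, rng: np.random.Generator):
    """Class-stratified partition into k folds with total sizes differing <= 1.

    Presence counts are assigned largest-first and absence counts
    largest-last, so per-fold totals stay balanced even when the class sizes
    are not divisible by k.
    """
    idx_p = np.flatnonzero(resp == 1)
    idx_a = np.flatnonzero(resp == 0)
    rng.shuffle(idx_p)
    rng.shuffle(idx_a)
    cp = _near_equal_counts(idx_p.size, k)
    ca = _near_equal_counts(idx_a.size, k)[::-1]
    folds = []
    sp = np.concatenate([[0], np.cumsum(cp)])
    sa = np.concatenate([[0], np.cumsum(ca)])
    for j in range(k):
        fold = np.concatenate([idx_p[sp[j] : sp[j + 1]], idx_a[sa[j] : sa[j + 1]]])
        folds.append(np.sort(fold))
    return folds


@dataclass
class ReplicateDesign:
    """One balanced down-sampled dataset with its fold partition."""

    site_or_region: str
    records: pd.DataFrame
    folds: list[np.ndarray]  # positional indices into records
    seed: int
    replicate_id: int

    def training_frame(self, held_out_fold: int) -> pd.DataFrame:
        idx = np.concatenate(
            [f for j, f in enumerate(self.folds) if j != held_out_fold]
        )
        return self.records.iloc[np.sort(idx)]

    def test_frame(self, held_out_fold: int) -> pd.DataFrame:
        return self.records.iloc[self.folds[held_out_fold]]

    def manifest_frame(self) -> pd.DataFrame:
        fold_of = np.empty(len(self.records), dtype=int)
        for j, f in enumerate(self.folds):
            fold_of[f] = j
        return pd.DataFrame(
            {
                "site_or_region": self.site_or_region,
                "replicate_id": self.replicate_id,
                "seed": self.seed,
                "row": np.arange(len(self.records)),
                "fold": fold_of,
            }
        )


def make_replicates(
    records: pd.DataFrame,
    n_replicates: int,
    base_seed: int,
    *,
    k_folds: int = 3,
    label: str | None = None,
) -> list[ReplicateDesign]:
    """Build ``n_replicates`` balanced datasets with fresh fold partitions.

    Replicate i uses seed ``base_seed + i`` for both the down-sampling draw
    and the fold shuffle, so every design is a pure function of
    (records, base_seed).
    """
    if n_replicates < 1:
        raise ResamplingError("n_replicates must be >= 1")
    if k_folds < 2:
        raise ResamplingError("k_folds must be >= 2")
    if label is None:
        sites = records["site"].unique() if "site" in records.columns else ["?"]
        label = "+".join(str(s) for s in sites)
    designs = []
    for i in range(n_replicates):
        seed = base_seed + i
        balanced = balance_downsample(records, seed).reset_index(drop=True)
        rng = np.random.default_rng(seed + 500_000)
        folds = _stratified_folds(
            balanced["response"].to_numpy(), k_folds, rng
        )
        designs.append(
            ReplicateDesign(
                site_or_region=label,
                records=balanced,
                folds=folds,
                seed=seed,
                replicate_id=i,
            )
        )
    return designs
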