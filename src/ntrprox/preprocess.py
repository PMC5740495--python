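"""Identification filtering, replicate merging, imputation, normalization.

Missing values in label-free proteomics are a mixture of two mechanisms
that require different treatment.  For every pairwise comparison of two
sample groups (n biological replicates each) a protein's missing pattern
is classified from the per-group observed counts alone:

* **MNAR** (missing not at random) — absent in all or all-but-one
  replicates of one group while present in at least n-1 replicates of
  the other: the absence itself carries biological signal, so the
  missing cells are filled with the lowest value observed in the same
  run ("MinDet" imputation).
* **MAR** (missing at random) — exactly one replicate missing in each
  group: filled by k-nearest-neighbour regression over similar protein
  profiles.
* **COMPLETE** — nothing missing.
* **EXCLUDED** — every other pattern carries too little information and
  the protein is dropped from that comparison.

After imputation, the comparison's columns are quantile-normalized so
that every run shares the same intensity distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import scipy.stats

from .iofmt import IntensityMatrix, ProteinRecord, StudyDesign, logger


class ContractError(ValueError):
    """A stage precondition is violated."""


class MissingClass(Enum):
    MNAR = "MNAR"
    MAR = "MAR"
    COMPLETE = "COMPLETE"
    EXCLUDED = "EXCLUDED"


# ---------------------------------------------------------------------------
# Identification filter
# ---------------------------------------------------------------------------

def filter_identifications(
    m: IntensityMatrix,
    design: StudyDesign,
    min_unique: int = 2,
    min_bio: int = 3,
) -> IntensityMatrix:
    """Keep proteins with enough unique peptides and replicate coverage.

    A protein survives if ``unique_peptides >= min_unique`` and it is
    observed in at least ``min_bio`` biological replicates of at least one
    cell line; a biological replicate counts as observed when any of its
    technical replicates is.
    """
    n_bio_by_line = {
        line: len(design.bio_groups(line)) for line in design.cell_lines
    }
    if min_bio > max(n_bio_by_line.values()):
        raise ContractError(
            f"min_bio={min_bio} exceeds the design's biological replicate "
            f"count {max(n_bio_by_line.values())}"
        )
    uniq_ok = np.array([p.unique_peptides >= min_unique for p in m.proteins])

    coverage_ok = np.zeros(len(m.proteins), dtype=bool)
    for line in design.cell_lines:
        groups = design.bio_groups(line)
        counts = np.zeros(len(m.proteins), dtype=int)
        for run_ids in groups.values():
            idx = m.run_index(run_ids)
            counts += m.observed[:, idx].any(axis=1)
        coverage_ok |= counts >= min_bio

    keep = uniq_ok & coverage_ok
    logger.info(
        "identification filter: %d of %d proteins retained",
        int(keep.sum()), len(keep),
    )
    return m.subset_proteins(keep)


# ---------------------------------------------------------------------------
# Technical replicate merge
# ---------------------------------------------------------------------------

def merge_technical(m: IntensityMatrix, design: StudyDesign) -> IntensityMatrix:
    """Collapse technical replicates to one column per (line, bio rep).

    The merged value is the mean of observed technical values; missing
    only if all technical replicates are missing.
    """
    if m.scale == "raw":
        raise ContractError("merge_technical expects log2-scale values")
    new_runs: list[str] = []
    cols_vals: list[np.ndarray] = []
    cols_obs: list[np.ndarray] = []
    for line in design.cell_lines:
        for bio, run_ids in sorted(design.bio_groups(line).items()):
            present = [r for r in run_ids if r in m.runs]
            if not present:
                continue
            idx = m.run_index(present)
            sub = m.values[:, idx]
            obs = m.observed[:, idx]
            n_obs = obs.sum(axis=1)
            total = np.where(obs, sub, 0.0).sum(axis=1)
            merged = total / np.maximum(n_obs, 1)
            any_obs = n_obs > 0
            new_runs.append(f"{line}_b{bio}")
            cols_vals.append(np.where(any_obs, merged, np.nan))
            cols_obs.append(any_obs)
    return IntensityMatrix(
        proteins=list(m.proteins), runs=new_runs,
        values=np.column_stack(cols_vals), observed=np.column_stack(cols_obs),
        scale=m.scale, ibaq=m.ibaq,
    )


def merged_run_id(cell_line: str, bio_rep: int) -> str:
    return f"{cell_line}_b{bio_rep}"


def merged_runs_for_line(design: StudyDesign, line: str) -> list[str]:
    return [merged_run_id(line, b) for b in sorted(design.bio_groups(line))]


# ---------------------------------------------------------------------------
# Missingness classification
# ---------------------------------------------------------------------------

def classify_missing(
    obs_a: int, obs_b: int, n_per_group: int = 4, n_b: int | None = None,
) -> MissingClass:
    """Classify one protein's missing pattern in one pairwise comparison.

    Pure, symmetric function of the two groups' observed counts.  With
    quadruplicate groups the rules are: MNAR when one group has at most
    one observed value and the other at least three; MAR when each group
    is missing exactly one value; COMPLETE with nothing missing; every
    other pattern is EXCLUDED.  Unequal group sizes (an NTR group versus
    the pooled control set) use the same thresholds as fractions:
    "at most one of four" becomes an observed fraction <= 1/4, "at least
    three of four" a fraction >= 3/4, and "missing one of four" a missing
    count between 1 and a quarter of the group.
    """
    n_a = n_per_group
    if n_b is None:
        n_b = n_per_group
    if not 0 <= obs_a <= n_a:
        raise ContractError(f"observed count {obs_a} outside [0, {n_a}]")
    if not 0 <= obs_b <= n_b:
        raise ContractError(f"observed count {obs_b} outside [0, {n_b}]")
    if obs_a == n_a and obs_b == n_b:
        return MissingClass.COMPLETE
    fa, fb = obs_a / n_a, obs_b / n_b
    if (fa <= 0.25 and fb >= 0.75) or (fb <= 0.25 and fa >= 0.75):
        return MissingClass.MNAR
    miss_a, miss_b = n_a - obs_a, n_b - obs_b
    if 1 <= miss_a <= n_a / 4 and 1 <= miss_b <= n_b / 4:
        return MissingClass.MAR
    return MissingClass.EXCLUDED


def classify_matrix(
    m: IntensityMatrix, cols_a: np.ndarray, cols_b: np.ndarray,
) -> np.ndarray:
    """Vector of MissingClass per protein for one two-group comparison."""
    n_a, n_b = len(cols_a), len(cols_b)
    obs_a = m.observed[:, cols_a].sum(axis=1)
    obs_b = m.observed[:, cols_b].sum(axis=1)
    return np.array([
        classify_missing(int(a), int(b), n_per_group=n_a, n_b=n_b)
        for a, b in zip(obs_a, obs_b)
    ])


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

class ImputationError(ValueError):
    pass


def impute_mnar(
    values: np.ndarray, observed: np.ndarray, targets: np.ndarray,
) -> np.ndarray:
    """MinDet: fill target cells with the minimum observed value of their run.

    ``targets`` is a boolean mask of cells to fill (missing cells of
    MNAR-classified proteins).  Returns a new value matrix.
    """
    out = values.copy()
    for j in range(values.shape[1]):
        col_targets = targets[:, j] & ~observed[:, j]
        if not col_targets.any():
            continue
        col_obs = observed[:, j]
        if not col_obs.any():
            raise ImputationError(
                f"column {j} has no observed values to draw a minimum from"
            )
        out[col_targets, j] = values[col_obs, j].min()
    return out


def impute_mar(
    values: np.ndarray, observed: np.ndarray, targets: np.ndarray,
    k: int = 10,
) -> np.ndarray:
    """kNN imputation of MAR cells.

    Neighbour distance is the Euclidean distance over mutually observed
    columns divided by the shared-column count (so rows sharing few
    columns are not favoured); neighbours must themselves be observed in
    the target column.  With no eligible neighbour the row's own observed
    mean is used and a warning logged.
    """
    out = values.copy()
    rows = np.flatnonzero((targets & ~observed).any(axis=1))
    for i in rows:
        for j in np.flatnonzero(targets[i] & ~observed[i]):
            eligible = np.flatnonzero(observed[:, j])
            eligible = eligible[eligible != i]
            if eligible.size == 0:
                row_obs = observed[i]
                out[i, j] = values[i, row_obs].mean()
                logger.warning(
                    "kNN imputation row %d col %d: no eligible neighbour, "
                    "falling back to row mean", i, j,
                )
                continue
            dists = np.full(eligible.size, np.inf)
            for e_idx, g in enumerate(eligible):
                shared = observed[i] & observed[g]
                n_shared = int(shared.sum())
                if n_shared == 0:
                    continue
                diff = values[i, shared] - values[g, shared]
                dists[e_idx] = np.sqrt(np.sum(diff**2)) / n_shared
            order = np.argsort(dists, kind="stable")
            order = order[np.isfinite(dists[order])]
            if order.size == 0:
                row_obs = observed[i]
                out[i, j] = values[i, row_obs].mean()
                logger.warning(
                    "kNN imputation row %d col %d: no comparable neighbour, "
                    "falling back to row mean", i, j,
                )
                continue
            chosen = eligible[order[:k]]
            out[i, j] = values[chosen, j].mean()
    return out


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a complete matrix.

    Column c's i-th smallest value is replaced by the mean of every
    column's i-th smallest value; ties within a column receive the mean
    over their rank range.
    """
    if np.isnan(values).any():
        raise ContractError("quantile_normalize requires a complete matrix")
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        # average ranks handle ties as the mean of their rank range
        ranks = scipy.stats.rankdata(values[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    return out


# ---------------------------------------------------------------------------
# Per-comparison pipeline
# ---------------------------------------------------------------------------

@dataclass
class ComparisonData:
    """A fully imputed and normalized two-group submatrix.

    ``protein_idx`` maps its rows back into the parent matrix; proteins
    EXCLUDED for this comparison are absent.
    """

    protein_idx: np.ndarray
    group_ids: list[str]
    values_a: np.ndarray
    values_b: np.ndarray
    classes: np.ndarray


def prepare_comparison(
    m: IntensityMatrix,
    runs_a: list[str],
    runs_b: list[str],
    knn_k: int = 10,
) -> ComparisonData:
    """Classify, impute (MinDet then kNN) and quantile-normalize one
    pairwise comparison of merged-replicate columns."""
    cols_a = m.run_index(runs_a)
    cols_b = m.run_index(runs_b)
    classes = classify_matrix(m, cols_a, cols_b)
    keep = classes != MissingClass.EXCLUDED
    idx = np.flatnonzero(keep)

    cols = np.concatenate([cols_a, cols_b])
    vals = m.values[np.ix_(idx, cols)]
    obs = m.observed[np.ix_(idx, cols)]
    cls = classes[idx]

    mnar_rows = cls == MissingClass.MNAR
    mar_rows = cls == MissingClass.MAR
    vals = impute_mnar(vals, obs, mnar_rows[:, None] & ~obs)
    obs_after_mnar = obs | (mnar_rows[:, None] & ~obs)
    vals = impute_mar(vals, obs_after_mnar, mar_rows[:, None] & ~obs, k=knn_k)

    vals = quantile_normalize(vals)
    n_a = len(runs_a)
    return ComparisonData(
        protein_idx=idx,
        group_ids=[m.proteins[i].group_id for i in idx],
        values_a=vals[:, :n_a],
        values_b=vals[:, n_a:],
        classes=cls,
    )
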