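"""NTR-specificity scoring from all-vs-all sample comparisons.

A protein that is enriched in one NTR sample relative to *many* other
NTR samples is a specific interactor of that receptor; a protein pulled
down by every receptor (an FG-nucleoporin, say) is shared machinery.
For every ordered pair of NTR samples (s, s') a one-sided moderated test
gives the p-value that a protein is enriched in s over s'.  Per
(protein, sample) the significant p-values (p < 0.01) are combined:

* specificity score = -log10 of the product of the significant p-values
  (0 when none are significant) — proteins enriched against many other
  samples accumulate a high score, proteins enriched everywhere have few
  significant pairwise contrasts and are penalized;
* average adjusted fold change over the same contrasts;
* Fisher's combination X2 = -2 * sum(ln p_i) on 2k df yields a single
  p-value per (protein, sample), Benjamini-Hochberg adjusted over the
  whole table; entries with adjusted Fisher p below 0.01 are the
  specific interactor calls.

Fisher's method is applied, deliberately, to post-selection p-values
(only those already below the significance cut enter the product); the
resulting anti-conservativeness is part of the scoring scheme, not a
bug, and is shared by the downstream BH adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .diffexpr import run_comparison
from .iofmt import IntensityMatrix, StudyDesign
from .nipcall import bh_adjust
from .preprocess import ContractError, merged_runs_for_line, prepare_comparison


def combine_specificity(
    entries: list[tuple[float, float]],
) -> tuple[float, float, float, float]:
    """Combine significant (p, FC) pairs into (score, avgFC, X2, fisher_p).

    The empty list returns (0, nan, 0, 1): no significant contrast means
    no specificity evidence.
    """
    if not entries:
        return 0.0, float("nan"), 0.0, 1.0
    ps = np.array([p for p, _ in entries], dtype=float)
    fcs = np.array([fc for _, fc in entries], dtype=float)
    log_p = np.log(ps)
    score = float(-np.sum(log_p) / np.log(10.0))
    x2 = float(-2.0 * np.sum(log_p))
    fisher_p = float(scipy.stats.chi2.sf(x2, df=2 * len(entries)))
    return score, float(fcs.mean()), x2, fisher_p


def pairwise_all(
    m: IntensityMatrix,
    design: StudyDesign,
    p_sig: float = 0.01,
    knn_k: int = 10,
) -> dict[str, dict[str, list[tuple[float, float]]]]:
    """All-vs-all NTR comparisons; collect significant enrichment evidence.

    For S NTR samples runs the S*(S-1) directed comparisons (each
    unordered pair is fitted once, yielding both directions).  Returns,
    per sample s, a map protein -> list of (p, FC) over the contrasts
    where the protein was enriched in s at p < ``p_sig``.  ``m`` must
    hold merged biological-replicate columns on the log2 scale.
    """
    samples = design.ntr_lines
    if len(samples) < 2:
        raise ContractError("pairwise_all needs at least two NTR samples")
    evidence: dict[str, dict[str, list[tuple[float, float]]]] = {
        s: {} for s in samples
    }
    for sa, sb in itertools.combinations(samples, 2):
        comp = prepare_comparison(
            m, merged_runs_for_line(design, sa),
            merged_runs_for_line(design, sb), knn_k=knn_k,
        )
        res_a, res_b = run_comparison(
            comp.values_a, comp.values_b, comp.group_ids,
        )
        for g, p, fc in zip(comp.group_ids, res_a.p, res_a.fc):
            if p < p_sig:
                evidence[sa].setdefault(g, []).append((float(p), float(fc)))
        for g, p, fc in zip(comp.group_ids, res_b.p, res_b.fc):
            if p < p_sig:
                evidence[sb].setdefault(g, []).append((float(p), float(-fc)))
    return evidence


@dataclass
class SpecificityTable:
    """Long-format per-(protein, sample) specificity results."""

    table: pd.DataFrame
    # columns: protein, sample, k, score, avg_fc, fisher_x2, fisher_p,
    #          fisher_p_adj, significant
    alpha: float

    def significant_pairs(self) -> set[tuple[str, str]]:
        t = self.table
        return set(
            zip(t.loc[t.significant, "protein"], t.loc[t.significant, "sample"])
        )


def build_table(
    evidence: dict[str, dict[str, list[tuple[float, float]]]],
    proteins: list[str] | None = None,
) -> pd.DataFrame:
    """Tabulate combine_specificity over every (protein, sample) pair.

    Only pairs with at least one significant contrast are materialized
    unless an explicit protein universe is given.
    """
    rows = []
    for sample, per_protein in evidence.items():
        universe = proteins if proteins is not None else sorted(per_protein)
        for g in universe:
            entries = per_protein.get(g, [])
            score, avg_fc, x2, fisher_p = combine_specificity(entries)
            rows.append({
                "protein": g, "sample": sample, "k": len(entries),
                "score": score, "avg_fc": avg_fc,
                "fisher_x2": x2, "fisher_p": fisher_p,
            })
    return pd.DataFrame(
        rows,
        columns=["protein", "sample", "k", "score", "avg_fc",
                 "fisher_x2", "fisher_p"],
    )


def adjust_and_flag(table: pd.DataFrame, alpha: float = 0.01) -> SpecificityTable:
    """BH-adjust Fisher p-values over the whole table and flag calls."""
    table = table.copy()
    if table.empty:
        table["fisher_p_adj"] = []
        table["significant"] = []
        return SpecificityTable(table=table, alpha=alpha)
    table["fisher_p_adj"] = bh_adjust(table["fisher_p"].to_numpy())
    table["significant"] = (table["fisher_p_adj"] < alpha) & (table["k"] > 0)
    return SpecificityTable(table=table, alpha=alpha)


def score_specificity(
    m: IntensityMatrix,
    design: StudyDesign,
    p_sig: float = 0.01,
    alpha: float = 0.01,
    knn_k: int = 10,
) -> SpecificityTable:
    """End-to-end specificity scoring on a merged-replicate matrix."""
    evidence = pairwise_all(m, design, p_sig=p_sig, knn_k=knn_k)
    # BH over the full protein x sample grid (k = 0 entries enter with p = 1)
    return adjust_and_flag(
        build_table(evidence, proteins=m.group_ids), alpha=alpha,
    )
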