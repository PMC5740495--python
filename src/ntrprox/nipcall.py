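"""Calling the NTR-interacting proteome (NIP) and background proteome.

Every NTR sample is compared one-sidedly against the pooled control set,
in both directions.  For each protein, the per-comparison p-values of
one direction are combined with the Simes global test,

    p_Simes = min_i  m * p_(i) / i        (ascending sort, m values),

which by the closed-testing shortcut equals the minimum Simes-adjusted
elementary p-value over all intersection hypotheses: it is small exactly
when the protein is truly enriched in at least one comparison.  The
per-protein Simes p-values are then Benjamini-Hochberg adjusted across
proteins within each direction; proteins below alpha in the NTR-enriched
direction form the NIP, those below alpha in the control-enriched
direction the background proteome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .iofmt import logger
from .preprocess import ContractError


def simes_pvalue(p: np.ndarray) -> float:
    """Simes combination of m p-values: min over i of m*p_(i)/i, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ContractError("simes_pvalue needs at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ContractError("p-values must lie in (0, 1]")
    m = p.size
    srt = np.sort(p)
    ranks = np.arange(1, m + 1)
    return float(min(1.0, (m * srt / ranks).min()))


def hommel_adjust(p: np.ndarray) -> np.ndarray:
    """Closed-testing adjusted p-values with Simes local tests (Hommel).

    For elementary hypothesis i the adjusted p-value is the maximum Simes
    p-value over every intersection hypothesis containing i; Hommel's
    shortcut computes all of them in O(m^2) instead of enumerating the
    2^m - 1 intersections.  Order-preserving.
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        raise ContractError("hommel_adjust needs at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ContractError("p-values must lie in (0, 1]")
    if n == 1:
        return p.copy()
    o = np.argsort(p, kind="stable")
    ps = p[o]
    i = np.arange(1, n + 1)
    q = np.full(n, (n * ps / i).min())
    pa = q.copy()
    for m in range(n - 1, 1, -1):
        i1 = np.arange(n - m + 1)          # 0-based: first n-m+1 entries
        i2 = np.arange(n - m + 1, n)
        q1 = (m * ps[i2] / np.arange(2, m + 1)).min()
        q[i1] = np.minimum(m * ps[i1], q1)
        q[i2] = q[n - m]
        pa = np.maximum(pa, q)
    out = np.empty(n)
    out[o] = np.maximum(pa, ps)
    return out


def min_simes_adjusted(p: np.ndarray) -> float:
    """Minimum Simes-adjusted elementary p-value of one protein.

    Small exactly when the protein is truly enriched in at least one of
    its comparisons: the closed-testing analogue of "significant in at
    least one NTR sample".
    """
    return float(hommel_adjust(p).min())


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class NipResult:
    """Per-protein NIP/background call."""

    table: pd.DataFrame
    # columns: protein, m, simes_nip, simes_bg, adj_nip, adj_bg, label
    alpha: float

    @property
    def nip(self) -> set[str]:
        t = self.table
        return set(t.loc[t.label == "NIP", "protein"])

    @property
    def background(self) -> set[str]:
        t = self.table
        return set(t.loc[t.label == "BACKGROUND", "protein"])


def call_nip(
    comparisons: list[tuple[dict[str, float], dict[str, float]]],
    alpha: float = 0.1,
) -> NipResult:
    """Combine NTR-vs-control comparisons into NIP/background calls.

    ``comparisons`` holds, per NTR sample, a pair of per-protein p-value
    maps: (NTR-enriched direction, control-enriched direction).  Proteins
    excluded from a comparison are simply absent from its maps.
    """
    per_protein_nip: dict[str, list[float]] = {}
    per_protein_bg: dict[str, list[float]] = {}
    for p_nip, p_bg in comparisons:
        for g, p in p_nip.items():
            per_protein_nip.setdefault(g, []).append(p)
        for g, p in p_bg.items():
            per_protein_bg.setdefault(g, []).append(p)

    proteins = sorted(set(per_protein_nip) | set(per_protein_bg))
    rows = []
    for g in proteins:
        ps_nip = per_protein_nip.get(g, [])
        ps_bg = per_protein_bg.get(g, [])
        if not ps_nip and not ps_bg:
            logger.warning("protein %s has no available comparisons; dropped", g)
            continue
        rows.append({
            "protein": g,
            "m": max(len(ps_nip), len(ps_bg)),
            "simes_nip": min_simes_adjusted(ps_nip) if ps_nip else 1.0,
            "simes_bg": min_simes_adjusted(ps_bg) if ps_bg else 1.0,
        })
    table = pd.DataFrame(rows, columns=["protein", "m", "simes_nip", "simes_bg"])
    if table.empty:
        table["adj_nip"] = table["adj_bg"] = table["label"] = []
        return NipResult(table=table, alpha=alpha)
    table["adj_nip"] = bh_adjust(table["simes_nip"].to_numpy())
    table["adj_bg"] = bh_adjust(table["simes_bg"].to_numpy())

    labels = []
    for _, row in table.iterrows():
        nip_hit = row.adj_nip < alpha
        bg_hit = row.adj_bg < alpha
        if nip_hit and bg_hit:
            logger.warning(
                "protein %s significant in both directions "
                "(adj NIP %.3g, adj background %.3g); assigning the smaller",
                row.protein, row.adj_nip, row.adj_bg,
            )
            labels.append("NIP" if row.adj_nip <= row.adj_bg else "BACKGROUND")
        elif nip_hit:
            labels.append("NIP")
        elif bg_hit:
            labels.append("BACKGROUND")
        else:
            labels.append("NEITHER")
    table["label"] = labels
    return NipResult(table=table, alpha=alpha)
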