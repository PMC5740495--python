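"""Biotinylation-site-level analysis.

BirA* biotinylates lysines of proximal proteins; the modified peptides
can be identified directly, localizing the contact to a residue.  This
module filters site observations by replicate support, normalizes and
median-centers their intensities for cross-sample comparison, maps the
residues onto structural domain annotations (FG repeats, RAN-binding
domains, importin-binding sites, ...), and relates per-protein site
counts to protein abundance (iBAQ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .iofmt import StudyDesign, logger


@dataclass
class SiteMatrix:
    """(protein, residue position) x runs intensities with missingness mask."""

    sites: list[tuple[str, int]]
    runs: list[str]
    values: np.ndarray
    observed: np.ndarray
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate (protein, position) sites")
        n, m = len(self.sites), len(self.runs)
        if self.values.shape != (n, m):
            raise ValueError(f"values shape {self.values.shape} != ({n},{m})")
        self.values = np.where(self.observed, self.values, np.nan)

    def to_log2(self) -> "SiteMatrix":
        if self.scale != "raw":
            return self
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log2(self.values)
        return SiteMatrix(sites=list(self.sites), runs=list(self.runs),
                          values=vals, observed=self.observed.copy(),
                          scale="log2")

    def run_index(self, run_ids) -> np.ndarray:
        pos = {r: i for i, r in enumerate(self.runs)}
        return np.array([pos[r] for r in run_ids], dtype=int)


@dataclass(frozen=True)
class DomainAnnotation:
    protein: str
    domain: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"domain {self.domain} on {self.protein}: start > end"
            )


def filter_sites(
    sm: SiteMatrix, design: StudyDesign, min_bio: int = 2,
) -> SiteMatrix:
    """Keep sites observed in >= min_bio biological replicates of >= 1 line.

    A biological replicate counts as observed if any of its technical
    replicates is.  Idempotent.
    """
    keep = np.zeros(len(sm.sites), dtype=bool)
    for line in design.cell_lines:
        counts = np.zeros(len(sm.sites), dtype=int)
        for run_ids in design.bio_groups(line).values():
            present = [r for r in run_ids if r in sm.runs]
            if not present:
                continue
            idx = sm.run_index(present)
            counts += sm.observed[:, idx].any(axis=1)
        keep |= counts >= min_bio
    logger.info("site filter: %d of %d sites retained",
                int(keep.sum()), len(keep))
    idx = np.flatnonzero(keep)
    return SiteMatrix(
        sites=[sm.sites[i] for i in idx], runs=list(sm.runs),
        values=sm.values[idx], observed=sm.observed[idx], scale=sm.scale,
    )


def normalize_center(sm: SiteMatrix) -> SiteMatrix:
    """Per-run median normalization then per-site median centering.

    Each run's median over observed sites is subtracted from that run
    (location normalization on the log2 scale), then each site's median
    over the runs where it is observed is subtracted from that site.
    The output is invariant to per-run additive shifts of the input.
    """
    if sm.scale == "raw":
        raise ValueError("normalize_center expects log2-scale values")
    vals = sm.values.copy()
    with np.errstate(all="ignore"):
        run_median = np.nanmedian(vals, axis=0)
    vals = vals - run_median[None, :]
    with np.errstate(all="ignore"):
        site_median = np.nanmedian(vals, axis=1)
    vals = vals - site_median[:, None]
    return SiteMatrix(sites=list(sm.sites), runs=list(sm.runs),
                      values=vals, observed=sm.observed.copy(),
                      scale="normalized")


def map_sites_to_domains(
    sm: SiteMatrix, annotations: list[DomainAnnotation],
    unannotated_label: str = "linker/disordered",
) -> dict[tuple[str, int], list[str]]:
    """Map each site to every domain containing it (1-based inclusive).

    Sites outside all annotated domains are labeled as linker/disordered
    sequence; overlapping domains are all reported.  No site is dropped.
    """
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein, []).append(ann)
    out: dict[tuple[str, int], list[str]] = {}
    for protein, position in sm.sites:
        labels = [
            ann.domain for ann in by_protein.get(protein, [])
            if ann.start <= position <= ann.end
        ]
        out[(protein, position)] = labels or [unannotated_label]
    return out


def site_count_vs_abundance(
    sm: SiteMatrix,
    ibaq: pd.DataFrame,
    design: StudyDesign,
) -> pd.DataFrame:
    """Per (protein, cell line): observed-site count vs mean iBAQ.

    Returns a long table with one row per (protein, line) plus a
    ``spearman`` column repeating the per-protein rank correlation of
    site count with iBAQ across lines (NaN when fewer than 3 lines pair
    up or either series is constant).
    """
    proteins = sorted({p for p, _ in sm.sites})
    rows = []
    site_idx: dict[str, np.ndarray] = {}
    for g in proteins:
        site_idx[g] = np.array([i for i, (p, _) in enumerate(sm.sites) if p == g])
    for g in proteins:
        for line in design.cell_lines:
            run_ids = [r for rs in design.bio_groups(line).values()
                       for r in rs if r in sm.runs]
            if not run_ids:
                continue
            idx = sm.run_index(run_ids)
            n_sites = int(sm.observed[np.ix_(site_idx[g], idx)].any(axis=1).sum())
            ibaq_cols = [r for r in run_ids if r in ibaq.columns]
            val = np.nan
            if ibaq_cols and g in ibaq.index:
                arr = ibaq.loc[g, ibaq_cols].to_numpy(dtype=float)
                if np.isfinite(arr).any():
                    val = float(np.nanmean(arr))
            rows.append({"protein": g, "line": line,
                         "n_sites": n_sites, "ibaq": val})
    table = pd.DataFrame(rows, columns=["protein", "line", "n_sites", "ibaq"])
    rhos = {}
    for g, sub in table.groupby("protein"):
        paired = sub.dropna(subset=["ibaq"])
        if len(paired) < 3 or paired.n_sites.nunique() < 2 \
                or paired.ibaq.nunique() < 2:
            rhos[g] = np.nan
            continue
        rho, _ = scipy.stats.spearmanr(paired.n_sites, paired.ibaq)
        rhos[g] = float(rho)
    table["spearman"] = table["protein"].map(rhos)
    return table
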