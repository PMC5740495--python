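"""Readers and writers for the pipeline's external tables.

All on-disk formats are plain tab-separated text:

* protein-group quantification tables in the MaxQuant ``proteinGroups.txt``
  dialect (``Majority protein IDs``, ``Gene names``, ``Unique peptides``,
  ``Reverse``, ``Potential contaminant``, per-run ``Intensity <run>`` and
  optional ``iBAQ <run>`` columns);
* a study-design table mapping every MS run to its cell line, bait,
  fusion terminus, biological and technical replicate;
* a STRING-style weighted edge list;
* a biotinylated-peptide site table (protein, residue position, per-run
  intensity).

Intensities of zero (or empty cells) are treated as missing values; the
in-memory container keeps an explicit boolean mask next to the value
matrix so downstream imputation can distinguish "observed" from "filled".
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ntrprox")

VALID_TERMINI = ("N", "C", "none")

DESIGN_COLUMNS = [
    "run_id", "cell_line", "bait", "terminus", "bio_rep", "tech_rep", "is_control",
]


class FormatError(ValueError):
    """A table on disk does not match the expected dialect."""


class DesignError(ValueError):
    """The study-design table is internally inconsistent."""


def setup_logging(level: int = logging.INFO) -> None:
    """Route pipeline logs to stderr (idempotent)."""
    root = logging.getLogger("ntrprox")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
        )
        root.addHandler(handler)
    root.setLevel(level)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunRecord:
    """One MS run and its place in the study design."""

    run_id: str
    cell_line: str
    bait: str
    terminus: str  # "N", "C" or "none"
    bio_rep: int
    tech_rep: int
    is_control: bool

    def __post_init__(self) -> None:
        if self.terminus not in VALID_TERMINI:
            raise DesignError(
                f"run {self.run_id!r}: unknown terminus {self.terminus!r} "
                f"(expected one of {VALID_TERMINI})"
            )
        if self.bio_rep < 1 or self.tech_rep < 1:
            raise DesignError(f"run {self.run_id!r}: replicate indices are 1-based")


@dataclass(frozen=True)
class StudyDesign:
    """Maps every MS run to (cell line, bait, terminus, bio rep, tech rep)."""

    runs: tuple[RunRecord, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, int]] = set()
        ids: set[str] = set()
        for r in self.runs:
            key = (r.cell_line, r.bio_rep, r.tech_rep)
            if key in seen:
                raise DesignError(f"duplicate (cell_line, bio_rep, tech_rep): {key}")
            if r.run_id in ids:
                raise DesignError(f"duplicate run id: {r.run_id!r}")
            seen.add(key)
            ids.add(r.run_id)

    @property
    def run_ids(self) -> list[str]:
        return [r.run_id for r in self.runs]

    @property
    def cell_lines(self) -> list[str]:
        out: list[str] = []
        for r in self.runs:
            if r.cell_line not in out:
                out.append(r.cell_line)
        return out

    @property
    def control_lines(self) -> list[str]:
        return [c for c in self.cell_lines if self.line_is_control(c)]

    @property
    def ntr_lines(self) -> list[str]:
        return [c for c in self.cell_lines if not self.line_is_control(c)]

    def line_is_control(self, cell_line: str) -> bool:
        flags = {r.is_control for r in self.runs if r.cell_line == cell_line}
        return flags == {True}

    def runs_for_line(self, cell_line: str) -> list[RunRecord]:
        return [r for r in self.runs if r.cell_line == cell_line]

    def bait_of(self, cell_line: str) -> str:
        baits = {r.bait for r in self.runs if r.cell_line == cell_line}
        if len(baits) != 1:
            raise DesignError(f"cell line {cell_line!r} has mixed baits {baits}")
        return baits.pop()

    def bio_groups(self, cell_line: str) -> dict[int, list[str]]:
        """run_ids per biological replicate of a cell line."""
        out: dict[int, list[str]] = {}
        for r in self.runs:
            if r.cell_line == cell_line:
                out.setdefault(r.bio_rep, []).append(r.run_id)
        return out

    def n_control_experiments(self) -> int:
        """Number of independent control isolations (control line x bio rep)."""
        pairs = {
            (r.cell_line, r.bio_rep) for r in self.runs if r.is_control
        }
        return len(pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "run_id": r.run_id, "cell_line": r.cell_line, "bait": r.bait,
                    "terminus": r.terminus, "bio_rep": r.bio_rep,
                    "tech_rep": r.tech_rep, "is_control": r.is_control,
                }
                for r in self.runs
            ],
            columns=DESIGN_COLUMNS,
        )


@dataclass(frozen=True)
class ProteinRecord:
    group_id: str
    gene_names: tuple[str, ...] = ()
    unique_peptides: int = 0
    is_reverse: bool = False
    is_contaminant: bool = False


@dataclass
class IntensityMatrix:
    """Proteins x runs quantification with an explicit missingness mask.

    ``values`` is float64 with NaN wherever ``observed`` is False; the two
    are kept consistent by construction.  ``scale`` tracks whether the
    values are raw MS intensities, log2, or log2 after normalization.
    """

    proteins: list[ProteinRecord]
    runs: list[str]
    values: np.ndarray
    observed: np.ndarray
    scale: str = "raw"  # raw | log2 | normalized
    ibaq: pd.DataFrame | None = None  # optional side table, proteins x runs

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        n, m = len(self.proteins), len(self.runs)
        if self.values.shape != (n, m) or self.observed.shape != (n, m):
            raise ValueError(
                f"shape mismatch: {n} proteins x {m} runs vs values "
                f"{self.values.shape}, observed {self.observed.shape}"
            )
        ids = [p.group_id for p in self.proteins]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate protein group ids")
        self.values = np.where(self.observed, self.values, np.nan)

    @property
    def group_ids(self) -> list[str]:
        return [p.group_id for p in self.proteins]

    def run_index(self, run_ids: Sequence[str]) -> np.ndarray:
        pos = {r: i for i, r in enumerate(self.runs)}
        missing = [r for r in run_ids if r not in pos]
        if missing:
            raise KeyError(f"runs not in matrix: {missing}")
        return np.array([pos[r] for r in run_ids], dtype=int)

    def subset_runs(self, run_ids: Sequence[str]) -> "IntensityMatrix":
        idx = self.run_index(run_ids)
        ibaq = self.ibaq.iloc[:, idx] if self.ibaq is not None else None
        return IntensityMatrix(
            proteins=list(self.proteins), runs=list(run_ids),
            values=self.values[:, idx], observed=self.observed[:, idx],
            scale=self.scale, ibaq=ibaq,
        )

    def subset_proteins(self, keep: np.ndarray) -> "IntensityMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        ibaq = self.ibaq.iloc[keep] if self.ibaq is not None else None
        return IntensityMatrix(
            proteins=[self.proteins[i] for i in keep], runs=list(self.runs),
            values=self.values[keep], observed=self.observed[keep],
            scale=self.scale, ibaq=ibaq,
        )

    def to_log2(self) -> "IntensityMatrix":
        if self.scale != "raw":
            return self
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log2(self.values)
        return IntensityMatrix(
            proteins=list(self.proteins), runs=list(self.runs),
            values=vals, observed=self.observed.copy(), scale="log2",
            ibaq=self.ibaq,
        )


@dataclass(frozen=True)
class Network:
    """Undirected weighted graph, weights on [0, 1], no self-loops."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for a, b, w in self.edges:
            if a == b:
                raise FormatError(f"self-loop on node {a!r}")
            if w < 0 or w > 1:
                raise FormatError(f"edge ({a!r},{b!r}) weight {w} outside [0,1]")
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                raise FormatError(f"duplicate undirected edge {key}")
            seen.add(key)
            if a not in node_set or b not in node_set:
                raise FormatError(f"edge references unknown node: ({a!r},{b!r})")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# Protein-group tables
# ---------------------------------------------------------------------------

_PG_ID = "Majority protein IDs"
_PG_GENES = "Gene names"
_PG_UNIQ = "Unique peptides"
_PG_REV = "Reverse"
_PG_CONT = "Potential contaminant"


def read_protein_groups(
    path: str | Path,
    intensity_prefix: str = "Intensity ",
    design: StudyDesign | None = None,
) -> IntensityMatrix:
    """Read a MaxQuant-dialect proteinGroups TSV into an IntensityMatrix.

    Zero intensities become missing; reverse-decoy and contaminant rows are
    dropped; ``iBAQ <run>`` columns, when present, are kept as a side table.
    When a design is given, every designed run must have an intensity
    column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if _PG_ID not in df.columns:
        raise FormatError(f"missing required column {_PG_ID!r} in {path}")
    int_cols = [c for c in df.columns if c.startswith(intensity_prefix)
                and not c.startswith("iBAQ")]
    if not int_cols:
        raise FormatError(
            f"no intensity columns with prefix {intensity_prefix!r} in {path}"
        )
    runs = [c[len(intensity_prefix):] for c in int_cols]
    if design is not None:
        absent = [r for r in design.run_ids if r not in runs]
        if absent:
            raise FormatError(
                f"intensity columns absent for designed runs: {absent}"
            )
        order = [intensity_prefix + r for r in design.run_ids]
        int_cols, runs = order, list(design.run_ids)

    if df[_PG_ID].duplicated().any():
        dups = df.loc[df[_PG_ID].duplicated(), _PG_ID].tolist()
        raise FormatError(f"duplicate protein group ids: {dups}")

    def _flag(col: str) -> pd.Series:
        if col in df.columns:
            return df[col].fillna("").str.strip() == "+"
        return pd.Series(False, index=df.index)

    rev = _flag(_PG_REV)
    cont = _flag(_PG_CONT)
    keep = ~(rev | cont)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d reverse/contaminant protein groups", n_drop)
    df = df[keep].reset_index(drop=True)

    proteins = []
    uniq = (
        pd.to_numeric(df[_PG_UNIQ], errors="coerce").fillna(0).astype(int)
        if _PG_UNIQ in df.columns else pd.Series(0, index=df.index)
    )
    genes = df[_PG_GENES] if _PG_GENES in df.columns else pd.Series("", index=df.index)
    for gid, g, u in zip(df[_PG_ID], genes.fillna(""), uniq):
        proteins.append(ProteinRecord(
            group_id=gid,
            gene_names=tuple(s for s in str(g).split(";") if s),
            unique_peptides=int(u),
        ))

    vals = df[int_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    observed = np.isfinite(vals) & (vals > 0)

    ibaq_cols = [c for c in df.columns if c.startswith("iBAQ ")]
    ibaq = None
    if ibaq_cols:
        ibaq = df[ibaq_cols].apply(pd.to_numeric, errors="coerce")
        ibaq.columns = [c[len("iBAQ "):] for c in ibaq_cols]
        ibaq.index = [p.group_id for p in proteins]

    return IntensityMatrix(
        proteins=proteins, runs=runs, values=vals, observed=observed,
        scale="raw", ibaq=ibaq,
    )


def write_protein_groups(m: IntensityMatrix, path: str | Path,
                         intensity_prefix: str = "Intensity ") -> None:
    """Write an IntensityMatrix back to the proteinGroups dialect.

    Only lossless for raw-scale matrices (missing cells are written as 0,
    the dialect's missing-value convention).
    """
    cols: dict[str, object] = {
        _PG_ID: m.group_ids,
        _PG_GENES: [";".join(p.gene_names) for p in m.proteins],
        _PG_UNIQ: [p.unique_peptides for p in m.proteins],
        _PG_REV: ["" for _ in m.proteins],
        _PG_CONT: ["" for _ in m.proteins],
    }
    vals = np.where(m.observed, m.values, 0.0)
    for j, run in enumerate(m.runs):
        cols[intensity_prefix + run] = vals[:, j]
    if m.ibaq is not None:
        for run in m.ibaq.columns:
            cols["iBAQ " + run] = m.ibaq[run].to_numpy()
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> StudyDesign:
    """Read a study-design TSV (run_id, cell_line, bait, terminus, bio_rep,
    tech_rep, is_control)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise DesignError(f"empty design file: {path}") from exc
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise DesignError(f"design file missing columns {missing}")
    if df.empty:
        raise DesignError(f"design file has no runs: {path}")
    runs = []
    for _, row in df.iterrows():
        runs.append(RunRecord(
            run_id=str(row.run_id), cell_line=str(row.cell_line),
            bait=str(row.bait), terminus=str(row.terminus),
            bio_rep=int(row.bio_rep), tech_rep=int(row.tech_rep),
            is_control=str(row.is_control).strip().lower() in ("true", "1", "yes"),
        ))
    return StudyDesign(runs=tuple(runs))


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def read_network(
    path: str | Path,
    threshold: float = 0.7,
    node_file: str | Path | None = None,
) -> Network:
    """Read a STRING-style weighted edge list and filter by combined score.

    Scores may be on [0,1] or [0,1000]; if any score exceeds 1 the whole
    file is taken to be on the 0-1000 scale and divided by 1000.  Edges are
    kept when the normalized weight is strictly greater than ``threshold``.
    Self-loops are dropped with a warning; duplicate undirected pairs keep
    their maximum weight.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     comment="#", names=["a", "b", "w"])
    if df.empty:
        return Network(nodes=(), edges=())
    w = pd.to_numeric(df["w"], errors="raise").to_numpy(dtype=float)
    if (w < 0).any():
        raise FormatError("negative edge weight in network file")
    if np.nanmax(w) > 1:
        w = w / 1000.0
        if np.nanmax(w) > 1:
            raise FormatError("edge weights exceed 1000; unknown score scale")
    a = df["a"].astype(str).to_numpy()
    b = df["b"].astype(str).to_numpy()

    best: dict[tuple[str, str], float] = {}
    n_self = 0
    for ai, bi, wi in zip(a, b, w):
        if ai == bi:
            n_self += 1
            continue
        key = (ai, bi) if ai <= bi else (bi, ai)
        if wi > best.get(key, -1.0):
            best[key] = wi
    if n_self:
        logger.warning("dropped %d self-loop edges", n_self)

    edges = tuple(
        (x, y, wt) for (x, y), wt in sorted(best.items()) if wt > threshold
    )
    nodes: list[str] = []
    seen: set[str] = set()
    for x, y, _ in edges:
        for n in (x, y):
            if n not in seen:
                seen.add(n)
                nodes.append(n)
    if node_file is not None:
        for line in Path(node_file).read_text().splitlines():
            n = line.strip()
            if n and n not in seen:
                seen.add(n)
                nodes.append(n)
    return Network(nodes=tuple(sorted(nodes)), edges=edges)


def write_network(net: Network, path: str | Path,
                  node_file: str | Path | None = None) -> None:
    with open(path, "w") as fh:
        for a, b, w in net.edges:
            fh.write(f"{a}\t{b}\t{w:.6g}\n")
    if node_file is not None:
        Path(node_file).write_text("\n".join(net.nodes) + "\n")


# ---------------------------------------------------------------------------
# Biotinylation-site tables
# ---------------------------------------------------------------------------

def read_site_table(path: str | Path, protein_lengths: dict[str, int] | None = None):
    """Read a biotinylation-site TSV (protein, position, per-run intensity).

    Returns a :class:`~ntrprox.sites.SiteMatrix`.  Duplicate (protein,
    position) rows — peptides sharing a modified residue — have their
    intensities summed per run with a logged warning.
    """
    from .sites import SiteMatrix  # late import: sites depends on iofmt types

    df = pd.read_csv(path, sep="\t")
    for col in ("protein", "position"):
        if col not in df.columns:
            raise FormatError(f"site table missing column {col!r}")
    if (df["position"] < 1).any():
        bad = df.loc[df["position"] < 1]
        raise FormatError(
            f"site positions must be 1-based >= 1; offending rows: "
            f"{bad[['protein', 'position']].to_dict('records')}"
        )
    run_cols = [c for c in df.columns if c not in ("protein", "position")]
    if df.duplicated(subset=["protein", "position"]).any():
        logger.warning("duplicate (protein, position) rows: summing intensities")
        df = df.groupby(["protein", "position"], as_index=False, sort=True)[
            run_cols
        ].sum(min_count=1)
    if protein_lengths:
        for _, row in df.iterrows():
            length = protein_lengths.get(str(row["protein"]))
            if length is not None and row["position"] > length:
                logger.warning(
                    "site %s:%d beyond protein length %d",
                    row["protein"], row["position"], length,
                )
    sites = [(str(p), int(q)) for p, q in zip(df["protein"], df["position"])]
    vals = df[run_cols].to_numpy(dtype=float)
    observed = np.isfinite(vals) & (vals > 0)
    return SiteMatrix(sites=sites, runs=list(run_cols),
                      values=vals, observed=observed, scale="raw")


def write_site_table(sm, path: str | Path) -> None:
    vals = np.where(sm.observed, sm.values, 0.0)
    cols: dict[str, object] = {
        "protein": [p for p, _ in sm.sites],
        "position": [q for _, q in sm.sites],
    }
    for j, run in enumerate(sm.runs):
        cols[run] = vals[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config root must be a mapping: {path}")
    return cfg
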