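"""End-to-end orchestration: simulate -> preprocess -> test -> call ->
score -> propagate -> sites, with a manifest and ground-truth evaluation.

Each stage writes plain TSV/JSON artifacts into the output directory and
is recorded in a manifest (stage name, parameters, output hashes, seed),
so a run is reproducible and auditable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import iofmt, netprop, nipcall, preprocess, specificity, synth
from .diffexpr import run_comparison
from .iofmt import IntensityMatrix, Network, StudyDesign, logger
from .preprocess import merged_runs_for_line, prepare_comparison
from .sites import SiteMatrix, filter_sites, normalize_center
from .synth import GroundTruth, SimulationConfig

STAGES = [
    "simulate", "preprocess", "diffexpr", "nipcall",
    "specificity", "netprop", "sites",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# NIP comparisons (NTR sample vs pooled control set)
# ---------------------------------------------------------------------------

def control_comparisons(
    merged: IntensityMatrix,
    design: StudyDesign,
    knn_k: int = 10,
) -> tuple[list[tuple[dict[str, float], dict[str, float]]], pd.DataFrame]:
    """One-sided comparisons of every NTR sample against the pooled controls.

    Returns per-sample (NTR-enriched, control-enriched) p-value maps for
    Simes combination, plus a long results table.
    """
    control_runs = [
        r for line in design.control_lines
        for r in merged_runs_for_line(design, line)
    ]
    if len(control_runs) < 2:
        raise preprocess.ContractError("need at least two pooled control columns")
    comparisons = []
    rows = []
    for line in design.ntr_lines:
        comp = prepare_comparison(
            merged, merged_runs_for_line(design, line), control_runs,
            knn_k=knn_k,
        )
        res_ntr, res_ctrl = run_comparison(
            comp.values_a, comp.values_b, comp.group_ids,
        )
        p_nip = dict(zip(comp.group_ids, map(float, res_ntr.p)))
        p_bg = dict(zip(comp.group_ids, map(float, res_ctrl.p)))
        comparisons.append((p_nip, p_bg))
        for g, fc, pn, pb in zip(comp.group_ids, res_ntr.fc,
                                 res_ntr.p, res_ctrl.p):
            rows.append({"comparison": f"{line}_vs_control", "protein": g,
                         "fc": float(fc), "p_ntr": float(pn),
                         "p_control": float(pb)})
    table = pd.DataFrame(
        rows, columns=["comparison", "protein", "fc", "p_ntr", "p_control"],
    )
    return comparisons, table


# ---------------------------------------------------------------------------
# Evaluation against planted truth
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    sensitivity: float
    fdp: float
    n_true_pairs: int
    n_called_pairs: int
    n_true_positive: int
    per_ntr_precision: dict[str, float]
    nip_confusion: dict[str, int]

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(
    truth: GroundTruth,
    spec_table: specificity.SpecificityTable,
    nip_result: nipcall.NipResult,
    design: StudyDesign,
) -> EvaluationReport:
    """Confusion of recovered cargo-NTR pairs and NIP calls vs truth.

    A (protein, NTR) pair counts as called when the specificity flag is
    significant in any sample (cell line) whose bait is that NTR.
    """
    called: set[tuple[str, str]] = set()
    for protein, sample in spec_table.significant_pairs():
        called.add((protein, design.bait_of(sample)))
    true_pairs = truth.cargo_pairs
    tp = called & true_pairs
    sensitivity = len(tp) / len(true_pairs) if true_pairs else float("nan")
    fdp = (len(called) - len(tp)) / len(called) if called else 0.0

    per_ntr: dict[str, float] = {}
    for bait in sorted({b for _, b in called} | {b for _, b in true_pairs}):
        called_b = {g for g, b in called if b == bait}
        true_b = {g for g, b in true_pairs if b == bait}
        per_ntr[bait] = (
            len(called_b & true_b) / len(called_b) if called_b else float("nan")
        )

    nip_called = nip_result.nip
    bg_called = nip_result.background
    nip_true = set(truth.cargo_map)
    bg_true = set(truth.control_enriched)
    confusion = {
        "nip_tp": len(nip_called & nip_true),
        "nip_fp": len(nip_called - nip_true),
        "nip_fn": len(nip_true - nip_called),
        "bg_tp": len(bg_called & bg_true),
        "bg_fp": len(bg_called - bg_true),
        "bg_fn": len(bg_true - bg_called),
    }
    return EvaluationReport(
        sensitivity=sensitivity, fdp=fdp,
        n_true_pairs=len(true_pairs), n_called_pairs=len(called),
        n_true_positive=len(tp), per_ntr_precision=per_ntr,
        nip_confusion=confusion,
    )


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def reference_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default desk-scale study: 1,000 proteins, 6 NTR fusion lines +
    2 control lines, biological quadruplicate, technical duplicate."""
    params = dict(
        n_proteins=1000, n_ntrs=6, n_controls=2, n_bio=4, n_tech=2,
        cargo_fraction=0.3, control_fraction=0.1,
        n_complexes=10, complex_size=5, seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def run_all(
    config: SimulationConfig,
    outdir: str | Path,
    nip_alpha: float = 0.1,
    spec_p_sig: float = 0.01,
    spec_alpha: float = 0.01,
    prop_alpha: float = 0.5,
    prop_iters: int = 30,
    top_fraction: float = 0.02,
    min_unique: int = 2,
    min_bio: int = 3,
) -> dict:
    """Run the full synthetic pipeline; returns the manifest dict.

    Deterministic given the config (including its seed): re-running with
    an identical config reproduces byte-identical stage outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "simulation": asdict(config),
            "nip_alpha": nip_alpha, "spec_p_sig": spec_p_sig,
            "spec_alpha": spec_alpha, "prop_alpha": prop_alpha,
            "prop_iters": prop_iters, "top_fraction": top_fraction,
            "min_unique": min_unique, "min_bio": min_bio,
        },
        "stages": [],
    }

    def record(stage: str, outputs: list[Path]) -> None:
        manifest["stages"].append({
            "stage": stage,
            "outputs": {p.name: _sha256(p) for p in outputs},
        })
        logger.info("stage %s done (%d outputs)", stage, len(outputs))

    # -- simulate ----------------------------------------------------------
    design = synth.generate_design(config)
    truth = synth.generate_truth(config)
    matrix = synth.generate_intensities(design, truth, config)
    network = synth.generate_network(truth, config)
    site_table = synth.generate_site_table(
        truth, design, config, intensities=matrix,
    )
    iofmt.write_design(design, outdir / "design.tsv")
    _write_log2_matrix(matrix, outdir / "intensities.tsv")
    iofmt.write_network(network, outdir / "network.tsv",
                        node_file=outdir / "network_nodes.tsv")
    iofmt.write_site_table(site_table, outdir / "sites.tsv")
    _write_truth(truth, outdir / "truth.tsv")
    record("simulate", [outdir / f for f in (
        "design.tsv", "intensities.tsv", "network.tsv",
        "network_nodes.tsv", "sites.tsv", "truth.tsv")])

    # -- preprocess --------------------------------------------------------
    filtered = preprocess.filter_identifications(
        matrix, design, min_unique=min_unique, min_bio=min_bio,
    )
    merged = preprocess.merge_technical(filtered, design)
    _write_log2_matrix(merged, outdir / "merged.tsv")
    record("preprocess", [outdir / "merged.tsv"])

    # -- diffexpr: NTR vs pooled control -----------------------------------
    comparisons, comp_table = control_comparisons(merged, design)
    comp_table.to_csv(outdir / "control_comparisons.tsv", sep="\t", index=False)
    record("diffexpr", [outdir / "control_comparisons.tsv"])

    # -- nipcall -----------------------------------------------------------
    nip_result = nipcall.call_nip(comparisons, alpha=nip_alpha)
    nip_result.table.to_csv(outdir / "nip.tsv", sep="\t", index=False)
    record("nipcall", [outdir / "nip.tsv"])

    # -- specificity -------------------------------------------------------
    spec_table = specificity.score_specificity(
        merged, design, p_sig=spec_p_sig, alpha=spec_alpha,
    )
    spec_table.table.to_csv(outdir / "specificity.tsv", sep="\t", index=False)
    record("specificity", [outdir / "specificity.tsv"])

    # -- netprop -----------------------------------------------------------
    w_norm, nodes = netprop.normalize_adjacency(network)
    node_pos = {n: i for i, n in enumerate(nodes)}
    prop_rows = []
    components_rows = []
    spec = spec_table.table
    for sample in design.ntr_lines:
        f0 = np.zeros(len(nodes))
        sub = spec[spec["sample"] == sample]
        for g, s in zip(sub["protein"], sub["score"]):
            if g in node_pos:
                f0[node_pos[g]] = s
        result = netprop.topology_bias_correct(
            f0, w_norm, nodes, alpha=prop_alpha, iters=prop_iters,
        )
        selected = netprop.select_top(
            result.f_corrected, fraction=top_fraction, nodes=nodes,
        )
        order = np.argsort(-result.f_corrected, kind="stable")
        rank = np.empty(len(nodes), dtype=int)
        rank[order] = np.arange(1, len(nodes) + 1)
        for i, node in enumerate(nodes):
            prop_rows.append({
                "sample": sample, "node": node, "f0": result.f0[i],
                "f": result.f[i], "bias": result.bias[i],
                "f_corrected": result.f_corrected[i],
                "rank": int(rank[i]), "selected": node in selected,
            })
        for ci, (members, density) in enumerate(
                netprop.extract_subnetworks(selected, network)):
            for member in members:
                components_rows.append({
                    "sample": sample, "component": ci, "node": member,
                    "size": len(members), "density": density,
                })
    pd.DataFrame(prop_rows).to_csv(outdir / "propagation.tsv",
                                   sep="\t", index=False)
    pd.DataFrame(
        components_rows,
        columns=["sample", "component", "node", "size", "density"],
    ).to_csv(outdir / "components.tsv", sep="\t", index=False)
    record("netprop", [outdir / "propagation.tsv", outdir / "components.tsv"])

    # -- sites -------------------------------------------------------------
    kept_sites = filter_sites(site_table, design, min_bio=2)
    centered = normalize_center(kept_sites)
    tidy = []
    for i, (protein, position) in enumerate(centered.sites):
        for j, run in enumerate(centered.runs):
            if centered.observed[i, j]:
                tidy.append({"protein": protein, "position": position,
                             "run": run,
                             "centered_intensity": centered.values[i, j]})
    pd.DataFrame(
        tidy, columns=["protein", "position", "run", "centered_intensity"],
    ).to_csv(outdir / "sites_centered.tsv", sep="\t", index=False)
    record("sites", [outdir / "sites_centered.tsv"])

    # -- evaluate ----------------------------------------------------------
    report = evaluate(truth, spec_table, nip_result, design)
    manifest["evaluation"] = report.to_dict()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _write_log2_matrix(m: IntensityMatrix, path: Path) -> None:
    df = pd.DataFrame(np.where(m.observed, m.values, np.nan),
                      columns=m.runs)
    df.insert(0, "protein", m.group_ids)
    df.insert(1, "unique_peptides", [p.unique_peptides for p in m.proteins])
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_log2_matrix(path: str | Path) -> IntensityMatrix:
    """Read a log2 matrix written by the pipeline (round-trip partner of
    the internal writer)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    runs = [c for c in df.columns if c not in ("protein", "unique_peptides")]
    vals = df[runs].to_numpy(dtype=float)
    proteins = [
        iofmt.ProteinRecord(group_id=str(g), gene_names=(str(g),),
                            unique_peptides=int(u))
        for g, u in zip(df["protein"], df["unique_peptides"])
    ]
    return IntensityMatrix(
        proteins=proteins, runs=runs, values=vals,
        observed=np.isfinite(vals), scale="log2",
    )


def _write_truth(truth: GroundTruth, path: Path) -> None:
    rows = []
    complex_of = {}
    for ci, (members, bait) in enumerate(truth.complexes):
        for g in members:
            complex_of[g] = ci
    for g in sorted(truth.cargo_map):
        for bait in sorted(truth.cargo_map[g]):
            rows.append({"protein": g, "role": "cargo", "bait": bait,
                         "complex": complex_of.get(g, -1)})
    for g in sorted(truth.control_enriched):
        rows.append({"protein": g, "role": "control_enriched", "bait": "none",
                     "complex": -1})
    pd.DataFrame(
        rows, columns=["protein", "role", "bait", "complex"],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    cargo: dict[str, set[str]] = {}
    control: set[str] = set()
    complexes: dict[int, tuple[set[str], str]] = {}
    for _, row in df.iterrows():
        if row.role == "cargo":
            cargo.setdefault(str(row.protein), set()).add(str(row.bait))
            if int(row["complex"]) >= 0:
                members, _ = complexes.setdefault(
                    int(row["complex"]), (set(), str(row.bait)))
                members.add(str(row.protein))
        else:
            control.add(str(row.protein))
    return GroundTruth(
        cargo_map={g: frozenset(b) for g, b in cargo.items()},
        control_enriched=frozenset(control),
        complexes=tuple(
            (frozenset(members), bait)
            for members, bait in complexes.values()
        ),
    )
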