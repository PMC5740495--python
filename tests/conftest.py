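import numpy as np
import pytest

import ntrprox as nx


@pytest.fixture(scope="session")
def reference_run(tmp_path_factory):
    """Full pipeline on the reference simulation (seed 0), run once."""
    outdir = tmp_path_factory.mktemp("reference_run")
    cfg = nx.reference_config(seed=0)
    manifest = nx.run_all(cfg, outdir)
    return {"config": cfg, "manifest": manifest, "outdir": outdir}


@pytest.fixture(scope="session")
def paper_design():
    """The full-study layout: 28 NTR fusion + 4 control lines, 4 bio x 2 tech."""
    cfg = nx.SimulationConfig(n_proteins=10, n_ntrs=28, n_controls=4,
                              n_bio=4, n_tech=2, cargo_fraction=0.0,
                              control_fraction=0.0, n_complexes=0,
                              complex_size=0, seed=0)
    return nx.generate_design(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def write_protein_groups_tsv(path, rows, runs):
    """Minimal MaxQuant-dialect proteinGroups writer for fixtures.

    rows: list of dicts with id, genes, uniq, rev, cont, intensities (list).
    """
    header = ["Majority protein IDs", "Gene names", "Unique peptides",
              "Reverse", "Potential contaminant"]
    header += [f"Intensity {r}" for r in runs]
    lines = ["\t".join(header)]
    for row in rows:
        cells = [row["id"], row.get("genes", ""), str(row.get("uniq", 2)),
                 row.get("rev", ""), row.get("cont", "")]
        cells += [str(v) for v in row["intensities"]]
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path
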