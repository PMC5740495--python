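"""Synthetic BioID study generator with planted ground truth.

Emulates the study layout of an NTR (nuclear transport receptor) BioID
screen: a panel of BirA* fusion cell lines plus control lines, each
measured in biological quadruplicate and technical duplicate.  Planted
effects give every downstream stage a known answer:

* *cargo* proteins carry a log2 enrichment ``delta`` in the runs of their
  assigned NTR line(s);
* *control-enriched* proteins (the naturally biotinylated background,
  e.g. mitochondrial carboxylases) carry an enrichment in control runs;
* *complexes* are disjoint blocks of cargo proteins that share one NTR
  and form dense modules of the planted interaction network.

Log2 intensities follow an additive Gaussian model:

    y[g, r] = a_g + delta * [g is cargo of bait(r)]
                  + delta_c * [g control-enriched and r is a control run]
                  + b[g, line, bio]  + t[g, run]

with protein baselines a_g ~ N(mu, tau^2), biological noise
b ~ N(0, sigma_b^2) shared across technical replicates, and technical
noise t ~ N(0, sigma_t^2).  Dropout is the union of an intensity-
dependent component (missing-not-at-random: probability
``logistic(-k * (y - m))``, so low-abundance measurements vanish more
often) and an independent Bernoulli(rho) component (missing at random).

All randomness flows from one integer seed through named substreams, so
each generated artifact is reproducible on its own.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .iofmt import IntensityMatrix, Network, ProteinRecord, RunRecord, StudyDesign


class ConfigError(ValueError):
    """Simulation configuration is inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the screen layout this pipeline targets: 28 NTR
    fusion lines plus 4 control lines, biological quadruplicate,
    technical duplicate.  Intensity-model defaults put log2 abundances
    around 25 with a 2-unit protein-to-protein spread, biological noise
    larger than technical noise, and roughly 10-15% overall missingness.
    """

    n_proteins: int = 1000
    n_ntrs: int = 28
    n_controls: int = 4
    n_bio: int = 4
    n_tech: int = 2
    base_mean: float = 25.0      # mu: mean log2 abundance
    base_spread: float = 2.0     # tau: protein-to-protein sd
    sigma_b: float = 0.5         # biological replicate sd (log2)
    sigma_t: float = 0.2         # technical replicate sd (log2)
    delta: float = 2.0           # planted cargo log2 enrichment
    delta_control: float = 2.0   # control-enriched background log2 enrichment
    cargo_fraction: float = 0.3
    control_fraction: float = 0.1
    n_complexes: int = 10
    complex_size: int = 5
    mnar_midpoint: float = 20.0  # m: log2 value at 50% MNAR dropout
    mnar_steepness: float = 1.0  # k: logistic slope; 0 disables MNAR dropout
    mar_rate: float = 0.05       # rho: random dropout probability
    p_in: float = 0.8            # within-complex edge probability
    p_out: float = 0.01          # background edge probability
    edge_weight_min: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_b <= 0 or self.sigma_t <= 0 or self.base_spread <= 0:
            raise ConfigError("noise parameters sigma_b, sigma_t, tau must be > 0")
        if self.sigma_t >= self.sigma_b:
            raise ConfigError("technical noise must be smaller than biological")
        if not 0 <= self.mar_rate < 1:
            raise ConfigError("mar_rate must lie in [0, 1)")
        if self.mnar_steepness < 0:
            raise ConfigError("mnar_steepness must be >= 0")
        if self.cargo_fraction + self.control_fraction > 1:
            raise ConfigError("cargo and control fractions sum above 1")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth: which proteins are cargo of which NTR bait."""

    cargo_map: Mapping[str, frozenset[str]]
    control_enriched: frozenset[str]
    complexes: tuple[tuple[frozenset[str], str], ...]  # (members, NTR bait)

    def __post_init__(self) -> None:
        overlap = set(self.cargo_map) & self.control_enriched
        if overlap:
            raise ConfigError(
                f"cargo and control-enriched sets overlap: {sorted(overlap)[:5]}"
            )
        for members, bait in self.complexes:
            for g in members:
                if bait not in self.cargo_map.get(g, frozenset()):
                    raise ConfigError(
                        f"complex member {g} not mapped to complex bait {bait}"
                    )

    @property
    def cargo_pairs(self) -> set[tuple[str, str]]:
        return {(g, b) for g, baits in self.cargo_map.items() for b in baits}


def _stream(config: SimulationConfig, name: str) -> np.random.Generator:
    """Named child RNG so each stage is independently reproducible."""
    key = zlib.crc32(name.encode())  # stable across processes
    ss = np.random.SeedSequence(config.seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def protein_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_proteins))
    return [f"P{i:0{width}d}" for i in range(1, config.n_proteins + 1)]


def bait_names(config: SimulationConfig) -> list[str]:
    return [f"NTR{i:02d}" for i in range(1, config.n_ntrs + 1)]


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

def generate_design(config: SimulationConfig) -> StudyDesign:
    """Fusion + control lines, each with n_bio x n_tech runs."""
    runs: list[RunRecord] = []
    lines = [(b, False) for b in bait_names(config)]
    lines += [(f"CTRL{i:02d}", True) for i in range(1, config.n_controls + 1)]
    for line, is_ctrl in lines:
        for bio in range(1, config.n_bio + 1):
            for tech in range(1, config.n_tech + 1):
                runs.append(RunRecord(
                    run_id=f"{line}_b{bio}_t{tech}",
                    cell_line=line,
                    bait="none" if is_ctrl else line,
                    terminus="none" if is_ctrl else "N",
                    bio_rep=bio, tech_rep=tech, is_control=is_ctrl,
                ))
    return StudyDesign(runs=tuple(runs))


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def generate_truth(config: SimulationConfig) -> GroundTruth:
    """Draw disjoint cargo and control-enriched sets plus planted complexes.

    Complexes are disjoint blocks of cargo proteins sharing one NTR; the
    remaining cargo proteins are assigned a single NTR uniformly at random.
    """
    rng = _stream(config, "truth")
    ids = protein_ids(config)
    baits = bait_names(config)
    n_cargo = int(round(config.cargo_fraction * config.n_proteins))
    n_ctrl = int(round(config.control_fraction * config.n_proteins))
    if n_cargo + n_ctrl > config.n_proteins:
        raise ConfigError("requested cargo + control fractions exceed 1")
    perm = rng.permutation(config.n_proteins)
    cargo_ids = [ids[i] for i in perm[:n_cargo]]
    control_ids = frozenset(ids[i] for i in perm[n_cargo:n_cargo + n_ctrl])

    n_complex_prot = config.n_complexes * config.complex_size
    if n_complex_prot > n_cargo:
        raise ConfigError(
            f"complexes need {n_complex_prot} cargo proteins, "
            f"only {n_cargo} available"
        )
    cargo_map: dict[str, frozenset[str]] = {}
    complexes: list[tuple[frozenset[str], str]] = []
    pos = 0
    for _ in range(config.n_complexes):
        members = frozenset(cargo_ids[pos:pos + config.complex_size])
        bait = baits[int(rng.integers(len(baits)))]
        complexes.append((members, bait))
        for g in members:
            cargo_map[g] = frozenset([bait])
        pos += config.complex_size
    for g in cargo_ids[pos:]:
        cargo_map[g] = frozenset([baits[int(rng.integers(len(baits)))]])

    return GroundTruth(
        cargo_map=cargo_map, control_enriched=control_ids,
        complexes=tuple(complexes),
    )


# ---------------------------------------------------------------------------
# Intensities
# ---------------------------------------------------------------------------

def generate_intensities(
    design: StudyDesign, truth: GroundTruth, config: SimulationConfig,
) -> IntensityMatrix:
    """Simulate the log2 intensity matrix with MNAR + MAR dropout."""
    rng = _stream(config, "intensities")
    ids = protein_ids(config)
    n = len(ids)
    runs = list(design.runs)
    m = len(runs)

    a = rng.normal(config.base_mean, config.base_spread, size=n)

    # biological term shared by technical replicates of one (line, bio rep)
    bio_keys = sorted({(r.cell_line, r.bio_rep) for r in runs})
    bio_idx = {k: i for i, k in enumerate(bio_keys)}
    b = rng.normal(0.0, config.sigma_b, size=(n, len(bio_keys)))
    t = rng.normal(0.0, config.sigma_t, size=(n, m))

    effect = np.zeros((n, m))
    id_pos = {g: i for i, g in enumerate(ids)}
    for j, r in enumerate(runs):
        if r.is_control:
            for g in truth.control_enriched:
                effect[id_pos[g], j] += config.delta_control
        else:
            for g, baits in truth.cargo_map.items():
                if r.bait in baits:
                    effect[id_pos[g], j] += config.delta

    cols = np.array([bio_idx[(r.cell_line, r.bio_rep)] for r in runs])
    values = a[:, None] + effect + b[:, cols] + t

    # dropout on the log2 scale, after noise
    if config.mnar_steepness > 0:
        p_mnar = 1.0 / (1.0 + np.exp(
            config.mnar_steepness * (values - config.mnar_midpoint)
        ))
    else:
        p_mnar = np.zeros_like(values)
    drop_mnar = rng.random(size=values.shape) < p_mnar
    drop_mar = rng.random(size=values.shape) < config.mar_rate
    observed = ~(drop_mnar | drop_mar)

    proteins = [ProteinRecord(group_id=g, gene_names=(g,), unique_peptides=2)
                for g in ids]
    return IntensityMatrix(
        proteins=proteins, runs=[r.run_id for r in runs],
        values=values, observed=observed, scale="log2",
    )


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def generate_network(truth: GroundTruth, config: SimulationConfig) -> Network:
    """Planted-partition graph: dense within complexes, sparse elsewhere."""
    if config.p_in <= config.p_out:
        raise ConfigError("within-complex edge probability must exceed background")
    rng = _stream(config, "network")
    ids = protein_ids(config)
    id_pos = {g: i for i, g in enumerate(ids)}
    n = len(ids)

    block = np.full(n, -1, dtype=int)
    for ci, (members, _) in enumerate(truth.complexes):
        for g in members:
            block[id_pos[g]] = ci

    iu, ju = np.triu_indices(n, k=1)
    same = (block[iu] >= 0) & (block[iu] == block[ju])
    p = np.where(same, config.p_in, config.p_out)
    realized = rng.random(p.shape) < p
    weights = rng.uniform(config.edge_weight_min, 1.0, size=int(realized.sum()))

    edges = tuple(
        (ids[i], ids[j], float(w))
        for i, j, w in zip(iu[realized], ju[realized], weights)
    )
    return Network(nodes=tuple(ids), edges=edges)


# ---------------------------------------------------------------------------
# Biotinylation sites
# ---------------------------------------------------------------------------

def generate_site_table(
    truth: GroundTruth, design: StudyDesign, config: SimulationConfig,
    intensities: IntensityMatrix | None = None,
    sites_per_protein: int = 3,
    n_site_proteins: int = 50,
    site_sd: float = 0.3,
):
    """Simulate biotinylation-site intensities tied to protein abundance.

    Sites of a protein inherit the protein's (noise-free would be ideal;
    here: simulated) log2 intensity in each run, plus a site-level offset
    and Gaussian noise, then pass through the same dropout model.  Sites
    of a protein that is missing in a run are missing too.
    """
    from .sites import SiteMatrix

    rng = _stream(config, "sites")
    if intensities is None:
        intensities = generate_intensities(design, truth, config)
    ids = intensities.group_ids
    chosen = [ids[i] for i in rng.choice(len(ids),
                                         size=min(n_site_proteins, len(ids)),
                                         replace=False)]
    site_list: list[tuple[str, int]] = []
    rows = []
    obs_rows = []
    id_pos = {g: i for i, g in enumerate(ids)}
    for g in chosen:
        positions = np.sort(rng.choice(np.arange(1, 1001),
                                       size=sites_per_protein, replace=False))
        base = intensities.values[id_pos[g]]
        base_obs = intensities.observed[id_pos[g]]
        for p in positions:
            offset = rng.normal(0.0, 1.0)
            noise = rng.normal(0.0, site_sd, size=len(intensities.runs))
            vals = base + offset + noise
            if config.mnar_steepness > 0:
                p_mnar = 1.0 / (1.0 + np.exp(
                    config.mnar_steepness * (vals - config.mnar_midpoint)
                ))
            else:
                p_mnar = np.zeros_like(vals)
            drop = (rng.random(vals.shape) < p_mnar) | \
                   (rng.random(vals.shape) < config.mar_rate)
            obs = base_obs & ~drop
            site_list.append((g, int(p)))
            rows.append(vals)
            obs_rows.append(obs)
    return SiteMatrix(
        sites=site_list, runs=list(intensities.runs),
        values=np.array(rows), observed=np.array(obs_rows), scale="log2",
    )
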