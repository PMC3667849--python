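"""Synthetic multi-species toxicogenomics studies with known ground truth.

Emulates the structure of a short-term (90-day) rodent expression study
wired to a two-year bioassay: ~26 chemicals at a single MTD-style dose,
half of them hepatocarcinogens that perturb a small set of causal pathways
(with the perturbation concentrated toward pathway termini, where the
network-weighted enrichment statistic looks hardest), treated/control
animal groups with Gaussian log2 expression noise, orthologous pathway
panels for extra species, and per-animal tumor outcomes that pass through
the poly-3 survival adjustment.  Every draw is deterministic given the
config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .carcinogenicity import BioassayRecord, poly3_adjusted_counts, poly3_z
from .enrichment import ExpressionMatrix
from .pathways import OrthologyMap, PathwayCollection, PathwayNetwork

__all__ = [
    "GeneratorConfig",
    "ChemicalTruth",
    "GroundTruth",
    "generate_pathway_db",
    "generate_study",
    "generate_cross_species_panel",
    "generate_dose_series_expression",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs for the synthetic generator (defaults = the
    conditions the pipeline is meant to operate under)."""

    seed: int = 0
    n_genes: int = 4000
    n_pathways: int = 200
    pathway_size: tuple = (10, 80)
    n_chemicals: int = 26
    n_causal_pathways: int = 5
    effect_size: float = 1.0  # delta, log2 units on causal-pathway genes
    noise_sd: float = 1.0  # sigma, within-group gene noise
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    animals_per_group: int = 4
    terminus_bias: float = 0.5  # extra effect fraction on the terminal half
    species: tuple = ("mouse", "rat", "human")
    ortholog_noise: float = 0.1  # epsilon, fraction of genes relabeled per species
    control_tumor_rate: float = 0.2  # q0
    tumor_gain: float = 1.5  # gamma, logistic link from mean shift to tumor prob
    animals_per_arm: int = 50
    death_fraction: float = 0.2  # tumor-free animals dying before term
    death_time_range: tuple = (0.4, 1.0)

    def __post_init__(self):
        probs = {
            "control_tumor_rate": self.control_tumor_rate,
            "death_fraction": self.death_fraction,
            "ortholog_noise": self.ortholog_noise,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} must be a probability")
        sizes = {
            "n_genes": self.n_genes,
            "n_pathways": self.n_pathways,
            "n_chemicals": self.n_chemicals,
            "animals_per_group": self.animals_per_group,
            "animals_per_arm": self.animals_per_arm,
        }
        for name, v in sizes.items():
            if v <= 0:
                raise ValueError(f"{name}={v} must be positive")
        lo, hi = self.pathway_size
        if not (2 <= lo <= hi <= self.n_genes):
            raise ValueError(f"pathway_size {self.pathway_size} out of range")
        if not 0 < self.n_causal_pathways <= self.n_pathways:
            raise ValueError("causal pathways must be a subset of generated pathways")
        if not self.species:
            raise ValueError("at least one species required")

    @property
    def reference_species(self) -> str:
        return self.species[0]


@dataclass
class ChemicalTruth:
    chemical_id: str
    carcinogen: bool
    causal_pathways: tuple
    mean_shift: float  # m, mean perturbation over causal-pathway genes
    latent_z: float  # z of the noise-free expected bioassay
    expression: dict  # species -> ExpressionMatrix
    bioassay: BioassayRecord


@dataclass
class GroundTruth:
    config: GeneratorConfig
    collections: Mapping[str, PathwayCollection]
    orthology: OrthologyMap
    panel: list
    causal_pathways: tuple
    chemicals: list

    @property
    def labels(self) -> dict:
        return {
            c.chemical_id: "positive" if c.carcinogen else "negative"
            for c in self.chemicals
        }


def _rng(config: GeneratorConfig, *tokens) -> np.random.Generator:
    ss = np.random.SeedSequence(
        [config.seed] + [abs(hash(str(t))) % (2**31) for t in tokens]
    )
    return np.random.default_rng(ss)


def _species_gene(species: str, gene: str) -> str:
    return f"{species}:{gene}"


def _relabel_map(config: GeneratorConfig, species: str, genes: Sequence[str]) -> dict:
    """Bijective relabeling: an epsilon-fraction of genes are cycled among
    themselves so no pathway ever acquires duplicate nodes."""
    mapping = {g: g for g in genes}
    n_move = int(round(config.ortholog_noise * len(genes)))
    if n_move >= 2:
        rng = _rng(config, "relabel", species)
        moved = rng.choice(len(genes), size=n_move, replace=False)
        cycle = [genes[i] for i in moved]
        for src, dst in zip(cycle, cycle[1:] + cycle[:1]):
            mapping[src] = dst
    return mapping


def generate_pathway_db(config: GeneratorConfig) -> tuple:
    """Random directed pathway skeletons shared across species.

    Each pathway is a preferential-attachment-style DAG over 10-80 genes
    drawn (with overlap across pathways) from the gene universe, with 1-3
    terminus nodes.  Non-reference species reuse the topology with an
    epsilon-fraction of gene labels re-drawn; the shared panel is all
    pathways.  Returns (species -> PathwayCollection, OrthologyMap).
    """
    rng = _rng(config, "pathways")
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    lo, hi = config.pathway_size

    skeletons = []  # (pathway_id, member genes in topological order, edge index pairs)
    for p in range(config.n_pathways):
        pid = f"P{p:03d}"
        size = int(rng.integers(lo, hi + 1))
        members = [genes[i] for i in rng.choice(config.n_genes, size, replace=False)]
        n_term = int(rng.integers(1, min(3, size - 1) + 1))
        indeg = np.zeros(size)
        edges = set()
        for i in range(size - n_term):
            later = np.arange(i + 1, size)
            n_out = int(rng.integers(1, min(2, later.size) + 1))
            w = indeg[later] + 1.0
            targets = rng.choice(later, size=n_out, replace=False, p=w / w.sum())
            for t in targets:
                edges.add((i, int(t)))
                indeg[int(t)] += 1
        skeletons.append((pid, members, edges))

    relabels = {
        sp: ({g: g for g in genes} if sp == config.reference_species else _relabel_map(config, sp, genes))
        for sp in config.species
    }
    collections = {}
    pairs = {}
    for sp in config.species:
        nets = []
        for pid, members, edges in skeletons:
            local = [_species_gene(sp, relabels[sp][g]) for g in members]
            nets.append(
                PathwayNetwork(
                    pid,
                    sp,
                    frozenset(local),
                    frozenset((local[i], local[j]) for i, j in edges),
                )
            )
        collections[sp] = PathwayCollection(nets)
        for g in genes:
            pairs[(sp, _species_gene(sp, relabels[sp][g]))] = g
    return collections, OrthologyMap(pairs)


def _terminal_half(net: PathwayNetwork) -> frozenset:
    """Nodes in the terminus-proximal half (by directed distance to a terminus)."""
    g = net.to_directed()
    termini = [v for v in g if g.out_degree(v) == 0]
    if not termini:
        return frozenset()
    d_t = nx.multi_source_dijkstra_path_length(g.reverse(copy=False), termini)
    med = float(np.median(list(d_t.values())))
    return frozenset(v for v, d in d_t.items() if d <= med)


def _shift_table(
    config: GeneratorConfig,
    collections: Mapping[str, PathwayCollection],
    orthology: OrthologyMap,
    causal: Sequence[str],
    scale: float = 1.0,
) -> tuple:
    """Per-canonical-gene expression shift for a carcinogen at ``scale`` x MTD.

    Shifts are defined on canonical (reference) gene tokens: the terminal
    half of each causal pathway shifts by delta*(1+b), the rest by delta.
    Returns (dict canonical gene -> shift, mean shift m).
    """
    ref = config.reference_species
    delta = config.effect_size * scale
    shifts: dict = {}
    for pid in causal:
        net = collections[ref][pid]
        term_half = _terminal_half(net)
        for node in net.nodes:
            canonical = orthology.canonical(ref, node)
            bump = delta * (1.0 + config.terminus_bias) if node in term_half else delta
            shifts[canonical] = max(shifts.get(canonical, 0.0), bump)
    m = float(np.mean(list(shifts.values()))) if shifts else 0.0
    return shifts, m


def _expression_for(
    config: GeneratorConfig,
    species: str,
    chemical_id: str,
    shifts: Mapping[str, float],
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Treated/control matrix over the species' gene universe.

    The biology shifts the species orthologs of the canonical causal genes;
    with ortholog noise, a fraction of the species' pathway nodes no longer
    coincide with the shifted genes.
    """
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    local_ids = [_species_gene(species, g) for g in genes]
    a = config.animals_per_group
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, 2 * a)) + baseline[:, None]
    if shifts:
        shift_vec = np.array([shifts.get(g, 0.0) for g in genes])
        values[:, :a] += shift_vec[:, None]  # treated columns first
    samples = [f"{chemical_id}_t{i+1}" for i in range(a)] + [
        f"{chemical_id}_c{i+1}" for i in range(a)
    ]
    groups = pd.Series(
        ["treated"] * a + ["control"] * a, index=samples, name="group"
    )
    return ExpressionMatrix(pd.DataFrame(values, index=local_ids, columns=samples), groups)


def _simulate_bioassay(
    config: GeneratorConfig,
    chemical_id: str,
    mean_shift: float,
    rng: np.random.Generator,
) -> tuple:
    """Per-animal tumor outcomes -> poly-3 adjusted BioassayRecord + latent z."""
    q0 = config.control_tumor_rate
    p_treat = float(expit(logit(q0) + config.tumor_gain * mean_shift)) if mean_shift else q0
    lo, hi = config.death_time_range

    def arm(prob):
        animals = []
        for _ in range(config.animals_per_arm):
            tumor = bool(rng.random() < prob)
            if not tumor and rng.random() < config.death_fraction:
                t = float(rng.uniform(lo, hi))
            else:
                t = 1.0
            animals.append((t, tumor))
        return poly3_adjusted_counts(animals)

    n_t, p_t = arm(p_treat)
    n_c, p_c = arm(q0)
    record = BioassayRecord(chemical_id, n_t, p_t, n_c, p_c)
    latent = poly3_z(
        BioassayRecord(
            chemical_id,
            float(config.animals_per_arm),
            p_treat,
            float(config.animals_per_arm),
            q0,
        )
    )
    return record, latent


def generate_study(config: GeneratorConfig) -> GroundTruth:
    """Full synthetic study: pathway db, reference-species expression per
    chemical, and poly-3 bioassay outcomes.

    The first ceil(n_chemicals / 2) chemicals are carcinogens sharing
    ``n_causal_pathways`` causal pathways; their causal-pathway genes shift
    by delta (terminal-half genes by delta*(1+b)) in treated samples, and
    their treated tumor probability follows a logistic link in the mean
    shift m.  Everything else is noise.
    """
    collections, orthology = generate_pathway_db(config)
    panel = sorted(collections[config.reference_species])
    rng = _rng(config, "study")
    causal = tuple(
        sorted(panel[i] for i in rng.choice(len(panel), config.n_causal_pathways, replace=False))
    )
    n_carc = math.ceil(config.n_chemicals / 2)
    shifts, m = _shift_table(config, collections, orthology, causal)
    chemicals = []
    for i in range(config.n_chemicals):
        chem = f"chem{i+1:02d}"
        carcinogen = i < n_carc
        chem_shifts = shifts if carcinogen else {}
        chem_m = m if carcinogen else 0.0
        expr = _expression_for(
            config,
            config.reference_species,
            chem,
            chem_shifts,
            _rng(config, "expr", config.reference_species, chem),
        )
        record, latent = _simulate_bioassay(
            config, chem, chem_m, _rng(config, "bioassay", chem)
        )
        chemicals.append(
            ChemicalTruth(
                chem,
                carcinogen,
                causal if carcinogen else (),
                chem_m,
                latent,
                {config.reference_species: expr},
                record,
            )
        )
    return GroundTruth(config, collections, orthology, panel, causal, chemicals)


def generate_cross_species_panel(
    truth: GroundTruth, species: str, config: GeneratorConfig | None = None
) -> dict:
    """Fresh treatment instances for another species.

    Re-uses each chemical's carcinogen flag and causal pathways; the shifted
    genes are the species orthologs of the canonical causal genes, while the
    species' pathway membership differs by the ortholog-noise fraction.
    Returns chemical_id -> ExpressionMatrix (labels via ``truth.labels``).
    """
    config = config or truth.config
    if species not in config.species:
        raise ValueError(f"unknown species {species!r}; configured: {config.species}")
    shifts, _ = _shift_table(
        config, truth.collections, truth.orthology, truth.causal_pathways
    )
    out = {}
    for chem in truth.chemicals:
        chem_shifts = shifts if chem.carcinogen else {}
        expr = _expression_for(
            config,
            species,
            chem.chemical_id,
            chem_shifts,
            _rng(config, "expr", species, chem.chemical_id),
        )
        chem.expression[species] = expr
        out[chem.chemical_id] = expr
    return out


def generate_dose_series_expression(
    truth: GroundTruth, chemical_id: str, dose_fractions: Sequence[float]
) -> dict:
    """Dose-series mode: the causal-gene shift scales with dose fraction.

    Returns dose fraction -> ExpressionMatrix for the reference species,
    mirroring a multi-dose 90-day design under an MTD-anchored ladder.
    """
    config = truth.config
    chem = next(c for c in truth.chemicals if c.chemical_id == chemical_id)
    out = {}
    for frac in dose_fractions:
        if chem.carcinogen:
            shifts, _ = _shift_table(
                config, truth.collections, truth.orthology, truth.causal_pathways, frac
            )
        else:
            shifts = {}
        out[frac] = _expression_for(
            config,
            config.reference_species,
            f"{chemical_id}_d{frac:g}",
            shifts,
            _rng(config, "dose", chemical_id, f"{frac:g}"),
        )
    return out
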