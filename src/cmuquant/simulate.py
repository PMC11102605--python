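"""Synthetic plaque-community generator with spike-ins and sequencing noise.

Generates ground-truth cell counts for a two-group (e.g. healthy vs.
gingivitis) supragingival-plaque community, then pushes them through a
forward model of spiked shotgun sequencing:

1. per-species baseline log10 cell counts are drawn from a normal
   distribution on the log10 scale (communities span several decades);
2. each species carries one clinical category; group membership shifts a
   sample's log10 counts by the group's per-category effect size (disease
   groups exceed health for most disease-associated categories);
3. per-taxon DNA mass = cells x genome molecular weight / Avogadro, plus the
   known spike-in DNA masses;
4. reads are drawn multinomially with probabilities proportional to DNA
   mass — not cell count — because genome length biases shotgun read share;
   this is exactly the bias the spike-in calibration corrects.

Relative abundances (counts / depth, or exact mass fractions in the
noise-free limit) feed the quantification module, which should invert the
forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.constants import Avogadro
from skbio import TreeNode

from .classification import CATEGORIES, ClassificationRecord, ClassificationTable
from .quantification import PER_BP_MASS_DS_DNA, SPIKE_IN_TAXA, SpikeInSpec

#: Default spike-in input DNA masses (ng per sample): three distinct values
#: spanning a decade give a well-conditioned calibration line.
DEFAULT_SPIKE_MASSES = dict(zip(SPIKE_IN_TAXA, (0.2, 0.5, 1.0)))

#: Approximate published genome sizes (bp) of the spike-in organisms.
SPIKE_GENOME_LENGTHS = dict(zip(SPIKE_IN_TAXA, (3_260_000, 3_110_000, 2_900_000)))

#: Default per-category log10 effect sizes of the disease group relative to
#: health: disease-associated categories enriched most, commensals mildly
#: (absolute loads rise across the board in gingivitis).
DEFAULT_GROUP_EFFECTS = {
    "healthy": {},
    "gingivitis": {
        "gingivitis": 1.0,
        "periodontitis": 0.8,
        "malodor": 0.6,
        "caries": 0.3,
        "commensal": 0.2,
    },
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic community.

    Defaults emulate the two-cohort baseline contrast of a gingivitis
    plaque survey: 32 subjects per group, species spanning several decades
    of absolute abundance around 1e5 cells, disease-group enrichment of
    0.2–1.0 log10 by category, three spike-ins, and a shallow-shotgun
    sequencing depth of 3 million reads.
    """

    n_species: int = 150
    n_samples_per_group: int = 32
    groups: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUP_EFFECTS.items()}
    )
    base_log10_mean: float = 5.0
    base_log10_sd: float = 1.0
    sample_log10_sd: float = 0.3
    spike_spec: SpikeInSpec = field(
        default_factory=lambda: SpikeInSpec(DEFAULT_SPIKE_MASSES)
    )
    genome_length_range: tuple[float, float] = (2e6, 6e6)
    sequencing_depth: int = 3_000_000
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1 or self.n_samples_per_group < 1:
            raise ValueError("n_species and n_samples_per_group must be >= 1")
        if self.base_log10_sd <= 0 or self.sample_log10_sd <= 0:
            raise ValueError("log10 standard deviations must be > 0")
        if self.sequencing_depth < 1000:
            raise ValueError("sequencing depth must be >= 1000")
        lo, hi = self.genome_length_range
        if not 0 < lo <= hi:
            raise ValueError("genome length range must be positive and ordered")
        for group, effects in self.groups.items():
            unknown = set(effects) - set(CATEGORIES)
            if unknown:
                raise ValueError(f"group '{group}': unknown categories {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruth:
    """True cell counts with the metadata needed to analyse them."""

    counts: pd.DataFrame  # samples x species, true cells
    categories: Mapping[str, str]  # species -> clinical category
    group_of: Mapping[str, str]  # sample -> group label
    genomes: Mapping[str, float]  # taxon (species + spikes) -> genome length bp
    tree: TreeNode | None  # None for single-species communities
    config: SimulationConfig

    def classification_table(self) -> ClassificationTable:
        """All simulated species as oral taxa with their single category."""
        records = {
            species: ClassificationRecord(
                source="oral", categories=frozenset([cat]), media_groups=frozenset()
            )
            for species, cat in self.categories.items()
        }
        return ClassificationTable(records)

    def group_series(self) -> pd.Series:
        return pd.Series(dict(self.group_of))


def simulate_tree(
    species_ids, seed: int | None = None, branch_scale: float = 0.1
) -> TreeNode:
    """Random rooted binary tree over the species, exponential branch lengths.

    Built by repeated random joins (a coalescent-like topology); a tree over
    n species has exactly n - 1 internal nodes.  Deterministic per seed.
    """
    species_ids = [str(s) for s in species_ids]
    if len(species_ids) < 2:
        raise ValueError("a tree needs at least 2 species")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=s) for s in species_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.exponential(branch_scale))
        right.length = float(rng.exponential(branch_scale))
        nodes.append(TreeNode(children=[left, right]))
    root = nodes[0]
    root.length = None
    return root


def simulate_community(config: SimulationConfig) -> GroundTruth:
    """Draw ground-truth cell counts per species per sample.

    Species baseline means come from Normal(base_log10_mean, base_log10_sd)
    on the log10 scale; a sample in group g shifts species of category c by
    the group's effect[c]; per-sample noise is Normal(0, sample_log10_sd).
    """
    rng = np.random.default_rng(config.seed)
    species = [f"Species {i + 1:03d}" for i in range(config.n_species)]
    categories = {
        s: CATEGORIES[int(rng.integers(len(CATEGORIES)))] for s in species
    }
    base = rng.normal(config.base_log10_mean, config.base_log10_sd, config.n_species)

    sample_ids, group_of, rows = [], {}, []
    for group, effects in config.groups.items():
        shift = np.array([effects.get(categories[s], 0.0) for s in species])
        for j in range(config.n_samples_per_group):
            sample = f"{group}_{j + 1:02d}"
            noise = rng.normal(0.0, config.sample_log10_sd, config.n_species)
            rows.append(10.0 ** (base + shift + noise))
            sample_ids.append(sample)
            group_of[sample] = group

    counts = pd.DataFrame(np.array(rows), index=sample_ids, columns=species)
    genomes = {
        s: float(rng.uniform(*config.genome_length_range)) for s in species
    }
    genomes.update(SPIKE_GENOME_LENGTHS)
    tree = (
        simulate_tree(species, seed=int(rng.integers(2**31)))
        if len(species) >= 2
        else None
    )
    return GroundTruth(
        counts=counts,
        categories=categories,
        group_of=group_of,
        genomes=genomes,
        tree=tree,
        config=config,
    )


def simulate_sequencing(
    truth: GroundTruth,
    spikes: SpikeInSpec | None = None,
    depth: int | None = None,
    seed: int | None = None,
    per_bp_mass: float = PER_BP_MASS_DS_DNA,
    extraction_efficiency: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Forward-simulate spiked shotgun sequencing into relative abundances.

    Per-taxon DNA mass is cells x genome length x per-bp mass / Avogadro
    (x an optional per-taxon extraction efficiency, default 1), plus the
    spike input masses.  With ``depth`` given, reads are multinomial with
    mass-proportional probabilities and relative abundance = count / depth;
    with ``depth=None`` the exact mass fractions are returned (the
    infinite-depth limit).
    """
    spikes = spikes if spikes is not None else truth.config.spike_spec
    efficiency = dict(extraction_efficiency or {})
    species = list(truth.counts.columns)
    taxa = species + list(spikes.taxa)

    mw = {s: truth.genomes[s] * per_bp_mass for s in species}
    spike_mass = spikes.masses
    rng = np.random.default_rng(seed)

    profiles = np.zeros((len(truth.counts), len(taxa)))
    cells = truth.counts.to_numpy()
    for i in range(len(truth.counts)):
        mass = np.empty(len(taxa))
        for k, taxon in enumerate(taxa):
            if taxon in spike_mass:
                mass[k] = spike_mass[taxon]
            else:
                mass[k] = (
                    cells[i, k]
                    * efficiency.get(taxon, 1.0)
                    * mw[taxon]
                    / Avogadro
                    * 1e9  # g -> ng
                )
        probs = mass / mass.sum()
        if depth is None:
            profiles[i] = probs
        else:
            profiles[i] = rng.multinomial(int(depth), probs) / float(depth)
    return pd.DataFrame(profiles, index=truth.counts.index, columns=taxa)


def simulate_dataset(config: SimulationConfig):
    """One-call bundle: (truth, relative-abundance table with spikes).

    Sequencing depth and seeds are taken from the config; the returned table
    is ready for :class:`cmuquant.estimator.CmuQuantifier`.
    """
    truth = simulate_community(config)
    profiles = simulate_sequencing(
        truth, depth=config.sequencing_depth, seed=config.seed + 1
    )
    return truth, profiles
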