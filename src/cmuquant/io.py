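"""Readers/writers for the interchange formats and the end-to-end pipeline.

Conventions: all tables are UTF-8 and tab-delimited with '.' decimals and
"NA" for missing values; abundance tables are wide (rows = taxa, columns =
samples) on disk but samples x taxa in memory; taxon identifiers are
exact-match strings (no fuzzy species-name matching — use ``validate`` to
list mismatches).
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from . import __version__
from .classification import (
    CATEGORIES,
    ClassificationTable,
    load_classification,
    pool_category_abundance,
    summarize_classification,
)
from .differential import compare_groups
from .diversity import (
    Ordination,
    observed_richness,
    pcoa,
    permanova,
    shannon_weaver,
    unifrac_distance_matrix,
)
from .errors import ConfigurationError, ParseError, PipelineStageError
from .estimator import CmuQuantifier, log10_table
from .quantification import SpikeInSpec

logger = logging.getLogger("cmuquant")

MISSING = "NA"


# ---------------------------------------------------------------------------
# abundance tables


def _validate_wide(frame: pd.DataFrame, path) -> pd.DataFrame:
    if frame.index.duplicated().any():
        dupes = sorted(set(frame.index[frame.index.duplicated()]))
        raise ParseError(f"{path}: duplicate taxon rows {dupes}")
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric abundance value ({exc})") from exc
    if (frame.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative abundance values")
    return frame


def _to_proportions(frame: pd.DataFrame, path) -> pd.DataFrame:
    """Columns are samples.  Proportions pass through; counts renormalise."""
    values = frame.to_numpy()
    if values.size and values.max() > 1 + 1e-9:
        logger.info(
            "%s: values exceed 1, interpreting as counts and renormalising "
            "to proportions per sample",
            path,
        )
        sums = frame.sum(axis=0)
        if (sums <= 0).any():
            raise ParseError(f"{path}: sample with zero total count")
        return frame / sums
    sums = frame.sum(axis=0)
    bad = sums[sums > 1 + 1e-9]
    if len(bad):
        raise ParseError(
            f"{path}: per-sample proportions sum to more than 1 for "
            f"samples {list(bad.index)}"
        )
    return frame


def read_abundance_table(path, dialect: str = "wide_tsv") -> pd.DataFrame:
    """Read an abundance table into a samples x taxa DataFrame of proportions.

    ``wide_tsv``: rows = taxa, columns = samples.  ``biom_json``: BIOM 1.0
    JSON (dense or sparse).  Values that exceed 1 anywhere are interpreted
    as read counts and renormalised per sample with a logged notice.
    """
    if dialect == "wide_tsv":
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            raise ParseError(f"{path}: could not parse wide TSV ({exc})") from exc
        frame = _validate_wide(frame, path)
    elif dialect == "biom_json":
        frame = _read_biom_json(path)
    else:
        raise ValueError(f"unknown dialect '{dialect}'")
    result = _to_proportions(frame, path).T
    result.index.name = None
    result.columns.name = None
    return result


def _read_biom_json(path) -> pd.DataFrame:
    """Minimal BIOM 1.0 JSON reader (taxa rows x sample columns)."""
    with open(path) as handle:
        doc = json.load(handle)
    try:
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        matrix_type = doc["matrix_type"]
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: not a BIOM 1.0 JSON table ({exc})") from exc
    if len(set(taxa)) != len(taxa):
        raise ParseError(f"{path}: duplicate taxon ids")
    values = np.zeros((len(taxa), len(samples)))
    if matrix_type == "dense":
        values[:] = np.asarray(data, dtype=float)
    elif matrix_type == "sparse":
        for i, j, v in data:
            values[int(i), int(j)] = float(v)
    else:
        raise ParseError(f"{path}: unknown matrix_type '{matrix_type}'")
    if (values < 0).any():
        raise ParseError(f"{path}: negative abundance values")
    return pd.DataFrame(values, index=taxa, columns=samples)


def write_abundance_table(table: pd.DataFrame, path) -> None:
    """Write a samples x taxa table as wide TSV (rows = taxa)."""
    table.T.to_csv(path, sep="\t", na_rep=MISSING, index_label="taxon_id")


write_cmu_table = write_abundance_table


def read_cmu_table(path) -> pd.DataFrame:
    """Read a wide CMU TSV back into a samples x taxa DataFrame.

    Unlike :func:`read_abundance_table` no proportion handling is applied:
    CMUs are absolute cell counts and must never be renormalised.
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: could not parse wide TSV ({exc})") from exc
    result = _validate_wide(frame, path).T
    result.index.name = None
    result.columns.name = None
    return result


def write_cmu_long(table: pd.DataFrame, path, log_floor: float = 1.0) -> None:
    """Long-format CMU TSV: sample_id, taxon_id, cmu, log10_cmu."""
    log_frame = log10_table(table, log_floor)
    long = table.stack().rename("cmu").reset_index()
    long.columns = ["sample_id", "taxon_id", "cmu"]
    long["log10_cmu"] = log_frame.stack().to_numpy()
    long.to_csv(path, sep="\t", index=False, na_rep=MISSING)


# ---------------------------------------------------------------------------
# spike / genome / metadata tables


def read_spike_csv(path) -> SpikeInSpec:
    frame = pd.read_csv(path)
    required = {"taxon_id", "input_dna_mass_ng"}
    if not required <= set(frame.columns):
        raise ParseError(f"{path}: spike CSV needs columns {sorted(required)}")
    try:
        return SpikeInSpec(
            list(zip(frame["taxon_id"], frame["input_dna_mass_ng"].astype(float)))
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_spike_csv(spikes: SpikeInSpec, path) -> None:
    pd.DataFrame(spikes.entries, columns=["taxon_id", "input_dna_mass_ng"]).to_csv(
        path, index=False
    )


def read_genome_csv(path) -> dict[str, float]:
    frame = pd.read_csv(path)
    required = {"taxon_id", "genome_length_bp"}
    if not required <= set(frame.columns):
        raise ParseError(f"{path}: genome CSV needs columns {sorted(required)}")
    if frame["taxon_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate taxon_id rows")
    lengths = frame["genome_length_bp"].astype(float)
    if (lengths <= 0).any():
        raise ParseError(f"{path}: genome lengths must be positive")
    return dict(zip(frame["taxon_id"].astype(str), lengths))


def write_genome_csv(genomes: dict[str, float], path) -> None:
    pd.DataFrame(
        sorted(genomes.items()), columns=["taxon_id", "genome_length_bp"]
    ).to_csv(path, index=False)


def read_sample_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV with at least sample_id plus e.g. group columns."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in frame.columns:
        raise ParseError(f"{path}: metadata needs a sample_id column")
    if frame["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id rows")
    return frame.set_index("sample_id")


# ---------------------------------------------------------------------------
# trees and distance matrices


def read_newick(path) -> TreeNode:
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ParseError(f"{path}: could not parse newick ({exc})") from exc
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ParseError(f"{path}: branch without a length")
        if node.length < 0:
            raise ParseError(f"{path}: negative branch length")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def newick_string(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ParseError(f"{path}: distance matrix row/column ids disagree")
    return DistanceMatrix(frame.to_numpy(dtype=float), ids=list(frame.index))


def write_ordination(ordination: Ordination, coords_path, eigen_path) -> None:
    ordination.coordinates.to_csv(coords_path, sep="\t", index_label="sample_id")
    n_pos = len(ordination.proportion_explained)
    eigen = pd.DataFrame(
        {
            "axis": [f"PC{i + 1}" for i in range(len(ordination.eigenvalues))],
            "eigenvalue": ordination.eigenvalues,
            "proportion_explained": list(ordination.proportion_explained)
            + [MISSING] * (len(ordination.eigenvalues) - n_pos),
        }
    )
    eigen.to_csv(eigen_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Paths and options for a full quantify -> classify -> diversity ->
    compare run.  ``metadata`` (sample_id/group TSV) enables the comparison
    and PERMANOVA stages; without it they are skipped with a notice."""

    profiles: str
    spikes: str
    genomes: str
    classification: str
    out_dir: str
    tree: str | None = None
    metadata: str | None = None
    group_column: str = "group"
    dialect: str = "wide_tsv"
    through_origin: bool = True
    per_bp_mass: float = 660.0
    copies_per_cell: float = 1.0
    log_floor: float = 1.0
    normalized_unifrac: bool = True
    n_perm: int = 999
    seed: int = 0

    def validate(self) -> None:
        for label in ("profiles", "spikes", "genomes", "classification"):
            value = getattr(self, label)
            if not Path(value).exists():
                raise ConfigurationError(f"{label} path does not exist: {value}")
        for label in ("tree", "metadata"):
            value = getattr(self, label)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{label} path does not exist: {value}")
        if self.log_floor <= 0 or self.per_bp_mass <= 0 or self.copies_per_cell <= 0:
            raise ConfigurationError("numeric options must be positive")
        if self.n_perm < 99:
            raise ConfigurationError("n_perm must be >= 99")


def _stage(name):
    def wrap(func):
        def inner(*args, **kwargs):
            try:
                return func(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the full analysis and write the artifact directory.

    Returns a mapping of artifact name -> written path.  Idempotent for
    identical inputs and seeds.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    notices: list[str] = []

    @_stage("quantify")
    def quantify():
        table = read_abundance_table(config.profiles, config.dialect)
        spikes = read_spike_csv(config.spikes)
        genomes = read_genome_csv(config.genomes)
        quantifier = CmuQuantifier(
            spikes=spikes,
            genomes=genomes,
            through_origin=config.through_origin,
            per_bp_mass=config.per_bp_mass,
            copies_per_cell=config.copies_per_cell,
        )
        cmus = quantifier.fit_transform(table)
        write_cmu_table(cmus, out / "cmu_wide.tsv")
        write_cmu_long(cmus, out / "cmu_long.tsv", config.log_floor)
        written["cmu_wide"] = str(out / "cmu_wide.tsv")
        written["cmu_long"] = str(out / "cmu_long.tsv")
        if quantifier.skipped_taxa_:
            notices.append(
                f"{len(quantifier.skipped_taxa_)} taxa lacked genome records "
                "and were skipped"
            )
        return cmus, quantifier

    cmus, quantifier = quantify()

    @_stage("classify")
    def classify():
        table = load_classification(config.classification)
        counts = summarize_classification(table, set(cmus.columns))
        pd.DataFrame(sorted(counts.items()), columns=["label", "count"]).to_csv(
            out / "classification_counts.tsv", sep="\t", index=False
        )
        written["classification_counts"] = str(out / "classification_counts.tsv")
        rows = []
        for sample_id in cmus.index:
            profile = quantifier._results_[str(sample_id)]
            for category in CATEGORIES:
                pooled, log_pooled = pool_category_abundance(
                    profile, table, category, config.log_floor
                )
                rows.append(
                    {
                        "sample_id": sample_id,
                        "category": category,
                        "pooled_cmu": pooled,
                        "log10_pooled_cmu": log_pooled,
                    }
                )
        pd.DataFrame(rows).to_csv(
            out / "category_totals.tsv", sep="\t", index=False
        )
        written["category_totals"] = str(out / "category_totals.tsv")
        return table

    classification = classify()

    @_stage("diversity")
    def diversity():
        alpha = pd.DataFrame(
            {
                "sample_id": cmus.index,
                "observed_richness": [
                    observed_richness(row.to_dict()) for _, row in cmus.iterrows()
                ],
                "shannon": [
                    shannon_weaver(row.to_dict()) for _, row in cmus.iterrows()
                ],
            }
        )
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False)
        written["alpha_diversity"] = str(out / "alpha_diversity.tsv")
        if config.tree is None:
            notices.append("no tree provided; UniFrac/PCoA/PERMANOVA skipped")
            return None
        tree = read_newick(config.tree)
        dm = unifrac_distance_matrix(tree, cmus, config.normalized_unifrac)
        write_distance_matrix(dm, out / "weighted_unifrac.tsv")
        written["weighted_unifrac"] = str(out / "weighted_unifrac.tsv")
        ordination = pcoa(dm)
        write_ordination(
            ordination, out / "pcoa_coordinates.tsv", out / "pcoa_eigenvalues.tsv"
        )
        written["pcoa_coordinates"] = str(out / "pcoa_coordinates.tsv")
        written["pcoa_eigenvalues"] = str(out / "pcoa_eigenvalues.tsv")
        return dm

    dm = diversity()

    @_stage("compare")
    def compare():
        if config.metadata is None:
            notices.append("no sample metadata; group comparison skipped")
            return
        metadata = read_sample_metadata(config.metadata)
        if config.group_column not in metadata.columns:
            raise ConfigurationError(
                f"metadata lacks group column '{config.group_column}'"
            )
        groups = metadata[config.group_column].reindex(
            [str(s) for s in cmus.index]
        )
        table = compare_groups(
            cmus, groups, classification, log_floor=config.log_floor
        )
        table.to_csv(
            out / "group_comparison.tsv",
            sep="\t",
            index=False,
            na_rep=MISSING,
            float_format="%.6g",
        )
        written["group_comparison"] = str(out / "group_comparison.tsv")
        if dm is not None:
            result = permanova(
                dm, list(groups), n_perm=config.n_perm, seed=config.seed
            )
            with open(out / "permanova.json", "w") as handle:
                json.dump(
                    {
                        "pseudo_F": result.pseudo_f,
                        "p_value": result.p_value,
                        "n_permutations": result.n_permutations,
                        "n_samples": result.n_samples,
                        "n_groups": result.n_groups,
                        "seed": config.seed,
                    },
                    handle,
                    indent=2,
                )
            written["permanova"] = str(out / "permanova.json")

    compare()

    metadata_record = {
        "cmuquant_version": __version__,
        "options": {
            "through_origin": config.through_origin,
            "per_bp_mass": config.per_bp_mass,
            "copies_per_cell": config.copies_per_cell,
            "log_floor": config.log_floor,
            "normalized_unifrac": config.normalized_unifrac,
            "n_perm": config.n_perm,
            "seed": config.seed,
        },
        "inputs": {
            "profiles": str(config.profiles),
            "spikes": str(config.spikes),
            "genomes": str(config.genomes),
            "classification": str(config.classification),
            "tree": config.tree and str(config.tree),
            "metadata": config.metadata and str(config.metadata),
        },
        "notices": notices,
        "artifacts": written,
    }
    with open(out / "run_metadata.json", "w") as handle:
        json.dump(metadata_record, handle, indent=2)
    written["run_metadata"] = str(out / "run_metadata.json")
    return written
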