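"""Clinical-relevance classification of oral taxa and pooled abundances.

Species detected in dental plaque fall into three sources: genuinely oral
taxa, extraoral contaminants (skin, environment, reagents), and taxa that
cannot be classified.  Oral taxa additionally carry clinical-relevance
categories curated from the literature (commensal, gingivitis-associated,
periodontitis-associated, malodor-associated, cariogenic/acidogenic, oral
health-associated, opportunistic and infectious pathogens); a species may
belong to several categories.  Selective-media groups map species onto the
classical culture counts (total anaerobes, fusobacteria, streptococci,
Actinomyces) so that sequencing-derived totals can be compared with
historical plate-count data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

from .errors import ParseError
from .quantification import CmuProfile, log10_cmu

SOURCES = ("oral", "extraoral_contaminant", "unknown_unclassified")

CATEGORIES = (
    "commensal",
    "gingivitis",
    "periodontitis",
    "malodor",
    "caries",
    "oral_health_associated",
    "opportunistic_pathogen",
    "infectious_pathogen",
)

MEDIA_GROUPS = ("total_anaerobe", "fusobacteria", "streptococci", "actinomyces")

#: Full permanent dentition (third molars included) vs. teeth sampled for
#: plaque; the ratio scales sampled totals up to whole-mouth equivalents.
DEFAULT_TEETH_TOTAL = 28
DEFAULT_TEETH_SAMPLED = 4


@dataclass(frozen=True)
class ClassificationRecord:
    source: str
    categories: frozenset[str]
    media_groups: frozenset[str]

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source label '{self.source}'")
        bad = set(self.categories) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown clinical categories {sorted(bad)}")
        bad = set(self.media_groups) - set(MEDIA_GROUPS)
        if bad:
            raise ValueError(f"unknown media groups {sorted(bad)}")
        if self.categories and self.source != "oral":
            raise ValueError(
                "clinical categories may only be carried by oral taxa "
                f"(source '{self.source}')"
            )


class ClassificationTable:
    """taxon_id -> (source, clinical categories, selective-media groups)."""

    def __init__(self, records: Mapping[str, ClassificationRecord]):
        self.records = dict(records)

    def __len__(self):
        return len(self.records)

    def __contains__(self, taxon_id):
        return taxon_id in self.records

    @property
    def taxa(self) -> set[str]:
        return set(self.records)

    def source_of(self, taxon_id: str) -> str:
        rec = self.records.get(taxon_id)
        return rec.source if rec is not None else "unknown_unclassified"

    def taxa_in_category(self, category: str) -> set[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown clinical category '{category}'")
        return {t for t, r in self.records.items() if category in r.categories}

    def taxa_in_media_group(self, group: str) -> set[str]:
        if group not in MEDIA_GROUPS:
            raise ValueError(f"unknown media group '{group}'")
        return {t for t, r in self.records.items() if group in r.media_groups}

    def oral_taxa(self) -> set[str]:
        return {t for t, r in self.records.items() if r.source == "oral"}


def _split_field(value: str) -> frozenset[str]:
    value = (value or "").strip()
    if not value:
        return frozenset()
    return frozenset(part.strip() for part in value.split(";") if part.strip())


def load_classification(path) -> ClassificationTable:
    """Read a classification CSV (taxon_id, source, categories, media_groups).

    ``categories`` and ``media_groups`` are semicolon-delimited; rows with a
    duplicate taxon_id, an unknown source label, or clinical categories on a
    non-oral taxon are rejected.
    """
    records: dict[str, ClassificationRecord] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        required = {"taxon_id", "source", "categories", "media_groups"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(
                f"{path}: classification CSV must have columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            taxon = (row["taxon_id"] or "").strip()
            if not taxon:
                raise ParseError(f"{path}:{lineno}: empty taxon_id")
            if taxon in records:
                raise ParseError(f"{path}:{lineno}: duplicate taxon_id '{taxon}'")
            try:
                records[taxon] = ClassificationRecord(
                    source=(row["source"] or "").strip(),
                    categories=_split_field(row["categories"]),
                    media_groups=_split_field(row["media_groups"]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return ClassificationTable(records)


def load_builtin_classification() -> ClassificationTable:
    """Load the bundled synthetic classification fixture.

    The fixture is a deterministic stand-in for a literature-curated
    classification of an 856-taxon plaque survey: 213 oral species, 257
    extraoral contaminants and 386 unknown/unclassified taxa, with clinical
    category and selective-media marginal counts matching the published
    survey it emulates.  Individual memberships (beyond a handful of
    well-known species) are synthetic.
    """
    ref = resources.files("cmuquant").joinpath("data/classification_fixture.csv")
    with resources.as_file(ref) as path:
        return load_classification(path)


def summarize_classification(
    table: ClassificationTable, universe: Iterable[str]
) -> dict[str, int]:
    """Count taxa of ``universe`` per source, category and media group.

    Universe taxa absent from the table count as unknown_unclassified; the
    three source counts always partition the universe (they sum to
    ``total``).  Category and media counts overlap and do not.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("taxon universe must be non-empty")
    counts = {"total": len(universe)}
    for source in SOURCES:
        counts[source] = sum(1 for t in universe if table.source_of(t) == source)
    for category in CATEGORIES:
        counts[category] = len(table.taxa_in_category(category) & universe)
    for group in MEDIA_GROUPS:
        counts[group] = len(table.taxa_in_media_group(group) & universe)
    return counts


def pool_category_abundance(
    cmu: CmuProfile,
    table: ClassificationTable,
    category: str,
    log_floor: float = 1.0,
) -> tuple[float, float]:
    """Pooled CMU total over one clinical category, and its log10.

    Raw CMUs of the member species are summed first and the log is taken of
    the sum; pooling is confined to the single named category so overlapping
    memberships in other categories cannot inflate it.
    """
    members = table.taxa_in_category(category)
    pooled = float(sum(v for t, v in cmu.cmus.items() if t in members))
    return pooled, log10_cmu(pooled, log_floor)


def media_equivalent_total(
    cmu: CmuProfile,
    table: ClassificationTable,
    media_group: str,
    teeth_sampled: int = DEFAULT_TEETH_SAMPLED,
    teeth_total: int = DEFAULT_TEETH_TOTAL,
    log_floor: float = 1.0,
) -> float:
    """Whole-mouth selective-media-equivalent total, log10 transformed.

    Sums CMUs over the species of a selective-media group, scales the
    sampled-teeth total to the whole dentition (x teeth_total/teeth_sampled),
    and returns log10.  On the log scale the adjustment adds exactly
    log10(teeth_total/teeth_sampled).
    """
    if not 1 <= teeth_sampled <= teeth_total:
        raise ValueError(
            f"teeth_sampled must be in [1, teeth_total]; got "
            f"{teeth_sampled}/{teeth_total}"
        )
    members = table.taxa_in_media_group(media_group)
    total = sum(v for t, v in cmu.cmus.items() if t in members)
    adjusted = total * (teeth_total / teeth_sampled)
    return log10_cmu(adjusted, log_floor)


def total_microbial_load(
    cmu: CmuProfile, table: ClassificationTable, scope: str = "oral_only"
) -> float:
    """Total microbial load (TML): summed CMUs over the scoped taxa.

    ``oral_only`` (default) restricts the sum to taxa classified as oral;
    ``all_taxa`` sums everything in the profile.
    """
    if scope == "all_taxa":
        return cmu.total()
    if scope == "oral_only":
        oral = table.oral_taxa()
        return float(sum(v for t, v in cmu.cmus.items() if t in oral))
    raise ValueError(f"unknown TML scope '{scope}' (use 'oral_only' or 'all_taxa')")
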