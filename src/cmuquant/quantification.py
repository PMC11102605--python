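"""Spike-in calibrated absolute quantification of shotgun metagenomic profiles.

Shotgun metagenomic pipelines report *relative* abundances, which cannot
distinguish a bloom of one taxon from a loss of the others.  Adding known
masses of DNA from organisms foreign to the habitat (spike-in controls)
before extraction preserves the absolute scale: within each sample, the
observed relative abundance of every spike organism is paired with its known
input DNA mass, a per-sample linear calibration curve is fitted, and the
curve converts any taxon's relative abundance into an estimated DNA mass.
Dividing that mass by the taxon's genome molecular weight (genome length x
average mass per base pair) and multiplying by Avogadro's number yields an
estimated genome — hence cell — count, the *calculated microbial unit* (CMU).

The per-sample calibration is an ordinary least-squares regression of spike
input DNA mass (response, ng) on observed relative abundance (predictor,
fraction).  By default the line is constrained through the origin, since a
taxon with zero abundance carries zero DNA; a free-intercept variant is
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.constants import Avogadro

from .errors import (
    CalibrationError,
    ConfigurationError,
    DegenerateDesignError,
    InvalidCalibrationError,
)

#: The three spike-in organisms of ZymoBIOMICS Spike-in Control II, all
#: foreign to the oral habitat.
SPIKE_IN_TAXA = (
    "Truepera radiovictrix",
    "Imtechella halotolerans",
    "Allobacillus halotolerans",
)

#: Average molecular weight of one double-stranded DNA base pair (g/mol/bp).
PER_BP_MASS_DS_DNA = 660.0


@dataclass(frozen=True)
class SpikeInSpec:
    """Known input DNA masses of the spike-in organisms, in ng per sample.

    Parameters
    ----------
    entries : mapping or iterable of (taxon_id, mass_ng)
        Input DNA mass per spike organism.  At least two entries with
        distinct masses are required for a two-point calibration; all
        masses must be positive.
    """

    entries: tuple[tuple[str, float], ...]

    def __init__(self, entries: Mapping[str, float] | Iterable[tuple[str, float]]):
        if isinstance(entries, Mapping):
            entries = entries.items()
        entries = tuple((str(t), float(m)) for t, m in entries)
        taxa = [t for t, _ in entries]
        if len(set(taxa)) != len(taxa):
            raise ValueError("spike-in taxon_ids must be unique")
        if not entries:
            raise ValueError("a spike-in specification needs at least 1 organism")
        masses = [m for _, m in entries]
        if any(m <= 0 for m in masses):
            raise ValueError("spike-in input DNA masses must be positive")
        # a single spike supports only a through-origin calibration; with
        # several spikes the masses must differ for the line to be identified
        if len(masses) >= 2 and len(set(masses)) < 2:
            raise ValueError("spike-in input DNA masses must not all be equal")
        object.__setattr__(self, "entries", entries)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.entries)

    @property
    def masses(self) -> dict[str, float]:
        return dict(self.entries)

    def scaled(self, factor: float) -> "SpikeInSpec":
        """Return a copy with every input mass multiplied by ``factor``."""
        return SpikeInSpec([(t, m * factor) for t, m in self.entries])


@dataclass(frozen=True)
class AbundanceProfile:
    """One sample's species-level relative abundances, spike-ins included."""

    sample_id: str
    abundances: Mapping[str, float]

    def __post_init__(self):
        abund = {str(t): float(v) for t, v in dict(self.abundances).items()}
        if any(v < 0 for v in abund.values()):
            raise ValueError(f"sample {self.sample_id}: negative relative abundance")
        if sum(abund.values()) > 1 + 1e-9:
            raise ValueError(
                f"sample {self.sample_id}: relative abundances sum to more than 1"
            )
        object.__setattr__(self, "abundances", abund)


@dataclass(frozen=True)
class CalibrationModel:
    """Per-sample linear map from relative abundance to DNA mass (ng).

    ``slope`` is in ng per unit relative abundance; ``r_squared`` is the
    coefficient of determination of the spike-point fit (uncentred for
    through-origin fits, as is standard for no-intercept regression).
    """

    sample_id: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self):
        if not math.isfinite(self.slope) or self.slope <= 0:
            raise InvalidCalibrationError(
                f"sample {self.sample_id}: calibration slope must be finite and > 0, "
                f"got {self.slope}"
            )
        if self.n_points < 1:
            raise ValueError("a calibration needs at least one spike point")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")

    def predict(self, rel_abundance: float) -> float:
        return estimate_dna_mass(self, rel_abundance)


@dataclass(frozen=True)
class GenomeRecord:
    """A taxon's genome length and derived molecular weight."""

    taxon_id: str
    genome_length: float  # bp
    per_bp_mass: float = PER_BP_MASS_DS_DNA  # g/mol per bp

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError(f"{self.taxon_id}: genome length must be > 0")
        if self.per_bp_mass <= 0:
            raise ValueError("per-base-pair mass must be > 0")

    @property
    def molecular_weight(self) -> float:
        """Genome molecular weight in g/mol."""
        return genome_molecular_weight(self.genome_length, self.per_bp_mass)


@dataclass(frozen=True)
class CmuProfile:
    """One sample's absolute cell counts (CMUs) per taxon.

    Spike-in taxa are never part of ``cmus``; native taxa that lacked a
    genome record are listed in ``skipped`` rather than silently dropped.
    """

    sample_id: str
    cmus: Mapping[str, float]
    skipped: tuple[str, ...] = field(default=())

    def __post_init__(self):
        cmus = {str(t): float(v) for t, v in dict(self.cmus).items()}
        if any(v < 0 for v in cmus.values()):
            raise ValueError(f"sample {self.sample_id}: negative CMU")
        object.__setattr__(self, "cmus", cmus)
        object.__setattr__(self, "skipped", tuple(self.skipped))

    def total(self) -> float:
        return float(sum(self.cmus.values()))


def fit_spike_calibration(
    profile: AbundanceProfile,
    spikes: SpikeInSpec,
    through_origin: bool = True,
) -> CalibrationModel:
    """Fit the per-sample calibration of spike input DNA mass on abundance.

    Ordinary least squares with input mass (ng) as the response and observed
    relative abundance as the predictor.  With ``through_origin`` the
    intercept is fixed at zero (one spike point suffices); otherwise at
    least two spike points with distinct abundances are required.

    Raises
    ------
    CalibrationError
        If a spike taxon is absent from the profile or observed at zero.
    DegenerateDesignError
        If all spike abundances coincide in a free-intercept fit.
    InvalidCalibrationError
        If the fitted slope is not finite and positive.
    """
    r, d = [], []
    for taxon, mass in spikes.entries:
        obs = profile.abundances.get(taxon, 0.0)
        if obs <= 0:
            raise CalibrationError(
                f"sample {profile.sample_id}: spike-in taxon '{taxon}' absent "
                "from the profile (or observed at zero abundance)"
            )
        r.append(obs)
        d.append(mass)
    r = np.asarray(r, dtype=float)
    d = np.asarray(d, dtype=float)
    n = len(r)

    if through_origin:
        slope = float(np.dot(r, d) / np.dot(r, r))
        intercept = 0.0
        resid = d - slope * r
        ss_tot = float(np.dot(d, d))  # uncentred total SS for no-intercept fit
    else:
        if n < 2:
            raise CalibrationError(
                "a free-intercept calibration needs at least 2 spike points"
            )
        if np.ptp(r) == 0:
            raise DegenerateDesignError(
                f"sample {profile.sample_id}: all spike abundances are equal; "
                "the free-intercept design is singular"
            )
        slope, intercept = (float(v) for v in np.polyfit(r, d, 1))
        resid = d - (intercept + slope * r)
        ss_tot = float(np.sum((d - d.mean()) ** 2))

    ss_res = float(np.dot(resid, resid))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r_squared = float(min(1.0, max(0.0, r_squared)))

    if not math.isfinite(slope) or slope <= 0:
        raise InvalidCalibrationError(
            f"sample {profile.sample_id}: fitted calibration slope {slope} is not "
            "positive; spike abundances are inconsistent with their input masses"
        )
    return CalibrationModel(
        sample_id=profile.sample_id,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        n_points=n,
    )


def estimate_dna_mass(model: CalibrationModel, rel_abundance: float) -> float:
    """DNA mass (ng) predicted for a relative abundance, floored at zero."""
    if rel_abundance < 0:
        raise ValueError(f"relative abundance must be >= 0, got {rel_abundance}")
    return max(0.0, model.intercept + model.slope * rel_abundance)


def genome_molecular_weight(
    genome_length: float, per_bp_mass: float = PER_BP_MASS_DS_DNA
) -> float:
    """Molecular weight (g/mol) of a genome of ``genome_length`` base pairs."""
    if genome_length <= 0:
        raise ValueError(f"genome length must be > 0, got {genome_length}")
    if per_bp_mass <= 0:
        raise ValueError(f"per-base-pair mass must be > 0, got {per_bp_mass}")
    return genome_length * per_bp_mass


def dna_to_cells(
    mass_ng: float, molecular_weight: float, copies_per_cell: float = 1.0
) -> float:
    """Convert a DNA mass (ng) into a genome — hence cell — count.

    cells = (mass * 1e-9 g / MW) * N_A / copies_per_cell, assuming by default
    one genome copy per cell.
    """
    if mass_ng < 0:
        raise ValueError(f"DNA mass must be >= 0, got {mass_ng}")
    if molecular_weight <= 0:
        raise ValueError(f"molecular weight must be > 0, got {molecular_weight}")
    if copies_per_cell <= 0:
        raise ValueError(f"copies per cell must be > 0, got {copies_per_cell}")
    return mass_ng * 1e-9 / molecular_weight * Avogadro / copies_per_cell


def log10_cmu(cmu: float, floor: float = 1.0) -> float:
    """log10 of a CMU value with a positive floor for zeros.

    The default floor of 1 cell maps empty taxa to log10 = 0; a sub-1 floor
    (e.g. 0.1) reproduces tables that print negative log abundances.
    """
    if floor <= 0:
        raise ValueError(f"log floor must be > 0, got {floor}")
    return math.log10(max(cmu, floor))


def quantify_sample(
    profile: AbundanceProfile,
    spikes: SpikeInSpec,
    catalog: Mapping[str, GenomeRecord] | Iterable[GenomeRecord],
    *,
    through_origin: bool = True,
    per_bp_mass: float | None = None,
    copies_per_cell: float = 1.0,
) -> CmuProfile:
    """Convert one relative-abundance profile into absolute CMUs.

    Composes calibration, mass estimation and the mass-to-cells conversion
    per native taxon.  Spike-in taxa are excluded from the output; native
    taxa without a genome record are reported in ``skipped``.

    Observed fractions are used as-is (no renormalisation after removing the
    spikes): the calibration maps raw observed fractions to mass, so
    renormalising would break it.
    """
    if not isinstance(catalog, Mapping):
        catalog = {g.taxon_id: g for g in catalog}
    if not catalog:
        raise ConfigurationError("genome catalog is empty")

    model = fit_spike_calibration(profile, spikes, through_origin=through_origin)
    spike_taxa = set(spikes.taxa)

    cmus: dict[str, float] = {}
    skipped: list[str] = []
    for taxon, rel in profile.abundances.items():
        if taxon in spike_taxa:
            continue
        record = catalog.get(taxon)
        if record is None:
            skipped.append(taxon)
            continue
        mw = genome_molecular_weight(
            record.genome_length,
            per_bp_mass if per_bp_mass is not None else record.per_bp_mass,
        )
        mass = estimate_dna_mass(model, rel)
        cmus[taxon] = dna_to_cells(mass, mw, copies_per_cell)
    return CmuProfile(sample_id=profile.sample_id, cmus=cmus, skipped=tuple(skipped))
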