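"""scikit-learn-style transformer for spike-in calibrated quantification.

`CmuQuantifier` turns a wide relative-abundance table (rows = samples,
columns = taxa, spike-ins included) into a table of absolute cell counts
(CMUs).  Calibration is *per sample*: ``fit`` learns one regression per row
from the spike-in columns, ``transform`` applies each sample's own curve to
its native taxa.  Because the fitted state is keyed by sample, ``transform``
only accepts samples seen during ``fit`` — the intended call is
``fit_transform`` on the full table, like other per-sample normalisers.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError
from .quantification import (
    PER_BP_MASS_DS_DNA,
    AbundanceProfile,
    CmuProfile,
    GenomeRecord,
    SpikeInSpec,
    log10_cmu,
    quantify_sample,
)


def _as_catalog(
    genomes: Mapping[str, float] | Mapping[str, GenomeRecord],
    per_bp_mass: float,
) -> dict[str, GenomeRecord]:
    catalog = {}
    for taxon, value in dict(genomes).items():
        if isinstance(value, GenomeRecord):
            catalog[str(taxon)] = value
        else:
            catalog[str(taxon)] = GenomeRecord(
                taxon_id=str(taxon), genome_length=float(value), per_bp_mass=per_bp_mass
            )
    return catalog


class CmuQuantifier(TransformerMixin, BaseEstimator):
    """Transform relative abundances into calculated microbial units (CMUs).

    Parameters
    ----------
    spikes : mapping taxon_id -> input DNA mass (ng), or SpikeInSpec
        Known spike-in input masses; at least two distinct positive masses.
    genomes : mapping taxon_id -> genome length (bp)
        Genome catalog for every native taxon to quantify.
    through_origin : bool, default True
        Constrain the per-sample calibration line through the origin.
    per_bp_mass : float, default 660.0
        Average molecular weight of one double-stranded base pair (g/mol/bp).
    copies_per_cell : float, default 1.0
        Genome copies assumed per cell.

    Attributes
    ----------
    calibrations_ : dict sample_id -> CalibrationModel
        Fitted per-sample calibration curves.
    skipped_taxa_ : tuple of str
        Native taxa present in the fitted table but absent from the catalog.
    feature_names_in_ : ndarray of str
        Taxon columns seen during fit.
    feature_names_out_ : ndarray of str
        Native (non-spike, catalogued) taxa emitted by transform.

    Examples
    --------
    >>> X = pd.DataFrame({"Truepera radiovictrix": [0.01],
    ...                   "Imtechella halotolerans": [0.02],
    ...                   "Allobacillus halotolerans": [0.04],
    ...                   "Streptococcus mitis": [0.1]}, index=["s1"])
    >>> q = CmuQuantifier(spikes={"Truepera radiovictrix": 0.1,
    ...                           "Imtechella halotolerans": 0.2,
    ...                           "Allobacillus halotolerans": 0.4},
    ...                   genomes={"Streptococcus mitis": 2_000_000})
    >>> cmus = q.fit_transform(X)
    """

    def __init__(
        self,
        spikes=None,
        genomes=None,
        through_origin: bool = True,
        per_bp_mass: float = PER_BP_MASS_DS_DNA,
        copies_per_cell: float = 1.0,
    ):
        self.spikes = spikes
        self.genomes = genomes
        self.through_origin = through_origin
        self.per_bp_mass = per_bp_mass
        self.copies_per_cell = copies_per_cell

    # -- validation helpers -------------------------------------------------

    def _check_config(self):
        if self.spikes is None:
            raise ConfigurationError("CmuQuantifier requires a spike-in specification")
        if self.genomes is None or not dict(self.genomes):
            raise ConfigurationError("CmuQuantifier requires a non-empty genome catalog")
        spec = (
            self.spikes
            if isinstance(self.spikes, SpikeInSpec)
            else SpikeInSpec(self.spikes)
        )
        catalog = _as_catalog(self.genomes, self.per_bp_mass)
        return spec, catalog

    @staticmethod
    def _check_table(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "CmuQuantifier expects a pandas DataFrame with samples as rows "
                "and taxa as named columns"
            )
        if X.columns.duplicated().any():
            raise ValueError("duplicate taxon columns in abundance table")
        values = X.to_numpy(dtype=float)
        if np.any(values < 0):
            raise ValueError("relative abundances must be non-negative")
        if np.any(values.sum(axis=1) > 1 + 1e-9):
            raise ValueError("per-sample relative abundances must sum to <= 1")
        return X.astype(float)

    def _profiles(self, X: pd.DataFrame):
        for sample_id, row in X.iterrows():
            yield AbundanceProfile(
                sample_id=str(sample_id),
                abundances={t: v for t, v in row.items() if v > 0},
            )

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None):
        """Fit one spike calibration curve per sample (row) of ``X``."""
        spec, catalog = self._check_config()
        X = self._check_table(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        spike_taxa = set(spec.taxa)
        native = [t for t in X.columns if t not in spike_taxa]
        self.feature_names_out_ = np.asarray(
            [t for t in native if t in catalog], dtype=object
        )
        self.skipped_taxa_ = tuple(t for t in native if t not in catalog)
        self.calibrations_ = {}
        self._results_ = {}
        for profile in self._profiles(X):
            result = quantify_sample(
                profile,
                spec,
                catalog,
                through_origin=self.through_origin,
                per_bp_mass=self.per_bp_mass,
                copies_per_cell=self.copies_per_cell,
            )
            self._results_[profile.sample_id] = result
            # quantify_sample refits internally; keep the model for reporting
            from .quantification import fit_spike_calibration

            self.calibrations_[profile.sample_id] = fit_spike_calibration(
                profile, spec, through_origin=self.through_origin
            )
        return self

    def transform(self, X) -> pd.DataFrame:
        """Return the CMU table for the fitted samples.

        Rows of ``X`` must have been seen during ``fit``; per-sample
        calibration does not generalise to unseen samples.
        """
        if not hasattr(self, "calibrations_"):
            raise RuntimeError("CmuQuantifier is not fitted; call fit or fit_transform")
        X = self._check_table(X)
        unseen = [str(s) for s in X.index if str(s) not in self._results_]
        if unseen:
            raise ValueError(
                "transform called with samples not seen during fit "
                f"(per-sample calibration): {unseen}"
            )
        out = pd.DataFrame(
            0.0, index=X.index, columns=list(self.feature_names_out_)
        )
        for sample_id in X.index:
            result = self._results_[str(sample_id)]
            for taxon, cmu in result.cmus.items():
                out.loc[sample_id, taxon] = cmu
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)

    # -- convenience --------------------------------------------------------

    def cmu_profiles(self) -> list[CmuProfile]:
        """Per-sample CmuProfile objects (with skipped-taxon lists)."""
        if not hasattr(self, "_results_"):
            raise RuntimeError("CmuQuantifier is not fitted")
        return list(self._results_.values())


def quantify_table(
    X: pd.DataFrame,
    spikes,
    genomes,
    *,
    through_origin: bool = True,
    per_bp_mass: float = PER_BP_MASS_DS_DNA,
    copies_per_cell: float = 1.0,
) -> pd.DataFrame:
    """Functional one-shot wrapper around :class:`CmuQuantifier`."""
    return CmuQuantifier(
        spikes=spikes,
        genomes=genomes,
        through_origin=through_origin,
        per_bp_mass=per_bp_mass,
        copies_per_cell=copies_per_cell,
    ).fit_transform(X)


def log10_table(X: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Element-wise log10 with a positive floor, for CMU tables."""
    return X.map(lambda v: log10_cmu(v, floor))
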