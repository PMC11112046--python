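"""Per-mutation feature assembly and two-stage feature selection.

Feature vectors concatenate four families: amino-acid property deltas,
mutation descriptors, evolutionary-profile (PSSM + conservation) features
and structure features at the mutation site.  Selection first drops one of
every highly correlated pair (|Pearson r| above a cutoff, 0.85 by default)
and then runs recursive feature elimination down to k features under a
seed-pinned random-forest importance.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import RFE

from .core_data import MutationDataset, MutationRecord
from .sequence_features import (ConservationProfile, PSSMProfile,
                                PropertyTable, conservation_feature,
                                delta_property, mutation_descriptors,
                                pssm_features)
from .structure_features import InterfaceRegion

logger = logging.getLogger(__name__)

DEFAULT_CORRELATION_CUTOFF = 0.85
DEFAULT_N_FEATURES = 50
DEFAULT_N_FEATURES_PER_CLASS = 20

REGION_COLUMNS = [f"region_{r.value}" for r in InterfaceRegion]
STRUCTURE_SCALAR_COLUMNS = [
    "sasa", "rsasa", "rsasa_monomer", "hbond_donors", "hbond_acceptors",
    "depth", "centrality_degree", "centrality_betweenness",
    "centrality_closeness", "centrality_eigenvector",
]


@dataclass
class FeatureMatrix:
    """Named feature columns x mutation rows with per-column family tags."""

    data: pd.DataFrame
    families: dict[str, str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature column names")
        unknown = set(self.data.columns) - set(self.families)
        if unknown:
            raise ValueError(f"columns without family tags: {sorted(unknown)}")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def to_files(self, tsv_path: str | Path) -> None:
        """Persist as TSV plus a JSON sidecar with families and provenance."""
        tsv_path = Path(tsv_path)
        self.data.to_csv(tsv_path, sep="\t", index_label="mutation")
        sidecar = tsv_path.with_suffix(tsv_path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"families": self.families, "provenance": self.provenance},
            indent=2, default=str))

    @classmethod
    def from_files(cls, tsv_path: str | Path) -> "FeatureMatrix":
        tsv_path = Path(tsv_path)
        data = pd.read_csv(tsv_path, sep="\t", index_col="mutation")
        sidecar = tsv_path.with_suffix(tsv_path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        return cls(data=data, families=meta["families"],
                   provenance=meta.get("provenance", {}))


@dataclass
class FeatureSpec:
    """Selected feature columns plus how and for which class they were chosen.

    Standardisation parameters (column means and standard deviations) are
    filled at model-fit time so prediction applies the identical transform.
    """

    selected: list[str]
    dropped_correlated: list[str] = field(default_factory=list)
    rfe_ranking: dict[str, int] = field(default_factory=dict)
    class_label: str | None = None
    standardize_mean: dict[str, float] = field(default_factory=dict)
    standardize_scale: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSpec":
        return cls(**json.loads(Path(path).read_text()))


class FeatureAssembler:
    """Resolves every feature family for mutation records.

    Providers are plain mappings so the assembler works identically with
    parsed real inputs and with synthetic fixtures:

    - ``pssms``: (complex_id, chain_id) -> PSSMProfile
    - ``conservation``: (complex_id, chain_id) -> ConservationProfile
    - ``structure_tables``: complex_id -> per-residue structure feature
      table (from :func:`ppamut.structure_features.residue_feature_table`)
    """

    def __init__(self,
                 property_table: PropertyTable | None = None,
                 pssms: Mapping[tuple[str, str], PSSMProfile] | None = None,
                 conservation: Mapping[tuple[str, str], ConservationProfile]
                 | None = None,
                 structure_tables: Mapping[str, pd.DataFrame] | None = None):
        self.property_table = property_table or PropertyTable.default()
        self.pssms = dict(pssms or {})
        self.conservation = dict(conservation or {})
        self.structure_tables = dict(structure_tables or {})

    @property
    def structure_columns(self) -> list[str]:
        return STRUCTURE_SCALAR_COLUMNS + REGION_COLUMNS

    def column_families(self) -> dict[str, str]:
        fams = {f"dp_{p}": "sequence" for p in self.property_table.property_names}
        fams.update({k: "mutation_descriptor"
                     for k in ("net_volume_change", "hydrophobicity_change",
                               "flexibility_change", "fluctuation_change")})
        fams.update({k: "sequence" for k in
                     ("pssm_score_wild", "pssm_score_mut", "pssm_score_delta",
                      "pssm_information", "conservation")})
        fams.update({k: "structure" for k in self.structure_columns})
        fams["structure_missing"] = "structure"
        return fams

    def assemble_row(self, record: MutationRecord,
                     sequence_position: int | None = None) -> pd.Series:
        """One deterministic feature row for a mutation record."""
        pos = sequence_position if sequence_position is not None else record.position
        row: dict[str, float] = {}
        for prop in self.property_table.property_names:
            row[f"dp_{prop}"] = delta_property(
                record.wild_aa, record.mutant_aa, prop, self.property_table)
        row.update(mutation_descriptors(record.wild_aa, record.mutant_aa,
                                        self.property_table))
        chain_key = (record.complex_id, record.chain_id)
        profile = self.pssms.get(chain_key)
        if profile is not None:
            row.update(pssm_features(profile, pos, record.wild_aa,
                                     record.mutant_aa))
        else:
            row.update({k: np.nan for k in
                        ("pssm_score_wild", "pssm_score_mut",
                         "pssm_score_delta", "pssm_information")})
        cons = self.conservation.get(chain_key)
        row["conservation"] = (conservation_feature(cons, pos)
                               if cons is not None else np.nan)

        table = self.structure_tables.get(record.complex_id)
        site = None
        if table is not None:
            hit = table[(table["chain"] == record.chain_id)
                        & (table["position"] == record.position)]
            if len(hit):
                site = hit.iloc[0]
        if site is not None:
            for col in STRUCTURE_SCALAR_COLUMNS:
                row[col] = float(site[col])
            for region_col in REGION_COLUMNS:
                row[region_col] = float(
                    region_col == f"region_{site['region']}")
            row["structure_missing"] = 0.0
        else:
            for col in STRUCTURE_SCALAR_COLUMNS + REGION_COLUMNS:
                row[col] = np.nan
            row["structure_missing"] = 1.0
        fams = self.column_families()
        return pd.Series(row, index=list(fams))


def assemble_features(dataset: MutationDataset,
                      assembler: FeatureAssembler,
                      impute: bool = True) -> FeatureMatrix:
    """Feature matrix for every record of a dataset, rows keyed by the
    mutation identity key.

    Missing structural/profile features are median-imputed (flagged by the
    ``structure_missing`` indicator column) so sequence-only prediction
    remains possible; all-missing columns fall back to 0.
    """
    rows, index = [], []
    for rec in dataset.records:
        rows.append(assembler.assemble_row(
            rec, sequence_position=dataset.sequence_position(rec)))
        index.append("_".join(map(str, rec.key)))
    data = pd.DataFrame(rows, index=pd.Index(index, name="mutation"))
    if impute and data.isna().any().any():
        medians = data.median()
        data = data.fillna(medians.fillna(0.0))
    return FeatureMatrix(
        data=data,
        families=assembler.column_families(),
        provenance={"n_records": len(dataset),
                    "properties": assembler.property_table.property_names},
    )


def correlation_filter(matrix: pd.DataFrame,
                       cutoff: float = DEFAULT_CORRELATION_CUTOFF,
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Greedy decorrelation: scanning columns in order, drop a column iff
    its absolute Pearson correlation with an already-retained column is
    strictly above the cutoff.  Zero-variance columns are dropped first.

    Returns the reduced matrix and the dropped column names.
    """
    if len(matrix) < 2:
        raise ValueError("correlation undefined on fewer than 2 rows")
    dropped: list[str] = []
    variances = matrix.var(ddof=0)
    constant = [c for c in matrix.columns if variances[c] == 0]
    if constant:
        logger.info("dropping %d zero-variance columns: %s",
                    len(constant), constant)
        dropped.extend(constant)
    work = matrix.drop(columns=constant)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = work.corr().abs()
    retained: list[str] = []
    for col in work.columns:
        if retained and (corr.loc[col, retained] > cutoff).any():
            dropped.append(col)
        else:
            retained.append(col)
    return matrix[retained], dropped


def _default_rfe_estimator(seed: int | None) -> RandomForestRegressor:
    return RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)


def rfe_select(matrix: pd.DataFrame, target: np.ndarray, k: int = DEFAULT_N_FEATURES,
               base_estimator=None, seed: int | None = None,
               class_label: str | None = None) -> FeatureSpec:
    """Recursive feature elimination to the top k columns.

    Fits the base estimator (random-forest importance by default),
    eliminates the single least-important column, and repeats until k
    remain.  Deterministic under a fixed seed.
    """
    if k > matrix.shape[1]:
        raise ValueError(f"k={k} exceeds {matrix.shape[1]} columns")
    if len(matrix) < 2 * k:
        warnings.warn(f"only {len(matrix)} rows for k={k} features; "
                      "selection may be unstable", stacklevel=2)
    if k == matrix.shape[1]:
        return FeatureSpec(selected=list(matrix.columns),
                           rfe_ranking={c: 1 for c in matrix.columns},
                           class_label=class_label)
    estimator = (base_estimator if base_estimator is not None
                 else _default_rfe_estimator(seed))
    rfe = RFE(estimator, n_features_to_select=k, step=1)
    rfe.fit(matrix.to_numpy(float), np.asarray(target, float))
    ranking = {c: int(r) for c, r in zip(matrix.columns, rfe.ranking_)}
    selected = [c for c, keep in zip(matrix.columns, rfe.support_) if keep]
    return FeatureSpec(selected=selected, rfe_ranking=ranking,
                       class_label=class_label)


def select_features(matrix: FeatureMatrix, target: np.ndarray,
                    k: int = DEFAULT_N_FEATURES_PER_CLASS,
                    correlation_cutoff: float = DEFAULT_CORRELATION_CUTOFF,
                    seed: int | None = None,
                    class_label: str | None = None) -> FeatureSpec:
    """Two-stage selection: correlation filter then RFE to k features."""
    reduced, dropped = correlation_filter(matrix.data, correlation_cutoff)
    k_eff = min(k, reduced.shape[1])
    spec = rfe_select(reduced, target, k=k_eff, seed=seed,
                      class_label=class_label)
    spec.dropped_correlated = dropped
    return spec


def standardize(matrix: pd.DataFrame, spec: FeatureSpec,
                fit: bool = False) -> pd.DataFrame:
    """Zero-mean unit-variance transform over the spec's selected columns.

    With ``fit=True`` the parameters are estimated from the matrix and
    stored on the spec; otherwise the stored parameters are applied.
    """
    cols = spec.selected
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"matrix lacks selected columns: {missing}")
    sub = matrix[cols].astype(float)
    if fit:
        mean = sub.mean()
        scale = sub.std(ddof=0).replace(0.0, 1.0)
        spec.standardize_mean = mean.to_dict()
        spec.standardize_scale = scale.to_dict()
    else:
        if not spec.standardize_mean:
            raise ValueError("spec carries no standardisation parameters")
        mean = pd.Series(spec.standardize_mean)[cols]
        scale = pd.Series(spec.standardize_scale)[cols]
    return (sub - mean) / scale
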