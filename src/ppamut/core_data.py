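"""Mutation data model, thermodynamic conversions and dataset curation.

The quantity predicted throughout the package is ddG, the change in binding
free energy of a protein-protein complex upon a single-point mutation
(kcal/mol).  The sign convention is ddG = dG_mut - dG_wild with dG more
negative meaning tighter binding, so positive ddG = reduced affinity.
"""

from __future__ import annotations

import itertools
import math
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

#: Gas constant in kcal mol^-1 K^-1 (so free energies come out in kcal/mol).
GAS_CONSTANT_KCAL = 1.9872e-3

#: Default temperature (K) when a record carries a Kd but no temperature.
DEFAULT_TEMPERATURE_K = 298.15

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"


class FunctionalClass(str, Enum):
    """Functional category of a protein-protein complex.

    Binding free energies and mutational responses differ systematically
    between these categories, so a separate model is trained per class.
    """

    ANTIGEN_ANTIBODY = "antigen_antibody"
    ENZYME_INHIBITOR = "enzyme_inhibitor"
    G_PROTEIN = "g_protein"
    RECEPTOR = "receptor"
    OTHER_ENZYME = "other_enzyme"
    MISCELLANEOUS = "miscellaneous"


class DataValidationError(ValueError):
    """A record or table violates the data contract."""


@dataclass(frozen=True)
class MutationRecord:
    """A single-point mutation in one chain of a complex.

    ``position`` is 1-based into the chain sequence (author numbering is
    reconciled upstream through an explicit per-chain offset map).
    ``ddg_exp`` is the measured change in binding free energy, kcal/mol;
    alternatively the pair ``kd_wild``/``kd_mut`` (molar) with a temperature
    lets ddG be derived via the dissociation-constant route.
    """

    complex_id: str
    chain_id: str
    position: int
    wild_aa: str
    mutant_aa: str
    functional_class: FunctionalClass
    ddg_exp: float | None = None
    kd_wild: float | None = None
    kd_mut: float | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        if self.wild_aa not in CANONICAL_AA:
            raise DataValidationError(f"unknown wild residue {self.wild_aa!r}")
        if self.mutant_aa not in CANONICAL_AA:
            raise DataValidationError(f"unknown mutant residue {self.mutant_aa!r}")
        if self.wild_aa == self.mutant_aa:
            raise DataValidationError("wild and mutant residues must differ")
        if self.position < 1:
            raise DataValidationError(f"position must be >= 1, got {self.position}")
        for name in ("kd_wild", "kd_mut"):
            kd = getattr(self, name)
            if kd is not None and kd <= 0:
                raise DataValidationError(f"{name} must be positive, got {kd}")
        if not isinstance(self.functional_class, FunctionalClass):
            raise DataValidationError(
                f"unknown functional class {self.functional_class!r}"
            )

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        """Identity key used for duplicate elimination."""
        return (self.complex_id, self.chain_id, self.position,
                self.wild_aa, self.mutant_aa)

    @property
    def site(self) -> tuple[str, str, int]:
        return (self.complex_id, self.chain_id, self.position)

    def resolve_ddg(self) -> float | None:
        """Measured ddG, deriving it from Kd pairs when necessary."""
        if self.ddg_exp is not None:
            return self.ddg_exp
        if self.kd_wild is not None and self.kd_mut is not None:
            t = self.temperature if self.temperature is not None else DEFAULT_TEMPERATURE_K
            return compute_ddg(kd_to_delta_g(self.kd_mut, t),
                               kd_to_delta_g(self.kd_wild, t))
        return None


@dataclass(frozen=True)
class RowRejection:
    """Why a mutation-table row was excluded during parsing."""

    row: int
    reason: str


@dataclass
class MutationDataset:
    """Validated mutation records plus the chain sequences they refer to.

    ``sequences`` maps complex_id -> chain_id -> one-letter sequence.
    ``offsets`` maps (complex_id, chain_id) -> integer added to a record's
    author position to obtain the 1-based index into the stored sequence.
    """

    records: list[MutationRecord] = field(default_factory=list)
    sequences: dict[str, dict[str, str]] = field(default_factory=dict)
    offsets: dict[tuple[str, str], int] = field(default_factory=dict)
    rejections: list[RowRejection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def sequence_position(self, record: MutationRecord) -> int:
        return record.position + self.offsets.get(
            (record.complex_id, record.chain_id), 0)

    def validate(self) -> None:
        """Check every record resolves to its sequence and matches wild_aa."""
        for i, rec in enumerate(self.records):
            chains = self.sequences.get(rec.complex_id)
            if chains is None or rec.chain_id not in chains:
                raise DataValidationError(
                    f"record {i}: no sequence for {rec.complex_id}/{rec.chain_id}")
            seq = chains[rec.chain_id]
            pos = self.sequence_position(rec)
            if not 1 <= pos <= len(seq):
                raise DataValidationError(
                    f"record {i}: position {pos} outside sequence of length {len(seq)}")
            if seq[pos - 1] != rec.wild_aa:
                raise DataValidationError(
                    f"record {i}: wild-type mismatch, sequence has "
                    f"{seq[pos - 1]} at position {pos}, record says {rec.wild_aa}")

    def complex_ids(self) -> list[str]:
        """Distinct complex ids in first-appearance order."""
        seen: OrderedDict[str, None] = OrderedDict()
        for rec in self.records:
            seen.setdefault(rec.complex_id, None)
        for cid in self.sequences:
            seen.setdefault(cid, None)
        return list(seen)

    def subset(self, records: Iterable[MutationRecord]) -> "MutationDataset":
        records = list(records)
        keep = {r.complex_id for r in records}
        return MutationDataset(
            records=records,
            sequences={c: dict(v) for c, v in self.sequences.items() if c in keep},
            offsets={k: v for k, v in self.offsets.items() if k[0] in keep},
        )


def kd_to_delta_g(kd: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Binding free energy dG = -RT ln(1/Kd) in kcal/mol.

    Parameters
    ----------
    kd : dissociation constant in molar; tighter binding = smaller Kd.
    temperature : absolute temperature in Kelvin.

    dG is 0 at Kd = 1 M and negative for sub-molar Kd (favourable binding).
    """
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return -GAS_CONSTANT_KCAL * temperature * math.log(1.0 / kd)


def compute_ddg(dg_mut: float, dg_wild: float) -> float:
    """Change in binding free energy upon mutation, dG_mut - dG_wild.

    Positive values mean the mutation destabilises the complex
    (reduced affinity).
    """
    if not (math.isfinite(dg_mut) and math.isfinite(dg_wild)):
        raise ValueError("free energies must be finite")
    return dg_mut - dg_wild


_REQUIRED_COLUMNS = ("complex_id", "chain", "position", "wild", "mutant", "class")
_CLASS_ALIASES = {c.value: c for c in FunctionalClass}


def read_fasta_sequences(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a multi-FASTA whose record ids are ``complexid_chainid``."""
    sequences: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "_" not in rec.id:
            raise DataValidationError(
                f"FASTA id {rec.id!r} is not of the form complexid_chainid")
        complex_id, chain_id = rec.id.rsplit("_", 1)
        sequences.setdefault(complex_id, {})[chain_id] = str(rec.seq).upper()
    return sequences


def parse_mutation_table(
    path: str | Path,
    sequences: Mapping[str, Mapping[str, str]] | None = None,
    fasta_path: str | Path | None = None,
    sep: str | None = None,
) -> MutationDataset:
    """Parse a delimited mutation table into a validated MutationDataset.

    Required columns: complex_id, chain, position, wild, mutant, class;
    optional: ddg, kd_wild, kd_mut, temp_K.  Rows that fail validation
    (unknown residues, unknown class, positions that do not resolve, or a
    stated wild type disagreeing with the sequence) are dropped and listed
    in the returned dataset's ``rejections``.
    """
    if sequences is None and fasta_path is not None:
        sequences = read_fasta_sequences(fasta_path)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing required columns: {missing}")

    dataset = MutationDataset(
        sequences={c: dict(v) for c, v in (sequences or {}).items()})

    def _opt_float(row, col):
        val = row.get(col, "")
        return float(val) if val not in ("", None) else None

    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based file line incl. header
        try:
            fclass = _CLASS_ALIASES.get(row["class"].strip().lower())
            if fclass is None:
                raise DataValidationError(f"unknown functional class {row['class']!r}")
            rec = MutationRecord(
                complex_id=row["complex_id"].strip(),
                chain_id=row["chain"].strip(),
                position=int(row["position"]),
                wild_aa=row["wild"].strip().upper(),
                mutant_aa=row["mutant"].strip().upper(),
                functional_class=fclass,
                ddg_exp=_opt_float(row, "ddg"),
                kd_wild=_opt_float(row, "kd_wild"),
                kd_mut=_opt_float(row, "kd_mut"),
                temperature=_opt_float(row, "temp_K"),
            )
            if sequences is not None:
                chains = dataset.sequences.get(rec.complex_id, {})
                if rec.chain_id not in chains:
                    raise DataValidationError(
                        f"no sequence for {rec.complex_id}/{rec.chain_id}")
                seq = chains[rec.chain_id]
                pos = dataset.sequence_position(rec)
                if not 1 <= pos <= len(seq):
                    raise DataValidationError(
                        f"position {pos} outside sequence (length {len(seq)})")
                if seq[pos - 1] != rec.wild_aa:
                    raise DataValidationError(
                        f"wild-type mismatch: sequence has {seq[pos - 1]} "
                        f"at position {pos}, table says {rec.wild_aa}")
        except (DataValidationError, ValueError) as exc:
            dataset.rejections.append(RowRejection(row=rownum, reason=str(exc)))
            continue
        dataset.records.append(rec)
    return dataset


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def sequence_identity(seq_a: str, seq_b: str,
                      aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment identity = identical columns / alignment length."""
    if not seq_a or not seq_b:
        return 0.0
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def _complex_identity(chains_a: Mapping[str, str], chains_b: Mapping[str, str],
                      aligner: PairwiseAligner) -> float:
    """Best chain-pair identity between two complexes."""
    best = 0.0
    for sa, sb in itertools.product(chains_a.values(), chains_b.values()):
        best = max(best, sequence_identity(sa, sb, aligner))
    return best


def filter_redundancy(dataset: MutationDataset,
                      identity_cutoff: float = 0.25) -> MutationDataset:
    """Remove duplicate mutations and sequence-redundant complexes.

    Exact duplicates (same complex, chain, position, wild, mutant) are
    collapsed to one record; conflicting measured ddG values for the same
    key are averaged.  Complexes whose best chain-pair global-alignment
    identity to an already-retained complex exceeds ``identity_cutoff``
    are dropped greedily in first-appearance order.
    """
    merged: OrderedDict[tuple, list[MutationRecord]] = OrderedDict()
    for rec in dataset.records:
        merged.setdefault(rec.key, []).append(rec)
    deduped: list[MutationRecord] = []
    for recs in merged.values():
        rec = recs[0]
        ddgs = [r.ddg_exp for r in recs if r.ddg_exp is not None]
        if len(ddgs) > 1:
            rec = replace(rec, ddg_exp=sum(ddgs) / len(ddgs))
        deduped.append(rec)

    aligner = _make_aligner()
    retained: list[str] = []
    order = MutationDataset(records=deduped, sequences=dataset.sequences).complex_ids()
    for cid in order:
        chains = dataset.sequences.get(cid, {})
        redundant = any(
            chains and dataset.sequences.get(kept)
            and _complex_identity(chains, dataset.sequences[kept], aligner)
            > identity_cutoff
            for kept in retained
        )
        if not redundant:
            retained.append(cid)
    retained_set = set(retained)
    out = dataset.subset(r for r in deduped if r.complex_id in retained_set)
    out.sequences.update(
        {c: dict(v) for c, v in dataset.sequences.items() if c in retained_set})
    return out


def partition_by_class(
    dataset: MutationDataset,
) -> dict[FunctionalClass, MutationDataset]:
    """Split a dataset into the six functional-class subsets.

    The subsets are disjoint and their union equals the input; classes with
    no records map to empty datasets.
    """
    buckets: dict[FunctionalClass, list[MutationRecord]] = {
        c: [] for c in FunctionalClass}
    for rec in dataset.records:
        buckets[rec.functional_class].append(rec)
    return {c: dataset.subset(recs) for c, recs in buckets.items()}
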