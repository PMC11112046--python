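"""Sequence-derived features for a mutation site.

Three families: amino-acid property differences (dP = P_mut - P_wild over a
configurable property table), evolutionary-profile features from PSI-BLAST
ASCII PSSM files, and per-position conservation scores ingested from an
AACon-style table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core_data import CANONICAL_AA

#: Column order of residues in a PSI-BLAST ASCII PSSM.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: Property scales backing the four classic mutation descriptors.
DESCRIPTOR_SCALES = {
    "net_volume_change": "volume_a3",
    "hydrophobicity_change": "hydrophobicity_kd",
    "flexibility_change": "flexibility",
    "fluctuation_change": "fluctuation",
}

_PROPERTY_METADATA = {
    "hydrophobicity_kd": "Kyte-Doolittle hydropathy index (unitless)",
    "volume_a3": "residue volume, A^3 (Zamyatnin)",
    "flexibility": "average flexibility index (Bhaskaran-Ponnuswamy)",
    "fluctuation": "normalized B-factor-derived flexibility (Vihinen)",
    "polarity": "polarity (Grantham)",
    "isoelectric_point": "isoelectric point, pH units",
    "helix_propensity": "Chou-Fasman alpha-helix propensity P_alpha",
    "sheet_propensity": "Chou-Fasman beta-sheet propensity P_beta",
    "bulkiness": "side-chain bulkiness (Zimmerman)",
    "interface_propensity":
        "generic protein-protein interface propensity (replaceable default)",
}


class PropertyLookupError(KeyError):
    """Residue or property not present in the table."""


@dataclass
class PropertyTable:
    """Per-residue numeric property scales, property name -> residue -> value.

    Every property must define a value for all 20 canonical residues.  The
    shipped default set covers the scales most used for mutation-effect
    modelling (hydrophobicity, volume, flexibility, fluctuation, polarity,
    pI, secondary-structure propensities, bulkiness, interface propensity)
    and can be replaced by any user table in the same CSV layout.
    """

    values: dict[str, dict[str, float]]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, scale in self.values.items():
            missing = sorted(set(CANONICAL_AA) - set(scale))
            if missing:
                raise ValueError(
                    f"property {name!r} lacks values for residues {missing}")

    @property
    def property_names(self) -> list[str]:
        return list(self.values)

    def __getitem__(self, name: str) -> dict[str, float]:
        try:
            return self.values[name]
        except KeyError as exc:
            raise PropertyLookupError(f"unknown property {name!r}") from exc

    @classmethod
    def from_csv(cls, path: str | Path,
                 metadata: Mapping[str, str] | None = None) -> "PropertyTable":
        """Load a table with a ``residue`` column and one column per property."""
        df = pd.read_csv(path).set_index("residue")
        values = {col: df[col].to_dict() for col in df.columns}
        return cls(values=values, metadata=dict(metadata or {}))

    @classmethod
    def default(cls) -> "PropertyTable":
        with resources.as_file(
                resources.files("ppamut.data") / "aa_properties.csv") as p:
            return cls.from_csv(p, metadata=_PROPERTY_METADATA)


def delta_property(wild_aa: str, mutant_aa: str, property_name: str,
                   table: PropertyTable) -> float:
    """Property change upon mutation, dP = P_mut - P_wild."""
    scale = table[property_name]
    try:
        return scale[mutant_aa] - scale[wild_aa]
    except KeyError as exc:
        raise PropertyLookupError(
            f"residue {exc.args[0]!r} not in property {property_name!r}") from exc


def mutation_descriptors(wild_aa: str, mutant_aa: str,
                         table: PropertyTable) -> dict[str, float]:
    """The four classic mutation descriptors: volume, hydrophobicity,
    flexibility and fluctuation change, each a dP over its designated scale."""
    return {
        name: delta_property(wild_aa, mutant_aa, scale, table)
        for name, scale in DESCRIPTOR_SCALES.items()
    }


class PSSMParseError(ValueError):
    """Malformed PSI-BLAST ASCII PSSM file."""


@dataclass
class PSSMProfile:
    """Position-specific scoring matrix of one chain.

    ``log_odds`` and ``percentages`` are L x 20 arrays in PSI-BLAST column
    order; ``information`` is the per-position information content (bits).
    """

    sequence: str
    log_odds: np.ndarray
    percentages: np.ndarray
    information: np.ndarray

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if L < 1:
            raise PSSMParseError("empty profile")
        for name in ("log_odds", "percentages"):
            arr = getattr(self, name)
            if arr.shape != (L, 20):
                raise PSSMParseError(
                    f"{name} has shape {arr.shape}, expected ({L}, 20)")
        if self.information.shape != (L,):
            raise PSSMParseError("information length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


def parse_pssm(path: str | Path) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM (the ``-out_ascii_pssm`` layout).

    Expects the two header lines, then one row per position carrying the
    position, residue, 20 integer log-odds, 20 weighted observed
    percentages and the information content.
    """
    lines = Path(path).read_text().splitlines()
    seq: list[str] = []
    log_odds: list[list[int]] = []
    percentages: list[list[float]] = []
    information: list[float] = []
    in_body = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            if in_body and seq:
                break  # footer (K, lambda) follows the matrix
            continue
        fields = stripped.split()
        if not in_body:
            if fields[0] == "A" and fields[:20] == list(PSSM_ALPHABET):
                in_body = True
            continue
        if not fields[0].isdigit():
            break
        if len(fields) < 43:
            raise PSSMParseError(
                f"line {lineno}: expected >=43 fields "
                f"(pos, aa, 20 log-odds, 20 percentages, info), got {len(fields)}")
        try:
            seq.append(fields[1])
            log_odds.append([int(v) for v in fields[2:22]])
            percentages.append([float(v) for v in fields[22:42]])
            information.append(float(fields[42]))
        except ValueError as exc:
            raise PSSMParseError(f"line {lineno}: {exc}") from exc
    if not seq:
        raise PSSMParseError(f"no PSSM matrix found in {path}")
    return PSSMProfile(
        sequence="".join(seq),
        log_odds=np.asarray(log_odds, dtype=int),
        percentages=np.asarray(percentages, dtype=float),
        information=np.asarray(information, dtype=float),
    )


def write_pssm(profile: PSSMProfile, path: str | Path) -> None:
    """Write a profile back in normalized PSI-BLAST ASCII layout.

    ``write(parse(f))`` is byte-stable for files produced by this writer,
    which is the round-trip contract the fixture generator relies on.
    """
    header_aa = "  ".join(PSSM_ALPHABET)
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + header_aa + "   " + header_aa,
    ]
    for i, aa in enumerate(profile.sequence):
        lo = " ".join(f"{v:3d}" for v in profile.log_odds[i])
        pc = " ".join(f"{v:4.0f}" for v in profile.percentages[i])
        out.append(f"{i + 1:5d} {aa} {lo}  {pc}  {profile.information[i]:5.2f} 1.00")
    out.append("")
    Path(path).write_text("\n".join(out))


def pssm_features(profile: PSSMProfile, position: int,
                  wild_aa: str, mutant_aa: str) -> dict[str, float]:
    """Per-site profile features: wild/mutant log-odds, their difference,
    and the site information content.  ``position`` is 1-based."""
    if not 1 <= position <= len(profile):
        raise IndexError(
            f"position {position} outside profile of length {len(profile)}")
    row = profile.log_odds[position - 1]
    iw = PSSM_ALPHABET.index(wild_aa)
    im = PSSM_ALPHABET.index(mutant_aa)
    score_wild = float(row[iw])
    score_mut = float(row[im])
    return {
        "pssm_score_wild": score_wild,
        "pssm_score_mut": score_mut,
        "pssm_score_delta": score_mut - score_wild,
        "pssm_information": float(profile.information[position - 1]),
    }


@dataclass
class ConservationProfile:
    """Per-position conservation scores ingested from an external scorer."""

    scores: np.ndarray
    method: str = "unknown"

    def __len__(self) -> int:
        return len(self.scores)


def parse_conservation(path: str | Path, method: str = "aacon") -> ConservationProfile:
    """Read a two-column (position, score) TSV of conservation scores."""
    df = pd.read_csv(path, sep="\t", header=None, names=["position", "score"],
                     comment="#")
    df = df.sort_values("position")
    return ConservationProfile(scores=df["score"].to_numpy(float), method=method)


def conservation_feature(profile: ConservationProfile, position: int) -> float:
    """The stored conservation score at a 1-based position, unchanged."""
    if not 1 <= position <= len(profile):
        raise IndexError(
            f"position {position} outside profile of length {len(profile)}")
    return float(profile.scores[position - 1])
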