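"""Synthetic inputs at toy scale: two-chain complexes with coordinates,
PSI-BLAST-style profiles, conservation tables and mutation datasets with a
known feature -> ddG law.

Everything is deterministic given its seed, and every file format written
here (PDB, FASTA, PSSM ASCII, conservation TSV, mutation CSV) is exactly
what the main pipeline reads, so the generator doubles as an end-to-end
test harness.  The linear-Gaussian ddG law spans roughly the -6..+8
kcal/mol range seen in curated mutation collections, so error metrics and
plot scales transfer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (CANONICAL_AA, FunctionalClass, MutationDataset,
                        MutationRecord)
from .feature_pipeline import FeatureMatrix
from .sequence_features import (PSSM_ALPHABET, ConservationProfile,
                                PSSMProfile, write_pssm)
from .structure_features import ONE_TO_THREE, StructureModel, parse_structure

#: Ideal consecutive C-alpha spacing, A.
CA_SPACING = 3.8

#: Fixed intra-residue heavy-atom offsets from C-alpha (toy geometry).
_BACKBONE_OFFSETS = {
    "N": (-0.83, -0.86, 0.30),
    "CA": (0.0, 0.0, 0.0),
    "C": (0.92, 0.70, -0.32),
    "O": (1.10, 1.90, -0.30),
    "CB": (0.30, -0.55, 1.25),
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic mutation dataset.

    ``signal_weights`` are kcal/mol per unit (standard-normal) feature;
    the default three-signal law with sigma = 0.3 kcal/mol yields ddG
    values spanning about -6..+8 kcal/mol, matching curated collections.
    """

    n_complexes: int = 6
    chain_lengths: tuple[int, int] = (36, 12)
    n_mutations: int = 300
    n_features: int = 20
    signal_weights: tuple[float, ...] = (1.5, -1.0, 0.8)
    noise_sigma: float = 0.3
    class_mixture: dict[FunctionalClass, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        if not all(math.isfinite(w) for w in self.signal_weights):
            raise ValueError("signal weights must be finite")
        if len(self.signal_weights) > self.n_features:
            raise ValueError("more signal weights than features")
        if min(self.chain_lengths) < 5:
            raise ValueError("chain lengths must be >= 5")


def _snake_path(n: int, nx_: int = 4, ny: int = 3) -> np.ndarray:
    """Space-filling lattice walk with unit steps, giving a compact blob
    whose central residues are buried."""
    pts = []
    x = y = z = 0
    dx, dy = 1, 1
    for _ in range(n):
        pts.append((x, y, z))
        if 0 <= x + dx < nx_:
            x += dx
        elif 0 <= y + dy < ny:
            y += dy
            dx = -dx
        else:
            z += 1
            dx, dy = -dx, -dy
    return np.asarray(pts, float)


def make_toy_complex(chain_lengths: tuple[int, int] = (36, 12),
                     gap: float = 4.5, seed: int = 0,
                     ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Coordinates and sequences of a synthetic two-chain complex.

    Chain A snakes through a compact lattice (3.8 A spacing) so it has
    both buried and exposed residues; chain B is a straight segment packed
    against one face of A at distance ``gap``, so interface residues exist
    by construction.  Returns an atom table (chain, resnum, aa, atom, x,
    y, z) and the chain sequences.
    """
    rng = np.random.default_rng(seed)
    len_a, len_b = chain_lengths
    ca_a = _snake_path(len_a) * CA_SPACING
    # chain B runs along x at fixed height above the top face of A
    top_z = ca_a[:, 2].max()
    start = np.array([0.5 * CA_SPACING, CA_SPACING, top_z + gap])
    ca_b = start + np.outer(np.arange(len_b), [CA_SPACING, 0.0, 0.0])

    seqs = {
        "A": "".join(rng.choice(list(CANONICAL_AA), size=len_a)),
        "B": "".join(rng.choice(list(CANONICAL_AA), size=len_b)),
    }
    rows = []
    for chain, ca in (("A", ca_a), ("B", ca_b)):
        for i, pos in enumerate(ca):
            aa = seqs[chain][i]
            for atom, off in _BACKBONE_OFFSETS.items():
                if atom == "CB" and aa == "G":
                    continue
                rows.append((chain, i + 1, aa, atom,
                             *(pos + np.asarray(off))))
    atoms = pd.DataFrame(rows, columns=["chain", "resnum", "aa", "atom",
                                        "x", "y", "z"])
    return atoms, seqs


def write_pdb(atoms: pd.DataFrame, path: str | Path) -> None:
    """Serialize a toy atom table as a valid PDB file."""
    lines = []
    serial = 1
    for _, row in atoms.iterrows():
        element = row["atom"][0]
        lines.append(
            f"ATOM  {serial:5d}  {row['atom']:<3s} {ONE_TO_THREE[row['aa']]:>3s} "
            f"{row['chain']}{int(row['resnum']):4d}    "
            f"{row['x']:8.3f}{row['y']:8.3f}{row['z']:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def make_toy_complex_files(out_dir: str | Path, complex_id: str = "toy1",
                           chain_lengths: tuple[int, int] = (36, 12),
                           gap: float = 4.5, seed: int = 0,
                           ) -> tuple[Path, Path]:
    """Write a toy complex as PDB + FASTA; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    atoms, seqs = make_toy_complex(chain_lengths, gap, seed)
    pdb_path = out_dir / f"{complex_id}.pdb"
    write_pdb(atoms, pdb_path)
    fasta_path = out_dir / f"{complex_id}.fasta"
    fasta_path.write_text("".join(
        f">{complex_id}_{chain}\n{seq}\n" for chain, seq in seqs.items()))
    return pdb_path, fasta_path


def make_toy_structure(chain_lengths: tuple[int, int] = (36, 12),
                       gap: float = 4.5, seed: int = 0,
                       tmp_dir: str | Path | None = None) -> StructureModel:
    """Parsed StructureModel of a toy complex (written and re-read so the
    fixture exercises the real PDB path)."""
    import tempfile
    with tempfile.TemporaryDirectory(dir=tmp_dir) as td:
        pdb_path, _ = make_toy_complex_files(td, chain_lengths=chain_lengths,
                                             gap=gap, seed=seed)
        return parse_structure(pdb_path)


def make_fixture_pssm(sequence: str, seed: int = 0) -> PSSMProfile:
    """Synthetic profile whose self-residue log-odds is maximal per row."""
    rng = np.random.default_rng(seed)
    L = len(sequence)
    log_odds = rng.integers(-4, 5, size=(L, 20))
    percentages = np.zeros((L, 20))
    for i, aa in enumerate(sequence):
        j = PSSM_ALPHABET.index(aa)
        log_odds[i, j] = 7  # self-match dominates
        pct = rng.integers(0, 5, size=20).astype(float)
        pct[j] = 60.0
        percentages[i] = np.floor(100.0 * pct / pct.sum())
    information = np.round(rng.uniform(0.1, 2.0, size=L), 2)
    return PSSMProfile(sequence=sequence, log_odds=np.asarray(log_odds),
                       percentages=percentages, information=information)


def write_fixture_pssm(sequence: str, path: str | Path, seed: int = 0) -> None:
    write_pssm(make_fixture_pssm(sequence, seed), path)


def make_fixture_conservation(sequence: str, seed: int = 0) -> ConservationProfile:
    rng = np.random.default_rng(seed)
    return ConservationProfile(
        scores=np.round(rng.uniform(0.0, 1.0, size=len(sequence)), 3),
        method="synthetic")


def write_conservation(profile: ConservationProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(profile.scores, start=1):
            fh.write(f"{i}\t{s}\n")


@dataclass
class SyntheticMutationData:
    """A generated dataset plus its generative ground truth."""

    dataset: MutationDataset
    features: FeatureMatrix
    ddg_true: np.ndarray
    weights: np.ndarray
    config: SyntheticConfig
    classes: np.ndarray = field(default_factory=lambda: np.empty(0, object))
    complexes: np.ndarray = field(default_factory=lambda: np.empty(0, object))
    sites: list = field(default_factory=list)


def make_synthetic_mutation_dataset(config: SyntheticConfig | None = None,
                                    ) -> SyntheticMutationData:
    """Mutations with features obeying ddG_i = sum_j w_j x_ij + eps_i.

    Features are standard normal; the first ``len(signal_weights)`` columns
    carry signal, the rest are decoys.  Records are spread over
    ``n_complexes`` two-chain complexes with sequences consistent with the
    stated wild-type residues, so the dataset passes full validation.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_mutations
    X = rng.standard_normal((n, config.n_features))
    weights = np.zeros(config.n_features)
    weights[:len(config.signal_weights)] = config.signal_weights
    noise = rng.normal(0.0, config.noise_sigma, size=n)
    ddg = X @ weights + noise

    mixture = config.class_mixture or {c: 1 / 6 for c in FunctionalClass}
    class_pool = list(mixture)
    class_p = np.asarray([mixture[c] for c in class_pool], float)
    class_p /= class_p.sum()

    complex_ids = [f"syn{i + 1}" for i in range(config.n_complexes)]
    sequences: dict[str, dict[str, str]] = {}
    for cid in complex_ids:
        sequences[cid] = {
            "A": list(rng.choice(list(CANONICAL_AA), size=config.chain_lengths[0])),
            "B": list(rng.choice(list(CANONICAL_AA), size=config.chain_lengths[1])),
        }
    complex_class = {cid: class_pool[i] for cid, i in zip(
        complex_ids, rng.choice(len(class_pool), size=len(complex_ids),
                                p=class_p))}

    records = []
    seen_keys = set()
    aa_list = list(CANONICAL_AA)
    for i in range(n):
        while True:
            cid = complex_ids[int(rng.integers(config.n_complexes))]
            chain = "A" if rng.random() < 0.7 else "B"
            seq = sequences[cid][chain]
            pos = int(rng.integers(1, len(seq) + 1))
            wild = seq[pos - 1]
            mutant = aa_list[int(rng.integers(20))]
            if mutant == wild:
                continue
            key = (cid, chain, pos, wild, mutant)
            if key in seen_keys:
                continue
            seen_keys.add(key)
            break
        records.append(MutationRecord(
            complex_id=cid, chain_id=chain, position=pos, wild_aa=wild,
            mutant_aa=mutant, functional_class=complex_class[cid],
            ddg_exp=float(ddg[i])))

    dataset = MutationDataset(
        records=records,
        sequences={cid: {ch: "".join(s) for ch, s in chains.items()}
                   for cid, chains in sequences.items()})
    dataset.validate()

    columns = ([f"signal_{j + 1}" for j in range(len(config.signal_weights))]
               + [f"decoy_{j + 1}" for j in
                  range(config.n_features - len(config.signal_weights))])
    features = FeatureMatrix(
        data=pd.DataFrame(X, columns=columns,
                          index=pd.Index(["_".join(map(str, r.key))
                                          for r in records], name="mutation")),
        families={c: "synthetic" for c in columns},
        provenance={"generator": "linear_gaussian",
                    "weights": list(map(float, weights)),
                    "noise_sigma": config.noise_sigma,
                    "seed": config.seed})
    return SyntheticMutationData(
        dataset=dataset, features=features, ddg_true=ddg, weights=weights,
        config=config,
        classes=np.asarray([r.functional_class.value for r in records]),
        complexes=np.asarray([r.complex_id for r in records]),
        sites=[r.site for r in records])


def write_mutation_csv(dataset: MutationDataset, path: str | Path) -> None:
    """Write records in the mutation-table layout the parser reads."""
    rows = []
    for r in dataset.records:
        rows.append({
            "complex_id": r.complex_id, "chain": r.chain_id,
            "position": r.position, "wild": r.wild_aa, "mutant": r.mutant_aa,
            "class": r.functional_class.value,
            "ddg": "" if r.ddg_exp is None else r.ddg_exp,
            "kd_wild": "" if r.kd_wild is None else r.kd_wild,
            "kd_mut": "" if r.kd_mut is None else r.kd_mut,
            "temp_K": "" if r.temperature is None else r.temperature,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fasta(dataset: MutationDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, chains in dataset.sequences.items():
            for chain, seq in chains.items():
                fh.write(f">{cid}_{chain}\n{seq}\n")
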