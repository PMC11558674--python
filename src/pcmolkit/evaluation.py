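"""Similarity-based evaluation of generated molecules.

Protocol: generate a batch of molecules per target, fingerprint everything
with ECFP4 (circular substructures of radius 2, folded to 1024 bits), and
report each generated molecule's maximum Tanimoto similarity to the
target's known actives, alongside validity / novelty / uniqueness
accounting and Bemis-Murcko scaffold frequencies. The family-match rate
operationalizes target specificity at desk scale: a generator that uses
its conditioning should place most generations nearest to the conditioning
target's own ligand family, while a corrupted-conditioning control falls
to chance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .bioactivity import standardize_smiles
from .errors import ConfigurationError, SmilesParseError

FP_BITS = 1024
FP_RADIUS = 2

_fp_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=FP_RADIUS, fpSize=FP_BITS
)


def ecfp4(smiles: str):
    """ECFP4 bit vector (1024 bits, radius 2) of the standardized molecule."""
    mol = Chem.MolFromSmiles(standardize_smiles(smiles))
    if mol is None:  # pragma: no cover - standardize already validated
        raise SmilesParseError(smiles)
    return _fp_generator.GetFingerprint(mol)


def fingerprint_array(fp) -> np.ndarray:
    """An RDKit bit vector as a uint8 numpy array of length 1024."""
    arr = np.zeros(FP_BITS, dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(fp, arr)
    return arr


def tanimoto(fp_a, fp_b) -> float:
    return float(DataStructs.TanimotoSimilarity(fp_a, fp_b))


@dataclass
class SimilarityReport:
    """Per-molecule nearest-known-ligand similarities plus summary stats."""

    per_molecule: pd.DataFrame  # columns: smiles, valid, max_tanimoto, nearest_reference
    fraction_valid: float
    fraction_novel: float
    fraction_unique: float

    @property
    def max_tanimotos(self) -> np.ndarray:
        vals = self.per_molecule.loc[self.per_molecule["valid"], "max_tanimoto"]
        return vals.to_numpy(dtype=float)

    @property
    def median(self) -> float:
        vals = self.max_tanimotos
        return float(np.median(vals)) if vals.size else float("nan")

    @property
    def quartiles(self) -> tuple[float, float]:
        vals = self.max_tanimotos
        if not vals.size:
            return float("nan"), float("nan")
        q1, q3 = np.percentile(vals, [25, 75])
        return float(q1), float(q3)

    def summary(self) -> dict:
        q1, q3 = self.quartiles
        return {
            "median_max_tanimoto": self.median,
            "q1_max_tanimoto": q1,
            "q3_max_tanimoto": q3,
            "fraction_valid": self.fraction_valid,
            "fraction_novel": self.fraction_novel,
            "fraction_unique": self.fraction_unique,
        }


def nearest_tanimoto(
    generated: Sequence[str], reference: Sequence[str]
) -> SimilarityReport:
    """Max Tanimoto of every generated molecule to a reference ligand set.

    Brute-force all-pairs semantics. Invalid generated strings are flagged,
    excluded from similarity, and counted in ``fraction_valid``. Novelty is
    exact canonical-SMILES absence from the reference set; uniqueness is
    over canonical forms of the valid generations.
    """
    if not reference:
        raise ConfigurationError("empty reference set")
    ref_canon = [standardize_smiles(s) for s in reference]
    ref_fps = [ecfp4(s) for s in ref_canon]
    ref_set = set(ref_canon)

    rows = []
    canon_seen: list[str] = []
    n_novel = 0
    for smi in generated:
        try:
            canon = standardize_smiles(smi)
            if canon == "":
                raise SmilesParseError(smi, "empty molecule")
        except SmilesParseError:
            rows.append((smi, False, np.nan, None))
            continue
        fp = ecfp4(canon)
        sims = DataStructs.BulkTanimotoSimilarity(fp, ref_fps)
        best = int(np.argmax(sims))
        rows.append((smi, True, float(sims[best]), ref_canon[best]))
        canon_seen.append(canon)
        if canon not in ref_set:
            n_novel += 1

    df = pd.DataFrame(
        rows, columns=["smiles", "valid", "max_tanimoto", "nearest_reference"]
    )
    n = len(generated)
    n_valid = int(df["valid"].sum())
    return SimilarityReport(
        per_molecule=df,
        fraction_valid=n_valid / n if n else 0.0,
        fraction_novel=n_novel / n_valid if n_valid else 0.0,
        fraction_unique=len(set(canon_seen)) / n_valid if n_valid else 0.0,
    )


@dataclass
class ScaffoldCounts:
    """Top-k Bemis-Murcko scaffolds plus the acyclic and invalid buckets."""

    top: list[tuple[str, int]]
    acyclic_count: int
    invalid_count: int


def murcko_scaffold_counts(smiles_list: Sequence[str], top_k: int = 4) -> ScaffoldCounts:
    """Most frequent Bemis-Murcko frameworks of a molecule list.

    Ring systems plus linkers, side chains removed; counts aggregate on the
    canonical scaffold SMILES; descending by count with lexicographic
    tie-break. Acyclic molecules have the empty scaffold and are reported
    separately rather than ranked.
    """
    if not smiles_list:
        raise ConfigurationError("empty molecule list")
    counts: Counter[str] = Counter()
    acyclic = invalid = 0
    for smi in smiles_list:
        try:
            canon = standardize_smiles(smi)
            scaffold = MurckoScaffold.MurckoScaffoldSmiles(canon)
        except (SmilesParseError, ValueError):
            invalid += 1
            continue
        if scaffold == "":
            acyclic += 1
        else:
            counts[scaffold] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ScaffoldCounts(top=ranked[:top_k], acyclic_count=acyclic, invalid_count=invalid)


def nearest_family(
    smiles: str, family_fps: Mapping[str, list]
) -> tuple[str, float]:
    """The reference family holding the most similar ligand to ``smiles``."""
    fp = ecfp4(smiles)
    best_fam, best_sim = None, -1.0
    for fam in sorted(family_fps):
        sims = DataStructs.BulkTanimotoSimilarity(fp, family_fps[fam])
        s = max(sims)
        if s > best_sim:
            best_fam, best_sim = fam, s
    return best_fam, best_sim


def family_match_rate(
    generate_fn: Callable[[str, int, int], Sequence[str]],
    target_families: Mapping[str, str],
    family_references: Mapping[str, Sequence[str]],
    n_per_target: int,
    seed: int = 0,
) -> float:
    """Fraction of targets whose generations land in their own ligand family.

    ``generate_fn(accession, n, seed)`` returns SMILES strings for one
    target (a trained model's sampler, a shuffled-conditioning control, or
    a replay oracle). For each target the modal nearest family over its
    valid generations is compared with the target's true family; the
    return value is the mean per-target hit indicator. Targets with no
    valid generation count as misses.
    """
    if not target_families:
        raise ConfigurationError("no targets")
    family_fps = {
        fam: [ecfp4(s) for s in refs] for fam, refs in family_references.items()
    }
    hits = 0
    for i, acc in enumerate(sorted(target_families)):
        smiles = generate_fn(acc, n_per_target, seed + i)
        assigned = []
        for s in smiles:
            try:
                fam, _ = nearest_family(s, family_fps)
            except SmilesParseError:
                continue
            assigned.append(fam)
        if not assigned:
            continue
        modal = Counter(assigned).most_common(1)[0][0]
        if modal == target_families[acc]:
            hits += 1
    return hits / len(target_families)


def write_report(report: SimilarityReport, directory) -> None:
    """Per-molecule TSV plus a key-value summary block."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    report.per_molecule.to_csv(directory / "per_molecule.tsv", sep="\t", index=False)
    with open(directory / "summary.txt", "w") as fh:
        for k, v in report.summary().items():
            fh.write(f"{k}\t{v:.6g}\n")
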