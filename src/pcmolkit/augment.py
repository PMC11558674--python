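"""Potency-weighted SMILES-enumeration data augmentation.

Per-target ligand counts in public bioactivity data follow a power law:
most targets have few actives, a handful have thousands. Training an
autoregressive generator on the raw corpus makes the loss concentrate on
the well-covered targets. The augmentation scheme counters this in two
moves:

1. A log-scaled per-target quota. With ``n_min`` and ``n_max`` the minimum
   and maximum ligand counts across the corpus, the post-augmentation count
   for a target with ``n_i`` ligands is

       n_i' = n_max * (ln(n_i / n_min) + 1) / (ln(n_max / n_min) + 1)

   which is monotone in ``n_i``, compresses the dynamic range from
   ``n_max/n_min`` down to ``ln(n_max/n_min) + 1``, and leaves the largest
   target unaugmented (``n_i' = n_i`` at ``n_i = n_max``).

2. Potency-weighted sampling of which records to enumerate. A record with
   pChEMBL value ``p`` gets weight ``w = C**(p - r)`` (defaults r=5.5,
   C=3: threefold weight per pChEMBL unit, unit weight at 5.5), normalized
   per target to selection probabilities ``P_j = w_j / sum_k w_k``. Extra
   copies are alternative SMILES spellings of the drawn molecules (SMILES
   enumeration), so augmentation adds no new chemistry but shifts the
   potency distribution of the corpus upward.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .bioactivity import TargetLigandSet, standardize_smiles
from .errors import ConfigurationError, DomainError, SmilesParseError, ValidationError

#: Potency at which a compound carries unit weight.
DEFAULT_R = 5.5
#: Fold-increase in weight per pChEMBL unit.
DEFAULT_C = 3.0
#: Corpus bounds of the full-scale public data set, pinnable for comparability.
PAPYRUS_N_MIN = 10
PAPYRUS_N_MAX = 5903


@dataclass(frozen=True)
class AugmentationConstants:
    """Corpus-level constants entering the count and weight formulas."""

    n_min: int
    n_max: int
    r: float = DEFAULT_R
    C: float = DEFAULT_C

    def __post_init__(self):
        if self.n_min < 1:
            raise ValidationError("n_min must be >= 1")
        if self.n_max < self.n_min:
            raise ValidationError("n_max must be >= n_min")
        if not (math.isfinite(self.r) and math.isfinite(self.C)):
            raise ValidationError("non-finite scaling constant")
        if self.C <= 1.0:
            raise ValidationError("C must exceed 1 for weights to favor potency")

    @classmethod
    def from_corpus(
        cls, ligand_sets: Sequence[TargetLigandSet], r: float = DEFAULT_R, C: float = DEFAULT_C
    ) -> "AugmentationConstants":
        if not ligand_sets:
            raise ConfigurationError("empty corpus")
        counts = [s.n for s in ligand_sets]
        return cls(n_min=min(counts), n_max=max(counts), r=r, C=C)


@dataclass
class AugmentationPlan:
    """Audit record of one augmentation run."""

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)  # acc -> (n_i, n_i')
    weights: dict[str, np.ndarray] = field(default_factory=dict)
    probabilities: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total_original(self) -> int:
        return sum(n for n, _ in self.counts.values())

    @property
    def total_augmented(self) -> int:
        return sum(np_ for _, np_ in self.counts.values())


def augmented_count_raw(n_i: float, constants: AugmentationConstants) -> float:
    """The count formula before rounding; exposed for oracle checks."""
    if not (constants.n_min <= n_i <= constants.n_max):
        raise DomainError(
            f"n_i={n_i} outside [{constants.n_min}, {constants.n_max}]"
        )
    num = math.log(n_i / constants.n_min) + 1.0
    den = math.log(constants.n_max / constants.n_min) + 1.0
    return constants.n_max * num / den


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def augmented_count(n_i: int, constants: AugmentationConstants) -> int:
    """Post-augmentation ligand count n_i' for a target with n_i ligands.

    Round-half-up to an integer, floored at n_i so a target never shrinks.
    Monotone non-decreasing in n_i.
    """
    return max(int(n_i), _round_half_up(augmented_count_raw(n_i, constants)))


def record_weight(pchembl: float, constants: AugmentationConstants | None = None) -> float:
    """Sampling weight of a record: C**(pChEMBL - r); strictly increasing."""
    r = DEFAULT_R if constants is None else constants.r
    C = DEFAULT_C if constants is None else constants.C
    if not math.isfinite(pchembl):
        raise ValidationError("non-finite pChEMBL")
    return C ** (pchembl - r)


def selection_probabilities(weights: Sequence[float]) -> np.ndarray:
    """Normalize non-negative weights to probabilities summing to 1."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ConfigurationError("no weights")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValidationError("weights must be finite and non-negative")
    total = w.sum()
    if total <= 0:
        raise ConfigurationError("all-zero weights are degenerate")
    return w / total


def enumerate_smiles(smiles: str, seed: int) -> str:
    """One alternative SMILES spelling of the same molecule, seed-determined.

    Uses randomized atom-traversal output; the result always canonicalizes
    back to the input molecule. Molecules with a single representation
    (e.g. methane) return that representation.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    variants = Chem.MolToRandomSmilesVect(mol, 1, randomSeed=int(seed) % (2**31 - 1) + 1)
    return variants[0]


def _subsidiary_seed(global_seed: int, accession: str) -> int:
    """Stable per-target seed: crc32 of the accession mixed with the global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(accession.encode())) % (2**31 - 1)


def build_augmented_corpus(
    ligand_sets: Sequence[TargetLigandSet],
    constants: AugmentationConstants | None = None,
    seed: int = 0,
    max_redraws: int = 20,
) -> tuple[list[tuple[str, str]], AugmentationPlan]:
    """Emit the augmented (accession, SMILES) training corpus.

    Each target contributes its originals once plus ``n_i' - n_i``
    enumerated variants of records drawn with replacement under the
    potency-derived probabilities. Duplicate variant strings are redrawn up
    to ``max_redraws`` times, then accepted. Per-target randomness derives
    from ``seed`` via a stable accession hash, so target order does not
    affect the output.
    """
    if constants is None:
        constants = AugmentationConstants.from_corpus(ligand_sets)
    plan = AugmentationPlan()
    corpus: list[tuple[str, str]] = []
    for lset in ligand_sets:
        if lset.n < 1:
            raise ValidationError(f"empty ligand set {lset.accession}")
        n_prime = augmented_count(lset.n, constants)
        w = np.array([record_weight(r.pchembl, constants) for r in lset.records])
        p = selection_probabilities(w)
        plan.counts[lset.accession] = (lset.n, n_prime)
        plan.weights[lset.accession] = w
        plan.probabilities[lset.accession] = p

        rng = np.random.default_rng(_subsidiary_seed(seed, lset.accession))
        for rec in lset.records:
            corpus.append((lset.accession, rec.smiles))
        seen: dict[int, set[str]] = {}
        for _ in range(n_prime - lset.n):
            j = int(rng.choice(len(lset.records), p=p))
            rec = lset.records[j]
            used = seen.setdefault(j, {rec.smiles})
            variant = None
            for _attempt in range(max_redraws):
                cand = enumerate_smiles(rec.smiles, int(rng.integers(0, 2**31 - 1)))
                if cand not in used:
                    variant = cand
                    break
            if variant is None:  # tiny molecule: accept a duplicate spelling
                variant = cand
            used.add(variant)
            corpus.append((lset.accession, variant))
    return corpus, plan


def corpus_pchembl_values(
    corpus: Sequence[tuple[str, str]], ligand_sets: Sequence[TargetLigandSet]
) -> np.ndarray:
    """pChEMBL of every emitted pair, resolved via canonical SMILES lookup."""
    lookup = {
        (s.accession, r.smiles): r.pchembl for s in ligand_sets for r in s.records
    }
    out = []
    for acc, smi in corpus:
        key = (acc, smi if (acc, smi) in lookup else standardize_smiles(smi))
        out.append(lookup[key])
    return np.asarray(out)


def write_corpus(
    corpus: Sequence[tuple[str, str]],
    ligand_sets: Sequence[TargetLigandSet],
    path,
) -> None:
    """Dump the corpus as TSV: accession, smiles, origin, source_pchembl."""
    import pandas as pd

    originals = {(s.accession, r.smiles) for s in ligand_sets for r in s.records}
    pch = corpus_pchembl_values(corpus, ligand_sets)
    rows = [
        (acc, smi, "original" if (acc, smi) in originals else "augmented", p)
        for (acc, smi), p in zip(corpus, pch)
    ]
    pd.DataFrame(
        rows, columns=["accession", "smiles", "origin", "source_pchembl"]
    ).to_csv(path, sep="\t", index=False)


def write_plan(plan: AugmentationPlan, path) -> None:
    """Dump per-target counts (accession, n_i, n_prime_i) for audit."""
    import pandas as pd

    rows = [(acc, n, npr) for acc, (n, npr) in plan.counts.items()]
    pd.DataFrame(rows, columns=["accession", "n_i", "n_prime_i"]).to_csv(
        path, sep="\t", index=False
    )
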