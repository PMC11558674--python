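"""Ligand bioactivity ingestion and target selection.

Records are (target accession, SMILES, pChEMBL) triples in the style of the
Papyrus bioactivity tables. pChEMBL is the negative log10 of a molar potency
(Ki, Kd or IC50); the activity filter keeps compounds with pChEMBL >= 6.5
(roughly sub-315 nM) by default. Stereochemistry is stripped during
standardization because the downstream generator does not use it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .errors import ConfigurationError, FormatError, SmilesParseError, ValidationError

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Inclusive pChEMBL activity threshold used throughout.
ACTIVITY_THRESHOLD = 6.5

REQUIRED_COLUMNS = ("accession", "SMILES", "pchembl_value")


@dataclass(frozen=True)
class BioactivityRecord:
    """A single standardized bioactivity measurement."""

    accession: str
    smiles: str
    pchembl: float

    def __post_init__(self):
        if not math.isfinite(self.pchembl):
            raise ValidationError(f"non-finite pChEMBL for {self.accession}")
        if not (3.0 <= self.pchembl <= 12.0):
            logger.warning(
                "pChEMBL %.3g for %s outside the typical [3, 12] range",
                self.pchembl,
                self.accession,
            )


@dataclass
class TargetLigandSet:
    """All deduplicated actives of one target; ``n`` is the ligand count n_i."""

    accession: str
    records: list[BioactivityRecord]

    def __post_init__(self):
        if any(r.accession != self.accession for r in self.records):
            raise ValidationError("mixed accessions in one ligand set")
        seen = set()
        for r in self.records:
            if r.smiles in seen:
                raise ValidationError(
                    f"duplicate canonical SMILES in set {self.accession}: {r.smiles}"
                )
            seen.add(r.smiles)

    @property
    def n(self) -> int:
        return len(self.records)


@dataclass
class IngestReport:
    """Row accounting for one table read."""

    n_rows: int = 0
    n_kept: int = 0
    n_unparseable: int = 0
    n_duplicates_collapsed: int = 0
    dropped_smiles: list[str] = field(default_factory=list)


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Pick the fragment with most heavy atoms among those containing carbon.

    Ties break by molecular weight, then by canonical SMILES string order,
    so salt stripping is deterministic. Falls back to the largest fragment
    overall if no fragment contains carbon.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]

    def has_carbon(m):
        return any(a.GetAtomicNum() == 6 for a in m.GetAtoms())

    candidates = [f for f in frags if has_carbon(f)] or list(frags)
    return max(
        candidates,
        key=lambda m: (
            m.GetNumHeavyAtoms(),
            Descriptors.MolWt(m),
            Chem.MolToSmiles(m),
        ),
    )


def standardize_smiles(raw: str) -> str:
    """Canonicalize a SMILES string for this pipeline.

    Keeps the largest organic fragment (counter-ions dropped), removes
    stereochemistry descriptors and explicit hydrogens, and returns the
    RDKit canonical SMILES. Idempotent: standardizing the output returns it
    unchanged. Charges are left as parsed after salt removal.
    """
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise SmilesParseError(raw)
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(raw, "empty molecule")
    mol = _largest_organic_fragment(mol)
    mol = Chem.RemoveHs(mol)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def is_valid_smiles(raw: str) -> bool:
    """True if ``raw`` standardizes without error."""
    try:
        standardize_smiles(raw)
        return True
    except SmilesParseError:
        return False


def ingest_bioactivity(path: str | Path) -> tuple[list[BioactivityRecord], IngestReport]:
    """Read a TSV bioactivity table, standardize and deduplicate.

    The table must carry ``accession``, ``SMILES`` and ``pchembl_value``
    columns (extras are ignored). Unparseable SMILES rows are dropped and
    counted; duplicate (accession, canonical SMILES) pairs collapse keeping
    the highest pChEMBL.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    report = IngestReport(n_rows=len(df))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in {path}")
    if df.empty:
        logger.warning("empty bioactivity table: %s", path)
        return [], report

    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for acc, smi, pch in df[list(REQUIRED_COLUMNS)].itertuples(index=False):
        try:
            canon = standardize_smiles(str(smi))
        except SmilesParseError:
            report.n_unparseable += 1
            report.dropped_smiles.append(str(smi))
            continue
        key = (str(acc), canon)
        if key in best:
            report.n_duplicates_collapsed += 1
            best[key] = max(best[key], float(pch))
        else:
            best[key] = float(pch)
            order.append(key)
    records = [BioactivityRecord(a, s, best[(a, s)]) for a, s in order]
    report.n_kept = len(records)
    logger.info(
        "%s: %d rows -> %d records (%d unparseable, %d duplicates collapsed)",
        path,
        report.n_rows,
        report.n_kept,
        report.n_unparseable,
        report.n_duplicates_collapsed,
    )
    return records, report


def read_bioactivity_table(path: str | Path) -> list[BioactivityRecord]:
    """Like :func:`ingest_bioactivity` but returning only the records."""
    return ingest_bioactivity(path)[0]


def write_bioactivity_table(records: Iterable[BioactivityRecord], path: str | Path) -> None:
    """Write records back out in the ingestible TSV schema.

    pChEMBL is printed at 6 significant digits (far beyond assay
    precision), which makes write -> read -> write a fixed point.
    """
    df = pd.DataFrame(
        [(r.accession, r.smiles, r.pchembl) for r in records],
        columns=list(REQUIRED_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def filter_actives(
    records: Sequence[BioactivityRecord], threshold: float = ACTIVITY_THRESHOLD
) -> list[BioactivityRecord]:
    """Keep records with pChEMBL >= threshold (inclusive), order preserved."""
    return [r for r in records if r.pchembl >= threshold]


def group_by_target(records: Sequence[BioactivityRecord]) -> list[TargetLigandSet]:
    """Group records into per-target ligand sets (insertion order kept)."""
    by_acc: dict[str, list[BioactivityRecord]] = {}
    for r in records:
        by_acc.setdefault(r.accession, []).append(r)
    return [TargetLigandSet(acc, recs) for acc, recs in by_acc.items()]


def select_targets(
    ligand_sets: Sequence[TargetLigandSet],
    lengths: Mapping[str, int],
    min_ligands: int = 10,
    max_length: int = 1536,
) -> list[TargetLigandSet]:
    """Apply the model-eligibility criteria: enough actives, short enough chain.

    A target is retained iff it has at least ``min_ligands`` ligands and its
    protein is at most ``max_length`` residues. Every accession must appear
    in ``lengths``.
    """
    missing = [s.accession for s in ligand_sets if s.accession not in lengths]
    if missing:
        raise ConfigurationError(f"no residue length known for {missing}")
    return [
        s
        for s in ligand_sets
        if s.n >= min_ligands and lengths[s.accession] <= max_length
    ]
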