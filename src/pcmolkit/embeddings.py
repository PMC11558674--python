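"""Per-target protein-embedding matrices: I/O, transforms, and the target split.

Each target carries two per-residue embedding streams extracted from
AlphaFold2's trunk — the Evoformer single representation and the Structure
module activations — each a [L x 384] matrix for a protein of L residues.
Matrices are stored residue-major (residues as rows), so averaging over the
residue dimension is a row reduction and yields a fixed-size 384-vector per
target regardless of L.

The shuffle transform destroys the information content of an embedding
while preserving its value statistics (the corrupted-conditioning control
regime): rows and columns are each permuted by one fixed seed-determined
permutation per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, NotFoundError, ValidationError

EMBED_DIM = 384
MAX_MODEL_LENGTH = 1536

STREAMS = ("evoformer", "structure")

SIDECAR_COLUMNS = ("accession", "length", "family", "species", "orthologue_group")


@dataclass
class AlphaFoldEmbedding:
    """Two [L x 384] per-residue embedding matrices plus metadata."""

    accession: str
    evoformer: np.ndarray
    structure: np.ndarray
    family: str | None = None
    species: str | None = None
    orthologue_group: str | None = None

    def __post_init__(self):
        self.evoformer = np.asarray(self.evoformer, dtype=np.float32)
        self.structure = np.asarray(self.structure, dtype=np.float32)
        for name in STREAMS:
            m = getattr(self, name)
            if m.ndim != 2 or m.shape[1] != EMBED_DIM:
                raise ValidationError(
                    f"{self.accession}/{name}: expected [L x {EMBED_DIM}], got {m.shape}"
                )
            if m.shape[0] < 1:
                raise ValidationError(f"{self.accession}/{name}: L must be >= 1")
            if not np.all(np.isfinite(m)):
                raise ValidationError(f"{self.accession}/{name}: non-finite entries")
        if self.evoformer.shape[0] != self.structure.shape[0]:
            raise FormatError(
                f"{self.accession}: stream length mismatch "
                f"{self.evoformer.shape[0]} vs {self.structure.shape[0]}"
            )

    @property
    def length(self) -> int:
        return int(self.evoformer.shape[0])

    def stream(self, name: str) -> np.ndarray:
        if name not in STREAMS:
            raise ConfigurationError(f"unknown stream {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class TargetSplit:
    """Disjoint train/test partition of an accession set."""

    train_accessions: frozenset[str]
    test_accessions: frozenset[str]

    def __post_init__(self):
        if self.train_accessions & self.test_accessions:
            raise ValidationError("train and test sets overlap")


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def save_container(
    embeddings: Sequence[AlphaFoldEmbedding],
    container_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> None:
    """Write a compressed archive of named float32 arrays plus a TSV sidecar.

    Array keys are ``<accession>/evoformer`` and ``<accession>/structure``.
    """
    arrays = {}
    for emb in embeddings:
        arrays[f"{emb.accession}/evoformer"] = emb.evoformer
        arrays[f"{emb.accession}/structure"] = emb.structure
    np.savez_compressed(container_path, **arrays)
    if sidecar_path is not None:
        rows = [
            (
                e.accession,
                e.length,
                e.family or "",
                e.species or "",
                e.orthologue_group or "",
            )
            for e in embeddings
        ]
        pd.DataFrame(rows, columns=list(SIDECAR_COLUMNS)).to_csv(
            sidecar_path, sep="\t", index=False
        )


def read_sidecar(sidecar_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(sidecar_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SIDECAR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sidecar missing column(s) {missing}")
    return df


def container_accessions(container_path: str | Path) -> list[str]:
    with np.load(container_path) as data:
        accs = sorted({k.rsplit("/", 1)[0] for k in data.files})
    return accs


def load_embedding(
    container_path: str | Path,
    accession: str,
    metadata: Mapping[str, Mapping[str, str]] | None = None,
) -> AlphaFoldEmbedding:
    """Load one target's two streams from a container archive.

    ``metadata`` optionally maps accession -> {family, species,
    orthologue_group}. Missing accessions raise :class:`NotFoundError`;
    mismatched stream lengths raise :class:`FormatError`; non-finite
    entries raise :class:`ValidationError`.
    """
    with np.load(container_path) as data:
        keys = [f"{accession}/{s}" for s in STREAMS]
        for k in keys:
            if k not in data.files:
                raise NotFoundError(f"accession {accession!r} not in container")
        evo, struct = (data[k] for k in keys)
    meta = (metadata or {}).get(accession, {})
    return AlphaFoldEmbedding(
        accession=accession,
        evoformer=evo,
        structure=struct,
        family=meta.get("family") or None,
        species=meta.get("species") or None,
        orthologue_group=meta.get("orthologue_group") or None,
    )


def load_all(
    container_path: str | Path, sidecar_path: str | Path | None = None
) -> list[AlphaFoldEmbedding]:
    metadata = None
    if sidecar_path is not None:
        df = read_sidecar(sidecar_path)
        metadata = {
            row["accession"]: {
                "family": row["family"],
                "species": row["species"],
                "orthologue_group": row["orthologue_group"],
            }
            for _, row in df.iterrows()
        }
    return [
        load_embedding(container_path, acc, metadata)
        for acc in container_accessions(container_path)
    ]


def validate_container(
    container_path: str | Path, sidecar_path: str | Path | None = None
) -> dict:
    """Load everything, raising on the first violation; return a summary."""
    embs = load_all(container_path, sidecar_path)
    return {
        "n_targets": len(embs),
        "lengths": {e.accession: e.length for e in embs},
        "model_eligible": sum(e.length <= MAX_MODEL_LENGTH for e in embs),
    }


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def average_embedding(emb: AlphaFoldEmbedding, stream: str = "evoformer") -> np.ndarray:
    """Mean over the residue dimension: [L x 384] -> vector of length 384."""
    return emb.stream(stream).mean(axis=0)


def averaged_matrix(
    embeddings: Sequence[AlphaFoldEmbedding], stream: str = "evoformer"
) -> np.ndarray:
    """Stack residue-averaged vectors into an [n_targets x 384] matrix."""
    return np.stack([average_embedding(e, stream) for e in embeddings])


def shuffle_embedding(emb: AlphaFoldEmbedding, seed: int) -> AlphaFoldEmbedding:
    """Corrupt an embedding by permuting residues then features.

    One fixed row permutation and one fixed column permutation are drawn per
    stream from ``seed``; entry multisets, shapes and metadata are
    preserved. This is the control input for measuring how much the
    generator actually relies on protein-side information.
    """
    rng = np.random.default_rng(seed)
    new = {}
    for name in STREAMS:
        m = emb.stream(name)
        rows = rng.permutation(m.shape[0])
        cols = rng.permutation(m.shape[1])
        new[name] = m[rows][:, cols]
    return replace(emb, evoformer=new["evoformer"], structure=new["structure"])


def cluster_families_ari(
    embeddings: Sequence[AlphaFoldEmbedding],
    n_clusters: int | None = None,
    stream: str = "evoformer",
    seed: int = 0,
) -> float:
    """Adjusted Rand index of k-means on residue-averaged vectors vs. families.

    The quantitative stand-in for the qualitative observation that
    low-dimensional projections of averaged embeddings cluster by protein
    family: near 1 when family structure is recoverable, near 0 when absent.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    labels = [e.family for e in embeddings]
    if any(l is None for l in labels):
        raise ConfigurationError("family labels required")
    k = n_clusters or len(set(labels))
    X = averaged_matrix(embeddings, stream)
    pred = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    return float(adjusted_rand_score(labels, pred))


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

def cosine_similarity_fn(a: AlphaFoldEmbedding, b: AlphaFoldEmbedding) -> float:
    """Default pairwise similarity: cosine of residue-averaged vectors, mapped to [0,1]."""
    va, vb = average_embedding(a), average_embedding(b)
    denom = float(np.linalg.norm(va) * np.linalg.norm(vb))
    if denom == 0.0:
        return 0.0
    return 0.5 * (1.0 + float(np.dot(va, vb)) / denom)


def sequence_identity_fn(sequences: Mapping[str, str]) -> Callable:
    """Similarity factory from amino-acid sequences: global-alignment identity.

    Returns a function over embedding pairs suitable for
    :func:`stratified_split` when sequences are available.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(mode="global", match_score=1, mismatch_score=0,
                                    open_gap_score=0, extend_gap_score=0)

    def fn(a: AlphaFoldEmbedding, b: AlphaFoldEmbedding) -> float:
        sa, sb = sequences[a.accession], sequences[b.accession]
        score = aligner.score(sa, sb)
        return float(score) / max(len(sa), len(sb))

    return fn


def stratified_split(
    embeddings: Sequence[AlphaFoldEmbedding],
    test_fraction: float,
    similarity_fn: Callable | None = None,
    seed: int = 0,
) -> TargetSplit:
    """Family-stratified, similarity-weighted train/test split.

    Within each protein family a rounded quota of targets is drawn into the
    test set. After the first (uniform) draw, each remaining target's
    selection weight is ``eps + max similarity`` to the targets already in
    test, so related targets concentrate in the same partition and data
    leakage across the split is reduced. Orthologue groups move as one
    unit: if any member is drawn, the whole group joins the test set.
    Families with a single member go to train (nothing to stratify).
    """
    if not (0.0 < test_fraction < 1.0):
        raise ConfigurationError("test_fraction must lie in (0, 1)")
    if any(e.family is None for e in embeddings):
        raise ConfigurationError("every embedding needs a family label")
    similarity_fn = similarity_fn or cosine_similarity_fn
    rng = np.random.default_rng(seed)
    eps = 0.05

    # orthologue groups are indivisible units
    unit_of: dict[str, tuple[str, ...]] = {}
    groups: dict[str, list[str]] = {}
    for e in embeddings:
        if e.orthologue_group:
            groups.setdefault(e.orthologue_group, []).append(e.accession)
    for members in groups.values():
        unit = tuple(sorted(members))
        for acc in members:
            unit_of[acc] = unit
    by_acc = {e.accession: e for e in embeddings}

    families: dict[str, list[str]] = {}
    for e in embeddings:
        families.setdefault(e.family, []).append(e.accession)

    # largest-remainder quota allocation: per-family quotas stay within one
    # of test_fraction * family size while the total matches the global quota
    eligible = {f: sorted(m) for f, m in families.items() if len(m) >= 2}
    n_eligible = sum(len(m) for m in eligible.values())
    total_quota = int(round(test_fraction * n_eligible))
    ideal = {f: test_fraction * len(m) for f, m in eligible.items()}
    quotas = {f: int(math.floor(q)) for f, q in ideal.items()}
    leftover = total_quota - sum(quotas.values())
    for f in sorted(eligible, key=lambda f: (-(ideal[f] - quotas[f]), f)):
        if leftover <= 0:
            break
        quotas[f] += 1
        leftover -= 1

    test: set[str] = set()
    for fam in sorted(eligible):
        members = eligible[fam]
        quota = quotas[fam]
        if quota == 0:
            continue
        remaining = [a for a in members]
        fam_test: set[str] = set()
        while len(fam_test) < quota and remaining:
            if not fam_test:
                weights = np.ones(len(remaining))
            else:
                weights = np.array(
                    [
                        eps
                        + max(
                            similarity_fn(by_acc[a], by_acc[t]) for t in fam_test
                        )
                        for a in remaining
                    ]
                )
            p = weights / weights.sum()
            pick = remaining[int(rng.choice(len(remaining), p=p))]
            unit = unit_of.get(pick, (pick,))
            for acc in unit:
                fam_test.add(acc)
                test.add(acc)
                if acc in remaining:
                    remaining.remove(acc)
            # orthologues outside this family also follow their unit
    all_accs = {e.accession for e in embeddings}
    # close test under orthologue groups across families
    changed = True
    while changed:
        changed = False
        for acc in list(test):
            for other in unit_of.get(acc, (acc,)):
                if other not in test:
                    test.add(other)
                    changed = True
    if not test:
        raise ConfigurationError(
            "test_fraction too small: produced an empty test set"
        )
    return TargetSplit(
        train_accessions=frozenset(all_accs - test),
        test_accessions=frozenset(test),
    )
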