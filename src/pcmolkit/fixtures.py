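"""Synthetic paired protein-embedding / ligand-family datasets.

The generator plants the two statistical structures the method relies on:

* embedding space: K protein families as well-separated Gaussian clusters
  of per-residue matrices, two correlated streams per target, variable
  residue counts — so residue-averaged vectors cluster by family;
* chemical space: one distinct ring-system scaffold per family, each
  target's ligands built by grammar-based decoration of its family core
  with acyclic substituents — so every ligand is valid by construction,
  carries its family scaffold as a substructure, and families are
  separable by fingerprint similarity.

Per-target ligand counts follow a truncated power law (most targets
sparse, a few rich) and pChEMBL values a two-component Gaussian mixture
clipped to [5.0, 9.5], emulating the skew and potency spread of public
bioactivity corpora. None of this mimics true AlphaFold statistics; the
point is recoverable structure, not realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem

from .bioactivity import BioactivityRecord, TargetLigandSet, standardize_smiles, write_bioactivity_table
from .embeddings import AlphaFoldEmbedding, save_container
from .errors import ConfigurationError, ValidationError

# one decoration template per family: three substitution sites on a
# distinct ring system, padded with short aliphatic/ether linkers so
# molecules average ~30 tokens
FAMILY_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("CCOc1cc({0})ccc1C(=O)N({1})CC{2}", "c1ccccc1"),
    ("COc1cc({0})ncc1C(=O)N({1})CC{2}", "c1ccncc1"),
    ("CC(C)Oc1ccc2cc({0})c(C(=O)N({1})C{2})cc2c1", "c1ccc2ccccc2c1"),
    ("CCn1cc({0})c2cc({1})c(OCC{2})cc21", "c1ccc2[nH]ccc2c1"),
    ("CCOc1ccc(-c2cc({0})c(C(=O)N({1})C{2})s2)cc1", "c1ccc(-c2cccs2)cc1"),
    ("O1CCN(C(=O)c2ccc({0})c(OC{1})c2)CC1{2}", "O=C(c1ccccc1)N1CCOCC1"),
    ("CCc1nc({0})c2cc({1})c(NCC{2})cc2n1", "c1ccc2ncncc2c1"),
    ("COC1CCN(c2ccc({0})c(C(=O)N({1})C{2})c2)CC1", "c1ccc(N2CCCCC2)cc1"),
)

SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "CCO", "OC", "OCC", "N(C)C", "CCN", "C(C)C",
    "CCOC", "F", "Cl", "C#N", "C(F)(F)F", "C(=O)OC", "OCCO",
)


def _template_framework(template: str) -> str:
    """The Murcko framework shared by every decoration of a template."""
    from rdkit.Chem.Scaffolds import MurckoScaffold

    probe = template.format("C", "C", "C")
    return MurckoScaffold.MurckoScaffoldSmiles(standardize_smiles(probe))


@dataclass
class FixtureSpec:
    """All knobs of the synthetic dataset; one seed drives everything."""

    num_families: int = 5
    targets_per_family: int = 6
    length_range: tuple[int, int] = (40, 120)
    family_separation: float = 10.0
    scaffold_templates: tuple[tuple[str, str], ...] | None = None
    count_exponent: float = 2.0
    count_range: tuple[int, int] = (10, 300)
    pchembl_means: tuple[float, float] = (6.3, 7.6)
    pchembl_sds: tuple[float, float] = (0.5, 0.6)
    pchembl_weights: tuple[float, float] = (0.45, 0.55)
    pchembl_range: tuple[float, float] = (5.0, 9.5)
    stream_mix: float = 0.5
    orthologue_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.num_families < 2:
            raise ValidationError("need at least 2 families")
        if self.scaffold_templates is None:
            if self.num_families > len(FAMILY_TEMPLATES):
                raise ConfigurationError(
                    f"at most {len(FAMILY_TEMPLATES)} built-in family scaffolds"
                )
            self.scaffold_templates = FAMILY_TEMPLATES[: self.num_families]
        lo, hi = self.length_range
        if not (1 <= lo <= hi <= 1536):
            raise ValidationError("length_range must lie within [1, 1536]")
        if not (1 <= self.count_range[0] <= self.count_range[1]):
            raise ValidationError("count_range must be well-ordered and >= 1")
        frameworks = [_template_framework(t) for t, _ in self.scaffold_templates]
        if len(set(frameworks)) != len(frameworks):
            raise ValidationError("family scaffolds must be distinct frameworks")

    def family_name(self, f: int) -> str:
        return f"FAM{f}"

    def accession(self, f: int, t: int) -> str:
        return f"F{f}T{t:02d}"


def _family_centroids(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    # per-coordinate spread = separation x within-family unit std
    return rng.normal(0.0, spec.family_separation, size=(spec.num_families, 384))


def make_embeddings(spec: FixtureSpec) -> list[AlphaFoldEmbedding]:
    """Family-clustered two-stream embedding matrices with variable L.

    Per family a 384-dim centroid; per target a unit-variance jitter of it;
    per residue unit isotropic noise, the structure stream's noise
    correlated with the evoformer's by ``stream_mix``. Optionally a
    fraction of targets is duplicated with small noise and a changed
    species label to simulate functional orthologues.
    """
    rng = np.random.default_rng(spec.seed)
    centroids = _family_centroids(spec, rng)
    lo, hi = spec.length_range
    mix = spec.stream_mix
    out: list[AlphaFoldEmbedding] = []
    for f in range(spec.num_families):
        for t in range(spec.targets_per_family):
            L = int(rng.integers(lo, hi + 1))
            target_center = centroids[f] + rng.normal(0.0, 1.0, 384)
            noise_e = rng.normal(0.0, 1.0, (L, 384))
            noise_s = mix * noise_e + np.sqrt(1 - mix**2) * rng.normal(0.0, 1.0, (L, 384))
            out.append(
                AlphaFoldEmbedding(
                    accession=spec.accession(f, t),
                    evoformer=target_center + noise_e,
                    structure=target_center + noise_s,
                    family=spec.family_name(f),
                    species="Homo sapiens",
                )
            )
    if spec.orthologue_fraction > 0:
        n_orth = max(1, int(round(spec.orthologue_fraction * len(out))))
        for emb in list(out[:n_orth]):
            group = f"OG_{emb.accession}"
            emb.orthologue_group = group
            out.append(
                AlphaFoldEmbedding(
                    accession=emb.accession + "_ORT",
                    evoformer=emb.evoformer + rng.normal(0.0, 0.1, emb.evoformer.shape),
                    structure=emb.structure + rng.normal(0.0, 0.1, emb.structure.shape),
                    family=emb.family,
                    species="Mus musculus",
                    orthologue_group=group,
                )
            )
    return out


def _power_law_counts(spec: FixtureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated Pareto counts in ``count_range`` with the requested exponent."""
    lo, hi = spec.count_range
    a = spec.count_exponent
    u = rng.random(n)
    # inverse-CDF of a Pareto(alpha = a - 1) truncated at hi
    alpha = a - 1.0
    cdf_hi = 1.0 - (lo / hi) ** alpha
    vals = lo * (1.0 - u * cdf_hi) ** (-1.0 / alpha)
    return np.clip(np.round(vals).astype(int), lo, hi)


def _sample_pchembl(spec: FixtureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    comp = rng.choice(2, size=n, p=np.asarray(spec.pchembl_weights) / sum(spec.pchembl_weights))
    vals = rng.normal(
        np.asarray(spec.pchembl_means)[comp], np.asarray(spec.pchembl_sds)[comp]
    )
    return np.clip(vals, *spec.pchembl_range)


def decorate_scaffold(
    template: str, rng: np.random.Generator, n_sites: int = 3
) -> str:
    """One valid decorated molecule from a family template."""
    subs = [SUBSTITUENTS[int(rng.integers(len(SUBSTITUENTS)))] for _ in range(n_sites)]
    smi = template.format(*subs)
    if Chem.MolFromSmiles(smi) is None:  # pragma: no cover - grammar guarantees validity
        raise ValidationError(f"template produced invalid SMILES: {smi}")
    return standardize_smiles(smi)


def make_ligands(spec: FixtureSpec) -> list[TargetLigandSet]:
    """Per-target ligand sets: decorated family scaffolds, power-law counts."""
    rng = np.random.default_rng(spec.seed + 1)
    counts = _power_law_counts(
        spec, spec.num_families * spec.targets_per_family, rng
    )
    max_combos = len(SUBSTITUENTS) ** 3
    out: list[TargetLigandSet] = []
    i = 0
    for f in range(spec.num_families):
        template = spec.scaffold_templates[f][0]
        for t in range(spec.targets_per_family):
            n = int(min(counts[i], max_combos))
            i += 1
            seen: set[str] = set()
            while len(seen) < n:
                seen.add(decorate_scaffold(template, rng))
            smiles = sorted(seen)
            pch = _sample_pchembl(spec, n, rng)
            acc = spec.accession(f, t)
            records = [
                BioactivityRecord(acc, s, float(p)) for s, p in zip(smiles, pch)
            ]
            out.append(TargetLigandSet(acc, records))
    return out


def family_scaffold(spec: FixtureSpec, f: int) -> str:
    """The Murcko framework every ligand of family ``f`` shares."""
    return _template_framework(spec.scaffold_templates[f][0])


def target_family_map(spec: FixtureSpec) -> dict[str, str]:
    return {
        spec.accession(f, t): spec.family_name(f)
        for f in range(spec.num_families)
        for t in range(spec.targets_per_family)
    }


def make_full_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write container + sidecar + bioactivity table + manifest to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "container": out_dir / "embeddings.npz",
        "sidecar": out_dir / "targets.tsv",
        "bioactivity": out_dir / "bioactivity.tsv",
        "manifest": out_dir / "manifest.json",
    }
    embs = make_embeddings(spec)
    ligands = make_ligands(spec)
    save_container(embs, paths["container"], paths["sidecar"])
    write_bioactivity_table(
        [r for s in ligands for r in s.records], paths["bioactivity"]
    )
    manifest = asdict(spec)
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=list) + "\n")
    return paths


def spec_from_manifest(path: str | Path) -> FixtureSpec:
    raw = json.loads(Path(path).read_text())
    for key in (
        "length_range", "count_range", "pchembl_means", "pchembl_sds",
        "pchembl_weights", "pchembl_range",
    ):
        raw[key] = tuple(raw[key])
    if raw.get("scaffold_templates"):
        raw["scaffold_templates"] = tuple(tuple(x) for x in raw["scaffold_templates"])
    return FixtureSpec(**raw)
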