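"""Shared fixtures: synthetic datasets and (expensive) trained tiny models.

Heavy artifacts — the memorization model and the conditioning-vs-shuffled
comparison — are session-scoped so multiple tests can interrogate one
training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import pcmolkit as pk

# tiny-model setup used by all training tests: d=64, 2 blocks, 4 heads
TINY_CONFIG = dict(
    d=64,
    num_blocks=2,
    num_heads=4,
    encoder_context=128,
    decoder_context=102,
    dropout=0.0,
    batch_size=20,
    learning_rate=3e-3,
)

OVERFIT_EPOCHS = 200
# family-level conditioning saturates well before full memorization, so the
# ablation runs train shorter than the memorization run
CONDITIONING_EPOCHS = 120


@pytest.fixture(scope="session")
def overfit_spec() -> pk.FixtureSpec:
    """20 targets (5 families x 4), exactly 10 ligands each."""
    return pk.FixtureSpec(
        num_families=5,
        targets_per_family=4,
        count_range=(10, 10),
        length_range=(30, 60),
        seed=7,
    )


@pytest.fixture(scope="session")
def overfit_data(overfit_spec):
    embs = pk.make_embeddings(overfit_spec)
    ligs = pk.make_ligands(overfit_spec)
    corpus = [(s.accession, r.smiles) for s in ligs for r in s.records]
    vocab = pk.build_vocabulary([s for _, s in corpus])
    return {
        "spec": overfit_spec,
        "embeddings": embs,
        "ligand_sets": ligs,
        "corpus": corpus,
        "vocab": vocab,
    }


@pytest.fixture(scope="session")
def overfit_run(overfit_data):
    """The memorization run: tiny model driven to near-zero training loss."""
    cfg = pk.ModelConfig(**TINY_CONFIG)
    model = pk.ConditionedLM(cfg, overfit_data["vocab"], seed=0)
    state = model.fit(
        overfit_data["corpus"],
        overfit_data["embeddings"],
        epochs=OVERFIT_EPOCHS,
        seed=0,
    )
    return {"model": model, "state": state, **overfit_data}


@pytest.fixture(scope="session")
def conditioning_runs(overfit_data):
    """Paired generations from the trained model: true vs shuffled conditioning.

    For each of three training seeds, the tiny model is trained on the
    5-family fixture and then sampled per target twice — once with the
    target's real embedding and once with a shuffle-corrupted copy.
    """
    spec = overfit_data["spec"]
    families = pk.fixtures.target_family_map(spec)
    family_refs: dict[str, list[str]] = {}
    for lset in overfit_data["ligand_sets"]:
        family_refs.setdefault(families[lset.accession], []).extend(
            r.smiles for r in lset.records
        )
    embs = {e.accession: e for e in overfit_data["embeddings"]}
    n_per_target = 12
    runs = []
    for train_seed in (0, 1, 2):
        cfg = pk.ModelConfig(**TINY_CONFIG)
        model = pk.ConditionedLM(cfg, overfit_data["vocab"], seed=train_seed)
        model.fit(
            overfit_data["corpus"],
            embs,
            epochs=CONDITIONING_EPOCHS,
            seed=train_seed,
        )

        def gen_true(acc, n, seed, _m=model):
            return _m.sample(embs[acc], n=n, temperature=1.0, seed=seed)[0]

        def gen_shuffled(acc, n, seed, _m=model):
            return _m.sample(
                embs[acc], n=n, temperature=1.0, seed=seed, shuffle_seed=seed + 1000
            )[0]

        rate_true = pk.family_match_rate(
            gen_true, families, family_refs, n_per_target, seed=100 + train_seed
        )
        rate_shuffled = pk.family_match_rate(
            gen_shuffled, families, family_refs, n_per_target, seed=100 + train_seed
        )
        runs.append({"seed": train_seed, "true": rate_true, "shuffled": rate_shuffled})
    return {
        "runs": runs,
        "n_targets": len(families),
        "k": spec.num_families,
        "families": families,
        "family_refs": family_refs,
    }
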