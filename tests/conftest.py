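"""Shared fixtures: phantom data, prepared pairs, and the scaled-down
training runs reused by the training and acceptance suites."""

from __future__ import annotations

import numpy as np
import pytest

from sctgan import (TrainConfig, build_flow_cache, build_slice_dataset,
                    generate_cohort, init_state, prepare_volume, train_step)

# Scaled-down study conditions: 64 x 64 phantoms, four training patients,
# narrow networks (the full-scale architecture is ngf = ndf = 64 with
# nine residual blocks), 200 optimizer steps, three seeds.
SMOKE = dict(size=64, n_slices=12, ngf=6, ndf=6, n_res=3, batch=4,
             steps=200, seeds=(0, 1, 2))


@pytest.fixture(scope="session")
def phantom_pair():
    """One prepared MR/CT phantom pair at test scale (64 x 64)."""
    patient = generate_cohort(1, site_assignment=[1], seed=11,
                              size=64, n_slices=12)[0]
    mr, _ = prepare_volume(patient.mr, size=64)
    ct, _ = prepare_volume(patient.ct, size=64)
    return patient, mr, ct


@pytest.fixture(scope="session")
def smoke_corpus():
    """4 train patients (sites 2/3) + 2 test patients (site 1), prepared,
    with ground-truth flow caches for both modalities."""
    cohort = generate_cohort(6, site_assignment=[2, 3, 2, 3, 1, 1],
                             seed=7, size=SMOKE["size"],
                             n_slices=SMOKE["n_slices"])
    prepared = []
    for p in cohort:
        mr, _ = prepare_volume(p.mr, size=SMOKE["size"])
        ct, _ = prepare_volume(p.ct, size=SMOKE["size"])
        trimmed_organs = {k: v[2:-2] for k, v in p.organs.items()}
        caches = (build_flow_cache(ct.slices), build_flow_cache(mr.slices))
        prepared.append(dict(patient=p, mr=mr, ct=ct, caches=caches,
                             organs=trimmed_organs))
    train = [e for e in prepared if e["patient"].site_id in (2, 3)]
    test = [e for e in prepared if e["patient"].site_id == 1]
    dataset = build_slice_dataset([(e["mr"], e["ct"]) for e in train],
                                  [e["caches"] for e in train])
    return dict(train=train, test=test, dataset=dataset)


def smoke_config(variant: str, seed: int, epochs: int = 50) -> TrainConfig:
    return TrainConfig(epochs=epochs, lr_constant_epochs=epochs,
                       lr_decay_epochs=0, batch_size=SMOKE["batch"],
                       variant=variant, seed=seed, ngf=SMOKE["ngf"],
                       ndf=SMOKE["ndf"], n_res=SMOKE["n_res"])


def run_steps(variant: str, seed: int, dataset, n_steps: int):
    """Run `n_steps` optimizer steps; returns (state, per-step records)."""
    cfg = smoke_config(variant, seed)
    state = init_state(cfg)
    rng = np.random.default_rng([seed, 77])
    order = rng.permutation(len(dataset))
    pos = 0
    records = []
    for _ in range(n_steps):
        if pos + SMOKE["batch"] > len(order):
            order = rng.permutation(len(dataset))
            pos = 0
        batch = [dataset[i] for i in order[pos:pos + SMOKE["batch"]]]
        pos += SMOKE["batch"]
        records.append(train_step(batch, state, cfg, lr=cfg.lr))
    return state, records


@pytest.fixture(scope="session")
def smoke_runs(smoke_corpus):
    """200-step runs of all four variants x three seeds (shared by the
    descent and interframe-consistency checks)."""
    out = {}
    for variant in ("cyclegan", "structcgan", "flowcgan", "sfcgan"):
        for seed in SMOKE["seeds"]:
            state, records = run_steps(variant, seed,
                                       smoke_corpus["dataset"],
                                       SMOKE["steps"])
            out[(variant, seed)] = dict(state=state, records=records)
    return out
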