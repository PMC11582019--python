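"""Shared fixtures: small simulated datasets and on-disk TSV bundles."""

import numpy as np
import pandas as pd
import pytest

import resptyper as rt


@pytest.fixture(scope="session")
def small_dataset():
    """60-ASV dataset at reduced depth; session-scoped, deterministic."""
    cfg = rt.SimConfig(s_asvs=60, depth=4000)
    return rt.simulate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def small_abund(small_dataset):
    ds, _ = small_dataset
    return rt.to_absolute(ds.counts, ds.qpcr)


@pytest.fixture(scope="session")
def recovery_runs():
    """Planted-type recovery over 20 synthetic datasets at the study's
    noise level (200 ASVs, depth 1e4, effect 1.5, sigma_rep 0.2).

    Yields per-seed per-trajectory accuracy, adjusted Rand index, and
    full-pattern (all four treatments correct) accuracy.
    """
    from sklearn.metrics import adjusted_rand_score

    accs, aris, pattern_accs = [], [], []
    for seed in range(20):
        ds, truth = rt.simulate_dataset(
            rt.SimConfig(s_asvs=200, depth=10_000), seed=seed)
        ab = rt.to_absolute(ds.counts, ds.qpcr)
        rep = rt.select_responsive_asvs(ab, ds.counts, ds.meta, ds.design)
        assign, _ = rt.assign_response_types(
            ab, ds.meta, ds.design, sorted(rep.responsive_set),
            seed=1000 + seed)
        est = assign.set_index(["asv_id", "treatment"])["response_type"]
        tru = truth.types.stack().loc[est.index]
        accs.append(float((tru == est).mean()))
        aris.append(float(adjusted_rand_score(tru, est)))
        wide_est = est.unstack()
        wide_tru = truth.types.loc[wide_est.index, wide_est.columns]
        pattern_accs.append(float((wide_est == wide_tru).all(axis=1).mean()))
    return accs, aris, pattern_accs


@pytest.fixture()
def tiny_files(tmp_path):
    """Hand-written 3 ASVs x 4 samples TSV bundle on disk."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "asv_id\tS1\tS2\tS3\tS4\n"
        "ASV1\t10\t0\t5\t1\n"
        "ASV2\t20\t30\t5\t9\n"
        "ASV3\t0\t10\t10\t10\n"
    )
    meta = tmp_path / "meta.tsv"
    meta.write_text(
        "sample_id\tmaize\tnematode\tday\treplicate\tshared_baseline\n"
        "S1\t0\t0\t0\t1\t1\n"
        "S2\t0\t0\t0\t2\t1\n"
        "S3\t0\t0\t4\t1\t0\n"
        "S4\t0\t0\t4\t2\t0\n"
    )
    qpcr = tmp_path / "qpcr.tsv"
    qpcr.write_text(
        "sample_id\ttotal_copies\n"
        "S1\t1e8\nS2\t2e8\nS3\t1.5e8\nS4\t1e8\n"
    )
    tax = tmp_path / "tax.tsv"
    tax.write_text(
        "asv_id\tdomain\tphylum\tclass\torder\tfamily\tgenus\n"
        "ASV1\tBacteria\tBacteroidota\tX\to1\tChitinophagaceae\tg1\n"
        "ASV2\tBacteria\tPseudomonadota\tX\to2\t\t\n"
        "ASV3\tArchaea\tNitrososphaerota\tX\to3\tNitrososphaeraceae\tg3\n"
    )
    return {"counts": counts, "meta": meta, "qpcr": qpcr, "tax": tax,
            "dir": tmp_path}
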