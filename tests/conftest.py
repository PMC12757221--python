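"""Shared fixtures: small and large synthetic corpora with ground truth."""

import pytest

from faerspv import faers_io, riskmodel, signal, synth


@pytest.fixture(scope="session")
def small_corpus():
    """A compact corpus (n=4,000) for unit-level oracle checks."""
    cfg = synth.demo_config(n_reports=4000, seed=7)
    reports, truth = synth.generate(cfg)
    return cfg, reports, truth


@pytest.fixture(scope="session")
def small_analysis(small_corpus):
    """The small corpus taken through dedup + normalization + case flags."""
    cfg, reports, truth = small_corpus
    dedup, _ = faers_io.deduplicate(reports)
    faers_io.normalize_drugs(dedup, faers_io.load_atc_table(synth.make_atc_table(cfg)))
    flags = faers_io.extract_cases(dedup, cfg.target_pt)
    return cfg, dedup, flags, truth


def injected_null_config(seed: int = 1, n_reports: int = 50_000) -> synth.SynthConfig:
    """Recovery benchmark: 5 drugs with reporting OR 5-10 over 15 null drugs."""
    injected = [
        synth.SynthDrugProfile(f"riskdrug{i:02d}", f"L01RD{i:02d}", 0.03, true_ror=r)
        for i, r in enumerate([5.0, 6.0, 7.0, 8.5, 10.0], start=1)
    ]
    nulls = [
        synth.SynthDrugProfile(f"nulldrug{i:02d}", f"L01ND{i:02d}", 0.03, true_ror=1.0)
        for i in range(1, 16)
    ]
    return synth.SynthConfig(
        n_reports=n_reports,
        drug_profiles=injected + nulls,
        seed=seed,
        baseline_event_rate=0.02,
        n_background_drugs=5,
    )


@pytest.fixture(scope="session")
def recovery_run():
    """Full signal + risk-model pass over the injected/null benchmark corpus.

    Computed once per session; shared by the risk-model unit tests and the
    end-to-end recovery acceptance test.
    """
    cfg = injected_null_config(seed=1)
    reports, truth = synth.generate(cfg)
    dedup, _ = faers_io.deduplicate(reports)
    faers_io.normalize_drugs(dedup, faers_io.load_atc_table(synth.make_atc_table(cfg)))
    flags = faers_io.extract_cases(dedup, cfg.target_pt)
    profile_drugs = [p.name for p in cfg.drug_profiles]
    score_table = signal.compute_signal_table(
        dedup, cfg.target_pt, drugs=profile_drugs
    )
    design = riskmodel.build_design(dedup, flags, profile_drugs)
    return {
        "config": cfg,
        "truth": truth,
        "reports": dedup,
        "flags": flags,
        "score_table": score_table,
        "design": design,
        "injected": [p.name for p in cfg.drug_profiles if p.true_ror > 1],
        "nulls": [p.name for p in cfg.drug_profiles if p.true_ror == 1],
    }
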