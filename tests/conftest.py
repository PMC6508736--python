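"""Shared fixtures: a small synthetic reference bundle and the default
synthetic cohort (generated once per session)."""

from importlib import resources

import pandas as pd
import pytest

import sertoli_sig as ss


@pytest.fixture(scope="session")
def cfg() -> ss.ThresholdConfig:
    return ss.ThresholdConfig()


@pytest.fixture(scope="session")
def default_refs() -> ss.SyntheticReferences:
    return ss.generate_references(seed=17)


@pytest.fixture(scope="session")
def default_cohort(default_refs):
    cm, samples, truth = ss.generate_bulk_cohort(default_refs, seed=17)
    return cm, samples, truth


@pytest.fixture(scope="session")
def groups(default_cohort) -> pd.Series:
    _, samples, _ = default_cohort
    return pd.Series(samples["group"].values, index=samples["sample_id"])


@pytest.fixture(scope="session")
def donors_table() -> pd.DataFrame:
    path = resources.files("sertoli_sig") / "data" / "cohort_donors.tsv"
    return ss.read_sample_table(str(path))


def run_signature_screen(refs, cm, groups, cfg, comp=None):
    """Candidate screen -> ortholog map -> deconvolution -> criteria,
    exactly as the pipeline wires the stages; returns the calls table."""
    comp = comp or ss.default_composition_cs()
    candidates = ss.rat_screen(refs.rat_ref, cfg.rat_fold)
    mapped, _ = ss.map_orthologs(candidates, refs.orthologs)
    tentative = ss.augment_candidates(mapped, [])
    factors = ss.tmm_factors(cm)
    tm = ss.tmm_cpm(cm, factors)
    cs_ids = [s for s in cm.sample_ids if groups[s] == "CS"]
    present = [g for g in tentative if g in tm.values.index]
    mean_cs = tm.values.loc[present, cs_ids].mean(axis=1)
    est = ss.estimate_sertoli(mean_cs, refs.human_ref, comp)
    return ss.call_signatures(est, refs.human_ref, comp, cfg)
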