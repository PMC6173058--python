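import pytest

import ess


@pytest.fixture(scope="session")
def fig1a():
    return ess.fig1a_model()


@pytest.fixture(scope="session")
def fig1b():
    return ess.fig1b_model()


@pytest.fixture(scope="session")
def ecoli():
    return ess.load_ecoli_core()


@pytest.fixture(scope="session")
def ecoli_cfg3():
    # ATPM is a maintenance pseudo-reaction and is excluded from candidacy
    return ess.AnalysisConfig(level_n=3, excluded_ids=frozenset({"ATPM"}))


@pytest.fixture(scope="session")
def ecoli_wt_l3(ecoli, ecoli_cfg3):
    """Level-3 minimal lethal sets of the wild-type E. coli core model.

    The single heavyweight computation of the suite (about a minute);
    session-scoped so every consumer shares it.
    """
    return ess.enumerate_minimal_lethal_sets(ecoli, ecoli_cfg3)


@pytest.fixture(scope="session")
def ecoli_wt_scores(ecoli_wt_l3):
    return ess.compute_escore(ecoli_wt_l3)


@pytest.fixture(scope="session")
def ecoli_mut_l3(ecoli, ecoli_cfg3):
    mutant = ecoli.remove_reaction("LDH_D")
    return ess.enumerate_minimal_lethal_sets(mutant, ecoli_cfg3)


@pytest.fixture(scope="session")
def ecoli_mut_scores(ecoli_mut_l3):
    return ess.compute_escore(ecoli_mut_l3)
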