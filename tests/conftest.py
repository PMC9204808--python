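"""Shared fixtures: small synthetic runs with known ground truth."""

import pytest

from coformscreen import (
    HomologSpec,
    SpikeSpec,
    SuspectEntry,
    SyntheticRunConfig,
    TheoreticalFragment,
    generate_blank,
    generate_run,
    parse_formula,
)

MCI = "methylchloroisothiazolinone"


@pytest.fixture(scope="session")
def mci_formula():
    return parse_formula("C4H4ClNOS")


@pytest.fixture(scope="session")
def mci_fragments():
    # two plausible even-electron fragments of the protonated molecule
    return (
        (TheoreticalFragment.from_formula("C3H4NS"), 0.6),
        (TheoreticalFragment.from_formula("C2H2NS"), 0.3),
    )


@pytest.fixture(scope="session")
def mci_spike(mci_formula, mci_fragments):
    return SpikeSpec(
        name=MCI, formula=mci_formula, apex_rt=2.0, apex_intensity=8e5,
        peak_sigma=0.05, fragments=mci_fragments)


@pytest.fixture(scope="session")
def small_config():
    """A 4-min acquisition: fast enough for unit tests, >= 15 points/peak."""
    return SyntheticRunConfig(
        run_length=4.0, ms1_cycle=2.0, mass_jitter_ppm=1.0,
        noise_rate=5.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_config():
    return SyntheticRunConfig(
        run_length=4.0, ms1_cycle=2.0, mass_jitter_ppm=0.0,
        noise_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def mci_run(small_config, mci_spike):
    return generate_run(small_config, [mci_spike])


@pytest.fixture(scope="session")
def blank_run(small_config):
    return generate_blank(small_config)


@pytest.fixture(scope="session")
def mci_db(mci_formula, mci_fragments):
    return [SuspectEntry(
        name=MCI, formula=mci_formula, adducts=("[M+H]+",),
        fragments=tuple(f for f, _ in mci_fragments),
        banned_eu=True, rfd=0.02)]
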