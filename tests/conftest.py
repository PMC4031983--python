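import pandas as pd
import pytest

from mirloh import AnalysisParams, simulate_cohort, simulate_screen


@pytest.fixture(scope="session")
def params():
    return AnalysisParams()


@pytest.fixture(scope="session")
def screen_sim():
    """One synthetic screen: 880 mimics, 20 planted hits, effect 0.5, CV 10%."""
    return simulate_screen(seed=1)


@pytest.fixture(scope="session")
def cohort_sim():
    """One synthetic cohort: 40 WT + 10 per deletion group, rates 60 vs 80."""
    return simulate_cohort(seed=1)


@pytest.fixture(scope="session")
def cohort_dir(cohort_sim, tmp_path_factory):
    """The same cohort written to disk in the pipeline's directory layout."""
    d = tmp_path_factory.mktemp("cohort")
    data, truth = cohort_sim
    data.write(d)
    truth.write(d / "truth.json")
    return d


def make_events(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end"])


def make_cn(rows):
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "log2_ratio"]
    )


def make_markers(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "allelic_cn"])
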