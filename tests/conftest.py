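import numpy as np
import pytest

from tapermix import (
    FixedParams,
    GeneratorConfig,
    RandomSpec,
    SectionObs,
    TaperDataset,
    TaperMixedModel,
    TreeRecord,
    VarComp,
    default_mixed_config,
    fit_foce,
    generate,
    load_coefficient_set,
)


def make_tree(plot="P1", tree="T1", d=24.0, h=14.0, sections=((1.0, 22.0), (7.0, 15.0))):
    return TreeRecord(
        plot_id=plot, tree_id=tree, d=d, h=h,
        sections=tuple(SectionObs(h_i=a, d_i=b) for a, b in sections),
    )


@pytest.fixture(scope="session")
def mm3_set():
    return load_coefficient_set("asturias-mm3")


@pytest.fixture(scope="session")
def mm3_model(mm3_set):
    return mm3_set.mixed_model()


@pytest.fixture(scope="session")
def ols_set():
    return load_coefficient_set("asturias-ols")


@pytest.fixture(scope="session")
def small_data():
    """A small hierarchical dataset generated under the study conditions."""
    cfg = default_mixed_config(n_plots=10, trees_per_plot=4, seed=1234)
    data, truth = generate(cfg)
    return data, truth, cfg


@pytest.fixture(scope="session")
def small_foce_fit(small_data):
    """One FOCE/REML fit on the small dataset, shared across tests."""
    data, _, cfg = small_data
    return fit_foce(data, cfg.spec, criterion="REML", variance=True, car1=False)
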