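import pytest

import drugrank as dr
from drugrank import io as pio
from drugrank.simulate import PanelSpec


@pytest.fixture(scope="session")
def reference_panel():
    """The canonical 24-line, 24-drug panel with ground truth."""
    return dr.generate_panel(dr.reference_settings())


@pytest.fixture(scope="session")
def small_panel():
    """A reduced panel for fast pipeline-level tests."""
    spec = PanelSpec(n_cell_lines=16, n_replicates=2, n_features=300, n_drugs=8,
                     n_clusters=2, n_sens_markers=12, n_res_markers=12,
                     effect_size=2.0, noise_sd=1.0, missing_rate=0.03, seed=7)
    return dr.generate_panel(spec)


@pytest.fixture(scope="session")
def reference_normalized(reference_panel):
    """Replicate matrix standardized on the cell-line scale, plus line averages."""
    omics, responses, truth = reference_panel
    normed = pio.center_scale_features(omics, stats_from="cell_lines")
    averaged = pio.average_replicates(normed)
    return normed, averaged, responses, truth
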