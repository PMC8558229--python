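import pytest

from xbptargets import io as xio


@pytest.fixture(scope="session")
def panel():
    """Packaged validated panel: (fold_changes, significance, motif_counts)."""
    return xio.load_validated_panel()


@pytest.fixture(scope="session")
def panel_fc(panel):
    return panel[0]


@pytest.fixture(scope="session")
def panel_sig(panel):
    return panel[1]


@pytest.fixture(scope="session")
def panel_motifs(panel):
    return panel[2]
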