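import numpy as np
import pandas as pd
import pytest

from volnet import CouplingSpec, FluxPanel, generate_clean_panel

TOY_GRAPH = """\
[nodes]
C_methanol\tmetabolite\tMethanol
C_formaldehyde\tmetabolite\tFormaldehyde
C_formate\tmetabolite\tFormate
C_tma\tmetabolite\tTrimethylamine
C_dms\tmetabolite\tDimethyl sulfide
G_mdh\tgene\tmethanol dehydrogenase
G_fdh\tgene\tformaldehyde dehydrogenase
G_tdh\tgene\ttrimethylamine dehydrogenase
G_dmo\tgene\tDMS monooxygenase
[edges]
C_methanol\tG_mdh\tR1\tP_methane
G_mdh\tC_formaldehyde\tR1\tP_methane
C_formaldehyde\tG_fdh\tR2\tP_methane
G_fdh\tC_formate\tR2\tP_methane;P_carbon
C_tma\tG_tdh\tR3\tP_methane
G_tdh\tC_formaldehyde\tR3\tP_methane
C_dms\tG_dmo\tR4\tP_sulfur
G_dmo\tC_formaldehyde\tR4\tP_sulfur
[pathways]
P_methane\tMethane metabolism
P_carbon\tCarbon fixation
P_sulfur\tSulfur metabolism
"""

TOY_ANNOTATION = """\
mz\tcompound\tnode_ids\tfragment_of
33.033\tmethanol\tC_methanol\t
31.018\tformaldehyde\tC_formaldehyde\t
47.013\tformate\tC_formate\t
60.081\ttrimethylamine\tC_tma\t
63.026\tdimethyl sulfide\tC_dms\t
99.999\tunknown\t\t
"""


@pytest.fixture
def toy_graph_path(tmp_path):
    p = tmp_path / "kegg_toy.tsv"
    p.write_text(TOY_GRAPH)
    return p


@pytest.fixture
def toy_annotation_path(tmp_path):
    p = tmp_path / "annotation.tsv"
    p.write_text(TOY_ANNOTATION)
    return p


@pytest.fixture
def coupled_spec():
    """Small benchmark: one strong lagged linear coupling, channel 1 -> 3."""
    return CouplingSpec(n_channels=4, duration=2160.0, step=5.0, seed=42,
                        edges=[(1, 3, 2, 1.5, "linear")],
                        pulse_channels=(), noise_sd=0.05)


@pytest.fixture
def coupled_panel(coupled_spec):
    return generate_clean_panel(coupled_spec)


@pytest.fixture
def flat_panel():
    """3-channel independent-noise panel on a 5-min grid."""
    rng = np.random.default_rng(0)
    t = np.arange(300) * 5.0
    df = pd.DataFrame(rng.normal(10, 1, size=(300, 3)), index=t,
                      columns=[31.018, 33.033, 45.033])
    return FluxPanel(df)
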