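import numpy as np
import pandas as pd
import pytest

import redoxtmt as rt


@pytest.fixture
def small_design() -> rt.ChannelDesign:
    """3 samples x (SH, Sox) in one plex run, two conditions."""
    return rt.make_design(("ctrl", "aza"), n_replicates=3)


@pytest.fixture
def toy_reporter_file(tmp_path):
    """Search-engine-dialect export: 5 peptides, one contaminant row and one
    non-Cys row, plus a duplicate peptide key to exercise aggregation."""
    design = rt.make_design(("ctrl",), n_replicates=1)
    channels = [ch for _, ch in design.columns]
    header = ["Accession", "Sequence", "Positions in Proteins",
              "Contaminant"] + channels
    rows = [
        ["P00001", "ACDEFK", "2", "FALSE", "10", "20"],
        ["P00001", "ACDEFK", "2", "FALSE", "5", "5"],      # duplicate key
        ["P00002", "MKLNR", "7", "FALSE", "30", "40"],      # no Cys -> dropped
        ["P00003", "CCGTK", "1;2", "FALSE", "50", "60"],
        ["P00004", "LCAAR", "9", "TRUE", "70", "80"],       # contaminant
    ]
    path = tmp_path / "reporter.tsv"
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    return path, design


def quantify_synthetic(config: rt.SyntheticRedoxConfig, strict: bool = True):
    """Run the simulate -> normalize -> oxidation path, returning
    (oxidation table, design, truth)."""
    table, design, truth = rt.simulate_redox_experiment(config)
    normalized = rt.normalize_channels(table, design)
    ox = rt.compute_oxidation(normalized, design, strict_pair_na=strict)
    return ox, design, truth
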