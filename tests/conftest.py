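import numpy as np
import pandas as pd
import pytest

import sortscreen as ss


@pytest.fixture(scope="session")
def toy_library() -> ss.ShRNALibrary:
    """Three genes x 2 hairpins plus one control, hand-written sequences."""
    rows = [
        ("GA.sh1", "GA", "ACGTACGTACGTACGTACGTA", "druggable"),
        ("GA.sh2", "GA", "TTTTGGGGCCCCAAAATTTTG", "druggable"),
        ("GB.sh1", "GB", "CCCCAAAATTTTGGGGCCCCA", "driver"),
        ("GB.sh2", "GB", "GGGGTTTTAAAACCCCGGGGT", "driver"),
        ("GC.sh1", "GC", "ATATATATATATATATATATA", "druggable"),
        ("GC.sh2", "GC", "GCGCGCGCGCGCGCGCGCGCG", "druggable"),
        ("NC001", "CONTROL", "AACCGGTTAACCGGTTAACCG", "control"),
    ]
    return ss.ShRNALibrary(
        pd.DataFrame(rows, columns=["shrna_id", "gene", "sense_seq",
                                    "category"])
    )


def make_counts(library: ss.ShRNALibrary, data: dict,
                meta: list) -> ss.ScreenCounts:
    m = pd.DataFrame(data, index=library.shrna_ids).astype(np.int64)
    m.index.name = "shrna_id"
    return ss.ScreenCounts(m, meta, library)


@pytest.fixture(scope="session")
def small_screen():
    """A complete simulated screen, shared across read-only tests."""
    cfg = ss.SimConfig(n_genes=120, n_controls=8, coverage=300, seed=42)
    library, truth = ss.simulate_library(cfg)
    counts = ss.simulate_screen(library, truth, cfg)
    return cfg, library, truth, counts
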