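from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spidrokit.synth import (
    gen_counts,
    gen_transcriptome,
    reference_library,
)


@pytest.fixture(scope="session")
def ref_library():
    return reference_library()


@pytest.fixture(scope="session")
def small_transcriptome():
    """15 spidroins, 3 per class, 1% noise, seeded."""
    nts, prots, manifest = gen_transcriptome(
        {"masp1": 3, "masp2": 3, "masp4": 3, "masp5": 3, "other": 3}, seed=11
    )
    return nts, prots, manifest


@pytest.fixture(scope="session")
def small_counts(small_transcriptome) -> pd.DataFrame:
    nts, _, manifest = small_transcriptome
    lengths = {r.id: len(r.residues) for r in nts}
    return pd.concat(
        [
            gen_counts(manifest, lengths, 1_000_000, seed=21, replicate="rep1"),
            gen_counts(manifest, lengths, 1_000_000, seed=22, replicate="rep2"),
        ],
        ignore_index=True,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
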