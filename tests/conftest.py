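import numpy as np
import pytest

from epifit import CountTable, LociPanel, LocusSpec, default_panel, synthetic_reference_orf


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def reference(panel):
    return synthetic_reference_orf(panel)


@pytest.fixture(scope="session")
def toy_panel():
    """Three binary loci: A1V, C2D, E3F (WT allele-ID 'ACE')."""
    return LociPanel(
        loci=(
            LocusSpec(1, "A", frozenset("V")),
            LocusSpec(2, "C", frozenset("D")),
            LocusSpec(3, "E", frozenset("F")),
        )
    )


@pytest.fixture
def toy_table(toy_panel):
    """Dense random counts over all 8 toy alleles at two timepoints."""
    rng = np.random.default_rng(42)
    alleles = [a + b + c for a in "AV" for b in "CD" for c in "EF"]
    counts = {
        "t0": {a: int(n) for a, n in zip(alleles, rng.integers(50, 500, 8))},
        "c1": {a: int(n) for a, n in zip(alleles, rng.integers(50, 500, 8))},
    }
    return CountTable.from_counts(counts, panel=toy_panel)
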