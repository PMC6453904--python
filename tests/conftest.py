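import numpy as np
import pytest

import spermsnc as s


@pytest.fixture(scope="session")
def toy_refset():
    """Small deterministic reference set covering all four classes."""
    return s.build_toy_references(n_trna=8, n_mirna=10, n_pirna=8, seed=42)


@pytest.fixture(scope="session")
def toy_trna():
    """A 76-nt tRNA with the anticodon at positions 33-36 (half-open)."""
    rng = np.random.default_rng(7)
    seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, size=76)))
    seq[33:36] = list("GCC")
    seq[-3:] = list("CCA")
    return s.ReferenceRecord(
        id="tRNA-GlyGCC",
        sequence="".join(seq),
        class_label="tRNA",
        subtype_label="GlyGCC",
        anticodon_interval=(33, 36),
    )


@pytest.fixture()
def smoke_design():
    """Tiny cohort for fast end-to-end paths."""
    return s.CohortDesign(
        n_high=3, n_low=4, depth_range=(3000, 5000), seed=5
    )


@pytest.fixture(scope="session")
def small_cohort(toy_refset):
    """One simulated small cohort with reads, shared across read-level tests."""
    design = s.CohortDesign(n_high=3, n_low=4, depth_range=(8000, 10000), seed=9)
    return design, s.simulate_cohort(toy_refset, design)
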