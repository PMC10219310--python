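import numpy as np
import pytest

from neovax.simulate import CohortSpec, make_cohort
from neovax.variants import PeptideContext


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """3 patients x 6 somatic mutations; fast enough for per-test reuse."""
    return make_cohort(CohortSpec(n_patients=3, n_mutations_per_patient=6, seed=11))


AA = "ACDEFGHIKLMNPQRSTVWY"


def random_context(rng, length=17, mut_position=9, context_len=None) -> PeptideContext:
    """A synthetic paired context of the given (possibly clipped) length."""
    context_len = context_len or length
    wt = "".join(rng.choice(list(AA), size=length))
    off = mut_position - 1 if length >= mut_position else rng.integers(0, length)
    off = int(min(off, length - 1))
    mut_aa = next(a for a in AA if a != wt[off])
    mut = wt[:off] + mut_aa + wt[off + 1 :]
    return PeptideContext(
        context_id=f"ctx{rng.integers(1e6)}",
        wt_window=wt,
        mut_window=mut,
        mut_offset=off,
        wt_aa=wt[off],
        mut_aa=mut_aa,
        context_len=context_len,
        sample_id="P01",
        vaf=0.5,
    )


@pytest.fixture
def make_context(rng):
    def _make(length=17, mut_position=9, mut_offset=None, context_len=None):
        if mut_offset is not None:
            return random_context(rng, length, mut_offset + 1, context_len)
        return random_context(rng, length, mut_position, context_len)

    return _make
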