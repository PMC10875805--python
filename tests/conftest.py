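import numpy as np
import pytest

from kinamotif import motif, synthetic
from kinamotif.seqio import CenteredPeptide


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240219)


@pytest.fixture(scope="session")
def small_benchmark():
    """3 preset kinases x 30 sites each, spliced into host proteins."""
    return synthetic.make_benchmark(k=3, n_per_kinase=30, seed=11)


@pytest.fixture(scope="session")
def basophilic_profile():
    """Profile fitted from 200 basophilic-PWM peptides, uniform background."""
    pwm = synthetic.preset_pwm("basophilic", sharpness=0.9)
    peptides = synthetic.sample_peptides(pwm, 200, seed=5)
    return motif.build_profile("PKAlike", peptides,
                               background=motif.Background.uniform())


def random_peptide(rng, n_j_prefix=0, n_j_suffix=0, center="S"):
    """A valid random CenteredPeptide with optional J overhangs."""
    from kinamotif._alphabet import AMINO_ACIDS
    chars = [AMINO_ACIDS[i] for i in rng.integers(20, size=13)]
    chars[6] = center
    for i in range(n_j_prefix):
        chars[i] = "J"
    for i in range(n_j_suffix):
        chars[12 - i] = "J"
    return CenteredPeptide("".join(chars))
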