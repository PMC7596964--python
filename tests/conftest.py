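import numpy as np
import pytest

from dcfs.simulate import SimSpec, generate
from dcfs.variants import Consequence, Region, VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20201030)


@pytest.fixture
def planted_cohort():
    """Small cohort with 2 positive- and 2 negative-associated features."""
    spec = SimSpec(
        n_samples=200,
        n_features=30,
        n_pos_assoc=2,
        n_neg_assoc=2,
        effect=0.6,
        background_rate=0.1,
        seed=7,
    )
    return generate(spec)


def make_record(**overrides) -> VariantRecord:
    """A record that survives all three filter steps unless overridden."""
    kwargs = dict(
        sample_id="s0",
        chrom="1",
        pos=1000,
        ref="A",
        alt="T",
        gene="GENE1",
        region=Region.EXONIC,
        consequence=Consequence.NONSYNONYMOUS,
        in_gnomad=False,
        in_esp6500=False,
        in_exac=False,
        in_cosmic=False,
        tumor_freq=60.0,
        normal_freq=0.0,
        fisher_p=0.001,
    )
    kwargs.update(overrides)
    return VariantRecord(**kwargs)
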