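import warnings

import pytest

from ownbias.models import ModelSpec, build_design
from ownbias.synth import generate_experiment, recovery_config

# hierarchical fits at desk scale legitimately trip the split-R-hat warning now
# and then; tests assert on recovered values, not on warning silence
warnings.filterwarnings("ignore", message="split-R-hat")


@pytest.fixture(scope="session")
def small_cohort():
    """Six single-condition subjects x 160 trials generated at z = 0.55."""
    cfg = recovery_config(n_subjects=6, z=0.55, seed=3, blocks=2)
    trials, truth = generate_experiment(cfg)
    return trials, truth


@pytest.fixture(scope="session")
def m2_posterior(small_cohort):
    """An M2 fit of the small cohort, shared across evaluation tests."""
    from ownbias.inference import sample_posterior

    trials, _ = small_cohort
    design = build_design(trials, ModelSpec.from_variant("M2"))
    return sample_posterior(design, n_samples=800, n_burn=300, seed=1)
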