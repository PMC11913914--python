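import numpy as np
import pytest

from ennseg.ensemble import EnsembleConfig, train_ensemble
from ennseg.io import MaskSlice
from ennseg.phantom import PhantomCohort, PhantomParams, generate_cohort
from ennseg.pipeline import cohort_slice_pairs, split_cohort


@pytest.fixture(scope="session")
def small_cohort() -> PhantomCohort:
    """A small two-phase phantom cohort reused across read-only tests."""
    return generate_cohort(PhantomParams(n_patients=6, phases=2, seed=42))


@pytest.fixture(scope="session")
def blob_mask() -> MaskSlice:
    """A single off-center elliptical reference mask on a 64x64 grid."""
    yy, xx = np.mgrid[0:64, 0:64]
    mask = ((yy - 30) / 9.0) ** 2 + ((xx - 26) / 7.0) ** 2 <= 1.0
    return MaskSlice(mask=mask, slice_index=0, patient_id="P0000")


@pytest.fixture(scope="session")
def tiny_trained(small_cohort):
    """A deliberately small trained ensemble (2 members, 8 epochs) plus its
    data splits; shared session-wide because training dominates runtime."""
    split = split_cohort(small_cohort, seed=3)
    train_pairs = cohort_slice_pairs(small_cohort, split.train)
    val_pairs = cohort_slice_pairs(small_cohort, split.validation)
    holdout_pairs = cohort_slice_pairs(small_cohort, split.holdout)
    config = EnsembleConfig(n_members=2, epochs=8, channels=6, base_seed=7)
    model = train_ensemble(train_pairs, val_pairs, config)
    return {
        "model": model,
        "config": config,
        "split": split,
        "train_pairs": train_pairs,
        "val_pairs": val_pairs,
        "holdout_pairs": holdout_pairs,
        "cohort": small_cohort,
    }
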