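import numpy as np
import pytest

from contourqa.data import SliceSample, StructureCatalogue, acceptable_pools
from contourqa.model import ContourQualityNet, ModelConfig
from contourqa.phantom import PhantomConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def square_mask(size: int, top: int, left: int, side: int) -> np.ndarray:
    m = np.zeros((size, size), dtype=np.uint8)
    m[top:top + side, left:left + side] = 1
    return m


def ellipse_mask(size: int, cy: float, cx: float, ay: float, ax: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0).astype(np.uint8)


def random_blob_masks(n: int, size: int = 48, seed: int = 0) -> list[np.ndarray]:
    """Random interior ellipse masks (>=2 px from every border)."""
    rng = np.random.default_rng(seed)
    masks = []
    while len(masks) < n:
        ay, ax = rng.uniform(3, min(9, size / 2 - 4), size=2)
        margin = max(ay, ax) + 3
        cy = rng.uniform(margin, size - 1 - margin)
        cx = rng.uniform(margin, size - 1 - margin)
        m = ellipse_mask(size, cy, cx, ay, ax)
        if m.sum() >= 9:
            masks.append(m)
    return masks


@pytest.fixture(scope="session")
def tiny_cohort():
    """8/2/2-patient phantom cohort with 2 slices per patient."""
    config = PhantomConfig(slices_per_patient=(2, 2), seed=99)
    train, val, test = generate_cohort(config, 8, 2, 2)
    catalogue = StructureCatalogue(names=config.structure_names)
    return config, catalogue, train, val, test


@pytest.fixture(scope="session")
def tiny_pools(tiny_cohort):
    config, catalogue, train, val, test = tiny_cohort
    return {
        "catalogue": catalogue,
        "train": acceptable_pools(train, catalogue),
        "val": acceptable_pools(val, catalogue),
        "test": acceptable_pools(test, catalogue),
    }


@pytest.fixture(scope="session")
def untrained_model():
    config = ModelConfig(structure_code_length=3, image_size=64)
    return ContourQualityNet(config, rng=np.random.default_rng(7))


@pytest.fixture
def one_sample(tiny_pools):
    return tiny_pools["train"]["bladder_like"][0]


def make_sample(mask: np.ndarray, structure: str = "a", code_index: int = 0,
                n_codes: int = 2, label: int = 0, perturbation=None,
                patient_id: str = "p0", slice_index: int = 0) -> SliceSample:
    code = np.zeros(n_codes)
    code[code_index] = 1.0
    return SliceSample(
        image=mask.astype(np.float64) * 0.5 + 0.25,
        mask=mask,
        structure=structure,
        structure_code=code,
        label=label,
        patient_id=patient_id,
        slice_index=slice_index,
        perturbation=perturbation,
    )
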