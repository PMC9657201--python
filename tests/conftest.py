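import numpy as np
import pytest

import silhofm as sf
from silhofm.geometry import FEATURE_ORDER, FeatureVector, features_from_mask


@pytest.fixture(scope="session")
def cohort20():
    """Small mixed cohort shared across tests (deterministic)."""
    return sf.sample_cohort(20, 0.5, seed=101)


@pytest.fixture(scope="session")
def rendered_subject(cohort20):
    """One female subject rendered at 2 MP with its ground truth."""
    params = cohort20[0]
    spec = sf.RenderSpec.for_megapixels(2.0)
    img, gt = sf.render_silhouette(params, spec)
    return params, spec, img, gt


def make_feature_vectors(n, gender, seed=0):
    """Plausible random feature vectors for model-level tests (no rendering)."""
    rng = np.random.default_rng(seed)
    fvs = []
    for _ in range(n):
        fvs.append(
            FeatureVector(
                occupancy_ratio=float(rng.uniform(0.2, 0.5)),
                width_chest=float(rng.uniform(0.10, 0.20)),
                width_belly=float(rng.uniform(0.08, 0.22)),
                width_thigh=float(rng.uniform(0.06, 0.12)),
                width_calf=float(rng.uniform(0.04, 0.09)),
                span_px=1300,
                gender=gender,
                stature_cm=float(rng.uniform(150, 190)),
            )
        )
    return fvs


def feature_matrix(fvs):
    return np.vstack([fv.as_array() for fv in fvs])


def render_features(params, megapixels=0.5, jitter=0.0, seed=0, config=None):
    """Render one body and run the full measurement path on it."""
    from silhofm.geometry import GeometryConfig

    spec = sf.RenderSpec.for_megapixels(megapixels, pose_jitter=jitter, seed=seed)
    img, gt = sf.render_silhouette(params, spec)
    fv = features_from_mask(img > 128, params.gender, params.stature,
                            config or GeometryConfig())
    return img, gt, fv
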