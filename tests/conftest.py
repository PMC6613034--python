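import numpy as np
import pytest

from virtdes import (PhantomParams, PipelineConfig, build_database,
                     generate_phantom_database)
from virtdes.config import GridMatchConfig
from virtdes import imgio


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def textured_pair():
    """Two crops of one textured phantom (ground-truth shift (8, 4)):
    projected descriptor fields and word maps, for matching tests."""
    from virtdes.descriptors import (build_filter_bank,
                                     compute_dense_descriptors,
                                     fit_descriptor_pca, project_descriptors,
                                     sample_vectors)
    from virtdes.preprocess import default_radius, normalize_radiograph
    from virtdes.retrieval import fit_codebook, quantize_field
    from virtdes.phantom import generate_phantom_triplet

    trip = generate_phantom_triplet(
        PhantomParams(image_size=192, noise_sigma=0.02, seed=6))
    dyn = trip.Y.max() - trip.Y.min()
    Y_n, _ = normalize_radiograph(trip.Y, default_radius(192),
                                  (0.2 * dyn) ** 2)
    src = Y_n[8:136, 4:132]      # src pixel (y,x) = tgt pixel (y+8,x+4)
    tgt = Y_n[0:128, 0:128]
    bank = build_filter_bank()
    fs = compute_dense_descriptors(src, bank=bank)
    ft = compute_dense_descriptors(tgt, bank=bank)
    r = np.random.default_rng(0)
    samp = np.vstack([sample_vectors(fs, 800, r),
                      sample_vectors(ft, 800, r)])
    pca = fit_descriptor_pca(samp, 32)
    fs = project_descriptors(fs, pca)
    ft = project_descriptors(ft, pca)
    cb = fit_codebook((samp - pca.mean_vector) @ pca.basis, 32, seed=0)
    return fs, quantize_field(fs, cb), ft, quantize_field(ft, cb)


@pytest.fixture(scope="session")
def small_db(tmp_path_factory):
    """A small prepared phantom database (8 cases, 128 px, K = 64) shared
    by pipeline-level tests."""
    d = tmp_path_factory.mktemp("smalldb")
    trips = generate_phantom_database(
        8, PhantomParams(image_size=128), 0.2, seed=7)
    imgio.save_database(trips, str(d))
    cfg = PipelineConfig(codebook_size=64, seed=7,
                         match=GridMatchConfig(seed=7))
    db = build_database(str(d), cfg)
    return db, trips
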