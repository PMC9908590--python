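import numpy as np
import pytest

from pnkit import synthetic as syn


@pytest.fixture(scope="session")
def tree():
    return syn.default_terminology()


@pytest.fixture(scope="session")
def synth_config():
    return syn.SynthConfig(seed=7, image_size=512)


@pytest.fixture(scope="session")
def sample_doc(tree, synth_config):
    """One fine-grain adenocarcinoma document with bundles."""
    return syn.generate_annotation(synth_config, "wsi-sample", "c-adenocarcinoma", tree)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, synth_config):
    """A full synthetic cohort written to disk once per session."""
    out = tmp_path_factory.mktemp("cohort")
    gt = syn.generate_cohort(synth_config, out)
    return out, gt


def make_stain_image(rng, h_vec, e_vec, n=20000, cmax=(1.2, 1.0), shape=(100, 200)):
    """RGB image mixed from two known unit stain vectors in OD space."""
    h_vec = h_vec / np.linalg.norm(h_vec)
    e_vec = e_vec / np.linalg.norm(e_vec)
    ch = rng.uniform(0.0, cmax[0], n)
    ce = rng.uniform(0.0, cmax[1], n)
    od = np.outer(ch, h_vec) + np.outer(ce, e_vec)
    img = np.clip(np.round(255 * 10 ** (-od) - 1), 0, 255).astype(np.uint8)
    return img.reshape(*shape, 3)
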