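"""Shared fixtures: synthetic datasets and a trained tiny model.

Everything is generated at test time from fixed seeds; nothing is read
from disk fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from svbdete.harness import tiny_train_config, train
from svbdete.synthsection import easy_config, write_dataset


@pytest.fixture(scope="session")
def easy_dataset(tmp_path_factory):
    """120 easy 64px scenes split 100/20 (train/val)."""
    root = tmp_path_factory.mktemp("easy_ds")
    manifest = write_dataset(120, easy_config(image_size=64, seed=7), root,
                             ratios=(100, 20, 0))
    return manifest


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """16 easy scenes for fast smoke runs (12 train / 2 val / 2 test)."""
    root = tmp_path_factory.mktemp("small_ds")
    manifest = write_dataset(16, easy_config(image_size=64, seed=11), root,
                             ratios=(12, 2, 2))
    return manifest


@pytest.fixture(scope="session")
def tiny_run(easy_dataset, tmp_path_factory):
    """The scaled-down end-to-end run: tiny model, easy preset, PIoU loss.

    Trains once per session and returns (record, checkpoint_path, config).
    """
    out = tmp_path_factory.mktemp("tiny_run")
    cfg = tiny_train_config(seed=1)
    record = train(cfg, easy_dataset, out_dir=out)
    return record, out / "model.npz", cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
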