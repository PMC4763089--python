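import numpy as np
import pytest

from rheopipe.config import FlowConfig, LarvaModel, PipelineConfig, SegmentationParams
from rheopipe import segmentation as seg
from rheopipe import synthdata as sd


@pytest.fixture(scope="session")
def flow():
    return FlowConfig()


@pytest.fixture(scope="session")
def larva():
    return LarvaModel()


@pytest.fixture(scope="session")
def seg_params():
    return SegmentationParams()


@pytest.fixture(scope="session")
def pipe_cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def empty_background(flow):
    return np.zeros(flow.shape, dtype=np.float32)


@pytest.fixture(scope="session")
def render_and_measure(flow, larva, seg_params, empty_background):
    """Render a single noiseless pose and measure it back through
    segmentation and posture.  Returns (blob, pose)."""
    from rheopipe.posture import pose_from_blob

    def _do(x, y, heading, kappa, config=None):
        cfg = config or flow
        canvas = np.zeros(cfg.shape, dtype=np.float32)
        sd.render_pose(canvas, np.array([x, y]), heading, kappa, larva, cfg)
        bg = empty_background if cfg is flow else np.zeros(cfg.shape, np.float32)
        blobs = seg.segment_frame(canvas, bg, seg_params, cfg.pixel_size)
        assert len(blobs) == 1, f"expected one blob, got {len(blobs)}"
        return blobs[0], pose_from_blob(blobs[0], cfg, t=0.0)

    return _do
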