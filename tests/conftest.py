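import numpy as np
import pytest

from fallflow.gloria_core import MotionParameters
from fallflow.synthetic_scenes import SyntheticSceneSpec


def scene_spec(seed=7, size=64, n_channels=1, schedule=None, **kw):
    if schedule is None:
        schedule = [MotionParameters(a=[0.5, 0, 0, 0, 0, 0])]
    return SyntheticSceneSpec(
        width=size,
        height=size,
        n_channels=n_channels,
        texture_seed=seed,
        schedule=schedule,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def texture64():
    from fallflow.synthetic_scenes import render_texture

    return render_texture(scene_spec(seed=7))


def stitch_schedule(windows):
    """Concatenate motion windows into a per-step parameter schedule."""
    vals = np.concatenate([w.values for w in windows], axis=1)  # 6 x T
    return [MotionParameters(a=vals[:, t]) for t in range(vals.shape[1])]


def detect_scenario(
    tmp_path,
    window_length=32,
    n_train=60,
    size=64,
    seed=0,
    max_epochs=8,
    architecture="cnn",
    transient_window=1,
    n_video_windows=3,
):
    """Build a trained model + synthetic fall video sharing one generative
    process: feature-space windows for training, and a rendered video whose
    ground-truth schedule is a stitched sequence of windows with a single
    fall transient in ``transient_window``.

    Returns (model_path, video_dir, config, expected_start_frame).
    """
    from fallflow.cli_pipeline import PipelineConfig, cmd_train
    from fallflow.fall_classifier import ClassifierConfig, ConvBlockSpec
    from fallflow.synthetic_scenes import (
        MotionDatasetSpec,
        TransientSpec,
        export_frames_png,
        export_windows_csv,
        render_sequence,
        simulate_motion_dataset,
    )

    # background amplitude small enough that warp displacements stay in the
    # linear regime the solver assumes (transient peak = 10x background)
    ds = dict(
        window_length=window_length,
        background_amplitude=0.05,
        fall_transient=TransientSpec(amplitude=10.0, duration=min(8, window_length // 4)),
    )
    train_windows, _ = simulate_motion_dataset(
        MotionDatasetSpec(n_windows=n_train, fall_fraction=0.5, seed=seed, **ds)
    )
    csv_path = tmp_path / "train_windows.csv"
    export_windows_csv(train_windows, csv_path)

    if window_length >= 64:
        blocks = [ConvBlockSpec(16, 7, 2), ConvBlockSpec(32, 5, 2), ConvBlockSpec(64, 3, 0)]
        dense, lstm, third = 64, 64, True
    else:
        blocks = [ConvBlockSpec(8, 5, 2), ConvBlockSpec(16, 3, 2)]
        dense, lstm, third = 16, 8, False
    config = PipelineConfig(
        window_length=window_length,
        seed=seed,
        classifier=ClassifierConfig(
            architecture=architecture,
            window_length=window_length,
            conv_blocks=blocks,
            use_third_block=third,
            dense_units=dense,
            lstm_units=lstm,
            max_epochs=max_epochs,
            seed=seed,
        ),
    )
    model_path = tmp_path / "model.npz"
    cmd_train(csv_path, config, model_out=model_path)

    # video: stitched windows, exactly one positive
    pieces, _ = simulate_motion_dataset(
        MotionDatasetSpec(n_windows=n_video_windows, fall_fraction=0.0, seed=seed + 1, **ds)
    )
    positive, _ = simulate_motion_dataset(
        MotionDatasetSpec(n_windows=2, fall_fraction=1.0, seed=seed + 2, **ds)
    )
    pieces[transient_window] = positive[0]
    schedule = stitch_schedule(pieces)
    frames, _ = render_sequence(
        scene_spec(seed=seed + 3, size=size, schedule=schedule)
    )
    video_dir = tmp_path / "video"
    export_frames_png(frames, video_dir)
    return model_path, video_dir, config, transient_window * window_length
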