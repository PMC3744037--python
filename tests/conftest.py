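import numpy as np
import pytest
from hypothesis import settings

from lymphnir import AnalysisConfig, FrameStack, IntensityTrace, Roi

settings.register_profile("repro", derandomize=True, database=None, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


def make_trace(values, dt_s=0.5, background_mean=0.0, background_sd=1.0,
               label="trace", t0_s=0.0, axial_mm=None) -> IntensityTrace:
    values = np.asarray(values, dtype=float)
    return IntensityTrace(
        roi_label=label,
        times_s=t0_s + np.arange(values.size) * dt_s,
        values=values,
        background_mean=background_mean,
        background_sd=background_sd,
        axial_mm=axial_mm,
    )


def gaussian_pulse_trace(pulse_times_s, duration_s=30.0, dt_s=0.05, amplitude=10.0,
                         width_s=0.3, background_sd=0.1, axial_mm=None) -> IntensityTrace:
    t = np.arange(int(round(duration_s / dt_s))) * dt_s
    v = np.zeros_like(t)
    for tk in pulse_times_s:
        v += amplitude * np.exp(-((t - tk) ** 2) / (2 * width_s**2))
    return IntensityTrace(roi_label="synthetic", times_s=t, values=v,
                          background_mean=0.0, background_sd=background_sd,
                          axial_mm=axial_mm)


def uniform_stack(value=7.0, t=5, h=12, w=16, dt_s=0.5) -> FrameStack:
    return FrameStack(frames=np.full((t, h, w), float(value), dtype=np.float32),
                      frame_interval_s=dt_s, pixel_size_mm=0.1)


@pytest.fixture
def vessel_roi() -> Roi:
    return Roi(label="vessel", purpose="vessel", kind="rect", x=2, y=2, width=10, height=4)


@pytest.fixture
def background_roi() -> Roi:
    return Roi(label="bg", purpose="background", kind="rect", x=2, y=8, width=10, height=3)
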