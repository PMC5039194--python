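"""Readers/writers for the pipeline's interchange formats.

Images and masks travel as PNG (TIFF also accepted on read), tables as CSV,
configuration and palettes as YAML.  Fluorescence traces use a three-column
CSV dialect — time_s, signal, event — where ``event`` labels the samples
belonging to a protocol window (FoWin, FmPulse, L1…L4, Lss, D1…D3) and is
empty elsewhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import imageio.v3 as iio

from .chlf import FluorTrace, in_window
from .rgb import RosetteMask


def save_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, np.uint8))


def load_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[..., :3]
    return img


def save_mask(path, mask) -> None:
    m = np.asarray(getattr(mask, "mask", mask), bool)
    iio.imwrite(path, (m * np.uint8(255)))


def load_mask(path, plant_id: str = "", day: int = 0) -> RosetteMask:
    return RosetteMask(iio.imread(path) > 127, plant_id=plant_id, day=day)


def trace_to_frame(trace: FluorTrace) -> pd.DataFrame:
    event = np.full(len(trace.time_s), "", dtype=object)
    for name, (t0, t1) in trace.events.items():
        event[in_window(trace.time_s, t0, t1)] = name
    return pd.DataFrame({"time_s": trace.time_s, "signal": trace.signal, "event": event})


def save_trace_csv(path, trace: FluorTrace) -> None:
    trace_to_frame(trace).to_csv(path, index=False, float_format="%.10g")


def load_trace_csv(path, plant_id: str = "", day: int = 0) -> FluorTrace:
    df = pd.read_csv(path, keep_default_na=False)
    t = df["time_s"].to_numpy(float)
    dt = float(np.median(np.diff(t)))
    events = {}
    for name, grp in df[df["event"] != ""].groupby("event"):
        tt = grp["time_s"].to_numpy(float)
        events[str(name)] = (float(tt.min()), float(tt.max()) + dt)
    return FluorTrace(time_s=t, signal=df["signal"].to_numpy(float), events=events,
                      plant_id=plant_id, day=day)
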