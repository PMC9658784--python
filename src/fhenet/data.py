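"""Seeded synthetic datasets and the label+pixel CSV reader.

Two generators stand in for the datasets the networks were designed around:

* :func:`gen_toy_images` — small images built from geometric prototypes plus
  Gaussian noise, a desk-scale stand-in for clothing-image classification.
* :func:`gen_yield_series` — environmental time-series windows (temperature,
  humidity, light, wind, precipitation, soil state, irrigation) with a
  positive yield response, emulating polytunnel strawberry yield forecasting
  at horizons of 7/14/21 days.  The latent yield mapping is fixed and
  documented so it doubles as a parameter-recovery oracle.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = [
    "ImageDataset",
    "YieldSeriesDataset",
    "gen_toy_images",
    "gen_yield_series",
    "read_label_pixel_csv",
    "split_train_test",
    "PROTOTYPE_NAMES",
    "latent_yield",
]


@dataclass
class ImageDataset:
    """Images normalised to [0, 1] with integer class labels."""

    images: np.ndarray  # (n, H, W)
    labels: np.ndarray  # (n,)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "ImageDataset":
        idx = np.asarray(idx)
        return ImageDataset(self.images[idx], self.labels[idx])


@dataclass
class YieldSeriesDataset:
    """Environmental feature windows with a positive yield target.

    ``windows`` is (n, T_x, F) with standardised numeric features and raw
    0/1 one-hot or binary columns; ``targets`` are strictly positive yields;
    ``horizon`` is the days-ahead gap between the window end and the yield.
    """

    windows: np.ndarray      # (n, T_x, F)
    targets: np.ndarray      # (n,)
    horizon: int
    feature_names: list[str] = field(default_factory=list)
    timestamps: np.ndarray | None = None  # window end day, for time splits

    def __len__(self) -> int:
        return len(self.targets)

    def subset(self, idx) -> "YieldSeriesDataset":
        idx = np.asarray(idx)
        ts = None if self.timestamps is None else self.timestamps[idx]
        return YieldSeriesDataset(self.windows[idx], self.targets[idx],
                                  self.horizon, list(self.feature_names), ts)


# ---------------------------------------------------------------------------
# Toy images
# ---------------------------------------------------------------------------

def _proto_hbar(H, W):
    img = np.zeros((H, W))
    img[H // 2 - max(H // 8, 1):H // 2 + max(H // 8, 1), :] = 1.0
    return img


def _proto_vbar(H, W):
    return _proto_hbar(W, H).T


def _proto_cross(H, W):
    return np.clip(_proto_hbar(H, W) + _proto_vbar(H, W), 0, 1)


def _proto_diag(H, W):
    img = np.zeros((H, W))
    for i in range(H):
        j = int(round(i * (W - 1) / max(H - 1, 1)))
        img[i, max(j - 1, 0):min(j + 2, W)] = 1.0
    return img


def _proto_block(H, W):
    img = np.zeros((H, W))
    img[H // 4:H - H // 4, W // 4:W - W // 4] = 1.0
    return img


def _proto_ring(H, W):
    img = np.zeros((H, W))
    img[1:-1, 1:-1] = 1.0
    img[2:-2, 2:-2] = 0.0
    return img


def _proto_checker(H, W):
    yy, xx = np.mgrid[0:H, 0:W]
    return (((yy // 2) + (xx // 2)) % 2).astype(float)


def _proto_corner(H, W):
    img = np.zeros((H, W))
    img[:H // 2, :W // 2] = 1.0
    return img


_PROTOTYPES = [
    ("hbar", _proto_hbar), ("vbar", _proto_vbar), ("cross", _proto_cross),
    ("diag", _proto_diag), ("block", _proto_block), ("ring", _proto_ring),
    ("checker", _proto_checker), ("corner", _proto_corner),
]

PROTOTYPE_NAMES = [name for name, _ in _PROTOTYPES]


def prototype_images(shape: Sequence[int], K: int) -> np.ndarray:
    """The K noiseless class prototypes for the given image shape."""
    H, W = shape
    if K > len(_PROTOTYPES):
        raise ValueError(
            f"at most {len(_PROTOTYPES)} distinct prototypes are available, "
            f"requested {K}")
    return np.stack([fn(H, W) for _, fn in _PROTOTYPES[:K]])


def gen_toy_images(n: int, shape: Sequence[int] = (8, 8), K: int = 2,
                   noise_sd: float = 0.1, seed: int | None = 0
                   ) -> ImageDataset:
    """Geometric-prototype images with Gaussian noise, clipped to [0, 1].

    Class counts are balanced to within one example; the default 8x8 size
    keeps encrypted runs desk-scale.
    """
    rng = np.random.default_rng(seed)
    protos = prototype_images(shape, K)
    labels = np.arange(n) % K
    rng.shuffle(labels)
    images = protos[labels] + rng.normal(0.0, noise_sd, (n,) + tuple(shape))
    if noise_sd > 0:
        images = np.clip(images, 0.0, 1.0)
    return ImageDataset(images.astype(np.float64), labels.astype(np.int64))


# ---------------------------------------------------------------------------
# Yield series
# ---------------------------------------------------------------------------

FEATURE_NAMES = [
    "temperature", "humidity", "light", "wind_speed",
    "precipitation", "soil_moisture", "soil_temperature",
    "wind_dir_N", "wind_dir_E", "wind_dir_S", "wind_dir_W",
    "irrigation_status",
]

#: indices of the standardised numeric features (one-hot/binary stay 0/1)
_NUMERIC = slice(0, 7)

# latent yield response constants (also the recovery-oracle ground truth)
_Y_MEAN = 1.2        # tonnes/row-equivalent scale of the mean yield
_Y_SPREAD = 0.18     # relative spread driven by the environment
_W_GDD = 0.9
_W_LIGHT = 0.6
_W_STRESS = -0.5
_W_IRRIG = 0.2


def latent_yield(gdd_z: np.ndarray, light_z: np.ndarray,
                 stress_z: np.ndarray, irrig_z: np.ndarray) -> np.ndarray:
    """Noiseless yield response to standardised window aggregates.

    A saturating (tanh) response of the mean yield to accumulated degree-days
    and light minus heat/drought stress, plus a small irrigation bonus.
    """
    z = (_W_GDD * gdd_z + _W_LIGHT * light_z
         + _W_STRESS * stress_z + _W_IRRIG * irrig_z)
    return _Y_MEAN * (1.0 + _Y_SPREAD * np.tanh(z))


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def gen_yield_series(n: int, T_x: int = 14, horizon: int = 7,
                     noise_sd: float = 0.05, seed: int | None = 0
                     ) -> YieldSeriesDataset:
    """Synthetic environmental windows with a yield response.

    Smooth latent weather processes (seasonal trend + AR(1) wobble) drive
    twelve daily features over non-overlapping windows of ``T_x`` days; the
    yield realised ``horizon`` days after each window end is a saturating
    function of the window's degree-day and light accumulations minus heat
    and drought stress, with multiplicative noise whose standard deviation
    grows as sqrt(horizon/7) — longer horizons are genuinely harder.
    """
    if T_x < 2:
        raise ValueError("windows need at least two timesteps")
    if horizon not in (7, 14, 21):
        raise ValueError("prediction horizon must be 7, 14 or 21 days")
    rng = np.random.default_rng(seed)
    days = n * T_x
    t = np.arange(days)

    season = np.sin(2 * np.pi * t / 120.0)
    def ar1(scale, rho=0.85):
        eps = rng.normal(0.0, scale, days)
        out = np.empty(days)
        acc = 0.0
        for i in range(days):
            acc = rho * acc + eps[i]
            out[i] = acc
        return out

    temperature = 16.0 + 7.0 * season + ar1(1.2)
    light = np.clip(18.0 + 9.0 * season + ar1(2.0), 0.0, None)
    humidity = np.clip(70.0 - 0.8 * (temperature - 16.0) + ar1(2.5), 20, 100)
    wind_speed = np.clip(4.0 + ar1(1.0), 0.0, None)
    wind_angle = (ar1(0.4).cumsum() / 3.0) % (2 * np.pi)
    precipitation = np.where(rng.random(days) < 0.25,
                             rng.exponential(3.0, days), 0.0)
    soil_moisture = np.empty(days)
    irrigation = np.zeros(days)
    sm = 0.30
    for i in range(days):
        sm = np.clip(sm + 0.01 * precipitation[i]
                     - 0.004 * max(temperature[i] - 10.0, 0.0), 0.05, 0.45)
        if sm < 0.18:
            irrigation[i] = 1.0
            sm += 0.08
        soil_moisture[i] = sm
    soil_temperature = 0.8 * temperature + 3.0 + ar1(0.3)
    sector = ((wind_angle / (np.pi / 2)).astype(int)) % 4
    wind_onehot = np.eye(4)[sector]

    features = np.column_stack([
        temperature, humidity, light, wind_speed, precipitation,
        soil_moisture, soil_temperature,
    ])
    features = np.apply_along_axis(_standardise, 0, features)
    features = np.column_stack([features, wind_onehot, irrigation])

    windows = features.reshape(n, T_x, features.shape[1])
    temp_w = temperature.reshape(n, T_x)
    light_w = light.reshape(n, T_x)
    soil_w = soil_moisture.reshape(n, T_x)
    irr_w = irrigation.reshape(n, T_x)

    gdd = np.maximum(temp_w - 8.0, 0.0).mean(axis=1)
    light_acc = light_w.mean(axis=1)
    stress = (np.maximum(temp_w - 26.0, 0.0).mean(axis=1)
              + 10.0 * np.maximum(0.20 - soil_w, 0.0).mean(axis=1))
    irr = irr_w.mean(axis=1)

    clean = latent_yield(_standardise(gdd), _standardise(light_acc),
                         _standardise(stress), _standardise(irr))
    sd = noise_sd * np.sqrt(horizon / 7.0)
    targets = np.clip(clean * (1.0 + rng.normal(0.0, sd, n)), 0.05, None)

    timestamps = (np.arange(n) + 1) * T_x + horizon
    return YieldSeriesDataset(
        windows=windows.astype(np.float64),
        targets=targets.astype(np.float64),
        horizon=horizon,
        feature_names=list(FEATURE_NAMES),
        timestamps=timestamps,
    )


# ---------------------------------------------------------------------------
# CSV dialect reader and splitting
# ---------------------------------------------------------------------------

def read_label_pixel_csv(path) -> ImageDataset:
    """Read the label + pixel-columns CSV dialect (values 0-255).

    Each row holds a class label followed by H*W pixel intensities; pixels
    are normalised to [0, 1] and reshaped to the square image they came from.
    """
    try:
        first = pd.read_csv(path, nrows=1, header=None)
        header = 0 if first.apply(
            lambda col: col.map(lambda v: isinstance(v, str))).any().any() \
            else None
        df = pd.read_csv(path, header=header)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"malformed label+pixel CSV: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError("expected a label column plus pixel columns")
    side = int(round(np.sqrt(df.shape[1] - 1)))
    if side * side != df.shape[1] - 1:
        raise ParseError(
            f"{df.shape[1] - 1} pixel columns do not form a square image")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1).to_numpy()
    if bad.any():
        raise ParseError(
            f"non-numeric or missing values in row {int(np.argmax(bad))}")
    arr = num.to_numpy(dtype=np.float64)
    if arr[:, 1:].min() < 0 or arr[:, 1:].max() > 255:
        raise ParseError("pixel values must lie in 0-255")
    images = (arr[:, 1:] / 255.0).reshape(-1, side, side)
    labels = arr[:, 0].astype(np.int64)
    return ImageDataset(images, labels)


def split_train_test(dataset, fraction: float = 0.8,
                     seed: int | None = None, time_blocked: bool = False):
    """Disjoint, exhaustive, seeded train/test split (default 80-20 random).

    ``time_blocked`` sorts series windows by timestamp and keeps the test
    block strictly later than every training window — the split a forecaster
    should prefer, since random splits let training windows neighbour test
    windows in time.
    """
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least two examples to split")
    n_train = int(round(n * fraction))
    n_train = min(max(n_train, 1), n - 1)
    if time_blocked:
        ts = getattr(dataset, "timestamps", None)
        if ts is None:
            raise ValueError("time-blocked split needs timestamps")
        order = np.argsort(ts, kind="stable")
    else:
        order = np.random.default_rng(seed).permutation(n)
    return dataset.subset(order[:n_train]), dataset.subset(order[n_train:])
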