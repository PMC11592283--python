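"""Entry/exit keypoint detection with a stacked-hourglass 3D network.

Keypoints (screw entry and exit per pedicle) are supervised as Gaussian
heatmaps and read out as heatmap maxima.  The network stacks two symmetric
hourglass modules; each has a four-module downsampling path and a
four-module upsampling path, every module being three groups of
[conv 3³ → batch-norm → ReLU] with a residual connection added to the third
group.  Each stack emits one non-negative heatmap per keypoint and receives
intermediate supervision; the final stack's heatmaps are the prediction.

Heatmaps live on a grid downsampled 2x from the input (a convolutional stem
pools once); peak extraction can optionally refine the argmax with a 3³
center-of-mass for sub-voxel precision.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from pedplan.errors import ValidationError
from pedplan.imaging import Volume, to_physical, to_voxel
from pedplan.keypoints import KeypointPair, KeypointSet
from pedplan.nn import Adam, BatchNorm3d, Conv3d, ConvTranspose3d, Module, Tensor, core

__all__ = [
    "KeypointNetConfig",
    "HeatmapStack",
    "KeypointSet",
    "StackedHourglass",
    "build_hourglass",
    "heatmap_target",
    "extract_peaks",
    "train_keypointer",
    "save_checkpoint",
    "load_checkpoint",
]

HG_DEPTH = 4  # four down- and four upsampling modules per hourglass


@dataclasses.dataclass(frozen=True)
class KeypointNetConfig:
    levels: tuple[str, ...] = ("L4",)
    channels: int = 8
    n_stacks: int = 2
    residual: bool = True
    coord_channels: bool = True  # append normalized x/y/z grids to the input
    loss: str = "ce"          # "ce": spatial-softmax cross-entropy; "mse": weighted MSE
    sigma_mm: float = 3.0     # Gaussian target width
    pos_weight: float = 50.0  # up-weighting of near-peak voxels in the MSE
    lr_drop: float = 0.1      # lr multiplier applied after 2/3 of the epochs
    lr: float = 1e-3
    epochs: int = 50
    seed: int = 0

    def keypoint_names(self) -> list[tuple[str, str, str]]:
        """Channel layout: 4 per instrumented level (side x entry/exit)."""
        return [
            (level, side, which)
            for level in self.levels
            for side in ("left", "right")
            for which in ("entry", "exit")
        ]

    def validate(self) -> None:
        if self.channels < 2 or self.n_stacks < 1:
            raise ValidationError("channels >= 2 and n_stacks >= 1 required")
        if self.sigma_mm <= 0:
            raise ValidationError("sigma_mm must be > 0")
        if self.loss not in ("ce", "mse"):
            raise ValidationError(f"loss must be 'ce' or 'mse', got {self.loss!r}")


@dataclasses.dataclass
class HeatmapStack:
    """One non-negative 3D heatmap per keypoint channel."""

    data: np.ndarray                       # (K, X, Y, Z), >= 0
    geometry: Volume                       # grid the heatmaps live on
    names: list[tuple[str, str, str]]      # (level, side, entry|exit) per channel

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[0] != len(self.names):
            raise ValidationError(
                f"heatmap stack shape {self.data.shape} inconsistent with {len(self.names)} channels"
            )
        if self.data.min() < 0:
            raise ValidationError("heatmaps must be non-negative")


# ---------------------------------------------------------------------------
# supervision targets and peak read-out
# ---------------------------------------------------------------------------

def heatmap_target(p, grid: Volume, sigma: float) -> np.ndarray:
    """Isotropic Gaussian (peak value 1) centered at physical point ``p``."""
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    if not to_voxel(p, grid).inside:
        raise ValidationError(f"keypoint {np.asarray(p)} outside the grid")
    p = np.asarray(p, dtype=float)
    ax = [
        np.asarray(grid.origin)[k] + np.asarray(grid.spacing)[k] * np.arange(grid.shape[k])
        for k in range(3)
    ]
    dx2 = (ax[0] - p[0])[:, None, None] ** 2
    dy2 = (ax[1] - p[1])[None, :, None] ** 2
    dz2 = (ax[2] - p[2])[None, None, :] ** 2
    return np.exp(-(dx2 + dy2 + dz2) / (2.0 * sigma**2)).astype(np.float32)


def _argmax_zyx(channel: np.ndarray) -> tuple[int, int, int]:
    """Argmax with ties broken by lowest (z, y, x) lexicographic index."""
    flat = channel.transpose(2, 1, 0).argmax()
    z, y, x = np.unravel_index(flat, channel.shape[::-1])
    return int(x), int(y), int(z)


def _refine_com(channel: np.ndarray, idx) -> np.ndarray:
    """3³ center-of-mass around the argmax (sub-voxel refinement)."""
    lo = np.maximum(np.asarray(idx) - 1, 0)
    hi = np.minimum(np.asarray(idx) + 2, channel.shape)
    patch = channel[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    w = np.maximum(patch, 0.0)
    if w.sum() <= 0:
        return np.asarray(idx, dtype=float)
    g = np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)], indexing="ij")
    return np.array([float((gk * w).sum() / w.sum()) for gk in g])


def extract_peaks(h: HeatmapStack, geometry: Volume | None = None, refine: bool = False) -> KeypointSet:
    """KeypointSet from per-channel heatmap maxima.

    The physical coordinate of the maximum voxel is returned per channel
    (deterministic lexicographic tie-break); all-zero channels are flagged
    as missing rather than raising.  ``refine=True`` applies a 3³
    center-of-mass around the argmax.
    """
    grid = geometry if geometry is not None else h.geometry
    points: dict[tuple[str, str, str], np.ndarray] = {}
    missing: list[tuple[str, str, str]] = []
    for channel, name in zip(h.data, h.names):
        if channel.max() <= 0:
            missing.append(name)
            continue
        idx = _argmax_zyx(channel)
        loc = _refine_com(channel, idx) if refine else np.asarray(idx, dtype=float)
        points[name] = to_physical(loc, grid)

    pairs: dict[tuple[str, str], KeypointPair] = {}
    missing_pairs: list[tuple[str, str]] = []
    keys = {(lv, sd) for (lv, sd, _) in list(points) + missing}
    for lv, sd in sorted(keys):
        e, x = points.get((lv, sd, "entry")), points.get((lv, sd, "exit"))
        if e is None or x is None or np.allclose(e, x):
            missing_pairs.append((lv, sd))
            continue
        pairs[(lv, sd)] = KeypointPair(e, x)
    return KeypointSet(pairs, missing_pairs)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class _Block(Module):
    """Three groups of [conv 3³ → BN → ReLU]; residual added to the third."""

    def __init__(self, c: int, residual: bool, *, rng):
        super().__init__()
        self.convs = [Conv3d(c, c, rng=rng) for _ in range(3)]
        self.bns = [BatchNorm3d(c) for _ in range(3)]
        self.residual = residual

    def __call__(self, x: Tensor) -> Tensor:
        y = x
        for i in range(3):
            y = self.bns[i](self.convs[i](y))
            if i == 2 and self.residual:
                y = core.add(y, x)
            y = core.relu(y)
        return y


class _Hourglass(Module):
    """One symmetric encoder-decoder hourglass with per-scale skip adds."""

    def __init__(self, c: int, residual: bool, *, rng):
        super().__init__()
        self.down = [_Block(c, residual, rng=rng) for _ in range(HG_DEPTH)]
        self.up = [_Block(c, residual, rng=rng) for _ in range(HG_DEPTH)]
        self.deconv = [ConvTranspose3d(c, c, rng=rng) for _ in range(HG_DEPTH)]
        self.bottom = _Block(c, residual, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        cur = x
        for blk in self.down:
            f = blk(cur)
            skips.append(f)
            cur = core.maxpool2(f)
        cur = self.bottom(cur)
        for d in reversed(range(HG_DEPTH)):
            cur = core.add(self.deconv[d](cur), skips[d])
            cur = self.up[d](cur)
        return cur


class StackedHourglass(Module):
    """Stem (2x pool) + N stacked hourglasses with intermediate supervision."""

    def __init__(self, cfg: KeypointNetConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.channels
        k = len(cfg.keypoint_names())
        # coordinate channels break the translational symmetry of the convs,
        # letting the net tell mirrored left/right structures apart
        cin = 4 if cfg.coord_channels else 1
        self.stem = Conv3d(cin, c, rng=rng)
        self.stem_bn = BatchNorm3d(c)
        self.hourglasses = [_Hourglass(c, cfg.residual, rng=rng) for _ in range(cfg.n_stacks)]
        self.heads = [Conv3d(c, k, k=1, rng=rng) for _ in range(cfg.n_stacks)]

    def forward_heatmaps(self, vol: np.ndarray) -> list[Tensor]:
        """Per-stack heatmap tensors (last = the prediction), half input res."""
        vol = np.asarray(vol, dtype=np.float32)
        if vol.ndim != 3:
            raise ValidationError(f"expected 3D volume, got shape {vol.shape}")
        x_np, crop = _pad_to_multiple_kp(vol[None])
        if self.cfg.coord_channels:
            axes = [np.linspace(-1.0, 1.0, n, dtype=np.float32) for n in x_np.shape[1:]]
            cx, cy, cz = np.meshgrid(*axes, indexing="ij")
            x_np = np.concatenate([x_np, cx[None], cy[None], cz[None]], axis=0)
        x = core.relu(self.stem_bn(self.stem(Tensor(x_np))))
        x = core.maxpool2(x)
        outs = []
        for hg, head in zip(self.hourglasses, self.heads):
            x = hg(x)
            h = head(x)
            # MSE training regresses non-negative heatmaps directly; CE
            # training treats the head output as spatial logits
            outs.append(core.relu(h) if self.cfg.loss == "mse" else h)
        self._crop = tuple(slice(s.start // 2, (s.stop + 1) // 2) for s in crop)
        return outs

    def heatmap_geometry(self, vol: Volume) -> Volume:
        """Geometry of the half-resolution output grid (block centers)."""
        sp = tuple(2 * s for s in vol.spacing)
        og = tuple(o + 0.5 * s for o, s in zip(vol.origin, vol.spacing))
        shape = tuple((n + 1) // 2 for n in vol.shape)
        return Volume(np.zeros(shape, dtype=np.float32), sp, og)

    def predict(self, vol: Volume) -> HeatmapStack:
        outs = self.forward_heatmaps(vol.data)
        data = outs[-1].data
        if self.cfg.loss == "ce":
            data = core.spatial_softmax(data)
            data = data / max(float(data.max()), 1e-12)  # peak-normalized
        data = data[(slice(None),) + self._crop]
        return HeatmapStack(data, self.heatmap_geometry(vol), self.cfg.keypoint_names())


def _pad_to_multiple_kp(x: np.ndarray) -> tuple[np.ndarray, tuple]:
    m = 2 ** (HG_DEPTH + 1)  # stem pool + hourglass depth
    shape = np.asarray(x.shape[-3:])
    target = (np.ceil(shape / m) * m).astype(int)
    pad = target - shape
    if np.all(pad == 0):
        return x, tuple(slice(0, int(s)) for s in shape)
    pads = [(0, 0)] + [(0, int(p)) for p in pad]
    return np.pad(x, pads), tuple(slice(0, int(s)) for s in shape)


def build_hourglass(cfg: KeypointNetConfig) -> StackedHourglass:
    return StackedHourglass(cfg)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _targets_for(model: StackedHourglass, vol: Volume, kps: KeypointSet) -> np.ndarray | None:
    grid = model.heatmap_geometry(vol)
    names = model.cfg.keypoint_names()
    t = np.zeros((len(names),) + grid.shape, dtype=np.float32)
    for ci, (level, side, which) in enumerate(names):
        pair = kps.pairs.get((level, side))
        if pair is None:
            continue
        p = pair.entry if which == "entry" else pair.exit
        if not to_voxel(p, vol).inside:
            return None  # keypoint outside the volume: sample rejected
        t[ci] = heatmap_target(p, grid, model.cfg.sigma_mm)
    return t


def train_keypointer(
    model: StackedHourglass,
    dataset: list[tuple[Volume, KeypointSet]],
    cfg: KeypointNetConfig,
    val_dataset: list[tuple[Volume, KeypointSet]] | None = None,
):
    """Seeded training minimizing heatmap MSE (all stacks supervised).

    Returns per-epoch training loss and, on the validation split, the mean
    Euclidean entry/exit localization errors in mm.
    """
    if not dataset:
        raise ValidationError("empty training dataset")
    samples = []
    for vol, kps in dataset:
        t = _targets_for(model, vol, kps)
        if t is None:
            warnings.warn("sample rejected: keypoint outside volume")
            continue
        samples.append((vol, t))
    if not samples:
        raise ValidationError("all samples rejected (keypoints outside volumes)")

    opt = Adam(model.parameters(), lr=cfg.lr)
    order_rng = np.random.default_rng(cfg.seed + 1)
    history = []
    for epoch in range(cfg.epochs):
        model.train()
        if epoch == (2 * cfg.epochs) // 3:
            opt.lr *= cfg.lr_drop
        total = 0.0
        for i in order_rng.permutation(len(samples)):
            vol, target = samples[i]
            outs = model.forward_heatmaps(vol.data)
            loss = None
            for out in outs:
                padded = _pad_target(target, out.data.shape)
                if cfg.loss == "ce":
                    term = core.heatmap_ce_loss(out, padded)
                else:
                    term = core.heatmap_mse_loss(out, padded, pos_weight=cfg.pos_weight)
                loss = term if loss is None else core.add(loss, term)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data)
        rec = {"epoch": epoch, "train_loss": total / len(samples)}
        if val_dataset:
            rec.update(localization_errors(model, val_dataset))
        history.append(rec)
    return history


def _pad_target(target: np.ndarray, shape) -> np.ndarray:
    if target.shape == tuple(shape):
        return target
    out = np.zeros(shape, dtype=np.float32)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(target.shape, shape))
    out[sl] = target[sl]
    return out


def localization_errors(model: StackedHourglass, dataset) -> dict[str, float]:
    """Mean Euclidean entry/exit errors (mm) of refined peaks vs truth."""
    model.eval()
    entry_err, exit_err = [], []
    for vol, kps in dataset:
        pred = extract_peaks(model.predict(vol), refine=True)
        for key, pair in kps.items():
            pp = pred.pairs.get(key)
            if pp is None:
                entry_err.append(np.inf)
                exit_err.append(np.inf)
                continue
            entry_err.append(float(np.linalg.norm(pp.entry - pair.entry)))
            exit_err.append(float(np.linalg.norm(pp.exit - pair.exit)))
    return {
        "entry_error_mm": float(np.mean(entry_err)),
        "exit_error_mm": float(np.mean(exit_err)),
    }


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: StackedHourglass, path) -> None:
    path = Path(path)
    np.savez(path, **model.state_dict())
    cfg = dataclasses.asdict(model.cfg)
    cfg["levels"] = list(cfg["levels"])
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=1) + "\n")


def load_checkpoint(path) -> StackedHourglass:
    path = Path(path)
    cfg_d = json.loads(path.with_suffix(".json").read_text())
    cfg_d["levels"] = tuple(cfg_d["levels"])
    model = StackedHourglass(KeypointNetConfig(**cfg_d))
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
        model.load_state_dict(dict(z))
    return model
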