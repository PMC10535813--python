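"""Self-supervised pigment decomposition model.

The network maps a linear-RGB skin patch to melanin, hemoglobin and shading
maps.  Training needs no pigment ground truth: the maps are pushed through
the differentiable reflectance-LUT renderer and the masked mean squared
error between the reconstruction and the input patch is minimized.  Models
whose running masked PSNR exceeds a save threshold (35 dB by default) are
recorded as checkpoints.  Full-image inference splits the image into
overlapping patches, decomposes each, and blends the per-patch maps with
crossfade weights.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .color_pipeline import srgb_to_linear
from .nn import Adam, ResUNet, Tensor, lut_render
from .nn.autograd import masked_log_mse_loss, masked_mse_loss
from .patchwork import PatchGrid, blend_patches, split_into_patches
from .renderer import PigmentMaps
from .spectral_optics import ReflectanceLUT, TissueParams

__all__ = [
    "ModelConfig",
    "TrainState",
    "build_model",
    "train_self_supervised",
    "decompose_image",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters (desk-scale defaults).

    The desk scale — 16 base channels, depth 4, 64 px patches — keeps the
    full training framework exercisable on a single CPU; ``base_channels``
    and ``patch_size`` scale up to the full configuration unchanged.
    """

    base_channels: int = 16
    max_width_factor: int = 2  # channel-doubling cap, in multiples of base
    depth: int = 4
    patch_size: int = 64
    seed: int = 0
    steps: int = 2000
    batch_size: int = 8
    learning_rate: float = 1e-3
    loss_space: str = "log"  # 'log' (equal fractional error) or 'linear'
    warmup_steps: int = 50  # linear learning-rate ramp, stabilizes early steps
    clip_grad_norm: float = 1.0
    weight_decay: float = 1e-4
    checkpoint_psnr_db: float = 35.0
    psnr_ema: float = 0.9  # smoothing of the running PSNR
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.patch_size % 2**self.depth:
            raise ValueError("patch_size must be divisible by 2**depth")
        if self.loss_space not in ("log", "linear"):
            raise ValueError("loss_space must be 'log' or 'linear'")
        if self.device != "cpu":
            raise ValueError("only the cpu device is available")


@dataclass
class TrainState:
    """Progress record of a self-supervised run."""

    step: int = 0
    running_mse: float = float("nan")
    running_psnr: float = float("-inf")
    mse_history: list[float] = field(default_factory=list)
    checkpoints: list[tuple[int, float]] = field(default_factory=list)


def build_model(cfg: ModelConfig) -> ResUNet:
    """Seeded network: 3-channel linear-RGB in, three bounded maps out."""
    return ResUNet(base_channels=cfg.base_channels, depth=cfg.depth,
                   seed=cfg.seed, max_width_factor=cfg.max_width_factor)


def _random_crop(rng, patch, mask, size):
    h, w = patch.shape[:2]
    if h == size and w == size:
        return patch, mask
    if h < size or w < size:
        raise ValueError("training patch smaller than model patch size")
    r = rng.integers(0, h - size + 1)
    c = rng.integers(0, w - size + 1)
    return patch[r : r + size, c : c + size], mask[r : r + size, c : c + size]


def train_self_supervised(
    images: list[np.ndarray],
    lut: ReflectanceLUT,
    cfg: ModelConfig,
    masks: list[np.ndarray] | None = None,
    tissue: TissueParams | None = None,
    model: ResUNet | None = None,
) -> tuple[ResUNet, TrainState]:
    """Train the decomposition network by reconstruction alone.

    Parameters
    ----------
    images
        Linear-RGB patches (H, W, 3) in [0, 1], already mask-overlaid.
        Patches larger than ``cfg.patch_size`` are randomly cropped each
        step (the framework's only augmentation).
    lut
        Reflectance table the renderer interpolates.
    masks
        Optional per-patch skin masks; defaults to all-skin.

    The run is deterministic under ``cfg.seed``.  A NaN loss aborts with a
    diagnostic.  Checkpoints (step, PSNR) are recorded whenever the running
    masked PSNR exceeds ``cfg.checkpoint_psnr_db``.
    """
    if not images:
        raise ValueError("empty training set")
    t = tissue or TissueParams()
    if masks is None:
        masks = [np.ones(im.shape[:2], bool) for im in images]
    model = model or build_model(cfg)
    opt = Adam(model.params, lr=cfg.learning_rate,
               clip_norm=cfg.clip_grad_norm, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)
    state = TrainState()
    ema_mse = None
    for step in range(1, cfg.steps + 1):
        idx = rng.integers(0, len(images), size=cfg.batch_size)
        batch, bmask = [], []
        for i in idx:
            p, m = _random_crop(rng, images[i], masks[i], cfg.patch_size)
            batch.append(np.moveaxis(p, -1, 0))
            bmask.append(m)
        x = np.stack(batch).astype(np.float32)
        m = np.stack(bmask)
        # non-skin pixels are zeroed, mirroring the mask overlay at inference
        x = x * m[:, None, :, :]
        out = model(Tensor(x))
        recon = lut_render(out, lut, t)
        loss = (
            masked_log_mse_loss(recon, x, m)
            if cfg.loss_space == "log"
            else masked_mse_loss(recon, x, m)
        )
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"non-finite loss at step {step}; "
                "lower the learning rate or check the input range"
            )
        opt.lr = cfg.learning_rate * min(1.0, step / max(cfg.warmup_steps, 1))
        opt.zero_grad()
        loss.backward()
        opt.step()
        # progress/checkpoints always track the linear-RGB MSE, whatever the
        # optimization domain
        lin_diff = np.where(m[:, None, :, :], recon.data - x, 0.0)
        mse_val = float((lin_diff**2).sum() / (m.sum() * 3))
        ema_mse = mse_val if ema_mse is None else (
            cfg.psnr_ema * ema_mse + (1 - cfg.psnr_ema) * mse_val
        )
        state.step = step
        state.running_mse = ema_mse
        state.running_psnr = (
            float("inf") if ema_mse == 0 else 10.0 * np.log10(1.0 / ema_mse)
        )
        state.mse_history.append(mse_val)
        if state.running_psnr > cfg.checkpoint_psnr_db:
            state.checkpoints.append((step, state.running_psnr))
    return model, state


def decompose_image(
    img: np.ndarray,
    mask: np.ndarray,
    model: ResUNet,
    grid: PatchGrid | None = None,
    input_space: str = "srgb",
) -> PigmentMaps:
    """Decompose a full image into pigment maps.

    Pipeline: overlay the skin mask, linearize (inverse gamma) when the
    input is sRGB, split into overlapping patches, run the network on each,
    and blend the per-patch maps seamlessly.  Non-skin pixels are zero in
    all three maps.
    """
    img = np.asarray(img, float)
    mask = np.asarray(mask, bool)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) image")
    if mask.shape != img.shape[:2]:
        raise ValueError("mask shape must match the image")
    if input_space not in ("srgb", "linear"):
        raise ValueError("input_space must be 'srgb' or 'linear'")
    overlaid = img * mask[..., None]
    linear = srgb_to_linear(overlaid) if input_space == "srgb" else overlaid
    if grid is None:
        grid = PatchGrid(linear.shape[:2], patch_size=64, overlap=15)
    patches = split_into_patches(linear, grid)
    out_patches = []
    for p in patches:
        x = np.moveaxis(p, -1, 0)[None].astype(np.float32)
        maps = model(Tensor(x)).data[0]  # (3, H, W)
        out_patches.append(np.moveaxis(maps, 0, -1).astype(float))
    blended = blend_patches(out_patches, grid)
    blended *= mask[..., None]
    return PigmentMaps(blended[..., 0], blended[..., 1], blended[..., 2])


def save_checkpoint(path: str | Path, model: ResUNet, cfg: ModelConfig,
                    state: TrainState | None = None) -> None:
    """Self-describing archive: config JSON alongside the parameters."""
    path = Path(path)
    meta = {"config": asdict(cfg)}
    if state is not None:
        meta["final_step"] = state.step
        meta["running_psnr"] = state.running_psnr
    np.savez_compressed(path, __meta__=json.dumps(meta), **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[ResUNet, ModelConfig]:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        cfg = ModelConfig(**meta["config"])
        model = build_model(cfg)
        model.load_state_dict(
            {k: npz[k] for k in npz.files if k != "__meta__"}
        )
    return model, cfg
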