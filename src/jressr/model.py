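"""The x2 super-resolution model: losses, patch selection, training, inference.

The generator maps a low-resolution J-Res spectrum to a spectrum with twice
the pixel count along both axes.  It is a residual convolutional network
with a global nearest-neighbour upsampling skip, so an untrained generator
already reproduces plain interpolation and training learns the sharpening
residual.  A small patch discriminator provides the adversarial signal.

Loss stack (weighted sum):

* pixel loss — mean absolute difference to the ground-truth HR patch;
* symmetric loss — J-Res spectra are mirror-symmetric about the J = 0 Hz
  line, so for every column containing signal we correlate the
  log-intensities of the upper half with those of the mirrored lower half
  and penalize ``1 - mean Pearson r`` (0 for a perfectly symmetric
  spectrum, at most 2);
* GAN loss — non-saturating adversarial objective on per-pixel realness
  logit maps;
* perceptual loss — optional pluggable hook (a callable computing loss and
  gradient in a fixed feature space); off by default since no pretrained
  backbone is bundled.

Spectra are normalized by the LR spectrum maximum before entering the
network and rescaled afterwards; spectral intensities span a high dynamic
range and the network is trained on O(1) inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from . import nn
from .core_io import Spectrum2D
from .degrade import DegradeConfig, degrade

__all__ = [
    "GeneratorConfig",
    "LossWeights",
    "TrainState",
    "Generator",
    "Discriminator",
    "symmetric_loss",
    "symmetric_loss_grad",
    "pixel_loss",
    "gan_losses",
    "select_training_patches",
    "train",
    "enhance",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture of the generator.  ``scale`` is fixed at 2."""

    scale: int = 2
    n_blocks: int = 3
    n_features: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale != 2:
            raise ValueError("only a x2 scale factor is supported")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


@dataclass(frozen=True)
class LossWeights:
    w_pixel: float = 1.0
    w_perceptual: float = 0.0
    w_gan: float = 0.05
    w_symmetric: float = 0.1

    def __post_init__(self) -> None:
        ws = (self.w_pixel, self.w_perceptual, self.w_gan, self.w_symmetric)
        if any(w < 0 for w in ws):
            raise ValueError("loss weights must be non-negative")
        if not any(w > 0 for w in ws):
            raise ValueError("at least one loss weight must be positive")


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _as_grid(x) -> np.ndarray:
    return x.grid if isinstance(x, Spectrum2D) else np.asarray(x)


def pixel_loss(pred, target) -> float:
    """Mean absolute difference over pixels."""
    p, t = _as_grid(pred), _as_grid(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    return float(np.mean(np.abs(np.asarray(p, dtype=np.float64) - t)))


def symmetric_loss_grad(grid: np.ndarray) -> tuple[float, np.ndarray]:
    """Symmetric loss of one 2D grid and its gradient.

    For each column i containing at least one strictly positive pixel, let
    S_iu be the log intensities of the upper half and S_il those of the
    lower half mirrored about J = 0.  The loss is ``1 - (1/n) sum_i r(S_iu,
    S_il)`` over the n contributing columns.  Intensities are clipped below
    at 0 and offset by ``eps = 1e-6 * global max`` before the log.  Columns
    where either half has zero variance are excluded, except that a column
    whose halves are identical constants contributes r = 1 (gradient 0).
    Returns 0 with zero gradient when no column contributes.

    The gradient treats the column selection, clipping mask and ``eps`` as
    locally constant.
    """
    y = np.asarray(grid, dtype=np.float64)
    if y.ndim != 2:
        raise ValueError("expected a 2D grid")
    h, w = y.shape
    if h % 2:
        raise ValueError(f"row count must be even, got {h}")
    h2 = h // 2
    grad = np.zeros_like(y)
    gmax = float(y.max(initial=0.0))
    if gmax <= 0.0:
        return 0.0, grad
    eps = 1e-6 * gmax
    clipped = np.maximum(y, 0.0)
    col_has_signal = (clipped > 0.0).any(axis=0)

    cu = clipped[:h2]                     # upper half, rows 0..h2-1
    cl = clipped[::-1][:h2]               # lower half mirrored about J = 0
    su = np.log(cu + eps)
    sl = np.log(cl + eps)
    a = su - su.mean(axis=0)
    b = sl - sl.mean(axis=0)
    a2 = (a * a).sum(axis=0)
    b2 = (b * b).sum(axis=0)
    c = (a * b).sum(axis=0)

    varying = col_has_signal & (a2 > 0) & (b2 > 0)
    const_equal = (
        col_has_signal & (a2 == 0) & (b2 == 0) & (su[0] == sl[0])
    )
    n = int(varying.sum() + const_equal.sum())
    if n == 0:
        return 0.0, grad

    r = np.zeros(w)
    denom = np.sqrt(a2[varying] * b2[varying])
    r[varying] = c[varying] / denom
    r[const_equal] = 1.0
    loss = 1.0 - (r[varying].sum() + r[const_equal].sum()) / n

    # d r / d a_k = (b_k - (C/A2) a_k) / sqrt(A2 B2), symmetrically for b.
    dr_da = np.zeros((h2, w))
    dr_db = np.zeros((h2, w))
    dr_da[:, varying] = (b[:, varying] - (c[varying] / a2[varying]) * a[:, varying]) / denom
    dr_db[:, varying] = (a[:, varying] - (c[varying] / b2[varying]) * b[:, varying]) / denom
    # centering: d a / d su = I - 1/h2; a gradient g maps back to g - mean(g)
    dsu = dr_da - dr_da.mean(axis=0)
    dsl = dr_db - dr_db.mean(axis=0)
    # chain through log and the clip (zero where the raw pixel was negative)
    dcu = np.where(y[:h2] >= 0, dsu / (cu + eps), 0.0)
    dcl = np.where(y[::-1][:h2] >= 0, dsl / (cl + eps), 0.0)
    grad[:h2] = dcu
    grad[h2:] += dcl[::-1]
    grad *= -1.0 / n          # loss = 1 - mean r
    return float(loss), grad


def symmetric_loss(s) -> float:
    """Symmetric loss of a spectrum (see :func:`symmetric_loss_grad`)."""
    return symmetric_loss_grad(_as_grid(s))[0]


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def gan_losses(disc_out_real: np.ndarray, disc_out_fake: np.ndarray) -> tuple[float, float]:
    """Non-saturating adversarial objectives on realness logit maps.

    Returns ``(generator term, discriminator term)``:
    ``L_G = mean softplus(-D(fake))``,
    ``L_D = mean softplus(-D(real)) + mean softplus(D(fake))``.
    At the decision midpoint (all logits 0) the generator term is ln 2 and
    the discriminator term 2 ln 2.
    """
    real = np.asarray(disc_out_real, dtype=np.float64)
    fake = np.asarray(disc_out_fake, dtype=np.float64)
    gen = float(np.mean(_softplus(-fake)))
    disc = float(np.mean(_softplus(-real)) + np.mean(_softplus(fake)))
    return gen, disc


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class Generator:
    """Residual CNN with a global nearest-upsample skip (x2 in both axes).

    All convolutions are bias-free, which together with leaky ReLU makes
    the network positively homogeneous: ``G(a x) = a G(x)`` for a > 0.
    Spectral intensities span orders of magnitude, and scale equivariance
    lets one network treat dim and bright regions identically regardless
    of the normalization applied outside.
    """

    def __init__(self, cfg: GeneratorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.n_features
        self.head = nn.Conv2d(1, f, rng=rng, bias=False)
        self.head_act = nn.LeakyReLU()
        self.blocks = [
            nn.Sequential(
                nn.Conv2d(f, f, rng=rng, bias=False), nn.LeakyReLU(),
                nn.Conv2d(f, f, rng=rng, init_scale=0.1, bias=False),
            )
            for _ in range(cfg.n_blocks)
        ]
        self.res_scale = 0.2
        self.up = nn.UpsampleNearest2x()
        self.base_up = nn.UpsampleNearest2x()
        self.tail1 = nn.Conv2d(f, f, rng=rng, bias=False)
        self.tail_act = nn.LeakyReLU()
        self.tail2 = nn.Conv2d(f, 1, rng=rng, init_scale=0.1, bias=False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        base = self.base_up.forward(x)
        h = self.head_act.forward(self.head.forward(x))
        for blk in self.blocks:
            h = h + self.res_scale * blk.forward(h)
        t = self.tail2.forward(self.tail_act.forward(self.tail1.forward(self.up.forward(h))))
        return base + t

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.tail2.backward(grad)
        g = self.tail_act.backward(g)
        g = self.tail1.backward(g)
        g = self.up.backward(g)
        for blk in reversed(self.blocks):
            g = g + blk.backward(self.res_scale * g)
        g = self.head_act.backward(g)
        g = self.head.backward(g)
        return g + self.base_up.backward(grad)

    def _modules(self):
        return [self.head, *self.blocks, self.tail1, self.tail2]

    def parameters(self):
        return [p for m in self._modules() for p in m.parameters()]

    def gradients(self):
        return [g for m in self._modules() for g in m.gradients()]

    def zero_grad(self):
        for g in self.gradients():
            g[...] = 0.0


class Discriminator(nn.Sequential):
    """Small patch discriminator producing a per-pixel realness logit map."""

    def __init__(self, n_features: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        f = n_features
        super().__init__(
            nn.Conv2d(1, f, rng=rng), nn.LeakyReLU(), nn.AvgPool2x(),
            nn.Conv2d(f, f, rng=rng), nn.LeakyReLU(), nn.AvgPool2x(),
            nn.Conv2d(f, 1, rng=rng),
        )

    def zero_grad(self):
        for g in self.gradients():
            g[...] = 0.0


@dataclass
class TrainState:
    """Opaque training handle: networks, optimizer config and loss history."""

    generator: Generator
    discriminator: Discriminator
    gen_cfg: GeneratorConfig
    loss_weights: LossWeights
    iteration: int = 0
    history: list = field(default_factory=list)
    learning_rate: float = 1e-4
    batch_size: int = 8


# ---------------------------------------------------------------------------
# Patch selection
# ---------------------------------------------------------------------------

def select_training_patches(
    hr: Spectrum2D,
    lr: Spectrum2D,
    patch_size: int = 256,
    rng: np.random.Generator | None = None,
    n_trials: int = 16,
    peak_threshold: float = 0.05,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Randomly crop peak-containing HR patches with co-located LR patches.

    Crops span the full F1 (row) extent and a random ``patch_size``-column
    window along F2, mirroring training crops whose height equals the
    spectrum's F1 dimension.  Keeping all rows preserves the J = 0 mirror
    line at the patch midline, so the symmetric loss evaluated on a patch
    measures the same symmetry as on the full spectrum — a random 2D crop
    would put the mirror axis at an arbitrary position.

    Column origins are even-aligned so the LR crop sits exactly at the
    halved coordinates with half the width.  A candidate patch is kept iff
    its maximum intensity exceeds ``peak_threshold`` times the spectrum's
    global maximum, which skips the empty regions dominating a J-Res grid.
    """
    rng = rng or np.random.default_rng()
    h, w = hr.shape
    if patch_size > w:
        raise ValueError(f"patch size {patch_size} larger than grid width {w}")
    if patch_size % 2 or h % 2:
        raise ValueError("patch size and row count must be even")
    if lr.shape != (h // 2, w // 2):
        raise ValueError("lr grid must be the x2-degraded counterpart of hr")
    gmax = float(hr.grid.max(initial=0.0))
    if gmax <= 0.0:
        return []
    out = []
    ps = patch_size
    for _ in range(n_trials):
        c0 = 2 * int(rng.integers(0, (w - ps) // 2 + 1))
        hp = hr.grid[:, c0:c0 + ps]
        if hp.max(initial=0.0) > peak_threshold * gmax:
            lp = lr.grid[:, c0 // 2:c0 // 2 + ps // 2]
            out.append((hp.copy(), lp.copy()))
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

PerceptualFn = Callable[[np.ndarray, np.ndarray], tuple[float, np.ndarray]]


def train(
    dataset: list[Spectrum2D],
    gen_cfg: GeneratorConfig = GeneratorConfig(),
    loss_weights: LossWeights = LossWeights(),
    iterations: int = 200,
    rng: np.random.Generator | None = None,
    *,
    learning_rate: float = 1e-4,
    batch_size: int = 8,
    patch_size: int = 48,
    degrade_cfg: DegradeConfig = DegradeConfig(),
    patches_per_spectrum: int = 40,
    peak_threshold: float = 0.05,
    perceptual_fn: PerceptualFn | None = None,
    disc_seed: int | None = None,
    lr_schedule: str = "cosine",
    ema_decay: float = 0.99,
    pixel_transform: str = "sqrt",
    loss_margin: int = 8,
) -> TrainState:
    """Train the generator (and discriminator) on LR->HR patch pairs.

    Each HR spectrum is degraded to its LR counterpart, both are scaled by
    the LR maximum (matching what inference can compute), and
    peak-containing patches are pooled.  Every iteration samples a batch,
    takes one Adam step on the generator against the weighted loss sum, and
    — when the GAN weight is positive — one Adam step on the discriminator.
    Deterministic given ``rng`` and the config seeds.  Raises on non-finite
    losses.

    The pixel term is, by default, the mean absolute difference of
    square-root-compressed intensities (``pixel_transform="sqrt"``;
    ``"identity"`` gives plain MAE).  Spectral peak heights span orders of
    magnitude even within one patch, and without compression the pixel
    loss is dominated by the most intense peaks — the same rationale the
    symmetric loss applies with its log transform.

    Following standard GAN super-resolution practice, an exponential
    moving average of the generator parameters (decay ``ema_decay``) is
    maintained and used for inference, and the learning rate optionally
    follows a half-cosine decay to zero over the run
    (``lr_schedule="cosine"``; ``"constant"`` disables it).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not dataset:
        raise ValueError("dataset must be non-empty")
    if loss_weights.w_perceptual > 0 and perceptual_fn is None:
        raise ValueError("w_perceptual > 0 requires a perceptual_fn hook")
    rng = rng or np.random.default_rng()

    # Patches are normalized by their own LR-patch maximum so that dim and
    # bright regions contribute equally to the loss; the bias-free
    # generator is scale-equivariant, so per-patch scaling at train time is
    # consistent with any positive scaling at inference.
    pool_hr: list[np.ndarray] = []
    pool_lr: list[np.ndarray] = []
    for hr in dataset:
        lr = degrade(hr, degrade_cfg)
        for hp, lp in select_training_patches(
            hr, lr, patch_size, rng, patches_per_spectrum, peak_threshold
        ):
            scale = float(lp.max(initial=0.0))
            if scale <= 0:
                continue
            pool_hr.append(hp.astype(np.float64) / scale)
            pool_lr.append(lp.astype(np.float64) / scale)
    if not pool_hr:
        raise ValueError("no peak-containing patches found in the dataset")

    gen = Generator(gen_cfg)
    disc = Discriminator(gen_cfg.n_features,
                         seed=disc_seed if disc_seed is not None else gen_cfg.seed + 1)
    adam_g = nn.Adam(gen.parameters(), gen.gradients(), lr=learning_rate)
    adam_d = nn.Adam(disc.parameters(), disc.gradients(), lr=learning_rate)
    w = loss_weights
    state = TrainState(gen, disc, gen_cfg, w,
                       learning_rate=learning_rate, batch_size=batch_size)

    if lr_schedule not in ("cosine", "constant"):
        raise ValueError(f"unknown lr_schedule {lr_schedule!r}")
    ema = [p.copy() for p in gen.parameters()]

    n_pool = len(pool_hr)
    for it in range(iterations):
        if lr_schedule == "cosine":
            frac = it / max(iterations - 1, 1)
            adam_g.lr = learning_rate * 0.5 * (1.0 + np.cos(np.pi * frac))
            adam_d.lr = adam_g.lr
        idx = rng.integers(0, n_pool, size=batch_size)
        x = np.stack([pool_lr[i] for i in idx])[:, None]     # (N,1,h,w)
        y = np.stack([pool_hr[i] for i in idx])[:, None]     # (N,1,2h,2w)

        sr = gen.forward(x)
        grad = np.zeros_like(sr)
        rec = {"iteration": it, "pixel": 0.0, "symmetric": 0.0,
               "perceptual": 0.0, "gan_g": 0.0, "gan_d": 0.0}

        # Columns whose receptive field is fully inside the patch; the
        # zero-padded column border sees context absent at full-grid
        # inference.  Rows span the full F1 extent, so row borders match
        # inference exactly and stay in the loss.
        m = min(loss_margin, (sr.shape[3] - 2) // 2)
        mask = np.zeros(sr.shape)
        mask[:, :, :, m:sr.shape[3] - m] = 1.0
        n_mask = mask.sum()

        if w.w_pixel > 0:
            if pixel_transform == "sqrt":
                # signed sqrt compression: T(x) = sign(x) (sqrt(|x|+c) - sqrt(c))
                c = 1e-3
                t_sr = np.sign(sr) * (np.sqrt(np.abs(sr) + c) - np.sqrt(c))
                t_y = np.sign(y) * (np.sqrt(np.abs(y) + c) - np.sqrt(c))
                diff = (t_sr - t_y) * mask
                rec["pixel"] = float(np.sum(np.abs(diff)) / n_mask)
                grad += (w.w_pixel * np.sign(diff)
                         * 0.5 / np.sqrt(np.abs(sr) + c) / n_mask)
            elif pixel_transform == "identity":
                diff = (sr - y) * mask
                rec["pixel"] = float(np.sum(np.abs(diff)) / n_mask)
                grad += w.w_pixel * np.sign(diff) / n_mask
            else:
                raise ValueError(f"unknown pixel_transform {pixel_transform!r}")

        if w.w_symmetric > 0:
            sym_total = 0.0
            for b in range(batch_size):
                sl, sg = symmetric_loss_grad(sr[b, 0])
                sym_total += sl
                grad[b, 0] += w.w_symmetric * sg / batch_size
            rec["symmetric"] = sym_total / batch_size

        if w.w_perceptual > 0:
            pl, pg = perceptual_fn(sr, y)
            rec["perceptual"] = float(pl)
            grad += w.w_perceptual * pg

        if w.w_gan > 0:
            logits_fake = disc.forward(sr)
            gen_term = float(np.mean(_softplus(-logits_fake)))
            rec["gan_g"] = gen_term
            dlogits = -_sigmoid(-logits_fake) / logits_fake.size
            grad += w.w_gan * disc.backward(dlogits)
            disc.zero_grad()      # those grads belong to the generator step

        total = (w.w_pixel * rec["pixel"] + w.w_symmetric * rec["symmetric"]
                 + w.w_perceptual * rec["perceptual"] + w.w_gan * rec["gan_g"])
        rec["total"] = total
        if not np.isfinite(total):
            raise RuntimeError(
                f"training diverged at iteration {it}: losses {rec}"
            )

        gen.zero_grad()
        gen.backward(grad)
        adam_g.step()
        for e, p in zip(ema, gen.parameters()):
            e *= ema_decay
            e += (1.0 - ema_decay) * p

        if w.w_gan > 0:
            logits_real = disc.forward(y)
            disc.backward(-_sigmoid(-logits_real) / logits_real.size)
            logits_fake = disc.forward(sr)     # sr is detached from G here
            disc.backward(_sigmoid(logits_fake) / logits_fake.size)
            _, disc_term = gan_losses(logits_real, logits_fake)
            rec["gan_d"] = disc_term
            adam_d.step()
            disc.zero_grad()

        state.history.append(rec)
        state.iteration = it + 1

    # inference uses the EMA weights
    for e, p in zip(ema, gen.parameters()):
        p[...] = e
    return state


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def enhance(
    lr: Spectrum2D,
    state: TrainState,
    tile: int | None = None,
    tile_context: int = 16,
    symmetrize: bool = True,
) -> Spectrum2D:
    """Super-resolve an LR spectrum: output has 2x the points on both axes.

    The grid is scaled by its maximum, passed through the generator and
    rescaled.  For large grids set ``tile`` (LR pixels): tiles are processed
    with ``tile_context`` pixels of surrounding context and only tile
    interiors are kept, which reproduces the full-grid computation wherever
    the context covers the receptive field (seam-free by construction).

    With ``symmetrize`` (default) the prediction is averaged with the
    F1-flipped prediction of the F1-flipped input — a geometric
    self-ensemble over the mirror symmetry J-Res spectra obey, which makes
    the output exactly flip-invariant for symmetric inputs and averages
    down prediction noise.
    """
    if state.iteration < 1:
        raise ValueError("enhance requires a trained state")
    gen = state.generator
    h, w = lr.shape
    scale = float(lr.grid.max(initial=0.0))
    if scale <= 0:
        scale = 1.0
    x = lr.grid.astype(np.float64) / scale

    def infer(x: np.ndarray) -> np.ndarray:
        if tile is None or (h <= tile and w <= tile):
            return gen.forward(x[None, None])[0, 0]
        out_full = np.zeros((2 * h, 2 * w))
        for r0 in range(0, h, tile):
            for c0 in range(0, w, tile):
                r1, c1 = min(r0 + tile, h), min(c0 + tile, w)
                rr0, cc0 = max(r0 - tile_context, 0), max(c0 - tile_context, 0)
                rr1, cc1 = min(r1 + tile_context, h), min(c1 + tile_context, w)
                out = gen.forward(x[None, None, rr0:rr1, cc0:cc1])[0, 0]
                out_full[2 * r0:2 * r1, 2 * c0:2 * c1] = out[
                    2 * (r0 - rr0):2 * (r0 - rr0) + 2 * (r1 - r0),
                    2 * (c0 - cc0):2 * (c0 - cc0) + 2 * (c1 - c0),
                ]
        return out_full

    if symmetrize:
        sr = 0.5 * (infer(x) + infer(x[::-1].copy())[::-1])
    else:
        sr = infer(x)
    sr = sr * scale
    if not np.all(np.isfinite(sr)):
        raise RuntimeError("generator produced non-finite intensities")
    return Spectrum2D(
        sr.astype(np.float32),
        lr.f1_axis.with_points(2 * h),
        lr.f2_axis.with_points(2 * w),
        lr.observe_frequency,
        lr.label,
        dict(lr.meta),
    )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(state: TrainState, path: str) -> None:
    """Store config, parameters and iteration in a single .npz file."""
    arrays = {}
    for i, p in enumerate(state.generator.parameters()):
        arrays[f"gen_{i}"] = p
    for i, p in enumerate(state.discriminator.parameters()):
        arrays[f"disc_{i}"] = p
    meta = {
        "gen_cfg": asdict(state.gen_cfg),
        "loss_weights": asdict(state.loss_weights),
        "iteration": state.iteration,
        "learning_rate": state.learning_rate,
        "batch_size": state.batch_size,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as f:
        np.savez(f, **arrays)


def load_checkpoint(path: str) -> TrainState:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        gen_cfg = GeneratorConfig(**meta["gen_cfg"])
        state = TrainState(
            Generator(gen_cfg),
            Discriminator(gen_cfg.n_features, seed=gen_cfg.seed + 1),
            gen_cfg,
            LossWeights(**meta["loss_weights"]),
            iteration=meta["iteration"],
            learning_rate=meta["learning_rate"],
            batch_size=meta["batch_size"],
        )
        for i, p in enumerate(state.generator.parameters()):
            p[...] = data[f"gen_{i}"]
        for i, p in enumerate(state.discriminator.parameters()):
            p[...] = data[f"disc_{i}"]
    return state
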