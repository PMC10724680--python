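"""CycleGAN training: identity pretraining, stabilized discriminator updates,
cycle-weight decay and age-balanced sampling.

Training strategy
-----------------
Two generators (A→B, B→A) and two patchGAN discriminators are trained with a
least-squares adversarial loss and an L1 cycle-consistency penalty whose
weight decays linearly from 200 to 100 over the run.  Stability devices:

* a generator is first pretrained to replicate its input (L1 loss, pooled
  sites) and both CycleGAN generators start from those weights;
* generators use batch size 1; each discriminator is updated per step with a
  batch of 4 real images, 2 newly-generated images and 2 images drawn from a
  50-image history buffer of formerly-generated images (when the buffer holds
  fewer than 2 images the shortfall is filled with extra new fakes);
* an optional age-balanced sampling plan equalizes the age distribution of
  the two streams: per 10-year bin, both sites are sampled with a shared
  probability proportional to ``min(n_A(bin), n_B(bin))``, uniform within a
  bin, so neither site's smallest populations are undersampled and the two
  training sets see identical age distributions in expectation.

Volumes are expected median-normalized; internally intensities are divided
by the median target (brain median = 1) so that the cycle weight of 100-200
is commensurate with the O(1) adversarial loss, and generator outputs are
rescaled back.  Every stochastic choice flows from a single seeded RNG; a
non-finite loss aborts with a diagnostic state dump.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import _ad as ad
from ._ad import Adam, Tensor
from .core import Volume
from .nets import (Discriminator, DiscriminatorSpec, Generator, GeneratorSpec,
                   masked_forward)

__all__ = [
    "TrainingConfig", "HistoryBuffer", "SamplerPlan", "NonFiniteLossError",
    "cycle_weight", "buffer_offer", "compose_disc_batch", "age_balanced_plan",
    "pretrain_identity", "train_cyclegan", "TrainResult", "harmonize_volume",
]


@dataclasses.dataclass
class TrainingConfig:
    """All CycleGAN hyperparameters."""

    total_steps: int = 300
    cycle_weight_start: float = 200.0
    cycle_weight_end: float = 100.0
    buffer_capacity: int = 50
    n_real: int = 4
    n_new_fake: int = 2
    n_old_fake: int = 2
    gen_batch: int = 1
    learning_rate: float = 2e-4
    disc_learning_rate: float | None = None   # defaults to learning_rate
    betas: tuple[float, float] = (0.5, 0.999)
    seed: int = 0
    mixed_precision: bool = False
    intensity_scale: float = 500.0   # brain-median target; network I/O scale
    disc_warmup_steps: int = 0       # discriminator-only updates before the joint loop
    gen_weight_ema: float = 0.0      # EMA decay for inference generator weights (0 = off)

    def __post_init__(self):
        if not (self.cycle_weight_start >= self.cycle_weight_end > 0):
            raise ValueError("need cycle_weight_start >= cycle_weight_end > 0")
        if self.buffer_capacity < self.n_old_fake:
            raise ValueError("buffer capacity must be >= n_old_fake")
        if min(self.n_real, self.n_new_fake, self.n_old_fake) < 0:
            raise ValueError("discriminator batch components must be >= 0")


class NonFiniteLossError(RuntimeError):
    """Raised when a loss becomes NaN/Inf; carries a diagnostic state dump."""

    def __init__(self, step: int, losses: dict[str, float], trace):
        super().__init__(f"non-finite loss at step {step}: {losses}")
        self.step = step
        self.losses = losses
        self.trace = trace


def cycle_weight(step: int, total: int, start: float = 200.0,
                 end: float = 100.0) -> float:
    """Linear decay of the cycle-consistency weight over the whole run."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= step <= total:
        raise ValueError(f"step {step} outside [0, {total}]")
    return start + (end - start) * step / total


class HistoryBuffer:
    """History of formerly-generated images (Shrivastava-style pool).

    ``offer`` stores while below capacity and returns the offered image;
    at capacity it returns, with probability 1/2 each, either the offered
    image unchanged or a uniformly chosen stored image (which is then
    replaced by the offer).
    """

    def __init__(self, capacity: int = 50, rng: np.random.Generator | None = None):
        self.capacity = int(capacity)
        self.images: list[np.ndarray] = []
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def __len__(self) -> int:
        return len(self.images)

    def offer(self, image: np.ndarray) -> np.ndarray:
        if len(self.images) < self.capacity:
            self.images.append(image)
            return image
        if self.rng.random() < 0.5:
            return image
        i = int(self.rng.integers(0, self.capacity))
        old = self.images[i]
        self.images[i] = image
        return old

    def sample(self, k: int) -> list[np.ndarray]:
        """Draw up to k distinct stored images uniformly (without replacement)."""
        k = min(k, len(self.images))
        if k == 0:
            return []
        idx = self.rng.choice(len(self.images), size=k, replace=False)
        return [self.images[int(i)] for i in idx]


def buffer_offer(buf: HistoryBuffer, image: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`HistoryBuffer.offer`."""
    return buf.offer(image)


def compose_disc_batch(reals: Sequence[np.ndarray], new_fakes: Sequence[np.ndarray],
                       buf: HistoryBuffer, cfg: TrainingConfig,
                       rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Labelled discriminator batch: (images (N,1,D,H,W), labels 1=real 0=fake).

    Default composition is 4 real / 2 new fake / 2 history fake.  If the
    buffer holds fewer than ``n_old_fake`` images the shortfall is filled
    with additional new fakes (cold-start fallback); the new fakes are
    offered to the buffer afterwards.
    """
    if len(reals) < cfg.n_real:
        raise ValueError(f"need >= {cfg.n_real} real images")
    if len(new_fakes) < cfg.n_new_fake:
        raise ValueError(f"need >= {cfg.n_new_fake} new fakes")
    ridx = rng.choice(len(reals), size=cfg.n_real, replace=False)
    batch = [np.asarray(reals[int(i)], dtype=np.float32) for i in ridx]
    labels = [1.0] * cfg.n_real

    old = buf.sample(cfg.n_old_fake)
    n_new = cfg.n_new_fake + (cfg.n_old_fake - len(old))
    fidx = rng.choice(len(new_fakes), size=n_new, replace=n_new > len(new_fakes))
    new = [np.asarray(new_fakes[int(i)], dtype=np.float32) for i in fidx]
    batch.extend(new + [np.asarray(o, dtype=np.float32) for o in old])
    labels.extend([0.0] * (len(new) + len(old)))

    for f in new_fakes:
        buf.offer(np.asarray(f, dtype=np.float32))

    images = np.stack(batch)[:, None]
    return images, np.asarray(labels, dtype=np.float32)


# ---------------------------------------------------------------------------
# age-balanced sampling
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SamplerPlan:
    """Shared per-bin sampling probabilities plus per-site within-bin indices."""

    edges: np.ndarray                  # bin edges, years
    q: np.ndarray                      # shared per-bin probability, sums to 1
    bins_a: list[np.ndarray]           # indices of site-A subjects per bin
    bins_b: list[np.ndarray]

    def sample(self, rng: np.random.Generator) -> tuple[int, int]:
        b = int(rng.choice(len(self.q), p=self.q))
        ia = int(rng.choice(self.bins_a[b]))
        ib = int(rng.choice(self.bins_b[b]))
        return ia, ib


def age_balanced_plan(ages_a: Sequence[float], ages_b: Sequence[float],
                      bin_width: float = 10.0) -> SamplerPlan:
    """Build the shared age-sampling plan.

    Per bin ``q(b) ∝ min(n_A(b), n_B(b))``; bins empty in either site get
    zero probability; sampling within a bin is uniform with replacement.
    Both sites therefore see the same age-bin distribution in expectation,
    and the limiting site per bin is used maximally.
    """
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both age lists must be nonempty")
    lo = np.floor(min(a.min(), b.min()) / bin_width) * bin_width
    hi = max(a.max(), b.max())
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    ia = np.clip(np.digitize(a, edges) - 1, 0, n_bins - 1)
    ib = np.clip(np.digitize(b, edges) - 1, 0, n_bins - 1)
    na = np.bincount(ia, minlength=n_bins)
    nb = np.bincount(ib, minlength=n_bins)
    raw = np.minimum(na, nb).astype(float)
    if raw.sum() == 0:
        raise ValueError("no age bin is populated in both sites")
    q = raw / raw.sum()
    bins_a = [np.flatnonzero(ia == k) for k in range(n_bins)]
    bins_b = [np.flatnonzero(ib == k) for k in range(n_bins)]
    return SamplerPlan(edges=edges, q=q, bins_a=bins_a, bins_b=bins_b)


# ---------------------------------------------------------------------------
# pretraining and the CycleGAN loop
# ---------------------------------------------------------------------------

def _to_net(vol: Volume, scale: float) -> tuple[np.ndarray, np.ndarray]:
    x = (vol.data / scale).astype(np.float32)[None, None]
    return x, vol.mask.astype(np.float32)[None, None]


def pretrain_identity(gen: Generator, volumes: Sequence[Volume], steps: int,
                      seed: int = 0, lr: float = 1e-3,
                      intensity_scale: float = 500.0) -> list[float]:
    """Train ``gen`` to replicate its (masked) input with an L1 loss over the
    pooled volumes; returns the loss trace."""
    if not volumes:
        raise ValueError("need at least one volume")
    rng = np.random.default_rng(seed)
    opt = Adam(gen.parameters(), lr=lr, betas=(0.5, 0.999))
    trace = []
    for _ in range(steps):
        vol = volumes[int(rng.integers(len(volumes)))]
        x, m = _to_net(vol, intensity_scale)
        xt = Tensor(x)
        out = masked_forward(gen, xt, m)
        loss = ad.mean_(ad.abs_(ad.sub(out, Tensor(x * m))))
        gen.zero_grad()
        loss.backward()
        opt.step()
        trace.append(loss.item())
    return trace


def harmonize_volume(gen: Generator, vol: Volume,
                     intensity_scale: float = 500.0) -> Volume:
    """Masked generation on the network's intensity scale.

    Divides by the brain-median target, applies the generator, re-applies the
    brain mask and rescales back to intensity units.
    """
    from .nets import masked_generate
    scaled = vol.copy_with(vol.data / intensity_scale)
    out = masked_generate(gen, scaled)
    return out.copy_with(out.data * intensity_scale)


@dataclasses.dataclass
class TrainResult:
    g_ab: Generator
    g_ba: Generator
    d_a: Discriminator
    d_b: Discriminator
    trace: "object"                   # pandas DataFrame of per-step losses


def _lsgan(pred: Tensor, target: float) -> Tensor:
    return ad.mean_(ad.square(ad.add_scalar(pred, -target)))


def train_cyclegan(vols_a: Sequence[Volume], vols_b: Sequence[Volume],
                   cfg: TrainingConfig,
                   gen_spec: GeneratorSpec | None = None,
                   disc_spec: DiscriminatorSpec | None = None,
                   plan: SamplerPlan | None = None,
                   init_state: dict | None = None,
                   pretrain_steps: int = 0) -> TrainResult:
    """Train the two-generator / two-discriminator CycleGAN.

    ``vols_a``/``vols_b`` are preprocessed (median-normalized, dims divisible
    by 2^depth).  ``plan`` enables age-balanced sampling.  ``init_state`` is
    a generator state dict (e.g. from identity pretraining) used to
    initialize both generators; alternatively ``pretrain_steps > 0`` runs the
    identity pretraining internally on the pooled sites.

    Harmonization direction: B is the reference domain — at inference only
    G(A→B) is applied, and reference-site images are never modified.
    """
    import pandas as pd

    gen_spec = gen_spec or GeneratorSpec()
    disc_spec = disc_spec or DiscriminatorSpec()
    rng = np.random.default_rng(cfg.seed)
    if cfg.mixed_precision:
        ad.set_storage_dtype(np.float16)
    try:
        g_ab = Generator(gen_spec, seed=int(rng.integers(2 ** 31)))
        g_ba = Generator(gen_spec, seed=int(rng.integers(2 ** 31)))
        d_a = Discriminator(disc_spec, seed=int(rng.integers(2 ** 31)))
        d_b = Discriminator(disc_spec, seed=int(rng.integers(2 ** 31)))

        if init_state is None and pretrain_steps > 0:
            pre = Generator(gen_spec, seed=int(rng.integers(2 ** 31)))
            pretrain_identity(pre, list(vols_a) + list(vols_b), pretrain_steps,
                              seed=int(rng.integers(2 ** 31)),
                              intensity_scale=cfg.intensity_scale)
            init_state = pre.state_dict()
        if init_state is not None:
            g_ab.load_state_dict(init_state)
            g_ba.load_state_dict(init_state)

        opt_g = Adam(g_ab.parameters() + g_ba.parameters(),
                     lr=cfg.learning_rate, betas=cfg.betas)
        d_lr = cfg.disc_learning_rate if cfg.disc_learning_rate is not None \
            else cfg.learning_rate
        opt_da = Adam(d_a.parameters(), lr=d_lr, betas=cfg.betas)
        opt_db = Adam(d_b.parameters(), lr=d_lr, betas=cfg.betas)
        buf_a = HistoryBuffer(cfg.buffer_capacity, rng)   # fakes in domain A
        buf_b = HistoryBuffer(cfg.buffer_capacity, rng)   # fakes in domain B

        xa = [_to_net(v, cfg.intensity_scale) for v in vols_a]
        xb = [_to_net(v, cfg.intensity_scale) for v in vols_b]
        reals_a = [x * m for x, m in xa]
        reals_b = [x * m for x, m in xb]

        # Discriminator warm-up: standard discriminator updates against the
        # (identity-initialized) generators' fakes, before any generator
        # update.  At desk scale this gives the generators a meaningful
        # adversarial gradient from the first joint step.
        for _ in range(cfg.disc_warmup_steps):
            i = int(rng.integers(len(vols_a)))
            j = int(rng.integers(len(vols_b)))
            fb = (g_ab(Tensor(reals_a[i])).data * xa[i][1]).astype(np.float32)
            fa = (g_ba(Tensor(reals_b[j])).data * xb[j][1]).astype(np.float32)
            for d_, opt_, buf_, reals, new in (
                    (d_b, opt_db, buf_b, reals_b, fb[0, 0]),
                    (d_a, opt_da, buf_a, reals_a, fa[0, 0])):
                imgs, lab = compose_disc_batch([x[0, 0] for x in reals],
                                               [new, new], buf_, cfg, rng)
                pred = d_(Tensor(imgs))
                t = Tensor(lab.reshape(-1, 1, 1, 1, 1).astype(np.float32))
                loss = ad.mean_(ad.square(ad.sub(pred, t)))
                d_.zero_grad()
                loss.backward()
                opt_.step()

        # optional Polyak averaging: the returned generators carry an
        # exponential moving average of the weights, damping late-training
        # adversarial oscillation at inference time
        ema = None
        if cfg.gen_weight_ema > 0:
            ema = {name: {k: v.copy() for k, v in g.state_dict().items()}
                   for name, g in (("g_ab", g_ab), ("g_ba", g_ba))}

        rows = []
        for step in range(cfg.total_steps):
            lam = cycle_weight(step, cfg.total_steps,
                               cfg.cycle_weight_start, cfg.cycle_weight_end)
            if plan is not None:
                i, j = plan.sample(rng)
            else:
                i = int(rng.integers(len(vols_a)))
                j = int(rng.integers(len(vols_b)))
            a_np, ma = xa[i]
            b_np, mb = xb[j]
            at = Tensor(a_np * ma)
            bt = Tensor(b_np * mb)

            # --- generator update (batch 1 per direction) ------------------
            fake_b = masked_forward(g_ab, at, ma)
            rec_a = masked_forward(g_ba, fake_b, ma)
            fake_a = masked_forward(g_ba, bt, mb)
            rec_b = masked_forward(g_ab, fake_a, mb)
            adv = ad.add(_lsgan(d_b(fake_b), 1.0), _lsgan(d_a(fake_a), 1.0))
            cyc = ad.add(ad.mean_(ad.abs_(ad.sub(rec_a, at))),
                         ad.mean_(ad.abs_(ad.sub(rec_b, bt))))
            g_loss = ad.add(adv, ad.scale(cyc, lam))
            for m_ in (g_ab, g_ba, d_a, d_b):
                m_.zero_grad()
            g_loss.backward()
            opt_g.step()

            # --- discriminator updates ------------------------------------
            # the two most recent generations serve as the "newly-generated"
            # pair (batch-1 generators emit one fake per direction per step)
            if step == 0:
                prev_b, prev_a = fake_b.data[0, 0], fake_a.data[0, 0]
            new_b = [fake_b.data[0, 0], prev_b]
            new_a = [fake_a.data[0, 0], prev_a]
            prev_b, prev_a = fake_b.data[0, 0], fake_a.data[0, 0]
            db_imgs, db_lab = compose_disc_batch([x[0, 0] for x in reals_b],
                                                 new_b, buf_b, cfg, rng)
            da_imgs, da_lab = compose_disc_batch([x[0, 0] for x in reals_a],
                                                 new_a, buf_a, cfg, rng)

            def disc_step(d, opt, imgs, lab):
                pred = d(Tensor(imgs))
                t = Tensor(lab.reshape(-1, 1, 1, 1, 1).astype(np.float32))
                loss = ad.mean_(ad.square(ad.sub(pred, t)))
                d.zero_grad()
                loss.backward()
                opt.step()
                return loss.item()

            db_loss = disc_step(d_b, opt_db, db_imgs, db_lab)
            da_loss = disc_step(d_a, opt_da, da_imgs, da_lab)

            losses = {"step": step, "lambda": lam, "g_adv": adv.item(),
                      "g_cycle": cyc.item(), "g_total": g_loss.item(),
                      "d_a": da_loss, "d_b": db_loss}
            if not all(np.isfinite(v) for v in losses.values()):
                raise NonFiniteLossError(step, losses, pd.DataFrame(rows))
            rows.append(losses)
            if ema is not None:
                d = cfg.gen_weight_ema
                for name, g in (("g_ab", g_ab), ("g_ba", g_ba)):
                    for k, p in g.params.items():
                        ema[name][k] *= d
                        ema[name][k] += (1.0 - d) * p.data
        if ema is not None:
            g_ab.load_state_dict(ema["g_ab"])
            g_ba.load_state_dict(ema["g_ba"])
    finally:
        ad.set_storage_dtype(np.float32)

    return TrainResult(g_ab=g_ab, g_ba=g_ba, d_a=d_a, d_b=d_b,
                       trace=pd.DataFrame(rows))
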