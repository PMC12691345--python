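"""Desk-scale trainable models, in plain NumPy.

The training contract is minimal: a model maps a preprocessed image batch
``(B, 1, H, W)`` to a logit batch ``(B, n_out)`` (``n_out = N`` for
softmax-head losses, ``N - 1`` for binary-task heads) and can apply gradient
updates given ``dL/dlogits``. :class:`SmallCNN` — three conv/ReLU/max-pool
blocks and a linear head — fills that contract for the synthetic cohorts;
larger backbones can be plugged in behind the same interface.

Convolutions are 3x3, stride 1, zero-padded, implemented by stacking the nine
shifted views of the padded input (im2col) and contracting with the kernel
matrix; the backward pass scatters the column gradients back. Adam with
decoupled-style L2 (weight decay added to the gradient) is the only optimiser.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = ["SmallCNN", "Adam"]


def _im2col(xp: np.ndarray, h: int, w: int) -> np.ndarray:
    """(B, C, h+2, w+2) padded input -> (B, C, 9, h*w) column stack."""
    views = [xp[:, :, ky : ky + h, kx : kx + w] for ky, kx in product(range(3), range(3))]
    return np.stack(views, axis=2).reshape(xp.shape[0], -1, h * w)


class SmallCNN:
    """3-block CNN: [conv3x3 -> ReLU -> maxpool2] x 3 -> linear head.

    ``channels`` are the per-block filter counts; the input side length must
    be divisible by 8. He-initialised from a seeded generator so runs are
    reproducible.
    """

    def __init__(
        self,
        image_size: tuple[int, int],
        n_out: int,
        channels: tuple[int, int, int] = (8, 16, 32),
        seed: int = 0,
        dtype: np.dtype | type = np.float32,
    ) -> None:
        h, w = image_size
        if h % 8 or w % 8:
            raise ValueError("image side lengths must be divisible by 8")
        rng = np.random.default_rng(seed)
        self.image_size = (h, w)
        self.channels = channels
        self.n_out = n_out
        self.dtype = np.dtype(dtype)  # float32 default; float64 for gradient checks
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for i, c_out in enumerate(channels):
            fan_in = c_in * 9
            self.params[f"W{i}"] = (
                rng.standard_normal((c_out, c_in, 3, 3)) * np.sqrt(2.0 / fan_in)
            ).astype(self.dtype)
            self.params[f"b{i}"] = np.zeros(c_out, dtype=self.dtype)
            c_in = c_out
        feat = channels[-1] * (h // 8) * (w // 8)
        self.params["Wf"] = (
            rng.standard_normal((feat, n_out)) * np.sqrt(2.0 / feat)
        ).astype(self.dtype)
        self.params["bf"] = np.zeros(n_out, dtype=self.dtype)
        self._cache: dict = {}

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch ``(B, 1, H, W)``; caches activations if train."""
        a = np.asarray(x, dtype=self.dtype)
        cache: dict = {"x": a}
        for i in range(len(self.channels)):
            w = self.params[f"W{i}"]
            b, c, hh, ww = a.shape[0], a.shape[1], a.shape[2], a.shape[3]
            xp = np.pad(a, ((0, 0), (0, 0), (1, 1), (1, 1)))
            cols = _im2col(xp, hh, ww)  # (B, C*9, H*W)
            wmat = w.reshape(w.shape[0], -1)
            z = wmat @ cols + self.params[f"b{i}"][:, None]  # batched BLAS matmul
            z = z.reshape(b, w.shape[0], hh, ww)
            r = np.maximum(z, 0.0)
            # 2x2 max pool with argmax bookkeeping
            h2, w2 = hh // 2, ww // 2
            rr = r.reshape(b, w.shape[0], h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
            rr = rr.reshape(b, w.shape[0], h2, w2, 4)
            amax = rr.argmax(axis=-1)
            pooled = np.take_along_axis(rr, amax[..., None], axis=-1)[..., 0]
            cache[f"cols{i}"], cache[f"z{i}"] = cols, z
            cache[f"amax{i}"], cache[f"rshape{i}"] = amax, r.shape
            a = pooled
        cache["feat_shape"] = a.shape
        flat = a.reshape(a.shape[0], -1)
        cache["flat"] = flat
        logits = flat @ self.params["Wf"] + self.params["bf"]
        if train:
            self._cache = cache
        return logits

    # -- backward ----------------------------------------------------------

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the cached forward pass wrt every parameter."""
        cache = self._cache
        dlogits = np.asarray(dlogits, dtype=self.dtype)
        grads: dict[str, np.ndarray] = {}
        flat = cache["flat"]
        grads["Wf"] = flat.T @ dlogits
        grads["bf"] = dlogits.sum(axis=0)
        da = (dlogits @ self.params["Wf"].T).reshape(cache["feat_shape"])
        for i in reversed(range(len(self.channels))):
            b, c_out, hh, ww = cache["rshape{}".format(i)]
            h2, w2 = hh // 2, ww // 2
            # un-pool: route gradient to the argmax of each 2x2 window
            drr = np.zeros((b, c_out, h2, w2, 4), dtype=self.dtype)
            np.put_along_axis(drr, cache[f"amax{i}"][..., None], da[..., None], axis=-1)
            dr = (
                drr.reshape(b, c_out, h2, w2, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(b, c_out, hh, ww)
            )
            dz = dr * (cache[f"z{i}"] > 0)
            dzf = dz.reshape(b, c_out, hh * ww)
            cols = cache[f"cols{i}"]
            wmat = self.params[f"W{i}"].reshape(c_out, -1)
            grads[f"W{i}"] = (dzf @ cols.transpose(0, 2, 1)).sum(axis=0).reshape(
                self.params[f"W{i}"].shape
            )
            grads[f"b{i}"] = dzf.sum(axis=(0, 2))
            if i == 0:
                break  # input gradient not needed
            dcols = wmat.T @ dzf
            c_in = self.params[f"W{i}"].shape[1]
            dcols = dcols.reshape(b, c_in, 3, 3, hh, ww)
            dxp = np.zeros((b, c_in, hh + 2, ww + 2), dtype=self.dtype)
            for ky, kx in product(range(3), range(3)):
                dxp[:, :, ky : ky + hh, kx : kx + ww] += dcols[:, :, ky, kx]
            da = dxp[:, :, 1:-1, 1:-1]
        return grads

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k] = v.copy()


class Adam:
    """Adam with conventional betas and additive L2 weight decay."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, g in grads.items():
            if self.wd and not k.startswith("b"):
                g = g + self.wd * params[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
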