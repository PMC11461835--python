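"""Layer-2 (feature-level) augmentation: a conditional tabular GAN.

The model follows the CTGAN recipe for mixed tabular data:

* **mode-specific normalization** — each continuous column is fitted with a
  variational Gaussian mixture (≤ ``max_modes`` modes, low-weight modes
  pruned); a value is encoded as a scalar normalized within its most
  responsible mode, ``alpha = (v - mu_k) / (4 sigma_k)``, plus a one-hot
  mode indicator;
* **condition vectors** — categorical columns are one-hot blocks; during
  training a (column, category) pair is sampled by log-frequency and the
  real batch is drawn from rows carrying that category
  (training-by-sampling), and the condition is concatenated to both the
  generator input and the discriminator input;
* **adversarial training** — fully connected generator and discriminator
  (two hidden layers of 256, latent dimension 128, pac 10) trained with
  the non-saturating cross-entropy GAN loss plus a condition
  cross-entropy term on the generator's categorical outputs.

Networks, backpropagation and the Adam optimizer are implemented directly
on numpy arrays.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import BayesianGaussianMixture

_STD_FLOOR = 1e-6
_GUMBEL_TAU = 0.2
_MODE_WEIGHT_MIN = 0.005


# --------------------------------------------------------------------------
# mode-specific normalization
# --------------------------------------------------------------------------

@dataclass
class _ColumnModes:
    name: str
    weights: np.ndarray
    means: np.ndarray
    stds: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.weights)


@dataclass
class ModeNormalizer:
    """Per-column Gaussian-mixture encoder for mixed tabular rows."""

    continuous: list[_ColumnModes] = field(default_factory=list)
    categorical: dict[str, list] = field(default_factory=dict)
    columns: list[str] = field(default_factory=list)

    @classmethod
    def fit(
        cls,
        table: pd.DataFrame,
        discrete_columns: tuple[str, ...] = (),
        max_modes: int = 10,
        seed: int = 0,
        fit_rows: int = 1000,
    ) -> "ModeNormalizer":
        """Fit the mixture of every continuous column and list categories.

        Continuous fits use a Bayesian Gaussian mixture on at most
        ``fit_rows`` subsampled values; modes below weight 0.005 are
        pruned.  A constant column degenerates to a single mode with a
        floored standard deviation.
        """
        if len(table) < 2:
            raise ValueError("need at least 2 rows to fit the normalizer")
        self = cls(columns=list(table.columns))
        rng = np.random.default_rng(seed)
        for col in table.columns:
            if col in discrete_columns:
                self.categorical[col] = sorted(table[col].astype(str).unique())
                continue
            v = table[col].to_numpy(dtype=np.float64)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"continuous column {col!r} has non-finite values")
            if v.std() == 0.0:
                self.continuous.append(
                    _ColumnModes(col, np.array([1.0]), np.array([v[0]]),
                                 np.array([_STD_FLOOR]))
                )
                continue
            sub = v if len(v) <= fit_rows else rng.choice(v, fit_rows, replace=False)
            with warnings.catch_warnings():
                # the capped EM iteration budget is intentional
                warnings.simplefilter("ignore", ConvergenceWarning)
                bgm = BayesianGaussianMixture(
                    n_components=min(max_modes, len(np.unique(sub))),
                    weight_concentration_prior=1e-3,
                    max_iter=1000,
                    n_init=3,
                    random_state=seed % 2**31,
                ).fit(sub[:, None])
            keep = bgm.weights_ > _MODE_WEIGHT_MIN
            w = bgm.weights_[keep]
            self.continuous.append(
                _ColumnModes(
                    col,
                    w / w.sum(),
                    bgm.means_.ravel()[keep],
                    np.maximum(np.sqrt(bgm.covariances_.ravel()[keep]), _STD_FLOOR),
                )
            )
        return self

    # ---- encoded layout ---------------------------------------------------

    @property
    def encoded_dim(self) -> int:
        d = sum(1 + c.n_modes for c in self.continuous)
        return d + sum(len(cats) for cats in self.categorical.values())

    @property
    def cond_dim(self) -> int:
        return sum(len(cats) for cats in self.categorical.values())

    def _mode_of(self, cm: _ColumnModes, v: np.ndarray) -> np.ndarray:
        # responsibility argmax: deterministic mode assignment
        logp = (
            np.log(cm.weights)[None, :]
            - 0.5 * ((v[:, None] - cm.means[None, :]) / cm.stds[None, :]) ** 2
            - np.log(cm.stds)[None, :]
        )
        return np.argmax(logp, axis=1)

    def encode(self, table: pd.DataFrame) -> np.ndarray:
        """Encode rows into the (alpha, mode one-hot, category one-hot) layout."""
        n = len(table)
        parts = []
        for cm in self.continuous:
            v = table[cm.name].to_numpy(dtype=np.float64)
            k = self._mode_of(cm, v)
            alpha = (v - cm.means[k]) / (4.0 * cm.stds[k])
            onehot = np.zeros((n, cm.n_modes))
            onehot[np.arange(n), k] = 1.0
            parts.append(alpha[:, None])
            parts.append(onehot)
        for col, cats in self.categorical.items():
            idx = {c: i for i, c in enumerate(cats)}
            onehot = np.zeros((n, len(cats)))
            for row, val in enumerate(table[col].astype(str)):
                if val not in idx:
                    raise ValueError(f"unknown category {val!r} in column {col!r}")
                onehot[row, idx[val]] = 1.0
            parts.append(onehot)
        return np.hstack(parts)

    def decode(self, encoded: np.ndarray) -> pd.DataFrame:
        """Invert :meth:`encode`; mode and category by argmax."""
        out: dict[str, np.ndarray | list] = {}
        pos = 0
        for cm in self.continuous:
            alpha = encoded[:, pos]
            onehot = encoded[:, pos + 1 : pos + 1 + cm.n_modes]
            k = np.argmax(onehot, axis=1)
            out[cm.name] = alpha * 4.0 * cm.stds[k] + cm.means[k]
            pos += 1 + cm.n_modes
        for col, cats in self.categorical.items():
            block = encoded[:, pos : pos + len(cats)]
            out[col] = [cats[i] for i in np.argmax(block, axis=1)]
            pos += len(cats)
        return pd.DataFrame(out)[self.columns]


def fit_normalizer(
    table: pd.DataFrame,
    discrete_columns: tuple[str, ...] = (),
    max_modes: int = 10,
    seed: int = 0,
) -> ModeNormalizer:
    """Convenience wrapper over :meth:`ModeNormalizer.fit`."""
    return ModeNormalizer.fit(table, discrete_columns, max_modes, seed)


# --------------------------------------------------------------------------
# numpy MLP with manual backprop + Adam
# --------------------------------------------------------------------------

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


class _MLP:
    """Fully connected stack with manual backprop and Adam.

    Hidden layers optionally apply batch normalization (generator) or
    leaky-ReLU + dropout (discriminator); the output layer is linear.
    """

    def __init__(self, rng: np.random.Generator, sizes: list[int],
                 batchnorm: bool = False, leaky: float = 0.0,
                 dropout: float = 0.0):
        self.batchnorm = batchnorm
        self.leaky = leaky
        self.dropout = dropout
        n_hidden = len(sizes) - 2
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.gamma = [np.ones(sizes[i + 1]) for i in range(n_hidden)]
        self.beta = [np.zeros(sizes[i + 1]) for i in range(n_hidden)]
        self.run_mean = [np.zeros(sizes[i + 1]) for i in range(n_hidden)]
        self.run_var = [np.ones(sizes[i + 1]) for i in range(n_hidden)]
        params = self._params()
        self._adam = [[np.zeros_like(p) for p in params],
                      [np.zeros_like(p) for p in params]]
        self._t = 0

    def _params(self):
        return self.W + self.b + self.gamma + self.beta

    def forward(self, x: np.ndarray, train: bool = True,
                rng: np.random.Generator | None = None) -> np.ndarray:
        self._cache = []
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            layer = {"x": h}
            if i < last:
                if self.batchnorm:
                    if train:
                        mu = z.mean(axis=0)
                        var = z.var(axis=0)
                        self.run_mean[i] = (_BN_MOMENTUM * self.run_mean[i]
                                            + (1 - _BN_MOMENTUM) * mu)
                        self.run_var[i] = (_BN_MOMENTUM * self.run_var[i]
                                           + (1 - _BN_MOMENTUM) * var)
                    else:
                        mu, var = self.run_mean[i], self.run_var[i]
                    std = np.sqrt(var + _BN_EPS)
                    zhat = (z - mu) / std
                    layer.update(zhat=zhat, std=std, z_centered=z - mu)
                    z = self.gamma[i] * zhat + self.beta[i]
                a = np.where(z > 0, z, self.leaky * z)
                layer["pre_act"] = z
                if self.dropout > 0 and train:
                    if rng is None:
                        raise RuntimeError("dropout needs an rng in training mode")
                    mask = (rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
                    a = a * mask
                    layer["drop_mask"] = mask
                h = a
            else:
                h = z
            self._cache.append(layer)
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Gradient wrt input; stores parameter grads for the next step()."""
        n_layers = len(self.W)
        self._gW = [None] * n_layers
        self._gb = [None] * n_layers
        self._ggamma = [np.zeros_like(g) for g in self.gamma]
        self._gbeta = [np.zeros_like(g) for g in self.beta]
        d = dout
        for i in range(n_layers - 1, -1, -1):
            layer = self._cache[i]
            if i < n_layers - 1:
                if "drop_mask" in layer:
                    d = d * layer["drop_mask"]
                pre = layer["pre_act"]
                d = d * np.where(pre > 0, 1.0, self.leaky)
                if self.batchnorm:
                    zhat, std = layer["zhat"], layer["std"]
                    m = zhat.shape[0]
                    self._ggamma[i] = (d * zhat).sum(axis=0)
                    self._gbeta[i] = d.sum(axis=0)
                    dzhat = d * self.gamma[i]
                    # standard batchnorm input gradient
                    d = (dzhat - dzhat.mean(axis=0)
                         - zhat * (dzhat * zhat).mean(axis=0)) / std
            self._gW[i] = layer["x"].T @ d
            self._gb[i] = d.sum(axis=0)
            d = d @ self.W[i].T
        return d

    def step(self, lr: float = 2e-4, beta1: float = 0.5, beta2: float = 0.9,
             eps: float = 1e-8, weight_decay: float = 1e-6):
        self._t += 1
        params = self._params()
        grads = self._gW + self._gb + self._ggamma + self._gbeta
        m, v = self._adam
        for i, (p, g) in enumerate(zip(params, grads)):
            g = g + weight_decay * p
            m[i] = beta1 * m[i] + (1 - beta1) * g
            v[i] = beta2 * v[i] + (1 - beta2) * g * g
            mh = m[i] / (1 - beta1**self._t)
            vh = v[i] / (1 - beta2**self._t)
            p -= lr * mh / (np.sqrt(vh) + eps)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


# --------------------------------------------------------------------------
# CTGAN
# --------------------------------------------------------------------------

class CTGAN:
    """Conditional tabular GAN over a labeled feature table.

    Parameters mirror the reference architecture: latent dimension 128,
    two 256-wide hidden layers in both networks, pac 10.  ``fit`` then
    ``sample``; ``save``/``load`` round-trip the trained model through a
    single ``.npz`` archive.
    """

    def __init__(
        self,
        embedding_dim: int = 128,
        gen_dims: tuple[int, int] = (256, 256),
        dis_dims: tuple[int, int] = (256, 256),
        pac: int = 10,
        lr: float = 2e-4,
        max_modes: int = 10,
    ):
        self.embedding_dim = embedding_dim
        self.gen_dims = tuple(gen_dims)
        self.dis_dims = tuple(dis_dims)
        self.pac = pac
        self.lr = lr
        self.max_modes = max_modes
        self.normalizer: ModeNormalizer | None = None
        self.loss_history: list[tuple[float, float]] = []
        self._gen: _MLP | None = None
        self._dis: _MLP | None = None

    # ---- activation bookkeeping -------------------------------------------

    def _slots(self):
        """(kind, start, stop) activation slots of the generator output."""
        slots = []
        pos = 0
        nz = self.normalizer
        for cm in nz.continuous:
            slots.append(("tanh", pos, pos + 1))
            slots.append(("softmax", pos + 1, pos + 1 + cm.n_modes))
            pos += 1 + cm.n_modes
        for col, cats in nz.categorical.items():
            slots.append(("cat_softmax", pos, pos + len(cats)))
            pos += len(cats)
        return slots

    def _activate(self, raw: np.ndarray, rng: np.random.Generator, hard: bool):
        """Apply per-slot output activations; returns (row, cache)."""
        out = np.empty_like(raw)
        cache = []
        for kind, a, b in self._slots():
            block = raw[:, a:b]
            if kind == "tanh":
                y = np.tanh(block)
                out[:, a:b] = y
                cache.append((kind, a, b, y))
            else:
                if hard:
                    y = _softmax(block)
                    oh = np.zeros_like(y)
                    oh[np.arange(len(y)), np.argmax(y, axis=1)] = 1.0
                    out[:, a:b] = oh
                    cache.append((kind, a, b, y))
                else:
                    g = rng.gumbel(size=block.shape)
                    y = _softmax((block + g) / _GUMBEL_TAU)
                    out[:, a:b] = y
                    cache.append((kind, a, b, y))
        return out, cache

    @staticmethod
    def _activation_grad(cache, dout: np.ndarray) -> np.ndarray:
        draw = np.zeros_like(dout)
        for kind, a, b, y in cache:
            d = dout[:, a:b]
            if kind == "tanh":
                draw[:, a:b] = d * (1.0 - y**2)
            else:
                s = (d * y).sum(axis=1, keepdims=True)
                draw[:, a:b] = (y * (d - s)) / _GUMBEL_TAU
        return draw

    # ---- condition sampling -----------------------------------------------

    def _cond_blocks(self):
        blocks = []
        pos = 0
        for col, cats in self.normalizer.categorical.items():
            blocks.append((col, cats, pos))
            pos += len(cats)
        return blocks

    def _category_probs(self, table: pd.DataFrame, log_freq: bool):
        probs = {}
        for col, cats, _ in self._cond_blocks():
            counts = table[col].astype(str).value_counts()
            if log_freq:
                w = np.array([np.log1p(counts.get(c, 0)) for c in cats])
            else:
                w = np.array([counts.get(c, 0) for c in cats], dtype=float)
            probs[col] = w / w.sum()
        return probs

    # ---- training ---------------------------------------------------------

    def fit(
        self,
        table: pd.DataFrame,
        discrete_columns: tuple[str, ...] = ("label",),
        epochs: int = 2000,
        batch_size: int = 500,
        seed: int = 0,
    ) -> "CTGAN":
        discrete_columns = tuple(c for c in discrete_columns if c in table.columns)
        self._train_columns = list(table.columns)
        self.normalizer = ModeNormalizer.fit(
            table, discrete_columns, self.max_modes, seed
        )
        data = self.normalizer.encode(table)
        n, d = data.shape
        batch = max(self.pac, min(batch_size, n))
        batch -= batch % self.pac
        if batch < self.pac:
            raise ValueError(f"table of {n} rows is smaller than one pac group")
        rng = np.random.default_rng(seed)
        cond_dim = self.normalizer.cond_dim
        self._gen = _MLP(
            rng, [self.embedding_dim + cond_dim, *self.gen_dims, d],
            batchnorm=True,
        )
        self._dis = _MLP(
            rng, [(d + cond_dim) * self.pac, *self.dis_dims, 1],
            leaky=0.2, dropout=0.5,
        )
        self._empirical_probs = self._category_probs(table, log_freq=False)
        train_probs = self._category_probs(table, log_freq=True)
        blocks = self._cond_blocks()

        # row indices per (column, category) for training-by-sampling
        row_pool = {
            (col, c): np.flatnonzero(table[col].astype(str).to_numpy() == c)
            for col, cats, _ in blocks
            for c in cats
        }

        steps = max(1, n // batch)
        self.loss_history = []
        for _epoch in range(epochs):
            dl_sum = gl_sum = 0.0
            for _step in range(steps):
                cond, real_idx = self._sample_conditions(
                    rng, batch, blocks, train_probs, row_pool
                )
                real = data[real_idx]
                z = rng.standard_normal((batch, self.embedding_dim))
                # --- discriminator step
                raw = self._gen.forward(np.hstack([z, cond]))
                fake, cache = self._activate(raw, rng, hard=False)
                d_in_real = self._pack(real, cond)
                d_in_fake = self._pack(fake, cond)
                # forward() caches only the last pass, so grad the two
                # halves in one packed batch
                both = np.vstack([d_in_real, d_in_fake])
                logits = self._dis.forward(both, train=True, rng=rng).ravel()
                bsz = len(d_in_real)
                dlog = np.empty_like(logits)
                dlog[:bsz] = -_sigmoid(-logits[:bsz]) / bsz
                dlog[bsz:] = _sigmoid(logits[bsz:]) / bsz
                self._dis.backward(dlog[:, None])
                self._dis.step(self.lr)
                d_loss = float(
                    np.mean(np.logaddexp(0, -logits[:bsz]))
                    + np.mean(np.logaddexp(0, logits[bsz:]))
                )
                # --- generator step
                z = rng.standard_normal((batch, self.embedding_dim))
                raw = self._gen.forward(np.hstack([z, cond]))
                fake, cache = self._activate(raw, rng, hard=False)
                d_in_fake = self._pack(fake, cond)
                l_fake = self._dis.forward(d_in_fake, train=True, rng=rng).ravel()
                g_adv = float(np.mean(np.logaddexp(0, -l_fake)))
                dlog = (-_sigmoid(-l_fake) / len(l_fake))[:, None]
                d_input_grad = self._dis.backward(dlog)
                dfake = self._unpack_grad(d_input_grad, fake.shape[1])
                draw = self._activation_grad(cache, dfake)
                # condition cross-entropy on the categorical logits
                g_ce = 0.0
                cat_slots = [s for s in self._slots() if s[0] == "cat_softmax"]
                for (col, cats, cpos), slot in zip(blocks, cat_slots):
                    a, b = slot[1], slot[2]
                    sm = _softmax(raw[:, a:b])
                    onehot = cond[:, cpos : cpos + len(cats)]
                    g_ce += float(
                        -np.mean(np.sum(onehot * np.log(sm + 1e-12), axis=1))
                    )
                    draw[:, a:b] += (sm - onehot) / batch
                self._gen.backward(draw)
                self._gen.step(self.lr)
                dl_sum += d_loss
                gl_sum += g_adv + g_ce
            self.loss_history.append((dl_sum / steps, gl_sum / steps))
            if not np.isfinite(self.loss_history[-1]).all():
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {_epoch}"
                )
        return self

    def _sample_conditions(self, rng, batch, blocks, probs, row_pool):
        """Training-by-sampling: one (column, category) per row in the batch."""
        if not blocks:
            raise ValueError("conditional training needs at least one discrete column")
        cond = np.zeros((batch, self.normalizer.cond_dim))
        real_idx = np.empty(batch, dtype=int)
        col_choice = rng.integers(0, len(blocks), batch)
        for i in range(batch):
            col, cats, cpos = blocks[col_choice[i]]
            k = rng.choice(len(cats), p=probs[col])
            cond[i, cpos + k] = 1.0
            pool = row_pool[(col, cats[k])]
            real_idx[i] = pool[rng.integers(0, len(pool))]
        return cond, real_idx

    def _pack(self, rows: np.ndarray, cond: np.ndarray) -> np.ndarray:
        x = np.hstack([rows, cond])
        return x.reshape(len(x) // self.pac, -1)

    def _unpack_grad(self, packed_grad: np.ndarray, row_dim: int) -> np.ndarray:
        g = packed_grad.reshape(-1, row_dim + self.normalizer.cond_dim)
        return g[:, :row_dim]

    # ---- sampling ---------------------------------------------------------

    def sample(
        self,
        n: int = 10000,
        condition: str | None = None,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Draw ``n`` synthetic rows; optional hard class condition.

        Unconditionally, conditions are drawn from the empirical category
        frequencies of the training table, so marginal class frequencies
        are reproduced.  The emitted categorical value is the condition
        the row was generated under, which makes conditional sampling
        100% compliant by construction.
        """
        if self.normalizer is None:
            raise RuntimeError("model is not fitted")
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        blocks = self._cond_blocks()
        cond = np.zeros((n, self.normalizer.cond_dim))
        chosen: dict[str, list[str]] = {col: [] for col, _, _ in blocks}
        for col, cats, cpos in blocks:
            if condition is not None:
                if condition not in cats:
                    raise ValueError(
                        f"unknown condition {condition!r}; column {col!r} "
                        f"has categories {cats}"
                    )
                ks = np.full(n, cats.index(condition))
            else:
                ks = rng.choice(len(cats), size=n, p=self._empirical_probs[col])
            cond[np.arange(n), cpos + ks] = 1.0
            chosen[col] = [cats[k] for k in ks]
        z = rng.standard_normal((n, self.embedding_dim))
        raw = self._gen.forward(np.hstack([z, cond]), train=False)
        rows, _ = self._activate(raw, rng, hard=True)
        df = self.normalizer.decode(rows)
        for col, vals in chosen.items():
            df[col] = vals
        return df

    # ---- persistence ------------------------------------------------------

    def save(self, path: str) -> None:
        """Serialize weights and normalizer into one ``.npz`` archive."""
        nz = self.normalizer
        meta = {
            "embedding_dim": self.embedding_dim,
            "gen_dims": list(self.gen_dims),
            "dis_dims": list(self.dis_dims),
            "pac": self.pac,
            "lr": self.lr,
            "max_modes": self.max_modes,
            "columns": nz.columns,
            "categorical": nz.categorical,
            "cont_names": [c.name for c in nz.continuous],
            "empirical_probs": {k: list(v) for k, v in self._empirical_probs.items()},
        }
        arrays = {"meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for i, cm in enumerate(nz.continuous):
            arrays[f"cw{i}"] = cm.weights
            arrays[f"cm{i}"] = cm.means
            arrays[f"cs{i}"] = cm.stds
        for tag, net in (("g", self._gen), ("d", self._dis)):
            for i, W in enumerate(net.W):
                arrays[f"{tag}W{i}"] = W
            for i, b in enumerate(net.b):
                arrays[f"{tag}b{i}"] = b
            for name, group in (("ga", net.gamma), ("be", net.beta),
                                ("rm", net.run_mean), ("rv", net.run_var)):
                for i, p in enumerate(group):
                    arrays[f"{tag}{name}{i}"] = p
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "CTGAN":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            self = cls(
                embedding_dim=meta["embedding_dim"],
                gen_dims=tuple(meta["gen_dims"]),
                dis_dims=tuple(meta["dis_dims"]),
                pac=meta["pac"],
                lr=meta["lr"],
                max_modes=meta["max_modes"],
            )
            nz = ModeNormalizer(columns=meta["columns"])
            nz.categorical = meta["categorical"]
            for i, name in enumerate(meta["cont_names"]):
                nz.continuous.append(
                    _ColumnModes(name, z[f"cw{i}"], z[f"cm{i}"], z[f"cs{i}"])
                )
            self.normalizer = nz
            self._empirical_probs = {
                k: np.array(v) for k, v in meta["empirical_probs"].items()
            }
            rng = np.random.default_rng(0)
            d = nz.encoded_dim
            self._gen = _MLP(
                rng, [self.embedding_dim + nz.cond_dim, *self.gen_dims, d],
                batchnorm=True,
            )
            self._dis = _MLP(
                rng, [(d + nz.cond_dim) * self.pac, *self.dis_dims, 1],
                leaky=0.2, dropout=0.5,
            )
            for tag, net in (("g", self._gen), ("d", self._dis)):
                net.W = [z[f"{tag}W{i}"] for i in range(len(net.W))]
                net.b = [z[f"{tag}b{i}"] for i in range(len(net.b))]
                net.gamma = [z[f"{tag}ga{i}"] for i in range(len(net.gamma))]
                net.beta = [z[f"{tag}be{i}"] for i in range(len(net.beta))]
                net.run_mean = [z[f"{tag}rm{i}"] for i in range(len(net.run_mean))]
                net.run_var = [z[f"{tag}rv{i}"] for i in range(len(net.run_var))]
        return self


# --------------------------------------------------------------------------
# real-vs-fake validation
# --------------------------------------------------------------------------

def validate_synthetic(
    real: pd.DataFrame,
    fake: pd.DataFrame,
    mean_tol_sd: float = 0.5,
    corr_frob_tol: float = 5.0,
) -> dict:
    """Compare per-column means/stds and the correlation structure.

    Returns a report with per-column (mean_real, mean_fake, std_real,
    std_fake, absolute differences), the Frobenius norm of the difference
    of correlation matrices over numeric columns, and a pass flag: every
    column's |mean difference| must be within ``mean_tol_sd`` real
    standard deviations and the Frobenius norm within ``corr_frob_tol``.
    """
    num_cols = [c for c in real.columns if pd.api.types.is_numeric_dtype(real[c])]
    if list(real.columns) != list(fake.columns):
        raise ValueError("schema mismatch between real and fake tables")
    per_col = {}
    flags = {}
    for c in num_cols:
        mr, mf = float(real[c].mean()), float(fake[c].mean())
        sr, sf = float(real[c].std()), float(fake[c].std())
        per_col[c] = {
            "mean_real": mr, "mean_fake": mf, "abs_mean_diff": abs(mr - mf),
            "std_real": sr, "std_fake": sf, "abs_std_diff": abs(sr - sf),
        }
        scale = sr if sr > 0 else 1.0
        flags[c] = abs(mr - mf) <= mean_tol_sd * scale
    cr = real[num_cols].corr().fillna(0.0).to_numpy()
    cf = fake[num_cols].corr().fillna(0.0).to_numpy()
    frob = float(np.linalg.norm(cr - cf, "fro"))
    return {
        "columns": per_col,
        "column_pass": flags,
        "corr_frobenius": frob,
        "passed": bool(all(flags.values()) and frob <= corr_frob_tol),
    }
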