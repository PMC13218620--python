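"""Attention-fused multi-representation molecular similarity model.

The model scores the similarity of a molecule pair in (0, 1) by fusing
three representations per molecule:

* a SELFIES bag-of-tokens vector through a linear encoder,
* a Morgan fingerprint through linear → ReLU → dropout → batch norm,
* the six-descriptor vector through the same encoder stack,

all mapped to a shared hidden space.  A multi-head attention block uses
the SELFIES embedding as the query over the stacked fingerprint and
descriptor embeddings as keys/values, so the topological context decides
how much weight each modality gets.  The attended SELFIES output is
concatenated with the fingerprint and descriptor embeddings into a
per-molecule embedding of length 3·hidden_dim.

Pairs are scored symmetrically: the two molecules share encoder weights
(siamese), and the fusion head consumes ``[|e_a − e_b|, e_a ⊙ e_b]``
through an MLP with a final sigmoid.  Training minimises MSE against
{0,1} pair labels with Adam, halving the learning rate when validation
loss plateaus, with early stopping on the best validation weights.

The classical Tanimoto coefficient over fingerprint bits is provided as
the benchmark, along with top-k enrichment for screening evaluation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from ._autograd import Tensor, concat, relu, sigmoid
from .activity_rules import ActivityLabel
from .chem_io import LigandTable
from .featurize import FeatureBundle

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class FusionConfig:
    hidden_dim: int = 128
    n_heads: int = 4
    dropout: float = 0.2
    mlp_dims: tuple[int, ...] = (128, 32)
    lr: float = 1e-3
    max_epochs: int = 50
    batch_size: int = 64
    plateau_patience: int = 5
    early_stop_patience: int = 10
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class PairSample:
    a_idx: int
    b_idx: int
    label: int

    def __post_init__(self):
        if self.a_idx == self.b_idx:
            raise ValueError("a pair must join two distinct molecules")
        if self.label not in (0, 1):
            raise ValueError("pair label must be 0 or 1")


class _BatchNorm:
    """1-D batch normalisation with running statistics for eval mode."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta

    @property
    def params(self):
        return [self.gamma, self.beta]


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> Tensor:
    scale = math.sqrt(6.0 / (n_in + n_out))
    return Tensor(rng.uniform(-scale, scale, size=(n_in, n_out)), requires_grad=True)


class FusionModel:
    """Siamese encoder stack + attention fusion + pair-scoring head."""

    def __init__(
        self,
        selfies_dim: int,
        fp_dim: int,
        desc_dim: int = 6,
        config: FusionConfig | None = None,
        vocab: list[str] | None = None,
        radius: int = 2,
    ):
        self.config = config or FusionConfig()
        self.selfies_dim = selfies_dim
        self.fp_dim = fp_dim
        self.desc_dim = desc_dim
        self.vocab = list(vocab) if vocab is not None else None
        self.radius = radius
        self.history: dict = {}
        self.force_uniform_attention = False  # test hook

        h = self.config.hidden_dim
        rng = np.random.default_rng(self.config.seed)
        self.W_s, self.b_s = _glorot(rng, selfies_dim, h), Tensor(np.zeros(h), requires_grad=True)
        self.W_f, self.b_f = _glorot(rng, fp_dim, h), Tensor(np.zeros(h), requires_grad=True)
        self.W_d, self.b_d = _glorot(rng, desc_dim, h), Tensor(np.zeros(h), requires_grad=True)
        self.bn_f = _BatchNorm(h)
        self.bn_d = _BatchNorm(h)
        self.W_q, self.W_k, self.W_v, self.W_o = (_glorot(rng, h, h) for _ in range(4))
        self.b_o = Tensor(np.zeros(h), requires_grad=True)

        dims = [2 * 3 * h, *self.config.mlp_dims, 1]
        self.mlp_W = [_glorot(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
        self.mlp_b = [Tensor(np.zeros(b), requires_grad=True) for b in dims[1:]]
        self.mlp_bn = [_BatchNorm(b) for b in self.config.mlp_dims]

        # input scalers, fitted once from the training molecules
        self.desc_mean = np.zeros(desc_dim)
        self.desc_std = np.ones(desc_dim)
        self.selfies_scale = 1.0
        self._train_rng = np.random.default_rng(self.config.seed + 1)

    # -- parameters ------------------------------------------------------
    @property
    def parameters(self) -> list[Tensor]:
        ps = [self.W_s, self.b_s, self.W_f, self.b_f, self.W_d, self.b_d,
              self.W_q, self.W_k, self.W_v, self.W_o, self.b_o]
        ps += self.bn_f.params + self.bn_d.params
        for W, b in zip(self.mlp_W, self.mlp_b):
            ps += [W, b]
        for bn in self.mlp_bn:
            ps += bn.params
        return ps

    def fit_scalers(self, fp: np.ndarray, desc: np.ndarray, selfies: np.ndarray) -> None:
        """Fit descriptor z-scoring and SELFIES count scaling on training data."""
        self.desc_mean = desc.mean(axis=0)
        std = desc.std(axis=0)
        std[std < 1e-12] = 1.0
        self.desc_std = std
        self.selfies_scale = max(float(selfies.sum(axis=1).mean()), 1.0)

    # -- forward pass ----------------------------------------------------
    def _dropout(self, x: Tensor, training: bool) -> Tensor:
        p = self.config.dropout
        if not training or p == 0:
            return x
        mask = (self._train_rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    def embed(self, fp: np.ndarray, desc: np.ndarray, selfies: np.ndarray, training: bool = False) -> Tensor:
        """Per-molecule embedding of shape (batch, 3·hidden_dim)."""
        cfg = self.config
        h, H = cfg.hidden_dim, cfg.n_heads
        dh = h // H
        Xs = Tensor(np.atleast_2d(selfies) / self.selfies_scale)
        Xf = Tensor(np.atleast_2d(fp).astype(float))
        Xd = Tensor((np.atleast_2d(desc) - self.desc_mean) / self.desc_std)
        if Xs.shape[1] != self.selfies_dim or Xf.shape[1] != self.fp_dim or Xd.shape[1] != self.desc_dim:
            raise ValueError(
                f"feature dimensions {Xs.shape[1]}/{Xf.shape[1]}/{Xd.shape[1]} do not match "
                f"model config {self.selfies_dim}/{self.fp_dim}/{self.desc_dim}"
            )
        B = Xs.shape[0]

        q = Xs @ self.W_s + self.b_s
        f = self.bn_f(self._dropout(relu(Xf @ self.W_f + self.b_f), training), training)
        d = self.bn_d(self._dropout(relu(Xd @ self.W_d + self.b_d), training), training)

        qh = (q @ self.W_q).reshape(B, H, dh)
        kf = (f @ self.W_k).reshape(B, H, dh)
        kd = (d @ self.W_k).reshape(B, H, dh)
        vf = (f @ self.W_v).reshape(B, H, dh)
        vd = (d @ self.W_v).reshape(B, H, dh)

        if self.force_uniform_attention:
            wf = Tensor(np.full((B, H, 1), 0.5))
            wd = Tensor(np.full((B, H, 1), 0.5))
        else:
            sf = (qh * kf).sum(axis=2) * (1.0 / math.sqrt(dh))
            sd = (qh * kd).sum(axis=2) * (1.0 / math.sqrt(dh))
            shift = Tensor(np.maximum(sf.data, sd.data))  # stop-grad max for stability
            ef = (sf - shift).exp()
            ed = (sd - shift).exp()
            denom = ef + ed
            wf = (ef / denom).reshape(B, H, 1)
            wd = (ed / denom).reshape(B, H, 1)
        attended = (wf * vf + wd * vd).reshape(B, h) @ self.W_o + self.b_o
        return concat([attended, f, d], axis=1)

    def pair_logits(self, emb_a: Tensor, emb_b: Tensor, training: bool = False) -> Tensor:
        diff = (emb_a - emb_b).abs()
        prod = emb_a * emb_b
        z = concat([diff, prod], axis=1)
        for i, (W, b) in enumerate(zip(self.mlp_W, self.mlp_b)):
            z = z @ W + b
            if i < len(self.mlp_W) - 1:
                z = self.mlp_bn[i](self._dropout(relu(z), training), training)
        return z

    def score_pairs_raw(
        self,
        fp_a, desc_a, selfies_a,
        fp_b, desc_b, selfies_b,
        training: bool = False,
    ) -> Tensor:
        ea = self.embed(fp_a, desc_a, selfies_a, training)
        eb = self.embed(fp_b, desc_b, selfies_b, training)
        return sigmoid(self.pair_logits(ea, eb, training))

    # -- (de)serialisation ----------------------------------------------
    def _named_params(self) -> dict[str, Tensor]:
        named = {
            "W_s": self.W_s, "b_s": self.b_s, "W_f": self.W_f, "b_f": self.b_f,
            "W_d": self.W_d, "b_d": self.b_d, "W_q": self.W_q, "W_k": self.W_k,
            "W_v": self.W_v, "W_o": self.W_o, "b_o": self.b_o,
            "bn_f.gamma": self.bn_f.gamma, "bn_f.beta": self.bn_f.beta,
            "bn_d.gamma": self.bn_d.gamma, "bn_d.beta": self.bn_d.beta,
        }
        for i, (W, b) in enumerate(zip(self.mlp_W, self.mlp_b)):
            named[f"mlp_W{i}"] = W
            named[f"mlp_b{i}"] = b
        for i, bn in enumerate(self.mlp_bn):
            named[f"mlp_bn{i}.gamma"] = bn.gamma
            named[f"mlp_bn{i}.beta"] = bn.beta
        return named

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {k: v.data for k, v in self._named_params().items()}
        arrays["bn_f.running_mean"] = self.bn_f.running_mean
        arrays["bn_f.running_var"] = self.bn_f.running_var
        arrays["bn_d.running_mean"] = self.bn_d.running_mean
        arrays["bn_d.running_var"] = self.bn_d.running_var
        for i, bn in enumerate(self.mlp_bn):
            arrays[f"mlp_bn{i}.running_mean"] = bn.running_mean
            arrays[f"mlp_bn{i}.running_var"] = bn.running_var
        arrays["desc_mean"] = self.desc_mean
        arrays["desc_std"] = self.desc_std
        arrays["selfies_scale"] = np.array([self.selfies_scale])
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, t in self._named_params().items():
            t.data = np.array(arrays[k], dtype=np.float64)
        self.bn_f.running_mean = np.array(arrays["bn_f.running_mean"])
        self.bn_f.running_var = np.array(arrays["bn_f.running_var"])
        self.bn_d.running_mean = np.array(arrays["bn_d.running_mean"])
        self.bn_d.running_var = np.array(arrays["bn_d.running_var"])
        for i, bn in enumerate(self.mlp_bn):
            bn.running_mean = np.array(arrays[f"mlp_bn{i}.running_mean"])
            bn.running_var = np.array(arrays[f"mlp_bn{i}.running_var"])
        self.desc_mean = np.array(arrays["desc_mean"])
        self.desc_std = np.array(arrays["desc_std"])
        self.selfies_scale = float(np.asarray(arrays["selfies_scale"]).ravel()[0])

    def save(self, path) -> None:
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": {**asdict(self.config), "mlp_dims": list(self.config.mlp_dims)},
            "selfies_dim": self.selfies_dim,
            "fp_dim": self.fp_dim,
            "desc_dim": self.desc_dim,
            "radius": self.radius,
            "vocab": self.vocab,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **self.state_arrays())

    @classmethod
    def load(cls, path) -> "FusionModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(f"unsupported checkpoint format version {meta['format_version']}")
            cfg_d = dict(meta["config"])
            cfg_d["mlp_dims"] = tuple(cfg_d["mlp_dims"])
            model = cls(
                selfies_dim=meta["selfies_dim"],
                fp_dim=meta["fp_dim"],
                desc_dim=meta["desc_dim"],
                config=FusionConfig(**cfg_d),
                vocab=meta["vocab"],
                radius=meta["radius"],
            )
            model.load_state_arrays({k: z[k] for k in z.files if k != "__meta__"})
        return model


# -- public functional API ----------------------------------------------

def embed_molecule(model: FusionModel, bundle: FeatureBundle) -> np.ndarray:
    """Deterministic eval-mode embedding, length 3·hidden_dim."""
    return model.embed(bundle.fp, bundle.desc, bundle.selfies_vec, training=False).data[0]


def pair_score(model: FusionModel, bundle_a: FeatureBundle, bundle_b: FeatureBundle) -> float:
    """Symmetric similarity score strictly inside (0, 1)."""
    s = model.score_pairs_raw(
        bundle_a.fp, bundle_a.desc, bundle_a.selfies_vec,
        bundle_b.fp, bundle_b.desc, bundle_b.selfies_vec,
    )
    return float(s.data.ravel()[0])


def _bundles_to_arrays(bundles: Sequence[FeatureBundle]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    fp = np.vstack([b.fp for b in bundles]).astype(float)
    desc = np.vstack([b.desc for b in bundles])
    sv = np.vstack([b.selfies_vec for b in bundles])
    return fp, desc, sv


def build_pair_dataset(
    table: LigandTable,
    labels: Sequence[ActivityLabel],
    max_pairs: int | None = None,
    balance: bool = True,
    seed: int = 0,
) -> list[PairSample]:
    """Positive pairs high×high, negative pairs with ≥1 low member.

    Medium-activity molecules never enter a pair.  With ``balance`` the
    majority class is subsampled to the minority size; ``max_pairs``
    caps the total (split evenly between classes when balancing).
    """
    if len(labels) != len(table):
        raise ValueError("labels must align with the table")
    high = [i for i, l in enumerate(labels) if l.klass == "high"]
    low = [i for i, l in enumerate(labels) if l.klass == "low"]
    if len(high) < 2 or len(low) < 2:
        raise ValueError(f"need at least 2 high and 2 low molecules, got {len(high)} high / {len(low)} low")
    rng = np.random.default_rng(seed)
    positives = [PairSample(a, b, 1) for a, b in combinations(high, 2)]
    negatives = [PairSample(a, b, 0) for a, b in combinations(low, 2)]
    negatives += [PairSample(a, b, 0) for a in low for b in high]

    def subsample(pairs: list[PairSample], k: int) -> list[PairSample]:
        if k >= len(pairs):
            return list(pairs)
        idx = rng.choice(len(pairs), size=k, replace=False)
        return [pairs[i] for i in np.sort(idx)]

    if balance:
        per_class = min(len(positives), len(negatives))
        if max_pairs is not None:
            per_class = min(per_class, max_pairs // 2)
        positives = subsample(positives, per_class)
        negatives = subsample(negatives, per_class)
    elif max_pairs is not None and len(positives) + len(negatives) > max_pairs:
        allpairs = positives + negatives
        allpairs = subsample(allpairs, max_pairs)
        positives = [p for p in allpairs if p.label == 1]
        negatives = [p for p in allpairs if p.label == 0]
    return positives + negatives


class _Adam:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m[:] = self.b1 * m + (1 - self.b1) * p.grad
            v[:] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class TrainingDiverged(RuntimeError):
    pass


def train_fusion(
    model: FusionModel,
    pairs: Sequence[PairSample],
    bundles: Sequence[FeatureBundle],
    config: FusionConfig | None = None,
) -> FusionModel:
    """Train in place with Adam + MSE; returns the model at best-val weights.

    A validation fraction of the pairs is held out of every gradient
    step; validation loss drives the plateau learning-rate halving and
    early stopping.  ``model.history`` records per-epoch losses, the
    learning-rate schedule and the validation pair indices.
    """
    cfg = config or model.config
    if not pairs:
        raise ValueError("no training pairs")
    fp, desc, sv = _bundles_to_arrays(bundles)
    model.fit_scalers(fp, desc, sv)

    rng = np.random.default_rng(cfg.seed)
    model._train_rng = np.random.default_rng(cfg.seed + 1)
    order = rng.permutation(len(pairs))
    n_val = max(1, int(round(len(pairs) * cfg.val_fraction)))
    if n_val >= len(pairs):
        raise ValueError("validation split leaves no training pairs")
    val_ids = np.sort(order[:n_val])
    train_ids = np.sort(order[n_val:])
    a_idx = np.array([p.a_idx for p in pairs])
    b_idx = np.array([p.b_idx for p in pairs])
    y = np.array([p.label for p in pairs], dtype=float)

    def forward_loss(ids: np.ndarray, training: bool) -> Tensor:
        s = model.score_pairs_raw(
            fp[a_idx[ids]], desc[a_idx[ids]], sv[a_idx[ids]],
            fp[b_idx[ids]], desc[b_idx[ids]], sv[b_idx[ids]],
            training=training,
        )
        return ((s - Tensor(y[ids].reshape(-1, 1))) ** 2).mean()

    opt = _Adam(model.parameters, cfg.lr)
    history = {"train_loss": [], "val_loss": [], "lr": [], "val_pair_indices": val_ids.tolist(),
               "train_pair_indices": train_ids.tolist()}
    best_val, best_state, best_epoch = math.inf, None, -1
    plateau, stall = 0, 0

    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(train_ids)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(perm), cfg.batch_size):
            batch = perm[start : start + cfg.batch_size]
            opt.zero_grad()
            loss = forward_loss(batch, training=True)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val_loss = float(forward_loss(val_ids, training=False).data)
        if not np.isfinite(val_loss):
            raise TrainingDiverged(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)

        if val_loss < best_val - 1e-6:
            best_val, best_epoch = val_loss, epoch
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            plateau, stall = 0, 0
        else:
            plateau += 1
            stall += 1
            if plateau >= cfg.plateau_patience:
                opt.lr *= 0.5
                plateau = 0
            if stall >= cfg.early_stop_patience:
                break

    if best_state is not None:
        model.load_state_arrays(best_state)
    history["best_val_loss"] = best_val
    history["best_epoch"] = best_epoch
    model.history = history
    return model


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """|intersection| / |union| over set bits; 1.0 for two empty sets."""
    a = np.asarray(fp_a).astype(bool)
    b = np.asarray(fp_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        return 1.0
    return float(np.sum(a & b) / union)


def compare_similarity_metrics(
    model: FusionModel,
    table: LigandTable,
    bundles: Sequence[FeatureBundle],
    pairs: Sequence[PairSample],
) -> tuple[pd.DataFrame, dict]:
    """One record per pair merging fusion score, Tanimoto and label.

    Returns the unified frame plus the Pearson correlation between the
    two similarity measures (with n).
    """
    fp, desc, sv = _bundles_to_arrays(bundles)
    a_idx = np.array([p.a_idx for p in pairs])
    b_idx = np.array([p.b_idx for p in pairs])
    scores = model.score_pairs_raw(
        fp[a_idx], desc[a_idx], sv[a_idx], fp[b_idx], desc[b_idx], sv[b_idx]
    ).data.ravel()
    tans = np.array([tanimoto(fp[a], fp[b]) for a, b in zip(a_idx, b_idx)])
    ids = table.ids
    df = pd.DataFrame(
        {
            "pair_id": [f"{ids[a]}|{ids[b]}" for a, b in zip(a_idx, b_idx)],
            "id_a": [ids[a] for a in a_idx],
            "id_b": [ids[b] for b in b_idx],
            "fusion_score": scores,
            "tanimoto": tans,
            "label": [p.label for p in pairs],
        }
    )
    if np.std(scores) > 0 and np.std(tans) > 0:
        corr = float(np.corrcoef(scores, tans)[0, 1])
    else:
        corr = None
    return df, {"pearson_r": corr, "n": len(pairs)}


def enrichment_at_k(scores: np.ndarray, is_high: np.ndarray, k: int) -> dict:
    """Fraction of actives in the top-k and its fold over the base rate.

    Ties are broken by stable candidate order.  Fold enrichment is
    flagged undefined when the base rate is zero.
    """
    scores = np.asarray(scores, dtype=float)
    is_high = np.asarray(is_high, dtype=bool)
    if scores.shape != is_high.shape:
        raise ValueError("scores and labels must align")
    n = scores.size
    if not 0 < k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    order = np.argsort(-scores, kind="stable")
    frac = float(is_high[order[:k]].mean())
    base = float(is_high.mean())
    return {
        "fraction": frac,
        "base_rate": base,
        "fold": frac / base if base > 0 else None,
        "k": k,
        "n": n,
    }
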