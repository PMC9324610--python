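"""Triplet loss, subject-constrained triplet mining, and embedder training.

The triplet objective pulls same-class segment embeddings together and
pushes different-class embeddings apart by at least a margin alpha:

    L = sum_i max( ||f(a_i) - f(p_i)||^2 - ||f(a_i) - f(n_i)||^2 + alpha, 0 )

with squared Euclidean distances on unit-norm embeddings. Two samplers are
provided. The *random* sampler draws anchor/positive/negative uniformly from
all valid triplets, enforcing only the class constraint and no temporal
overlap between anchor and positive. The *subject* sampler additionally
requires all three members to come from a single subject, which shrinks the
triplet universe from O(N^3) to O(N) and concentrates the objective on
within-subject class separation — the property personalized nearest-neighbor
inference actually relies on. *Mixed* mode draws a configurable fraction of
subject triplets and fills the rest with random ones.

Training resamples triplets fresh every epoch (an epoch is defined as N
drawn triplets, N being the number of training segments) and reuses the same
Adam + gradient-clipping machinery as cross-entropy training, at a reduced
default learning rate of 0.0002.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Adam, clip_global_norm
from .fcn import FCNModel
from .preprocessing import Segment, SegmentSet, segments_overlap

TRIPLET_LEARNING_RATE = 0.0002
DEFAULT_MARGIN = 0.3


@dataclass
class Triplet:
    """Anchor/positive/negative segment references with their set indices."""

    anchor: Segment
    positive: Segment
    negative: Segment
    indices: tuple[int, int, int] = (-1, -1, -1)

    def is_valid(self, require_same_subject: bool = False) -> bool:
        ok = (
            self.anchor.label == self.positive.label
            and self.anchor.label != self.negative.label
            and not segments_overlap(self.anchor, self.positive)
        )
        if require_same_subject:
            ok = ok and (
                self.anchor.subject_id
                == self.positive.subject_id
                == self.negative.subject_id
            )
        return ok


@dataclass
class TripletSamplerConfig:
    mode: str = "mixed"  # one of {"random", "subject", "mixed"}
    subject_fraction: float = 0.5
    triplets_per_epoch: int | None = None  # None -> N (number of segments)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("random", "subject", "mixed"):
            raise ValueError(f"unknown sampler mode {self.mode!r}")
        if not 0.0 <= self.subject_fraction <= 1.0:
            raise ValueError("subject_fraction must lie in [0, 1]")


@dataclass
class TripletLossConfig:
    margin: float = DEFAULT_MARGIN

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be nonnegative")


def triplet_losses(
    anchors: np.ndarray, positives: np.ndarray, negatives: np.ndarray, margin: float
) -> np.ndarray:
    """Per-triplet hinge losses for batched embedding rows."""
    anchors = np.atleast_2d(anchors)
    positives = np.atleast_2d(positives)
    negatives = np.atleast_2d(negatives)
    if not anchors.shape == positives.shape == negatives.shape:
        raise ValueError("anchor/positive/negative embeddings must share shape")
    d_ap = ((anchors - positives) ** 2).sum(axis=1)
    d_an = ((anchors - negatives) ** 2).sum(axis=1)
    return np.maximum(d_ap - d_an + margin, 0.0)


def triplet_loss(
    anchor_emb: np.ndarray,
    positive_emb: np.ndarray,
    negative_emb: np.ndarray,
    margin: float = DEFAULT_MARGIN,
) -> float:
    """Hinge triplet loss; for 2-D inputs, the sum over the batch."""
    return float(triplet_losses(anchor_emb, positive_emb, negative_emb, margin).sum())


# ---- sampling -------------------------------------------------------------


def _overlap_rows(segments: SegmentSet, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    src = segments.source_ids
    iv = segments.intervals
    same_src = src[i] == src[j]
    starts = np.maximum(iv[i, 0], iv[j, 0])
    ends = np.minimum(iv[i, 1], iv[j, 1])
    return same_src & (starts < ends)


def _group_has_nonoverlapping_pair(segments: SegmentSet, idx: np.ndarray) -> bool:
    if idx.shape[0] < 2:
        return False
    src = segments.source_ids[idx]
    if np.unique(src).shape[0] > 1:
        return True
    iv = segments.intervals[idx]
    order = np.argsort(iv[:, 0])
    iv = iv[order]
    min_end = iv[0, 1]
    for r in range(1, iv.shape[0]):
        if iv[r, 0] >= min_end:
            return True
        min_end = min(min_end, iv[r, 1])
    return False


def _feasible(segments: SegmentSet, same_subject: bool) -> bool:
    labels = segments.labels
    subjects = segments.subject_ids
    if same_subject:
        for s in np.unique(subjects):
            s_mask = subjects == s
            s_labels = labels[s_mask]
            if np.unique(s_labels).shape[0] < 2:
                continue
            for c in np.unique(s_labels):
                idx = np.flatnonzero(s_mask & (labels == c))
                if _group_has_nonoverlapping_pair(segments, idx):
                    return True
        return False
    if np.unique(labels).shape[0] < 2:
        return False
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if _group_has_nonoverlapping_pair(segments, idx):
            return True
    return False


def _rejection_sample(
    segments: SegmentSet,
    count: int,
    rng: np.random.Generator,
    same_subject: bool,
) -> list[Triplet]:
    """Uniform draws over the valid-triplet universe via rejection sampling."""
    n = len(segments)
    labels = segments.labels
    subjects = segments.subject_ids
    found: list[tuple[int, int, int]] = []
    batch = max(4096, count * 16)
    rounds = 0
    while len(found) < count:
        rounds += 1
        ai = rng.integers(0, n, batch)
        pi = rng.integers(0, n, batch)
        ni = rng.integers(0, n, batch)
        ok = (labels[ai] == labels[pi]) & (labels[ai] != labels[ni])
        if same_subject:
            ok &= (subjects[ai] == subjects[pi]) & (subjects[ai] == subjects[ni])
        sel = np.flatnonzero(ok)
        if sel.size:
            sel = sel[~_overlap_rows(segments, ai[sel], pi[sel])]
            found.extend(zip(ai[sel].tolist(), pi[sel].tolist(), ni[sel].tolist()))
        if rounds >= 50 and not found:
            if not _feasible(segments, same_subject):
                kind = "subject " if same_subject else ""
                raise ValueError(f"no valid {kind}triplet exists in this segment set")
        if rounds > 5000:  # pragma: no cover - pathological acceptance rate
            raise RuntimeError("triplet rejection sampling failed to converge")
    return [
        Triplet(segments[a], segments[p], segments[q], indices=(a, p, q))
        for a, p, q in found[:count]
    ]


def sample_random_triplets(
    segments: SegmentSet, cfg: TripletSamplerConfig | None = None, count: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Triplet]:
    """Uniform random valid triplets (class + anchor/positive non-overlap only)."""
    cfg = cfg or TripletSamplerConfig(mode="random")
    count = count if count is not None else (cfg.triplets_per_epoch or len(segments))
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if not _feasible(segments, same_subject=False):
        raise ValueError("no valid triplet exists in this segment set")
    return _rejection_sample(segments, count, rng, same_subject=False)


def sample_subject_triplets(
    segments: SegmentSet, cfg: TripletSamplerConfig | None = None, count: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Triplet]:
    """Uniform random valid single-subject triplets."""
    cfg = cfg or TripletSamplerConfig(mode="subject")
    count = count if count is not None else (cfg.triplets_per_epoch or len(segments))
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if not _feasible(segments, same_subject=True):
        raise ValueError("no subject admits a valid triplet")
    return _rejection_sample(segments, count, rng, same_subject=True)


def sample_triplets(
    segments: SegmentSet, cfg: TripletSamplerConfig, count: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Triplet]:
    """Draw one epoch's triplets according to the sampler mode."""
    count = count if count is not None else (cfg.triplets_per_epoch or len(segments))
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if cfg.mode == "random":
        return sample_random_triplets(segments, cfg, count, rng)
    if cfg.mode == "subject":
        return sample_subject_triplets(segments, cfg, count, rng)
    n_subject = int(round(cfg.subject_fraction * count))
    out: list[Triplet] = []
    if n_subject:
        out.extend(sample_subject_triplets(segments, cfg, n_subject, rng))
    if count - n_subject:
        out.extend(sample_random_triplets(segments, cfg, count - n_subject, rng))
    return out


# ---- training -------------------------------------------------------------


def train_triplet_embedder(
    model: FCNModel,
    segments: SegmentSet,
    sampler_cfg: TripletSamplerConfig | None = None,
    loss_cfg: TripletLossConfig | None = None,
    epochs: int | None = None,
    learning_rate: float | None = None,
) -> FCNModel:
    """Train a headless FCN core by minimizing the summed triplet loss.

    Triplets are resampled every epoch; each minibatch embeds its anchors,
    positives, and negatives through the same network in one forward pass
    (so batch-norm statistics are shared) and backpropagates the exact hinge
    gradient. Defaults: mixed sampling with half subject triplets, margin
    0.3, learning rate 0.0002.
    """
    if model.head is not None:
        raise ValueError("triplet training expects a headless FCN core")
    sampler_cfg = sampler_cfg or TripletSamplerConfig()
    loss_cfg = loss_cfg or TripletLossConfig()
    cfg = model.config
    epochs = cfg.epochs if epochs is None else epochs
    lr = TRIPLET_LEARNING_RATE if learning_rate is None else learning_rate
    margin = loss_cfg.margin

    x = model._check_input(segments.windows)
    per_epoch = sampler_cfg.triplets_per_epoch or len(segments)
    rng = np.random.default_rng(sampler_cfg.seed)
    dropout_rng = np.random.default_rng(cfg.seed + 1)
    model._set_dropout_rng(dropout_rng)
    opt = Adam(model.parameters(), lr=lr)

    for epoch in range(epochs):
        triplets = sample_triplets(segments, sampler_cfg, per_epoch, rng)
        order = rng.permutation(len(triplets))
        losses, norms = [], []
        for start in range(0, len(triplets), cfg.batch_size):
            batch = [triplets[i] for i in order[start : start + cfg.batch_size]]
            m = len(batch)
            ai = np.array([t.indices[0] for t in batch])
            pi = np.array([t.indices[1] for t in batch])
            ni = np.array([t.indices[2] for t in batch])
            xb = np.concatenate([x[ai], x[pi], x[ni]], axis=0)
            emb = model._forward_embedding(xb, train=True)
            ea, ep, en = emb[:m], emb[m : 2 * m], emb[2 * m :]
            hinge = triplet_losses(ea, ep, en, margin)
            active = (hinge > 0).astype(emb.dtype)[:, None]
            demb = np.concatenate(
                [
                    2.0 * (en - ep) * active,
                    2.0 * (ep - ea) * active,
                    2.0 * (ea - en) * active,
                ],
                axis=0,
            )
            model._backward_from_embedding(demb)
            grads = model.gradients()
            norms.append(clip_global_norm(grads, cfg.gradient_clip_norm))
            opt.step(grads)
            losses.append(float(hinge.sum()))
        model.history.append(
            {
                "epoch": epoch,
                "loss": float(np.sum(losses)),
                "mean_triplet_loss": float(np.sum(losses) / len(triplets)),
                "max_post_clip_grad_norm": float(np.max(norms)),
                "objective": f"triplet[{sampler_cfg.mode}]",
            }
        )
    return model
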