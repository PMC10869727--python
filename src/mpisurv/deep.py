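"""End-to-end survival training of convolutional risk-score models.

The scorer maps a subject's slice stack (slices as input channels of a 2D
convolutional encoder) to a single scalar f(x): the log-relative-hazard of
the proportional-hazards model.  Training maximizes the batch Cox log
partial likelihood — equivalently minimizes :func:`survival_loss`, its
negation with risk sets restricted to the mini-batch — by mini-batch
gradient ascent with the Adam optimizer.  Batches without any event carry no
likelihood term and are skipped.

Three input modes mirror the clinical-fusion variants: ``image_only``,
``clinical_only`` (a small fully connected network on the covariate vector),
and ``combined`` (clinical covariates concatenated to the pooled image
representation as additional entry nodes before the score head).

Model selection uses k-fold cross-validation: one scorer per fold, each
evaluated on its held-out fold by the truncated concordance index at the
configured horizons (default 1000/2000/3000 days), keeping the scorer with
the highest selection statistic (maximum across horizons by default).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from . import nn
from .cox import partial_likelihood_gradient, partial_log_likelihood
from .core import (ClinicalCovariates, RiskScore, SubjectOutcome,
                   TomogramStudy)
from .evaluate import concordance_index

ARCH_SCALES = ("linear", "tiny", "small", "resnet50_like")
MODES = ("image_only", "clinical_only", "combined")

#: residual-stage channel plans per architecture scale
_STAGE_PLANS = {
    "tiny": ((8, 1), (16, 1), (32, 1)),
    "small": ((16, 2), (32, 2), (64, 2)),
    "resnet50_like": ((64, 3), (128, 4), (256, 6), (512, 3)),
}
_STEM_CHANNELS = {"tiny": 8, "small": 16, "resnet50_like": 64}


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture contract of a risk scorer."""

    input_channels: int = 96
    input_size: int = 32
    architecture_scale: str = "tiny"
    clinical_input_dim: int = 0
    mode: str = "image_only"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.architecture_scale not in ARCH_SCALES:
            raise ValueError(f"unknown scale {self.architecture_scale!r}")
        if self.mode == "clinical_only" and self.clinical_input_dim < 1:
            raise ValueError("clinical_only mode requires clinical_input_dim >= 1")
        if self.mode != "clinical_only" and self.input_channels < 1:
            raise ValueError("image modes require input_channels >= 1")
        if self.mode == "combined" and self.clinical_input_dim < 1:
            raise ValueError("combined mode requires clinical_input_dim >= 1")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol: batched gradient ascent on the partial likelihood."""

    batch_size: int = 16
    learning_rate: float = 1e-4
    epochs: int = 70
    k_folds: int = 5
    horizons_days: tuple[int, ...] = (1000, 2000, 3000)
    seed: int = 0
    min_events_per_batch: int = 1
    stratify_batches: bool = False
    selection: str = "max"  # "max" | "mean" across horizons

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if list(self.horizons_days) != sorted(set(self.horizons_days)):
            raise ValueError("horizons must be strictly increasing")
        if self.selection not in ("max", "mean"):
            raise ValueError(f"unknown selection statistic {self.selection!r}")


def survival_loss(batch_scores: np.ndarray,
                  batch_outcomes: Sequence[SubjectOutcome]) -> float:
    """Negative batch Cox log partial likelihood; 0 for all-censored batches."""
    return -partial_log_likelihood(batch_scores, batch_outcomes)


def survival_loss_gradient(batch_scores: np.ndarray,
                           batch_outcomes: Sequence[SubjectOutcome]) -> np.ndarray:
    """Gradient of :func:`survival_loss` with respect to the batch scores."""
    return -partial_likelihood_gradient(batch_scores, batch_outcomes)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class _RiskNetwork:
    """Internal scorer: encoder + optional clinical concatenation + linear head."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        self.encoder: nn.Layer | None = None
        feat_dim = 0
        if config.mode != "clinical_only":
            scale = config.architecture_scale
            if scale == "linear":
                raise ValueError("linear scale applies to clinical_only mode")
            stem_c = _STEM_CHANNELS[scale]
            layers: list[nn.Layer] = [
                nn.Conv2d(config.input_channels, stem_c, 3, 1, rng),
                nn.BatchNorm2d(stem_c), nn.ReLU()]
            c_in = stem_c
            for c_out, n_blocks in _STAGE_PLANS[scale]:
                for b in range(n_blocks):
                    layers.append(nn.ResidualBlock(c_in, c_out,
                                                   stride=2 if b == 0 else 1,
                                                   rng=rng))
                    c_in = c_out
            layers.append(nn.GlobalAvgPool())
            self.encoder = nn.Sequential(layers)
            feat_dim = c_in
        self.clinical_net: nn.Layer | None = None
        if config.mode == "clinical_only":
            d = config.clinical_input_dim
            if config.architecture_scale == "linear":
                self.clinical_net = nn.Sequential([])
                feat_dim = d
            else:
                hidden = 16
                self.clinical_net = nn.Sequential(
                    [nn.Linear(d, hidden, rng), nn.ReLU()])
                feat_dim = hidden
        head_in = feat_dim + (config.clinical_input_dim
                              if config.mode == "combined" else 0)
        self.head = nn.Linear(head_in, 1, rng)
        self.head_in_dim = head_in

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        if self.encoder is not None:
            ps += self.encoder.params()
        if self.clinical_net is not None:
            ps += self.clinical_net.params()
        ps += self.head.params()
        return ps

    def buffers(self) -> list[np.ndarray]:
        bs: list[np.ndarray] = []
        if self.encoder is not None:
            bs += self.encoder.buffers()
        if self.clinical_net is not None:
            bs += self.clinical_net.buffers()
        return bs

    def forward(self, images: np.ndarray | None, clinical: np.ndarray | None,
                train: bool = True) -> np.ndarray:
        cfg = self.config
        if cfg.mode == "clinical_only":
            feats = self.clinical_net.forward(clinical, train)
        else:
            feats = self.encoder.forward(images, train)
            if cfg.mode == "combined":
                self._clin_dim = clinical.shape[1]
                feats = np.concatenate([feats, clinical], axis=1)
        return self.head.forward(feats, train)[:, 0]

    def backward(self, dscores: np.ndarray) -> None:
        dfeats = self.head.backward(dscores[:, None])
        cfg = self.config
        if cfg.mode == "clinical_only":
            self.clinical_net.backward(dfeats)
            return
        if cfg.mode == "combined":
            dfeats = dfeats[:, :-self._clin_dim]
        self.encoder.backward(dfeats)


def _config_hash(net_config: NetworkConfig, train_config: TrainingConfig) -> str:
    blob = json.dumps([asdict(net_config), asdict(train_config)],
                      sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class TrainedScorer:
    """A trained risk-score model plus its training history and provenance."""

    network: _RiskNetwork
    net_config: NetworkConfig
    train_config: TrainingConfig
    history: list[dict]
    provenance: dict

    def score(self, images: np.ndarray | None,
              clinical: np.ndarray | None) -> np.ndarray:
        return self.network.forward(images, clinical, train=False)


# ---------------------------------------------------------------------------
# data marshalling
# ---------------------------------------------------------------------------

def _stack_images(studies: Sequence[TomogramStudy],
                  config: NetworkConfig) -> np.ndarray:
    stacks = []
    for st in studies:
        if st.n_slices != config.input_channels:
            raise ValueError(
                f"study {st.subject_id!r} has {st.n_slices} slices but the "
                f"network expects {config.input_channels} input channels"
            )
        if st.slice_shape != (config.input_size, config.input_size):
            raise ValueError(
                f"study {st.subject_id!r} slice shape {st.slice_shape} "
                f"differs from configured input size {config.input_size}"
            )
        stacks.append(st.slices)
    return np.stack(stacks)


def _clinical_matrix(clinical: Mapping[str, ClinicalCovariates],
                     subject_ids: Sequence[str]) -> np.ndarray:
    missing = [s for s in subject_ids if s not in clinical]
    if missing:
        raise ValueError(f"no clinical record for subject(s): {missing[:5]}")
    return np.stack([clinical[s].as_vector() for s in subject_ids])


def build_risk_network(config: NetworkConfig,
                       seed: int = 0) -> TrainedScorer:
    """An untrained scorer with seeded He-style initialization."""
    rng = np.random.default_rng(seed)
    net = _RiskNetwork(config, rng)
    return TrainedScorer(net, config, TrainingConfig(seed=seed), [],
                         {"seed": seed, "trained": False})


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _make_batches(n: int, events: np.ndarray, cfg: TrainingConfig,
                  rng: np.random.Generator) -> list[np.ndarray]:
    if cfg.stratify_batches:
        # deal event subjects round-robin so every batch sees some events
        ev = rng.permutation(np.flatnonzero(events == 1))
        cen = rng.permutation(np.flatnonzero(events == 0))
        n_batches = max(n // cfg.batch_size, 1)
        batches: list[list[int]] = [[] for _ in range(n_batches)]
        for i, idx in enumerate(ev):
            batches[i % n_batches].append(int(idx))
        k = 0
        for idx in cen:
            while len(batches[k % n_batches]) >= cfg.batch_size:
                k += 1
            batches[k % n_batches].append(int(idx))
            k += 1
        return [np.array(b) for b in batches if len(b) >= 2]
    perm = rng.permutation(n)
    return [perm[i:i + cfg.batch_size] for i in range(0, n, cfg.batch_size)
            if len(perm[i:i + cfg.batch_size]) >= 2]


def train_model(studies: Sequence[TomogramStudy] | None,
                outcomes: Sequence[SubjectOutcome],
                clinical: Mapping[str, ClinicalCovariates] | None,
                net_config: NetworkConfig,
                train_config: TrainingConfig) -> TrainedScorer:
    """Mini-batch gradient ascent on the batch Cox partial likelihood.

    All randomness (initialization, shuffling) flows from
    ``train_config.seed``.  Raises when the cohort has no events or a
    non-finite loss appears.
    """
    n = len(outcomes)
    events = np.array([o.event for o in outcomes])
    if events.sum() == 0:
        raise ValueError("training cohort has no events")
    subject_ids = [o.subject_id for o in outcomes]

    images = None
    img_mu = img_sd = None
    if net_config.mode != "clinical_only":
        if studies is None:
            raise ValueError("image modes require studies")
        by_id = {s.subject_id: s for s in studies}
        images = _stack_images([by_id[s] for s in subject_ids], net_config)
        # per-channel standardization over the training cohort
        img_mu = images.mean(axis=(0, 2, 3))
        sd = images.std(axis=(0, 2, 3))
        img_sd = np.where(sd > 0, sd, 1.0)
        images = (images - img_mu[None, :, None, None]) / img_sd[None, :, None, None]
    clin = None
    clin_mu = clin_sd = None
    if net_config.mode != "image_only":
        if clinical is None:
            raise ValueError(f"{net_config.mode} mode requires clinical covariates")
        clin = _clinical_matrix(clinical, subject_ids)
        if clin.shape[1] != net_config.clinical_input_dim:
            raise ValueError("clinical_input_dim disagrees with covariate table")
        clin_mu = clin.mean(axis=0)
        clin_sd = np.where(clin.std(axis=0) > 0, clin.std(axis=0), 1.0)
        clin = (clin - clin_mu) / clin_sd

    rng = np.random.default_rng(train_config.seed)
    net = _RiskNetwork(net_config, rng)
    opt = nn.Adam(net.params(), lr=train_config.learning_rate)
    history: list[dict] = []
    skipped = 0
    for epoch in range(train_config.epochs):
        batch_losses = []
        for idx in _make_batches(n, events, train_config, rng):
            b_out = [outcomes[i] for i in idx]
            n_ev = sum(o.event for o in b_out)
            b_img = images[idx] if images is not None else None
            b_clin = clin[idx] if clin is not None else None
            scores = net.forward(b_img, b_clin, train=True)
            loss = survival_loss(scores, b_out)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}")
            if n_ev < max(train_config.min_events_per_batch, 1):
                skipped += 1
                continue
            opt.zero_grad()
            net.backward(survival_loss_gradient(scores, b_out))
            opt.step()
            batch_losses.append(loss / n_ev)
        history.append({
            "epoch": epoch + 1,
            "mean_loss_per_event": float(np.mean(batch_losses))
            if batch_losses else float("nan"),
            "batches_skipped": skipped,
        })
    provenance = {
        "seed": train_config.seed,
        "config_hash": _config_hash(net_config, train_config),
        "trained": True,
        "clinical_mean": clin_mu.tolist() if clin_mu is not None else None,
        "clinical_std": clin_sd.tolist() if clin_sd is not None else None,
        "image_mean": img_mu.tolist() if img_mu is not None else None,
        "image_std": img_sd.tolist() if img_sd is not None else None,
    }
    return TrainedScorer(net, net_config, train_config, history, provenance)


def score_cohort(scorer: TrainedScorer,
                 studies: Sequence[TomogramStudy] | None,
                 clinical: Mapping[str, ClinicalCovariates] | None = None,
                 batch_size: int = 64) -> list[RiskScore]:
    """Deterministic inference: one finite score per subject."""
    cfg = scorer.net_config
    if cfg.mode == "clinical_only":
        if clinical is None:
            raise ValueError("clinical_only scorer needs clinical covariates")
        subject_ids = sorted(clinical)
    else:
        if studies is None:
            raise ValueError("image-mode scorer needs studies")
        subject_ids = [s.subject_id for s in studies]
    images = None
    if cfg.mode != "clinical_only":
        images = _stack_images(list(studies), cfg)
        mu = scorer.provenance.get("image_mean")
        sd = scorer.provenance.get("image_std")
        if mu is not None:
            images = ((images - np.asarray(mu)[None, :, None, None])
                      / np.asarray(sd)[None, :, None, None])
    clin = None
    if cfg.mode != "image_only":
        clin = _clinical_matrix(clinical, subject_ids)
        mu = scorer.provenance.get("clinical_mean")
        sd = scorer.provenance.get("clinical_std")
        if mu is not None:
            clin = (clin - np.asarray(mu)) / np.asarray(sd)
    out: list[RiskScore] = []
    for i in range(0, len(subject_ids), batch_size):
        sl = slice(i, i + batch_size)
        scores = scorer.score(
            images[sl] if images is not None else None,
            clin[sl] if clin is not None else None)
        for sid, sc in zip(subject_ids[sl], scores):
            out.append(RiskScore(sid, float(sc)))
    return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValReport:
    """Per-fold scorers and per-horizon validation concordance."""

    fold_scorers: list[TrainedScorer]
    fold_cindex: list[dict[int, float]]  # fold -> {horizon: C}
    fold_subjects: list[list[str]]       # held-out subject ids per fold
    selected_fold: int                   # 1-based
    selection_value: float
    selection: str

    @property
    def selected_scorer(self) -> TrainedScorer:
        return self.fold_scorers[self.selected_fold - 1]


def _fold_statistic(cindex: dict[int, float], selection: str) -> float:
    vals = [v for v in cindex.values() if np.isfinite(v)]
    if not vals:
        return float("-inf")
    return max(vals) if selection == "max" else float(np.mean(vals))


def crossval(studies: Sequence[TomogramStudy] | None,
             outcomes: Sequence[SubjectOutcome],
             clinical: Mapping[str, ClinicalCovariates] | None,
             net_config: NetworkConfig,
             train_config: TrainingConfig,
             evaluator: Callable[[np.ndarray, Sequence[SubjectOutcome], float],
                                 float] | None = None) -> CrossValReport:
    """k-fold cross-validation with per-horizon concordance model selection.

    Each fold's scorer is trained on the other folds and evaluated on the
    held-out fold with the truncated concordance index at every configured
    horizon; the scorer maximizing the selection statistic (max across
    horizons by default, mean as the alternative) is selected.  ``evaluator``
    can replace the concordance computation (used for testing the selection
    contract).
    """
    k = train_config.k_folds
    if k < 2:
        raise ValueError("k_folds must be >= 2")
    n = len(outcomes)
    rng = np.random.default_rng(train_config.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    eval_fn = evaluator or (lambda s, o, h: concordance_index(s, o, h))

    by_id = {s.subject_id: s for s in studies} if studies is not None else None
    scorers: list[TrainedScorer] = []
    fold_cindex: list[dict[int, float]] = []
    fold_subjects: list[list[str]] = []
    for f, val_idx in enumerate(folds, start=1):
        val_mask = np.zeros(n, dtype=bool)
        val_mask[val_idx] = True
        tr_out = [outcomes[i] for i in range(n) if not val_mask[i]]
        va_out = [outcomes[i] for i in range(n) if val_mask[i]]
        if sum(o.event for o in tr_out) == 0:
            raise ValueError(f"fold {f}: training part has no events")
        tr_studies = ([by_id[o.subject_id] for o in tr_out]
                      if by_id is not None else None)
        va_studies = ([by_id[o.subject_id] for o in va_out]
                      if by_id is not None else None)
        fold_cfg = TrainingConfig(
            **{**asdict(train_config),
               "seed": train_config.seed + f,
               "horizons_days": tuple(train_config.horizons_days)})
        scorer = train_model(tr_studies, tr_out, clinical, net_config, fold_cfg)
        va_clin = ({o.subject_id: clinical[o.subject_id] for o in va_out}
                   if clinical is not None else None)
        scored = score_cohort(scorer, va_studies, va_clin)
        sc_by_id = {s.subject_id: s.score for s in scored}
        va_scores = np.array([sc_by_id[o.subject_id] for o in va_out])
        per_h: dict[int, float] = {}
        for h in train_config.horizons_days:
            try:
                per_h[int(h)] = float(eval_fn(va_scores, va_out, float(h)))
            except ValueError:
                per_h[int(h)] = float("nan")
        scorers.append(scorer)
        fold_cindex.append(per_h)
        fold_subjects.append([o.subject_id for o in va_out])
    stats = [_fold_statistic(c, train_config.selection) for c in fold_cindex]
    best = int(np.argmax(stats))
    return CrossValReport(scorers, fold_cindex, fold_subjects, best + 1,
                          float(stats[best]), train_config.selection)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_scorer(scorer: TrainedScorer, path: str | Path) -> None:
    """Write parameters (.npz) plus a JSON sidecar with config and provenance."""
    path = Path(path)
    params = scorer.network.params()
    buffers = scorer.network.buffers()
    arrays = {f"param_{i}": p.value for i, p in enumerate(params)}
    arrays.update({f"buffer_{i}": b for i, b in enumerate(buffers)})
    np.savez_compressed(path, **arrays)
    sidecar = {
        "net_config": asdict(scorer.net_config),
        "train_config": asdict(scorer.train_config),
        "provenance": scorer.provenance,
        "history": scorer.history,
        "n_params": len(params),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2,
                                                    default=list))


def load_scorer(path: str | Path) -> TrainedScorer:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    nc = dict(sidecar["net_config"])
    tc = dict(sidecar["train_config"])
    tc["horizons_days"] = tuple(tc["horizons_days"])
    net_config = NetworkConfig(**nc)
    train_config = TrainingConfig(**tc)
    rng = np.random.default_rng(0)
    net = _RiskNetwork(net_config, rng)
    with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as z:
        for i, p in enumerate(net.params()):
            p.value[...] = z[f"param_{i}"]
        for i, b in enumerate(net.buffers()):
            b[...] = z[f"buffer_{i}"]
    return TrainedScorer(net, net_config, train_config,
                         sidecar.get("history", []), sidecar["provenance"])
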