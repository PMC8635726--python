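"""Serial-report neural Cox survival model.

`SerialCoxModel` follows the model/results idiom: construct it from a
:class:`~serialcox.corpus.Cohort` (plus an optional configuration), call
``fit(seed=...)``, and work with the returned :class:`SerialCoxResults`,
which carries the trained parameters, the loss trace, prediction and
evaluation methods, and a ``summary()`` table.

The risk score is a log relative hazard:

    risk(patient) = beta . GRU(attention-pooled report vectors)

trained end-to-end by full-batch Adam on the negative log Cox partial
likelihood with Breslow tie handling,

    L = - sum_{i: event} [ r_i - log sum_{j: t_j >= t_i} exp(r_j) ].

The loss is summed (not averaged) over events and optimized full-batch so
every risk set is exact.  For fixed data and seed, training is
deterministic.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .corpus import Cohort, PatientRecord
from .encoder import (
    DEFAULT_MAX_TOKENS,
    UNK_TOKEN,
    AttentionParams,
    LookupEmbeddingBackbone,
    ReportVector,
    build_vocab,
    tokenize,
)
from .network import Batch, SerialCoxNetwork, build_batch, init_params

__all__ = [
    "cox_loss",
    "cox_loss_grad",
    "NoEventsWarning",
    "GRUParams",
    "aggregate_serial",
    "ModelConfig",
    "SerialCoxModel",
    "SerialCoxResults",
    "predict_risk",
]


class NoEventsWarning(UserWarning):
    """Cox partial likelihood requested on data without any events."""


def _cox_prepare(risks, times, events):
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if not (risks.shape == times.shape == events.shape) or risks.ndim != 1:
        raise ValueError("risks, times, events must be equal-length 1-D arrays")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be binary")
    return risks, times, events.astype(float)


def _cox_loss_and_grad(risks, times, events):
    """Breslow negative log partial likelihood and its gradient in risks."""
    risks, times, events = _cox_prepare(risks, times, events)
    if events.sum() == 0:
        warnings.warn("no events: Cox partial likelihood is empty",
                      NoEventsWarning, stacklevel=3)
        return 0.0, np.zeros_like(risks)
    order = np.argsort(-times, kind="stable")
    r = risks[order]
    t = times[order]
    e = events[order]
    m = r.max()
    csum = np.cumsum(np.exp(r - m))
    # tie groups share the full risk set: map each entry to its group's last row
    n = len(t)
    boundary = np.flatnonzero(np.diff(t) != 0)  # t[i] != t[i+1]
    gend = np.empty(n, dtype=np.int64)
    start = 0
    for b in list(boundary) + [n - 1]:
        gend[start : b + 1] = b
        start = b + 1
    log_s = m + np.log(csum[gend])
    loss = float(np.sum(e * (log_s - r)))
    # grad_k = -e_k + exp(r_k) * sum_{events i with t_i <= t_k} 1 / S_i
    inv_s = e / csum[gend]
    suffix = np.cumsum(inv_s[::-1])[::-1]  # suffix[p] = sum_{i >= p} inv_s[i]
    gstart = np.empty(n, dtype=np.int64)
    start = 0
    for b in list(boundary) + [n - 1]:
        gstart[start : b + 1] = start
        start = b + 1
    grad_sorted = -e + np.exp(r - m) * suffix[gstart]
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return loss, grad


def cox_loss(risks, times, events) -> float:
    """Negative log Cox partial likelihood (Breslow ties), summed over events."""
    loss, _ = _cox_loss_and_grad(risks, times, events)
    return loss


def cox_loss_grad(risks, times, events) -> np.ndarray:
    """Analytic gradient of :func:`cox_loss` with respect to the risks."""
    _, grad = _cox_loss_and_grad(risks, times, events)
    return grad


# --------------------------------------------------------------- GRU ops


@dataclass
class GRUParams:
    """Gate weights of a GRU cell (input dim d, hidden dim h)."""

    Wz: np.ndarray
    Uz: np.ndarray
    bz: np.ndarray
    Wr: np.ndarray
    Ur: np.ndarray
    br: np.ndarray
    Wh: np.ndarray
    Uh: np.ndarray
    bh: np.ndarray

    def __post_init__(self) -> None:
        h, d = self.Wz.shape
        expect = {"Wz": (h, d), "Wr": (h, d), "Wh": (h, d),
                  "Uz": (h, h), "Ur": (h, h), "Uh": (h, h),
                  "bz": (h,), "br": (h,), "bh": (h,)}
        for name, shape in expect.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"GRU {name} has shape {arr.shape}, expected {shape}")
            if not np.isfinite(arr).all():
                raise ValueError(f"GRU {name} has non-finite entries")
            setattr(self, name, arr)

    @property
    def hidden_dim(self) -> int:
        return self.Wz.shape[0]

    @classmethod
    def from_params(cls, p: dict[str, np.ndarray]) -> "GRUParams":
        return cls(p["Wz"], p["Uz"], p["bz"], p["Wr"], p["Ur"], p["br"],
                   p["Wh"], p["Uh"], p["bh"])

    def step(self, x: np.ndarray, h: np.ndarray) -> np.ndarray:
        """One GRU step h' = (1-z)h + z*tanh(Wh x + r*(Uh h) + bh)."""
        z = 1.0 / (1.0 + np.exp(-(self.Wz @ x + self.Uz @ h + self.bz)))
        r = 1.0 / (1.0 + np.exp(-(self.Wr @ x + self.Ur @ h + self.br)))
        hh = np.tanh(self.Wh @ x + r * (self.Uh @ h) + self.bh)
        return (1.0 - z) * h + z * hh


def aggregate_serial(report_vectors, gru: GRUParams) -> np.ndarray:
    """Fold chronologically ordered report vectors into a patient vector.

    Runs the GRU recurrence from a zero initial state and returns the
    final hidden state.
    """
    vectors = [rv.values if isinstance(rv, ReportVector) else np.asarray(rv, float)
               for rv in report_vectors]
    if not vectors:
        raise ValueError("aggregate_serial needs at least one report vector")
    h = np.zeros(gru.hidden_dim)
    for x in vectors:
        h = gru.step(np.asarray(x, dtype=float), h)
    return h


# ------------------------------------------------------------- training


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    Dimensions are deliberately desk-scale (d = 32); the backbone
    registry accepts "default-embed" (trainable lookup table) or an
    externally constructed backbone object passed to SerialCoxModel.
    """

    embed_dim: int = 32
    attn_dim: int = 32
    hidden_dim: int = 32
    max_tokens: int = DEFAULT_MAX_TOKENS
    backbone: str = "default-embed"
    train_backbone: bool = True
    lr: float = 5e-3
    epochs: int = 60
    weight_decay: float = 0.0  # decoupled (AdamW-style) L2 shrinkage

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class SerialCoxModel:
    """Neural Cox model over a cohort of serial free-text reports.

    Parameters
    ----------
    cohort : Cohort
        Training cohort; its report texts define the vocabulary.
    config : ModelConfig, optional
    """

    def __init__(self, cohort: Cohort, config: ModelConfig | None = None):
        if len(cohort) == 0:
            raise ValueError("cannot build a model from an empty cohort")
        if cohort.n_events < 2:
            raise ValueError(
                f"training requires >= 2 events, cohort has {cohort.n_events}"
            )
        self.cohort = cohort
        self.config = config or ModelConfig()
        texts = [rep.text for rec in cohort for rep in rec.reports]
        self.vocab = build_vocab(texts, max_tokens=self.config.max_tokens)
        self._batch = _cohort_batch(cohort, self.vocab, self.config.max_tokens)
        self._times = cohort.times()
        self._events = cohort.events()
        # per-report token ids grouped by patient, for mini-batch subsets
        unk = self.vocab[UNK_TOKEN]
        self._id_lists = [
            [np.array([self.vocab.get(t, unk)
                       for t in tokenize(rep.text, self.config.max_tokens).tokens],
                      dtype=np.int64)
             for rep in rec.reports]
            for rec in cohort
        ]

    def _subset_batch(self, indices) -> Batch:
        lists = [ids for i in indices for ids in self._id_lists[i]]
        counts = [len(self._id_lists[i]) for i in indices]
        pids = [self.cohort[i].patient_id for i in indices]
        return build_batch(lists, counts, pids)

    @classmethod
    def from_corpus(cls, path, format: str = "jsonl",
                    config: ModelConfig | None = None) -> "SerialCoxModel":
        from .corpus import read_corpus

        return cls(read_corpus(path, format=format), config=config)

    def fit(self, seed: int = 0, epochs: int | None = None,
            lr: float | None = None, weight_decay: float | None = None,
            batch_size: int | None = None,
            verbose: bool = False) -> "SerialCoxResults":
        """Train by Adam on the Cox partial likelihood.

        Full-batch by default, so every event's risk set is exact.  For
        corpora too large for that, ``batch_size`` enables mini-batches
        whose risk sets are approximated within each batch.
        """
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        lr = cfg.lr if lr is None else lr
        weight_decay = cfg.weight_decay if weight_decay is None else weight_decay
        params = init_params(len(self.vocab), cfg.embed_dim, cfg.attn_dim,
                             cfg.hidden_dim, seed=seed)
        net = SerialCoxNetwork(params)
        mstate = {k: np.zeros_like(v) for k, v in params.items()}
        vstate = {k: np.zeros_like(v) for k, v in params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        adam_t = 0
        shuffle_rng = np.random.default_rng(seed + 104729)
        trace: list[float] = []

        def adam_step(grads):
            nonlocal adam_t
            adam_t += 1
            for k in params:
                g = grads[k]
                mstate[k] = b1 * mstate[k] + (1 - b1) * g
                vstate[k] = b2 * vstate[k] + (1 - b2) * g * g
                mhat = mstate[k] / (1 - b1**adam_t)
                vhat = vstate[k] / (1 - b2**adam_t)
                params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
                if weight_decay:
                    params[k] *= 1.0 - lr * weight_decay

        n = len(self.cohort)
        for epoch in range(1, epochs + 1):
            if batch_size is None or batch_size >= n:
                risks, cache = net.forward(self._batch, need_cache=True)
                loss, drisks = _cox_loss_and_grad(risks, self._times, self._events)
                adam_step(net.backward(cache, drisks,
                                       train_backbone=cfg.train_backbone))
            else:
                order = shuffle_rng.permutation(n)
                loss = 0.0
                for start in range(0, n, batch_size):
                    idx = order[start : start + batch_size]
                    if self._events[idx].sum() == 0:
                        continue  # no risk-set anchor within this batch
                    sub = self._subset_batch(idx)
                    risks, cache = net.forward(sub, need_cache=True)
                    part, drisks = _cox_loss_and_grad(
                        risks, self._times[idx], self._events[idx]
                    )
                    loss += part
                    adam_step(net.backward(cache, drisks,
                                           train_backbone=cfg.train_backbone))
            trace.append(loss)
            if verbose and (epoch == 1 or epoch % 10 == 0):
                print(f"epoch {epoch:4d}  loss {loss:.4f}")
        final_risks, _ = net.forward(self._batch)
        return SerialCoxResults(self, net, trace, seed,
                                train_risks=final_risks)


def _cohort_batch(cohort: Cohort, vocab: dict[str, int], max_tokens: int) -> Batch:
    unk = vocab[UNK_TOKEN]
    id_lists, counts, pids = [], [], []
    for rec in cohort:
        counts.append(rec.n_reports)
        pids.append(rec.patient_id)
        for rep in rec.reports:
            toks = tokenize(rep.text, max_tokens=max_tokens).tokens
            id_lists.append(np.array([vocab.get(t, unk) for t in toks],
                                     dtype=np.int64))
    return build_batch(id_lists, counts, pids)


def _record_batch(record: PatientRecord, vocab, max_tokens, mode: str) -> Batch:
    if mode not in ("serial", "first_report"):
        raise ValueError(f"unknown mode {mode!r}; use 'serial' or 'first_report'")
    reports = record.reports if mode == "serial" else record.reports[:1]
    trimmed = PatientRecord(record.patient_id, reports, record.outcome)
    return _cohort_batch(Cohort((trimmed,), name="single"), vocab, max_tokens)


class SerialCoxResults:
    """Fitted serial Cox model: parameters, diagnostics, prediction.

    Attributes
    ----------
    params : dict of ndarray
        All trained weights (embedding table E, attention W/v, GRU gates,
        Cox head beta).
    loss_trace : list of float
        Training negative log partial likelihood per epoch.
    """

    def __init__(self, model: SerialCoxModel, network: SerialCoxNetwork,
                 loss_trace: list[float], seed: int,
                 train_risks: np.ndarray | None = None):
        self.model = model
        self.network = network
        self.loss_trace = list(loss_trace)
        self.seed = seed
        self.config = model.config
        self.vocab = model.vocab
        self._train_risks = train_risks

    # ------------------------------------------------------------ views

    @property
    def params(self) -> dict[str, np.ndarray]:
        return self.network.params

    @property
    def beta(self) -> np.ndarray:
        return self.network.params["beta"]

    @property
    def backbone(self) -> LookupEmbeddingBackbone:
        return LookupEmbeddingBackbone(self.vocab, dim=self.config.embed_dim,
                                       table=self.params["E"])

    @property
    def attention(self) -> AttentionParams:
        return AttentionParams(W=self.params["W"], v=self.params["v"])

    @property
    def gru(self) -> GRUParams:
        return GRUParams.from_params(self.params)

    @property
    def train_risks(self) -> np.ndarray:
        if self._train_risks is None:
            self._train_risks = self.predict_cohort(self.model.cohort)
        return self._train_risks

    # ------------------------------------------------------- prediction

    def predict_cohort(self, cohort: Cohort, mode: str = "serial") -> np.ndarray:
        """Risk score (log relative hazard) per patient, cohort order."""
        if mode not in ("serial", "first_report"):
            raise ValueError(f"unknown mode {mode!r}; use 'serial' or 'first_report'")
        if mode == "first_report":
            cohort = Cohort(
                tuple(PatientRecord(r.patient_id, r.reports[:1], r.outcome)
                      for r in cohort),
                name=cohort.name,
            )
        batch = _cohort_batch(cohort, self.vocab, self.config.max_tokens)
        risks, _ = self.network.forward(batch)
        return risks

    def predict_risk(self, record: PatientRecord, mode: str = "serial") -> float:
        """Risk score for one patient record."""
        batch = _record_batch(record, self.vocab, self.config.max_tokens, mode)
        risks, _ = self.network.forward(batch)
        return float(risks[0])

    def patient_vectors(self, cohort: Cohort, mode: str = "serial") -> np.ndarray:
        """Final GRU hidden state per patient (N, h), cohort order."""
        if mode == "first_report":
            cohort = Cohort(
                tuple(PatientRecord(r.patient_id, r.reports[:1], r.outcome)
                      for r in cohort),
                name=cohort.name,
            )
        batch = _cohort_batch(cohort, self.vocab, self.config.max_tokens)
        _, aux = self.network.forward(batch)
        return aux["patient_vectors"]

    # ------------------------------------------------------- evaluation

    def evaluate(self, cohort: Cohort, mode: str = "serial"):
        from .evaluation import evaluate as _evaluate

        return _evaluate(self, cohort, mode=mode)

    def survival_graph(self, record: PatientRecord, fraction: float = 0.05,
                       train_cohort: Cohort | None = None):
        from .survival_graph import neighbor_km

        return neighbor_km(record, self, train_cohort or self.model.cohort,
                           fraction=fraction)

    def summary(self) -> str:
        """Human-readable fit summary."""
        cohort = self.model.cohort
        lines = [
            "Serial neural Cox survival model",
            "=" * 40,
            f"patients:            {len(cohort)}",
            f"events (deaths):     {cohort.n_events}",
            f"reports:             {sum(r.n_reports for r in cohort)}",
            f"vocabulary size:     {len(self.vocab)}",
            f"embed/attn/hidden:   {self.config.embed_dim}/"
            f"{self.config.attn_dim}/{self.config.hidden_dim}",
            f"epochs:              {len(self.loss_trace)}",
            f"seed:                {self.seed}",
            f"initial loss:        {self.loss_trace[0]:.4f}",
            f"final loss:          {self.loss_trace[-1]:.4f}",
            f"|beta|_2:            {float(np.linalg.norm(self.beta)):.4f}",
        ]
        return "\n".join(lines)

    # ---------------------------------------------------- serialization

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        np.savez(os.path.join(directory, "params.npz"), **self.params)
        meta = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "loss_trace": self.loss_trace,
            "vocab": self.vocab,
        }
        with open(os.path.join(directory, "meta.json"), "w", encoding="utf-8") as fh:
            json.dump(meta, fh)

    @staticmethod
    def load(directory, cohort: Cohort) -> "SerialCoxResults":
        """Rebuild results from disk; ``cohort`` is the training cohort."""
        with open(os.path.join(directory, "meta.json"), encoding="utf-8") as fh:
            meta = json.load(fh)
        config = ModelConfig.from_dict(meta["config"])
        model = SerialCoxModel(cohort, config=config)
        model.vocab = dict(meta["vocab"])
        model._batch = _cohort_batch(cohort, model.vocab, config.max_tokens)
        with np.load(os.path.join(directory, "params.npz")) as npz:
            params = {k: npz[k] for k in npz.files}
        net = SerialCoxNetwork(params)
        return SerialCoxResults(model, net, meta["loss_trace"], meta["seed"])


def predict_risk(results: SerialCoxResults, record: PatientRecord,
                 mode: str = "serial") -> float:
    """Functional form of :meth:`SerialCoxResults.predict_risk`."""
    return results.predict_risk(record, mode=mode)
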