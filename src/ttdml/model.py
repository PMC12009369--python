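"""The ODE-RNN classifier and its recurrent machinery.

The hidden state h summarizing the longitudinal history evolves in
continuous time between observations by integrating a learned vector field
dh/dt = f_ODE(h) with a fixed-step solver, and is updated at each
observation by a GRU cell fed the concatenation of the (imputed) values,
the observation mask, and the time gap since the previous observation.
The final hidden state is processed by f_longitudinal and fused with the
f_static encoding of the static variables into the *latent phenotype*,
from which an MLP classifier predicts the four TTD class probabilities.

The dynamics are autonomous, so only gaps between observations matter:
shifting all observation times by a constant leaves the prediction
unchanged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .nn import MLP, GRUCell, Module, Tensor, concat, softmax_cross_entropy
from .preprocessing import PreparedPatient

logger = logging.getLogger(__name__)

MINUTES_PER_HOUR = 60.0


@dataclass
class ModelConfig:
    n_channels: int = 25
    n_static: int = 5
    n_classes: int = 4
    hidden_dim: int = 64
    phenotype_dim: int = 16
    static_hidden: list[int] = field(default_factory=lambda: [16])
    ode_hidden: list[int] = field(default_factory=lambda: [32])
    longitudinal_hidden: list[int] = field(default_factory=lambda: [32])
    fusion_hidden: list[int] = field(default_factory=lambda: [32])
    classifier_hidden: list[int] = field(default_factory=lambda: [16])
    solver: str = "euler"              # euler | rk4
    max_step: float = 15.0             # minutes of model time per solver step
    gap_cap_min: float = 1440.0        # longer gaps integrate this duration
    time_feature: str = "delta"        # delta | absolute
    h0_learned: bool = True
    lr: float = 2e-3
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    val_fraction: float = 0.15
    patience: int = 25
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if self.hidden_dim <= 0 or self.phenotype_dim <= 0:
            raise ValueError("dimensions must be positive")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")
        if self.solver not in ("euler", "rk4"):
            raise ValueError(f"unknown solver {self.solver!r}")


class _Batch:
    """Padded arrays for a list of prepared patients."""

    def __init__(self, patients: list[PreparedPatient], config: ModelConfig):
        B = len(patients)
        T = max(p.n_observations for p in patients)
        k = config.n_channels
        self.X = np.zeros((B, T, k))
        self.M = np.zeros((B, T, k))
        self.DT = np.zeros((B, T))
        self.TIME = np.zeros((B, T))
        self.VALID = np.zeros((B, T))
        self.S = np.zeros((B, config.n_static))
        self.y = np.array([p.label for p in patients], dtype=int)
        for b, p in enumerate(patients):
            n = p.n_observations
            self.X[b, :n] = p.values
            self.M[b, :n] = p.mask
            self.DT[b, :n] = p.delta_t
            self.TIME[b, :n] = p.times
            self.VALID[b, :n] = 1.0
            self.S[b] = p.statics
        self.T = T


class SequenceClassifier(Module):
    """Recurrent TTD classifier: cell updates at observations, identity
    evolution between them. Subclasses override :meth:`_evolve`."""

    cell_kind = "gru"

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(np.random.PCG64(config.seed))
        n_in = 2 * config.n_channels + 1
        H = config.hidden_dim
        self._build_cell(n_in, H, rng)
        enc_dim = config.phenotype_dim
        self.f_static = MLP(config.n_static, config.static_hidden, enc_dim, rng)
        self.f_longitudinal = MLP(H, config.longitudinal_hidden, enc_dim, rng)
        self.f_fusion = MLP(2 * enc_dim, config.fusion_hidden,
                            config.phenotype_dim, rng)
        self.f_classifier = MLP(config.phenotype_dim, config.classifier_hidden,
                                config.n_classes, rng)
        h0 = rng.normal(0.0, 0.1, size=(1, H)) if config.h0_learned else np.zeros((1, H))
        self.h0 = Tensor(h0)

    def _build_cell(self, n_in: int, H: int, rng) -> None:
        self.cell = GRUCell(n_in, H, rng)

    # -- evolution between observations (identity for plain RNN family) --

    def _evolve(self, h: Tensor, dt: np.ndarray) -> Tensor:
        return h

    def _cell_init(self, B: int) -> dict:
        return {}

    def _cell_step(self, u: Tensor, h: Tensor, valid: np.ndarray,
                   state: dict) -> Tensor:
        h_new = self.cell(u, h)
        v = valid[:, None]
        return v * h_new + (1.0 - v) * h

    def _forward(self, batch: _Batch) -> tuple[Tensor, Tensor]:
        cfg = self.config
        B = batch.X.shape[0]
        h = self.h0 * np.ones((B, 1))
        if cfg.time_feature == "absolute":
            tfeat = batch.TIME / MINUTES_PER_HOUR
        else:
            tfeat = batch.DT / MINUTES_PER_HOUR
        U = np.concatenate([batch.X, batch.M, tfeat[..., None]], axis=2)
        state = self._cell_init(B)
        for t in range(batch.T):
            h = self._evolve(h, batch.DT[:, t] * batch.VALID[:, t])
            h = self._cell_step(Tensor(U[:, t, :]), h, batch.VALID[:, t], state)
        z = self.f_fusion(concat([self.f_static(Tensor(batch.S)),
                                  self.f_longitudinal(h)], axis=1))
        logits = self.f_classifier(z)
        return logits, z

    # -- public API -------------------------------------------------------

    def predict_proba(self, patients: list[PreparedPatient],
                      batch_size: int = 256) -> np.ndarray:
        out = []
        for lo in range(0, len(patients), batch_size):
            batch = _Batch(patients[lo:lo + batch_size], self.config)
            logits, _ = self._forward(batch)
            out.append(nn.softmax(logits.data))
        return np.vstack(out)

    def predict(self, patients: list[PreparedPatient]) -> np.ndarray:
        """4-way argmax; probability ties break toward the lower category."""
        return np.argmax(self.predict_proba(patients), axis=1)

    def encode(self, patients: list[PreparedPatient],
               batch_size: int = 256) -> np.ndarray:
        """Latent phenotype matrix, one row per patient."""
        out = []
        for lo in range(0, len(patients), batch_size):
            batch = _Batch(patients[lo:lo + batch_size], self.config)
            _, z = self._forward(batch)
            out.append(z.data)
        return np.vstack(out)

    def gru_update(self, h: np.ndarray, x: np.ndarray, m: np.ndarray,
                   delta_t: float) -> np.ndarray:
        """One observation update of the hidden state (single patient)."""
        k = self.config.n_channels
        if x.shape[-1] != k or m.shape[-1] != k:
            raise ValueError(f"expected {k} channels")
        u = np.concatenate([np.atleast_2d(x), np.atleast_2d(m),
                            [[delta_t / MINUTES_PER_HOUR]]], axis=1)
        out = self.cell(Tensor(u), Tensor(np.atleast_2d(h)))
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite hidden state after update")
        return out.data[0]

    # -- training ---------------------------------------------------------

    def fit(self, patients: list[PreparedPatient],
            log_every: int = 0) -> dict:
        """Mini-batch Adam on categorical cross-entropy.

        A validation fraction (split by patient) is held out for early
        stopping; the weights with the best validation loss are restored.
        Deterministic given ``config.seed``.
        """
        cfg = self.config
        rng = np.random.default_rng(np.random.PCG64([cfg.seed, 0x7E57]))
        idx = rng.permutation(len(patients))
        n_val = int(round(cfg.val_fraction * len(patients)))
        n_val = min(max(n_val, 0), len(patients) - 1)
        val = [patients[i] for i in idx[:n_val]]
        train = [patients[i] for i in idx[n_val:]]

        weights = None
        if cfg.class_weighting:
            counts = np.bincount([p.label for p in train], minlength=cfg.n_classes)
            inv = len(train) / np.maximum(counts, 1) / cfg.n_classes
            weights = {c: inv[c] for c in range(cfg.n_classes)}

        opt = nn.Adam(self.parameters(), lr=cfg.lr)
        history = {"train_loss": [], "val_loss": []}
        best_val = np.inf
        best_weights = self.get_weights()
        stale = 0

        order = np.argsort([p.n_observations for p in train], kind="stable")
        for epoch in range(cfg.epochs):
            starts = np.arange(0, len(train), cfg.batch_size)
            rng.shuffle(starts)
            epoch_loss = 0.0
            n_seen = 0
            for lo in starts:
                chunk = [train[i] for i in order[lo:lo + cfg.batch_size]]
                batch = _Batch(chunk, cfg)
                sw = (np.array([weights[p.label] for p in chunk])
                      if weights else None)
                self.zero_grad()
                logits, _ = self._forward(batch)
                loss, _ = softmax_cross_entropy(logits, batch.y, sw)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        "training diverged (non-finite loss); try a smaller "
                        "learning rate or solver max_step")
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(chunk)
                n_seen += len(chunk)
            history["train_loss"].append(epoch_loss / max(n_seen, 1))

            if val:
                probs = self.predict_proba(val)
                y_val = np.array([p.label for p in val])
                nll = -np.mean(np.log(np.clip(
                    probs[np.arange(len(y_val)), y_val], 1e-12, None)))
            else:
                nll = history["train_loss"][-1]
            history["val_loss"].append(float(nll))
            if nll < best_val - 1e-6:
                best_val = float(nll)
                best_weights = self.get_weights()
                stale = 0
            else:
                stale += 1
            if log_every and (epoch + 1) % log_every == 0:
                logger.info("epoch %d: train loss %.4f, val loss %.4f",
                            epoch + 1, history["train_loss"][-1], nll)
            if stale >= cfg.patience:
                break
        self.set_weights(best_weights)
        history["best_val_loss"] = best_val
        return history

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(path, __config__=json.dumps(asdict(self.config)),
                 __class__=type(self).__name__, **arrays)

    @classmethod
    def load(cls, path) -> "SequenceClassifier":
        with np.load(path, allow_pickle=False) as data:
            config = ModelConfig(**json.loads(str(data["__config__"])))
            cls_name = str(data["__class__"])
            model = _MODEL_CLASSES[cls_name](config)
            n = len([k for k in data.files if k.startswith("w")])
            model.set_weights([data[f"w{i}"] for i in range(n)])
        return model


class ODERNNClassifier(SequenceClassifier):
    """ODE-RNN: continuous hidden-state dynamics between observations."""

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(np.random.PCG64([config.seed, 0x0DE]))
        # small output scale keeps the initial vector field gentle so the
        # first integration steps cannot blow up the hidden state
        self.f_ode = MLP(config.hidden_dim, config.ode_hidden,
                         config.hidden_dim, rng, final_scale=0.1)

    def _evolve(self, h: Tensor, dt: np.ndarray) -> Tensor:
        """Integrate dh/dt = f_ODE(h) over per-sample gaps ``dt`` minutes.

        Fixed-step integration with per-sample step size dt/n_sub where
        n_sub = ceil(dt / max_step); samples with dt = 0 take zero-length
        steps (exact identity). Gaps beyond ``gap_cap_min`` integrate the
        capped duration.
        """
        cfg = self.config
        dt = np.clip(np.asarray(dt, dtype=float), 0.0, cfg.gap_cap_min)
        n_sub = np.maximum(np.ceil(dt / cfg.max_step).astype(int), 1)
        n_max = int(n_sub.max()) if len(n_sub) else 1
        # the vector field is expressed per hour of model time, so even a
        # day-long capped gap only integrates ~24 units of dynamics
        step = dt / n_sub / MINUTES_PER_HOUR
        for s in range(n_max):
            eff = np.where(s < n_sub, step, 0.0)[:, None]
            if cfg.solver == "euler":
                h = h + eff * self.f_ode(h)
            else:  # rk4
                k1 = self.f_ode(h)
                k2 = self.f_ode(h + (0.5 * eff) * k1)
                k3 = self.f_ode(h + (0.5 * eff) * k2)
                k4 = self.f_ode(h + eff * k3)
                h = h + (eff * (1.0 / 6.0)) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        return h

    def ode_evolve(self, h: np.ndarray, t_from: float, t_to: float) -> np.ndarray:
        """Evolve a single hidden state from ``t_from`` to ``t_to`` minutes."""
        if t_to < t_from:
            raise ValueError("t_to must be >= t_from")
        out = self._evolve(Tensor(np.atleast_2d(h)), np.array([t_to - t_from]))
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError(
                "non-finite hidden state during integration; reduce max_step "
                "or the learning rate")
        return out.data[0]


class GRUBaseline(SequenceClassifier):
    """Plain GRU over the same (values, mask, gap) encoding; no ODE segment."""


class RNNBaseline(SequenceClassifier):
    def _build_cell(self, n_in, H, rng):
        self.cell = nn.RNNCell(n_in, H, rng)


class LSTMBaseline(SequenceClassifier):
    def _build_cell(self, n_in, H, rng):
        self.cell = nn.LSTMCell(n_in, H, rng)

    def _cell_init(self, B: int) -> dict:
        return {"c": Tensor(np.zeros((B, self.config.hidden_dim)))}

    def _cell_step(self, u, h, valid, state):
        h_new, c_new = self.cell(u, h, state["c"])
        v = valid[:, None]
        state["c"] = v * c_new + (1.0 - v) * state["c"]
        return v * h_new + (1.0 - v) * h


_MODEL_CLASSES = {
    "ODERNNClassifier": ODERNNClassifier,
    "GRUBaseline": GRUBaseline,
    "RNNBaseline": RNNBaseline,
    "LSTMBaseline": LSTMBaseline,
}


def train_model(patients: list[PreparedPatient], config: ModelConfig,
                kind: str = "ode_rnn") -> SequenceClassifier:
    """Train one classifier of the given kind on prepared patients."""
    model = make_model(kind, config)
    model.fit(patients)
    return model


def make_model(kind: str, config: ModelConfig) -> SequenceClassifier:
    classes = {"ode_rnn": ODERNNClassifier, "gru": GRUBaseline,
               "rnn": RNNBaseline, "lstm": LSTMBaseline}
    if kind not in classes:
        raise ValueError(f"unknown model kind {kind!r}")
    return classes[kind](config)


def train_ensemble(patients: list[PreparedPatient], config: ModelConfig,
                   n_seeds: int = 5, kind: str = "ode_rnn") -> list[SequenceClassifier]:
    """Train ``n_seeds`` models with seeds config.seed + 0..n-1.

    A diverging member is reported and dropped; at least two survivors are
    required.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    members = []
    for s in range(n_seeds):
        member_cfg = replace(config, seed=config.seed + s)
        try:
            members.append(train_model(patients, member_cfg, kind))
        except RuntimeError as exc:
            logger.warning("ensemble member seed %d diverged: %s",
                           member_cfg.seed, exc)
    if len(members) < 2:
        raise RuntimeError("fewer than 2 ensemble members converged")
    return members
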