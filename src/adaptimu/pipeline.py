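"""End-to-end training: synthetic sessions -> trained runtime components.

Ties the modules together in the fixed order: simulate, condition and
window the streams, split at subject level (70 / 11.5 / 18.5 %), rebalance
the training split (SMOTE + class weights), train the two branches,
calibrate the quantized CNN path, fit the GP risk head, and train the
Q-learning agent on replayed training sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import models, preprocessing as pp, rl, runtime, synthetic
from .gp import GpKernelParams, RiskHead, fit_hyperparameters, fit_risk_head
from .rl import ExplorationSchedule, QLearner
from .runtime import RuntimeComponents, run_session, window_features


@dataclass
class SimulationConfig:
    n_subjects: int = 6
    session_s: float = 60.0
    injury_rate: float = 3.0      # events per minute
    scenario_mix: dict | None = None
    seed: int = 0


@dataclass
class SystemConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    prune_ratio: float = 0.4
    cnn_epochs: int = 8
    lstm_epochs: int = 8
    finetune_epochs: int = 2
    lr: float = 1e-3
    batch_size: int = 64
    patience: int = 3
    fit_gp: bool = False          # default: printed kernel variances
    rl_passes: int = 2
    seed: int = 0


@dataclass
class WindowedDataset:
    X: np.ndarray                 # (n, 40, C) normalized
    y: np.ndarray
    subjects: np.ndarray
    starts: np.ndarray
    session_idx: np.ndarray


def simulate_cohort(cfg: SimulationConfig) -> list[synthetic.LabeledImuStream]:
    streams = []
    for s in range(cfg.n_subjects):
        streams.append(synthetic.generate_session(
            cfg.session_s, cfg.scenario_mix, cfg.injury_rate,
            seed=cfg.seed * 10_007 + s, subject_id=s))
    return streams


def window_streams(streams, norm_stats=None):
    """Condition + window every stream; returns (per-stream windows, stats).

    Normalization stats are computed on the provided (training) windows
    when ``norm_stats`` is None and must then be reused for other splits."""
    per_stream = [pp.preprocess_stream(s) for s in streams]
    return per_stream


def build_dataset(windowed, norm_stats) -> WindowedDataset:
    X, y, subj, starts, sess = [], [], [], [], []
    for si, ws in enumerate(windowed):
        normed = pp.z_normalize(ws, norm_stats)
        for w in normed:
            X.append(w.x)
            y.append(w.label)
            subj.append(w.subject_id)
            starts.append(w.start_s)
            sess.append(si)
    return WindowedDataset(np.asarray(X), np.asarray(y, int),
                           np.asarray(subj), np.asarray(starts),
                           np.asarray(sess, int))


@dataclass
class TrainedSystem:
    components: RuntimeComponents
    norm_stats: pp.NormStats
    splits: dict
    streams: list
    windowed_raw: list
    history: dict


def train_system(cfg: SystemConfig) -> TrainedSystem:
    streams = simulate_cohort(cfg.sim)
    windowed = window_streams(streams)
    splits = pp.split_subjects([s.subject_id for s in streams],
                               seed=cfg.seed)
    train_ws = [w for s, ws in zip(streams, windowed)
                if s.subject_id in splits["train"] for w in ws]
    norm_stats = pp.compute_norm_stats(train_ws, split="train")

    def subset(ids):
        sel = [ws for s, ws in zip(streams, windowed) if s.subject_id in ids]
        return build_dataset(sel, norm_stats)

    ds_tr = subset(splits["train"])
    ds_va = subset(splits["val"]) if len(splits["val"]) else ds_tr

    X_bal, y_bal, class_w = pp.rebalance_training(ds_tr.X, ds_tr.y,
                                                  seed=cfg.seed)
    tc = models.TrainConfig(lr=cfg.lr, batch_size=cfg.batch_size,
                            patience=cfg.patience, class_weights=class_w,
                            seed=cfg.seed)

    tc_cnn = models.TrainConfig(**{**tc.__dict__, "max_epochs": cfg.cnn_epochs})
    cnn, hist_cnn = models.train_branch(X_bal, y_bal, "cnn", tc_cnn,
                                        X_val=ds_va.X, y_val=ds_va.y)
    models.calibrate_activation_scales(cnn, ds_va.X[:64])

    tc_lstm = models.TrainConfig(**{**tc.__dict__, "max_epochs": cfg.lstm_epochs})
    lstm_dense, hist_lstm = models.train_branch(X_bal, y_bal, "lstm", tc_lstm,
                                                X_val=ds_va.X, y_val=ds_va.y)
    # prune at the training-time ratio and briefly fine-tune under the mask
    pruned = models.magnitude_prune(lstm_dense, cfg.prune_ratio)
    tc_ft = models.TrainConfig(**{**tc.__dict__,
                                  "max_epochs": cfg.finetune_epochs,
                                  "lr": cfg.lr / 3})
    pruned, hist_ft = models.train_branch(X_bal, y_bal, "lstm", tc_ft,
                                          X_val=ds_va.X, y_val=ds_va.y,
                                          params=pruned)
    # the fine-tuned dense weights are the checkpoint the runtime re-prunes
    lstm_dense = models.LstmParams(
        layers=[models.LstmLayer(W=l.W.copy(), U=l.U.copy(), b=l.b.copy())
                for l in pruned.layers],
        Wl=pruned.Wl.copy(), bl=pruned.bl.copy(), dropout=pruned.dropout)

    # GP kernel: printed variances by default, optionally refit on features
    theta = GpKernelParams()
    if cfg.fit_gp:
        feats = np.array([window_features(x) for x in ds_tr.X[:80]])
        t_feat = ds_tr.starts[:80]
        order = np.argsort(t_feat)
        theta = fit_hyperparameters(t_feat[order], feats[order],
                                    seed=cfg.seed)

    # risk head on training-split motion features; the SMOTE-rebalanced
    # windows keep the head calibrated despite the ~1:15 class imbalance
    feats_tr = np.array([window_features(x) for x in X_bal])
    head = fit_risk_head(feats_tr, y_bal)

    components = RuntimeComponents(
        cnn=cnn, lstm_dense=lstm_dense, gp_theta=theta, risk_head=head,
        schedule=ExplorationSchedule())
    grid = components.action_grid
    qnet = rl.init_qnetwork(state_dim=5, n_actions=len(grid), seed=cfg.seed)
    components.qnet = qnet

    # agent training: replayed passes over the training sessions
    learner = QLearner(qnet, gamma=0.95, learning_rate=1e-3, target_sync=100)
    replay = rl.ReplayBuffer()
    train_streams = [s for s in streams if s.subject_id in splits["train"]]
    for p in range(cfg.rl_passes):
        for s, ws in zip(streams, windowed):
            if s.subject_id not in splits["train"]:
                continue
            normed = pp.z_normalize(ws, norm_stats)
            run_session(normed, components, mode="full",
                        seed=cfg.seed + 31 * p, train_agent=True,
                        learner=learner, replay=replay,
                        event_times=[e.time_s for e in s.events])
    components.qnet = learner.net

    history = {"cnn": hist_cnn, "lstm": hist_lstm, "lstm_finetune": hist_ft,
               "n_train_windows": int(len(ds_tr.y)),
               "n_train_streams": len(train_streams)}
    return TrainedSystem(components=components, norm_stats=norm_stats,
                         splits=splits, streams=streams,
                         windowed_raw=windowed, history=history)


def evaluate_split(system: TrainedSystem, split: str = "test",
                   mode: str = "full", seed: int = 0):
    """Stream every session of a split in the given mode; returns results."""
    ids = system.splits[split]
    results = []
    for s, ws in zip(system.streams, system.windowed_raw):
        if s.subject_id not in ids:
            continue
        normed = pp.z_normalize(ws, system.norm_stats)
        results.append(run_session(
            normed, system.components, mode=mode, seed=seed,
            event_times=[e.time_s for e in s.events]))
    return results
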