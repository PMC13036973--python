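"""Streaming orchestrator: the five-step adaptive inference loop.

For every 200 ms window the runtime

1. processes the window through the current ensemble configuration
   (quantized CNN branch mixed with the beta-pruned LSTM branch at alpha),
2. updates the Gaussian process with the observed motion features,
3. generates the risk forecast for the next time window,
4. has the RL agent select the next (alpha, beta) action, and
5. adjusts the ensemble architecture accordingly — the new configuration
   takes effect on the NEXT window (causal ordering).

Because no hardware counters exist here, CPU usage, latency and energy
enter the agent's state and reward through an analytic multiply-accumulate
(MAC) proxy over the active topology; the proxy is strictly decreasing in
the pruning ratio and drops a branch entirely at alpha in {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import models, rl
from .gp import (DEFAULT_HORIZON_S, RISK_THRESHOLD, GpBuffer, GpForecast,
                 GpKernelParams, RiskHead, predict_ahead, risk_score)
from .preprocessing import MotionWindow
from .rl import ActionGrid, ExplorationSchedule, QLearner, ReplayBuffer, \
    RewardConfig, RlTransition, build_state, select_action

RUN_MODES = ("full", "no_rl", "no_gp", "no_dyn_prune", "fixed_ensemble")
DEFAULT_ALPHA = 0.5
DEFAULT_BETA = 0.4


@dataclass
class FusionState:
    alpha_t: float = DEFAULT_ALPHA
    beta_t: float = DEFAULT_BETA
    last_action_step: int = -1

    def __post_init__(self):
        if not (0.0 <= self.alpha_t <= 1.0):
            raise ValueError("alpha_t must lie in [0, 1]")
        if not (0.0 <= self.beta_t < 1.0):
            raise ValueError("beta_t must lie in [0, 1)")


@dataclass
class EnsembleOutput:
    p_cnn: np.ndarray
    p_lstm: np.ndarray
    y_hat: np.ndarray
    decision: int
    alert: bool = False


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - np.max(logits)
    p = np.exp(z)
    return p / p.sum()


def fuse_predictions(alpha: float, cnn_logits: np.ndarray,
                     lstm_logits: np.ndarray) -> EnsembleOutput:
    """Convex combination of the branch softmax outputs at weight alpha."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    p_cnn = _softmax(np.asarray(cnn_logits, float))
    p_lstm = _softmax(np.asarray(lstm_logits, float))
    y_hat = alpha * p_cnn + (1.0 - alpha) * p_lstm
    return EnsembleOutput(p_cnn=p_cnn, p_lstm=p_lstm, y_hat=y_hat,
                          decision=int(np.argmax(y_hat)))


def apply_action(fusion_state: FusionState, action: tuple[float, float],
                 lstm_dense: models.LstmParams | None,
                 step: int = 0) -> tuple[FusionState, models.LstmParams | None]:
    """Set (alpha, beta) and re-prune the LSTM from its dense checkpoint.

    Masks are recomputed from the dense weights at each beta, so pruning
    changes are reversible.  alpha = 1 short-circuits the LSTM branch."""
    alpha, beta = action
    if lstm_dense is None:
        raise ValueError("missing dense LSTM checkpoint")
    new_state = FusionState(alpha_t=alpha, beta_t=beta, last_action_step=step)
    if alpha == 1.0:
        return new_state, None  # CNN-only fallback mode
    return new_state, models.magnitude_prune(lstm_dense, beta)


# ---------------------------------------------------------------------------
# resource proxy


@dataclass
class ResourceProxy:
    mac_count: float
    cpu_usage: float
    energy_proxy: float
    latency_proxy: float
    adaptation_macs: float = 0.0


def cnn_mac_count(params: models.CnnParams) -> float:
    t = params.input_len
    c_in = params.in_channels
    macs = 0.0
    for blk in params.blocks:
        k = blk.Wd.shape[0]
        c_out = blk.Wd.shape[1] if params.conv_order == "as_printed" \
            else blk.Wp.shape[1]
        t_out = -(-t // 2)
        if params.conv_order == "as_printed":
            macs += t * c_in * c_out          # pointwise on input length
            macs += t_out * k * c_out         # depthwise, strided
        else:
            macs += t_out * k * c_in
            macs += t_out * c_in * c_out
        t, c_in = t_out, c_out
    macs += c_in * params.Wc.shape[1]         # classifier projection
    return macs


def lstm_mac_count(params: models.LstmParams, beta: float,
                   seq_len: int = 40) -> float:
    """Gate MACs over the sequence; prunable matrices scaled by (1 - beta)."""
    macs = 0.0
    for layer in params.layers:
        c_in, h = layer.W.shape[0], layer.hidden
        macs += seq_len * 4 * h * (c_in + h) * (1.0 - beta)
    macs += params.Wl.shape[0] * params.Wl.shape[1]
    return macs


def qnet_mac_count(net: rl.QNetwork) -> float:
    return float(net.W1.size + net.W2.size)


def gp_mac_count(n_obs: int, n_features: int) -> float:
    # Cholesky n^3/3 plus solves and cross-covariances
    return n_obs ** 3 / 3.0 + 2.0 * n_obs ** 2 * n_features + n_obs * n_features


def reprune_mac_count(params: models.LstmParams) -> float:
    # magnitude ranking pass over all prunable weights
    return float(sum(layer.W.size + layer.U.size for layer in params.layers))


@dataclass
class ProxyConfig:
    """Maps MAC counts onto latency/energy-equivalent scales.

    kappa and mu are calibrated so that the full ensemble at
    (alpha=0.5, beta=0) corresponds to ~26.4 ms-equivalent latency; they
    feed the agent's reward only and are never performance claims."""

    mu_ms_per_mac: float
    kappa_mj_per_mac: float
    cpu_budget_macs: float

    @classmethod
    def calibrated(cls, cnn_params: models.CnnParams,
                   lstm_params: models.LstmParams,
                   latency_ref_ms: float = 26.4,
                   energy_ref_mj: float = 4.8) -> "ProxyConfig":
        ref = cnn_mac_count(cnn_params) + lstm_mac_count(lstm_params, 0.0)
        return cls(mu_ms_per_mac=latency_ref_ms / ref,
                   kappa_mj_per_mac=energy_ref_mj / ref,
                   cpu_budget_macs=1.5 * ref)


def estimate_resources(cnn_params: models.CnnParams,
                       lstm_params: models.LstmParams,
                       fusion_state: FusionState,
                       proxy: ProxyConfig,
                       adaptation_macs: float = 0.0) -> ResourceProxy:
    macs = 0.0
    if fusion_state.alpha_t > 0.0:
        macs += cnn_mac_count(cnn_params)
    if fusion_state.alpha_t < 1.0:
        macs += lstm_mac_count(lstm_params, fusion_state.beta_t)
    total = macs + adaptation_macs
    return ResourceProxy(
        mac_count=macs,
        cpu_usage=float(np.clip(total / proxy.cpu_budget_macs, 0.0, 1.0)),
        energy_proxy=total * proxy.kappa_mj_per_mac,
        latency_proxy=total * proxy.mu_ms_per_mac,
        adaptation_macs=adaptation_macs)


# ---------------------------------------------------------------------------
# runtime


def window_features(x: np.ndarray, gyro_cols=(3, 4, 5)) -> np.ndarray:
    """Per-channel RMS plus peak gyro magnitude — the GP's motion features."""
    x = np.asarray(x, float)
    rms = np.sqrt(np.mean(x * x, axis=0))
    gyro = x[:, list(gyro_cols)] if x.shape[1] > max(gyro_cols) else x
    peak = np.max(np.abs(gyro))
    return np.concatenate([rms, [peak]])


@dataclass
class RuntimeComponents:
    """Trained artifacts the streaming loop needs."""

    cnn: models.CnnParams
    lstm_dense: models.LstmParams
    gp_theta: GpKernelParams
    risk_head: RiskHead
    qnet: rl.QNetwork | None = None
    action_grid: ActionGrid = field(default_factory=ActionGrid)
    reward_cfg: RewardConfig = field(default_factory=RewardConfig)
    schedule: ExplorationSchedule = field(default_factory=ExplorationSchedule)
    proxy: ProxyConfig | None = None
    tau: float = RISK_THRESHOLD
    horizon_s: float = DEFAULT_HORIZON_S
    quantized_cnn: bool = True

    def __post_init__(self):
        if self.proxy is None:
            self.proxy = ProxyConfig.calibrated(self.cnn, self.lstm_dense)
        if self.quantized_cnn and self.cnn.act_scales is None:
            raise ValueError("quantized CNN path requires activation "
                             "calibration before streaming")


@dataclass
class ModePolicy:
    agent_on: bool = True
    gp_on: bool = True
    fixed_alpha: float | None = None
    fixed_beta: float | None = None
    lambda4_on: bool = True


def _mode_policy(mode: str) -> ModePolicy:
    if mode == "full":
        return ModePolicy()
    if mode == "no_rl":
        return ModePolicy(agent_on=False, fixed_alpha=DEFAULT_ALPHA,
                          fixed_beta=DEFAULT_BETA)
    if mode == "no_gp":
        return ModePolicy(gp_on=False, lambda4_on=False)
    if mode == "no_dyn_prune":
        return ModePolicy(fixed_beta=DEFAULT_BETA)
    if mode == "fixed_ensemble":
        return ModePolicy(agent_on=False, fixed_alpha=DEFAULT_ALPHA,
                          fixed_beta=DEFAULT_BETA)
    raise ValueError(f"unknown run mode {mode!r}; expected one of {RUN_MODES}")


class AdaptiveRuntime:
    """Stateful five-step loop over a windowed session."""

    def __init__(self, components: RuntimeComponents, mode: str = "full",
                 seed: int = 0, train_agent: bool = False,
                 replay: ReplayBuffer | None = None,
                 learner: QLearner | None = None):
        self.c = components
        self.mode = mode
        self.policy = _mode_policy(mode)
        self.rng = np.random.default_rng(seed)
        self.train_agent = train_agent and self.policy.agent_on
        self.learner = learner
        self.replay = replay if replay is not None else ReplayBuffer()
        if self.train_agent and self.learner is None:
            raise ValueError("train_agent requires a QLearner")
        a0 = self.policy.fixed_alpha if self.policy.fixed_alpha is not None \
            else DEFAULT_ALPHA
        b0 = self.policy.fixed_beta if self.policy.fixed_beta is not None \
            else DEFAULT_BETA
        self.fusion = FusionState(alpha_t=a0, beta_t=b0)
        self.lstm_current = models.magnitude_prune(components.lstm_dense, b0)
        self.buffer = GpBuffer()
        self.step_count = 0
        self._pending = None      # (state, action_idx, reward)
        self._pending_adapt_macs = 0.0
        self.logs: list[dict] = []

    # -- five-step loop ----------------------------------------------------
    def step(self, window: MotionWindow, y_true: int | None = None):
        c = self.c
        fallback = False
        alpha = self.fusion.alpha_t
        if window.valid is not None and not window.valid.any():
            alpha, fallback = 1.0, True   # all channels missing: CNN-only

        # 1. ensemble inference under the current configuration
        x = np.nan_to_num(window.x)
        cnn_logits = models.cnn_forward(x, c.cnn, quantized=c.quantized_cnn) \
            if alpha > 0.0 else np.zeros(2)
        if alpha < 1.0 and self.lstm_current is not None:
            h, _ = _lstm_seq_single(x, self.lstm_current)
            lstm_logits = models.lstm_logits(h, self.lstm_current)
        else:
            lstm_logits = np.zeros(2)
        out = fuse_predictions(alpha, cnn_logits, lstm_logits)

        # 2. update the Gaussian process with the observed motion pattern
        feats = window_features(x)
        if self.policy.gp_on:
            self.buffer.push(window.start_s, feats)

        # 3. risk forecast for the next time window
        if self.policy.gp_on and len(self.buffer) >= 3:
            forecast = predict_ahead(self.buffer, c.gp_theta, c.horizon_s)
            risk = risk_score(forecast, c.risk_head)
        else:
            forecast = GpForecast(x_hat=feats, variance=np.zeros_like(feats),
                                  horizon_s=c.horizon_s, risk=0.5)
            risk = 0.5
        out.alert = bool(risk > c.tau or out.decision == 1)

        # 4. RL agent selects the next (alpha, beta)
        adapt_macs = self._pending_adapt_macs
        if self.policy.gp_on and len(self.buffer) >= 3:
            adapt_macs += gp_mac_count(len(self.buffer), feats.size)
        lstm_active = self.lstm_current if self.lstm_current is not None \
            else c.lstm_dense
        res = estimate_resources(c.cnn, lstm_active,
                                 replace(self.fusion, alpha_t=alpha),
                                 c.proxy, adaptation_macs=adapt_macs)
        risk_clipped = float(np.clip(risk, 1e-6, 1 - 1e-6))
        state = build_state(out.y_hat, risk_clipped, res.cpu_usage,
                            res.energy_proxy)
        action_idx = None
        if self.policy.agent_on and c.qnet is not None:
            adapt_macs += qnet_mac_count(c.qnet)
            step_for_eps = self.step_count if self.train_agent else 10**9
            action_idx = select_action(state, c.qnet, c.schedule,
                                       step_for_eps, self.rng)
            action = self._constrain_action(c.action_grid.actions[action_idx])
            if self.train_agent and y_true is not None:
                risk_for_reward = risk if self.policy.lambda4_on else 0.0
                reward = rl.compute_reward(y_true, out.y_hat,
                                           res.latency_proxy, res.energy_proxy,
                                           risk_for_reward, c.reward_cfg)
                if self._pending is not None:
                    ps, pa, pr = self._pending
                    self.replay.push(RlTransition(ps, pa, pr, state))
                    if len(self.replay) >= 32:
                        self.learner.td_update(self.replay.sample(32, self.rng))
                self._pending = (state, action_idx, reward)
        else:
            action = (self.fusion.alpha_t, self.fusion.beta_t)

        # 5. adjust the architecture — effective from the next window
        reprune = 0.0
        if action != (self.fusion.alpha_t, self.fusion.beta_t):
            if action[1] != self.fusion.beta_t:
                reprune = reprune_mac_count(c.lstm_dense)
            self.fusion, self.lstm_current = apply_action(
                self.fusion, action, c.lstm_dense, self.step_count)
            if self.lstm_current is None:
                self.lstm_current = models.magnitude_prune(c.lstm_dense,
                                                           action[1])
        self._pending_adapt_macs = reprune

        self.logs.append({
            "window": self.step_count, "t": window.start_s,
            "alpha": alpha, "beta": self.fusion.beta_t,
            "p_risk": float(out.y_hat[1]), "risk": risk,
            "decision": out.decision, "alert": out.alert,
            "y_true": y_true if y_true is not None else -1,
            "macs": res.mac_count + res.adaptation_macs,
            "adapt_macs": res.adaptation_macs,
            "latency_proxy": res.latency_proxy,
            "energy_proxy": res.energy_proxy,
            "cpu_usage": res.cpu_usage,
            "action": -1 if action_idx is None else action_idx,
            "fallback": fallback,
        })
        self.step_count += 1
        return out, forecast, self.fusion

    def _constrain_action(self, action: tuple[float, float]):
        alpha, beta = action
        if self.policy.fixed_alpha is not None:
            alpha = self.policy.fixed_alpha
        if self.policy.fixed_beta is not None:
            beta = self.policy.fixed_beta
        return (alpha, beta)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.logs)


def _lstm_seq_single(x: np.ndarray, params: models.LstmParams):
    state = None
    h = None
    for t in range(x.shape[0]):
        h, state = models.lstm_forward(x[t], state, params)
    return h, state


@dataclass
class SessionResult:
    mode: str
    logs: pd.DataFrame
    event_times: list[float]
    alert_times: list[float]
    window_s: float = 0.2


def run_session(windows: list[MotionWindow], components: RuntimeComponents,
                mode: str = "full", seed: int = 0,
                event_times: list[float] | None = None,
                train_agent: bool = False,
                learner: QLearner | None = None,
                replay: ReplayBuffer | None = None) -> SessionResult:
    """Stream one preprocessed session through the loop in the given mode.

    Alert times are the *end* of each alerting window plus the forecast
    horizon for risk-driven alerts (the forecast refers to t + horizon)."""
    rt = AdaptiveRuntime(components, mode=mode, seed=seed,
                         train_agent=train_agent, learner=learner,
                         replay=replay)
    for w in windows:
        rt.step(w, y_true=w.label)
    logs = rt.log_frame()
    alert_times = [] if logs.empty else \
        (logs.loc[logs["alert"], "t"] + 0.2).tolist()
    return SessionResult(mode=mode, logs=logs,
                         event_times=list(event_times or []),
                         alert_times=alert_times)
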