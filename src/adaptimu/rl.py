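"""Q-learning controller for ensemble sizing.

The agent observes s_t = [y_hat, r_forecast, cpu_usage, energy] and picks a
discrete action (alpha, beta): the CNN/LSTM mixing coefficient and the LSTM
pruning ratio.  The reward trades detection accuracy against latency and
energy proxies, with a bonus term when the forecast risk crosses the
threshold tau = 0.6 (rewarding vigilance ahead of predicted high-risk
transitions):

    R_t = l1 * Acc(y, y_hat) - l2 * Latency - l3 * Energy + l4 * I(r > tau)

The Q-function is a two-layer network with a swish hidden layer,
Q(s, a) = w2^T swish(W1 s + b1) + b2, trained by Q-learning with a circular
experience-replay buffer (capacity 10,000), a periodically synced target
network, and epsilon-greedy exploration decaying linearly from 0.1 to 0.01
over the first 1,000 timesteps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gp import RISK_THRESHOLD

REPLAY_CAPACITY = 10_000
DEFAULT_ALPHAS = tuple(round(a, 1) for a in np.arange(0.0, 1.01, 0.1))
DEFAULT_BETAS = (0.0, 0.2, 0.4, 0.6, 0.8)


@dataclass(frozen=True)
class ActionGrid:
    """Cross product of admissible mixing coefficients and pruning ratios."""

    alphas: tuple = DEFAULT_ALPHAS
    betas: tuple = DEFAULT_BETAS

    def __post_init__(self):
        if any(not 0.0 <= a <= 1.0 for a in self.alphas):
            raise ValueError("alphas must lie in [0, 1]")
        if any(not 0.0 <= b < 1.0 for b in self.betas):
            raise ValueError("betas must lie in [0, 1)")

    @property
    def actions(self) -> list[tuple[float, float]]:
        return [(a, b) for a in self.alphas for b in self.betas]

    def __len__(self) -> int:
        return len(self.alphas) * len(self.betas)

    def index_of(self, alpha: float, beta: float) -> int:
        return self.actions.index((alpha, beta))


def build_state(y_hat, risk: float, cpu: float, energy: float) -> np.ndarray:
    """Concatenate [y_hat, risk, cpu_usage, energy] into the state vector."""
    y_hat = np.asarray(y_hat, dtype=float)
    if abs(y_hat.sum() - 1.0) > 1e-6:
        raise ValueError("y_hat must be a probability vector summing to 1")
    if not (0.0 < risk < 1.0):
        raise ValueError("risk must lie in (0, 1)")
    if not (0.0 <= cpu <= 1.0):
        raise ValueError("cpu_usage must lie in [0, 1]")
    return np.concatenate([y_hat, [risk, cpu, energy]])


@dataclass
class RewardConfig:
    lambda1: float = 1.0
    lambda2: float = 0.01
    lambda3: float = 0.01
    lambda4: float = 0.5
    tau: float = RISK_THRESHOLD
    latency_scale: float = 1.0
    energy_scale: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must lie in (0, 1)")
        for name in ("lambda1", "lambda2", "lambda3", "lambda4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def compute_reward(y_true: int, y_hat, latency_proxy: float,
                   energy_proxy: float, risk: float,
                   cfg: RewardConfig) -> float:
    """Four-term reward; accuracy is the 0/1 agreement of argmax(y_hat)."""
    acc = 1.0 if int(np.argmax(np.asarray(y_hat))) == int(y_true) else 0.0
    r = (cfg.lambda1 * acc
         - cfg.lambda2 * latency_proxy / cfg.latency_scale
         - cfg.lambda3 * energy_proxy / cfg.energy_scale
         + cfg.lambda4 * (1.0 if risk > cfg.tau else 0.0))
    return float(r)


# ---------------------------------------------------------------------------
# Q-network


def swish(z: np.ndarray) -> np.ndarray:
    return z / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class QNetwork:
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray          # hidden x |A|
    b2: np.ndarray

    @property
    def n_actions(self) -> int:
        return self.W2.shape[1]

    def copy(self) -> "QNetwork":
        return QNetwork(self.W1.copy(), self.b1.copy(),
                        self.W2.copy(), self.b2.copy())


def init_qnetwork(state_dim: int, n_actions: int, hidden: int = 32,
                  seed: int = 0) -> QNetwork:
    rng = np.random.default_rng(seed)
    return QNetwork(
        W1=rng.standard_normal((state_dim, hidden)) / np.sqrt(state_dim),
        b1=np.zeros(hidden),
        W2=rng.standard_normal((hidden, n_actions)) / np.sqrt(hidden),
        b2=np.zeros(n_actions))


def q_forward(state: np.ndarray, net: QNetwork) -> np.ndarray:
    """Q-values for every action: w2^T swish(W1 s + b1) + b2."""
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != net.W1.shape[0]:
        raise ValueError("state dimension does not match Q-network")
    return swish(state @ net.W1 + net.b1) @ net.W2 + net.b2


def _q_forward_cached(S: np.ndarray, net: QNetwork):
    z = S @ net.W1 + net.b1
    h = swish(z)
    return h @ net.W2 + net.b2, (z, h)


def _q_backward(dq: np.ndarray, S: np.ndarray, cache, net: QNetwork) -> dict:
    z, h = cache
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    dswish = sig * (1.0 + z * (1.0 - sig))
    dh = dq @ net.W2.T
    dz = dh * dswish
    return {"W1": S.T @ dz, "b1": dz.sum(axis=0),
            "W2": h.T @ dq, "b2": dq.sum(axis=0)}


# ---------------------------------------------------------------------------
# exploration and replay


@dataclass
class ExplorationSchedule:
    eps_start: float = 0.1
    eps_end: float = 0.01
    decay_steps: int = 1000

    def epsilon(self, step: int) -> float:
        """Linear decay from eps_start at step 0 to eps_end at decay_steps."""
        if step >= self.decay_steps:
            return self.eps_end
        frac = step / self.decay_steps
        return self.eps_start + frac * (self.eps_end - self.eps_start)


def select_action(state: np.ndarray, net: QNetwork,
                  schedule: ExplorationSchedule, step: int,
                  rng: np.random.Generator) -> int:
    """Epsilon-greedy action; greedy ties break to the lowest index."""
    if step < 0:
        raise ValueError("step must be non-negative")
    if rng.uniform() < schedule.epsilon(step):
        return int(rng.integers(0, net.n_actions))
    return int(np.argmax(q_forward(state, net)))


@dataclass
class RlTransition:
    state: np.ndarray
    action: int
    reward: float
    next_state: np.ndarray


class ReplayBuffer:
    """Fixed-capacity circular buffer of transitions (FIFO overwrite)."""

    def __init__(self, capacity: int = REPLAY_CAPACITY):
        self.capacity = capacity
        self._data: list[RlTransition] = []
        self._cursor = 0

    def __len__(self) -> int:
        return len(self._data)

    def __getitem__(self, i: int) -> RlTransition:
        return self._data[i]

    def push(self, transition: RlTransition) -> "ReplayBuffer":
        if len(self._data) < self.capacity:
            self._data.append(transition)
        else:
            self._data[self._cursor] = transition
        self._cursor = (self._cursor + 1) % self.capacity
        return self

    def sample(self, n: int, rng: np.random.Generator) -> list[RlTransition]:
        """Uniform sample without replacement within the minibatch."""
        if len(self._data) == 0:
            raise ValueError("cannot sample from an empty replay buffer")
        if n > len(self._data):
            raise ValueError("minibatch larger than buffer contents")
        idx = rng.choice(len(self._data), size=n, replace=False)
        return [self._data[i] for i in idx]


def push_transition(buffer: ReplayBuffer, transition: RlTransition) -> ReplayBuffer:
    return buffer.push(transition)


def sample_minibatch(buffer: ReplayBuffer, n: int,
                     rng: np.random.Generator) -> list[RlTransition]:
    return buffer.sample(n, rng)


# ---------------------------------------------------------------------------
# learning


class QLearner:
    """Q-learning with experience replay and a periodically synced target."""

    def __init__(self, net: QNetwork, gamma: float = 0.95,
                 learning_rate: float = 1e-3, target_sync: int = 100):
        if not (0.0 <= gamma < 1.0):
            raise ValueError("gamma must lie in [0, 1)")
        self.net = net
        self.target = net.copy()
        self.gamma = gamma
        self.learning_rate = learning_rate
        self.target_sync = target_sync
        self._updates = 0

    def td_update(self, minibatch: list[RlTransition]) -> float:
        """One gradient step on the squared TD error of the minibatch."""
        S = np.stack([tr.state for tr in minibatch])
        A = np.array([tr.action for tr in minibatch])
        R = np.array([tr.reward for tr in minibatch])
        S2 = np.stack([tr.next_state for tr in minibatch])
        target_q = R + self.gamma * q_forward(S2, self.target).max(axis=1)
        q_all, cache = _q_forward_cached(S, self.net)
        n = len(minibatch)
        td = q_all[np.arange(n), A] - target_q
        dq = np.zeros_like(q_all)
        dq[np.arange(n), A] = 2.0 * td / n
        grads = _q_backward(dq, S, cache, self.net)
        if self.learning_rate > 0:
            self.net.W1 -= self.learning_rate * grads["W1"]
            self.net.b1 -= self.learning_rate * grads["b1"]
            self.net.W2 -= self.learning_rate * grads["W2"]
            self.net.b2 -= self.learning_rate * grads["b2"]
            self._updates += 1
            if self._updates % self.target_sync == 0:
                self.target = self.net.copy()
        return float(np.mean(td * td))


def td_update(net: QNetwork, minibatch, gamma: float,
              learning_rate: float) -> QNetwork:
    """Functional single-step wrapper around :class:`QLearner`."""
    learner = QLearner(net.copy(), gamma=gamma, learning_rate=learning_rate,
                       target_sync=10**9)
    learner.target = net.copy()
    learner.td_update(minibatch)
    return learner.net


def run_training(env, episodes: int = 500, seed: int = 0,
                 gamma: float = 0.95, learning_rate: float = 1e-3,
                 batch_size: int = 32, hidden: int = 32,
                 schedule: ExplorationSchedule | None = None,
                 buffer_capacity: int = REPLAY_CAPACITY,
                 target_sync: int = 100):
    """Episodic training loop coupling action selection, replay, and TD
    updates.  ``env`` must expose reset() -> state and step(action) ->
    (next_state, reward, done).  Returns (net, reward_curve)."""
    rng = np.random.default_rng(seed)
    schedule = schedule or ExplorationSchedule()
    state = env.reset()
    net = init_qnetwork(len(np.asarray(state)), env.n_actions,
                        hidden=hidden, seed=seed)
    learner = QLearner(net, gamma=gamma, learning_rate=learning_rate,
                       target_sync=target_sync)
    buffer = ReplayBuffer(buffer_capacity)
    curve = []
    step_count = 0
    for _ep in range(episodes):
        state = env.reset()
        ep_reward, done = 0.0, False
        while not done:
            action = select_action(state, learner.net, schedule,
                                   step_count, rng)
            next_state, reward, done = env.step(action)
            if not np.isfinite(reward):
                raise ValueError("environment returned a non-finite reward")
            buffer.push(RlTransition(np.asarray(state, float), action,
                                     float(reward), np.asarray(next_state, float)))
            if len(buffer) >= batch_size:
                learner.td_update(buffer.sample(batch_size, rng))
            state = next_state
            ep_reward += reward
            step_count += 1
        curve.append(ep_reward)
    return learner.net, np.asarray(curve)
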