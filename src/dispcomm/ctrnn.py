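"""Genome encoding and continuous-time recurrent neural network dynamics.

Each agent is controlled by a small CTRNN with three input neurons, five
fully recurrent hidden neurons and two (receiver) or three (sender) output
neurons.  The two motor outputs set speed and direction; the sender's third
output is the emitted signal amplitude.

Every parameter of a network is encoded by one gene in ``[0, 1]``:

* connection weights map linearly to ``[-4, 4]`` (``w = 8 g - 4``),
* biases map to ``[-2, 2]`` (``theta = 4 g - 2``),
* time constants map to ``[0.1, 1.0]`` (``tau = 0.1 + 0.9 g``).

Gene ordering (the on-disk and in-memory layout) is: input->hidden weights
(input-major), hidden->hidden weights (source-major), hidden->output weights
(source-major), then per-neuron biases and per-neuron time constants, each in
input, hidden, output order.  This yields genome lengths of 77 for senders
(15 + 25 + 15 + 11 + 11) and 70 for receivers (15 + 25 + 10 + 10 + 10).

State integration follows the standard CTRNN leaky Euler step

    s_i(t) = s_i(t-1) + (alpha / tau_i) * (drive_i(t) - s_i(t-1)),
    y_i(t) = sigmoid(s_i(t) + theta_i),

with step size ``alpha = 0.1``; time constants then span memory horizons of
one to ten steps.  A tau-multiplicative variant
(``s = alpha * tau * (drive - s)``, ``integration="printed"``) is retained
as a sensitivity switch; it crushes state within a single step (see
``DEFAULT_INTEGRATION``) and cannot support memory-dependent behavior.
Within one time step the layers update in order: input neurons integrate the
raw sensory values (their drive is the sensory value itself), then hidden
neurons integrate the freshly updated input activations plus the previous
hidden activations (recurrence), then output neurons integrate the fresh
hidden activations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHA = 0.1  # Euler step size

#: Default state-integration scheme.  "leaky" is the conventional CTRNN Euler
#: step s += alpha/tau * (drive - s); "printed" is the tau-multiplicative
#: variant s = alpha * tau * (drive - s), kept as a sensitivity switch.  The
#: printed variant forgets its state within one step and attenuates every
#: drive by alpha*tau <= 0.1, leaving the network without the memory that
#: displaced communication requires, so the leaky form is the default.
DEFAULT_INTEGRATION = "leaky"

WEIGHT_RANGE = (-4.0, 4.0)
BIAS_RANGE = (-2.0, 2.0)
TAU_RANGE = (0.1, 1.0)

SENDER = "sender"
RECEIVER = "receiver"


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class Architecture:
    """Fixed network topology for one agent role."""

    n_inputs: int = 3
    n_hidden: int = 5
    n_outputs: int = 3  # 3 for sender (2 motor + signal), 2 for receiver

    @property
    def n_neurons(self) -> int:
        return self.n_inputs + self.n_hidden + self.n_outputs

    @property
    def n_weights(self) -> int:
        return (
            self.n_inputs * self.n_hidden
            + self.n_hidden * self.n_hidden
            + self.n_hidden * self.n_outputs
        )

    @property
    def genome_length(self) -> int:
        # weights + biases + time constants, one gene each
        return self.n_weights + 2 * self.n_neurons


SENDER_ARCH = Architecture(n_inputs=3, n_hidden=5, n_outputs=3)
RECEIVER_ARCH = Architecture(n_inputs=3, n_hidden=5, n_outputs=2)

ARCHITECTURES = {SENDER: SENDER_ARCH, RECEIVER: RECEIVER_ARCH}


def architecture_for(role: str) -> Architecture:
    try:
        return ARCHITECTURES[role]
    except KeyError:
        raise ValueError(f"unknown role {role!r}") from None


@dataclass
class Genome:
    """A flat vector of genes in [0, 1] encoding one agent's network."""

    genes: np.ndarray
    role: str

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=float)
        arch = architecture_for(self.role)
        if self.genes.shape != (arch.genome_length,):
            raise ValueError(
                f"{self.role} genome must have length {arch.genome_length}, "
                f"got shape {self.genes.shape}"
            )
        if np.any(self.genes < 0) or np.any(self.genes > 1):
            raise ValueError("genes must lie in [0, 1]")

    @property
    def architecture(self) -> Architecture:
        return architecture_for(self.role)


@dataclass
class NetworkParams:
    """Decoded network parameters for one agent.

    ``w_in``: (n_inputs, n_hidden), ``w_hh``: (n_hidden, n_hidden) with
    ``w_hh[j, i]`` the weight from hidden j to hidden i, ``w_out``:
    (n_hidden, n_outputs).  ``bias`` and ``tau`` are per-neuron in input,
    hidden, output order.  There are no input->output or output->anything
    connections.
    """

    w_in: np.ndarray
    w_hh: np.ndarray
    w_out: np.ndarray
    bias: np.ndarray
    tau: np.ndarray
    alpha: float = ALPHA

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[-2]

    @property
    def n_hidden(self) -> int:
        return self.w_hh.shape[-1]

    @property
    def n_outputs(self) -> int:
        return self.w_out.shape[-1]


@dataclass
class NetworkState:
    """Per-neuron internal states ``s`` and activations ``y``."""

    s: np.ndarray
    y: np.ndarray


def decode_genome(genome: Genome) -> NetworkParams:
    """Map a genome's genes onto weights, biases and time constants.

    The map is linear and bijective onto the parameter ranges; see the module
    docstring for the gene layout.
    """
    arch = genome.architecture
    g = genome.genes
    ni, nh, no = arch.n_inputs, arch.n_hidden, arch.n_outputs
    nn = arch.n_neurons

    k = 0
    w_in = (8.0 * g[k : k + ni * nh] - 4.0).reshape(ni, nh)
    k += ni * nh
    w_hh = (8.0 * g[k : k + nh * nh] - 4.0).reshape(nh, nh)
    k += nh * nh
    w_out = (8.0 * g[k : k + nh * no] - 4.0).reshape(nh, no)
    k += nh * no
    bias = 4.0 * g[k : k + nn] - 2.0
    k += nn
    tau = 0.1 + 0.9 * g[k : k + nn]
    k += nn
    assert k == arch.genome_length
    return NetworkParams(w_in=w_in, w_hh=w_hh, w_out=w_out, bias=bias, tau=tau)


def decode_population(genes: np.ndarray, arch: Architecture) -> NetworkParams:
    """Decode a whole population at once.

    ``genes`` has shape (n, genome_length); the returned params carry a
    leading population axis on every array and broadcast through
    :func:`ctrnn_step` and :func:`init_state`.
    """
    g = np.asarray(genes, dtype=float)
    if g.ndim != 2 or g.shape[1] != arch.genome_length:
        raise ValueError(f"expected shape (n, {arch.genome_length}), got {g.shape}")
    n = g.shape[0]
    ni, nh, no = arch.n_inputs, arch.n_hidden, arch.n_outputs
    nn = arch.n_neurons
    k = 0
    w_in = (8.0 * g[:, k : k + ni * nh] - 4.0).reshape(n, ni, nh)
    k += ni * nh
    w_hh = (8.0 * g[:, k : k + nh * nh] - 4.0).reshape(n, nh, nh)
    k += nh * nh
    w_out = (8.0 * g[:, k : k + nh * no] - 4.0).reshape(n, nh, no)
    k += nh * no
    bias = 4.0 * g[:, k : k + nn] - 2.0
    k += nn
    tau = 0.1 + 0.9 * g[:, k : k + nn]
    return NetworkParams(w_in=w_in, w_hh=w_hh, w_out=w_out, bias=bias, tau=tau)


def encode_params(params: NetworkParams, role: str) -> Genome:
    """Inverse of :func:`decode_genome` (used for fixtures and round-trips)."""
    genes = np.concatenate(
        [
            (params.w_in.ravel() + 4.0) / 8.0,
            (params.w_hh.ravel() + 4.0) / 8.0,
            (params.w_out.ravel() + 4.0) / 8.0,
            (params.bias + 2.0) / 4.0,
            (params.tau - 0.1) / 0.9,
        ]
    )
    return Genome(genes=np.clip(genes, 0.0, 1.0), role=role)


def init_state(params: NetworkParams) -> NetworkState:
    """Fresh state at trial start: all internal states zero, y = sigmoid(bias).

    Networks are re-initialized before every trial so the five food
    placements of an evaluation are exchangeable.
    """
    nn = params.bias.shape[-1]
    s = np.zeros(params.bias.shape)
    y = sigmoid(s + params.bias)
    return NetworkState(s=s, y=y)


def _integrate(s_prev, drive, tau, alpha, integration):
    if integration == "printed":
        return alpha * tau * (drive - s_prev)
    elif integration == "leaky":
        return s_prev + (alpha / tau) * (drive - s_prev)
    raise ValueError(f"unknown integration scheme {integration!r}")


def ctrnn_step(
    params: NetworkParams,
    state: NetworkState,
    sensory_inputs: np.ndarray,
    integration: str = DEFAULT_INTEGRATION,
) -> NetworkState:
    """Advance the network one time step given raw sensory values.

    Input neurons integrate the sensory value as their drive; hidden neurons
    integrate the new input activations and the previous hidden activations;
    output neurons integrate the new hidden activations.  Supports a leading
    batch dimension on ``state``/``params`` arrays (sensory_inputs then has
    shape ``(..., n_inputs)``).
    """
    ni = params.n_inputs
    nh = params.n_hidden
    x = np.asarray(sensory_inputs, dtype=float)
    if x.shape[-1] != ni:
        raise ValueError(f"expected {ni} sensory inputs, got {x.shape[-1]}")

    s_prev = state.s
    y_prev = state.y
    s = np.empty_like(s_prev)
    y = np.empty_like(y_prev)

    tau, bias, alpha = params.tau, params.bias, params.alpha
    sl_in = slice(0, ni)
    sl_h = slice(ni, ni + nh)
    sl_out = slice(ni + nh, None)

    s[..., sl_in] = _integrate(s_prev[..., sl_in], x, tau[..., sl_in], alpha, integration)
    y[..., sl_in] = sigmoid(s[..., sl_in] + bias[..., sl_in])

    drive_h = np.einsum("...i,...ij->...j", y[..., sl_in], params.w_in) + np.einsum(
        "...i,...ij->...j", y_prev[..., sl_h], params.w_hh
    )
    s[..., sl_h] = _integrate(s_prev[..., sl_h], drive_h, tau[..., sl_h], alpha, integration)
    y[..., sl_h] = sigmoid(s[..., sl_h] + bias[..., sl_h])

    drive_o = np.einsum("...i,...ij->...j", y[..., sl_h], params.w_out)
    s[..., sl_out] = _integrate(s_prev[..., sl_out], drive_o, tau[..., sl_out], alpha, integration)
    y[..., sl_out] = sigmoid(s[..., sl_out] + bias[..., sl_out])

    return NetworkState(s=s, y=y)


def motor_command(y_a, y_b, max_speed):
    """Translate the two motor activations into (speed, direction).

    Speed is the absolute difference of the two activations scaled by the
    maximum speed; direction is the sign of the difference (+1 on an exact
    tie, where the speed is zero anyway).
    """
    diff = np.asarray(y_a) - np.asarray(y_b)
    speed = np.abs(diff) * max_speed
    direction = np.where(diff >= 0, 1.0, -1.0)
    return speed, direction


def make_fixture_genome(behavior: str, amplitude: float | None = None) -> Genome:
    """Hand-constructed genomes with provable behavior, for tests and probes.

    Supported behaviors:

    * ``"stationary"`` (receiver or sender): all genes 0.5 decode to all-zero
      weights and biases, so the two motor activations are identical at every
      step and the agent never moves.
    * ``"constant_full_speed_ccw"`` (sender): hidden neurons are driven to
      saturation by maximal biases and feed the first motor output with
      maximal positive weights and the second with maximal negative weights,
      so the speed is constant and close to (but, sigmoid outputs being open,
      strictly below) the maximum, with counterclockwise direction.
    * ``"constant_amplitude"`` (sender): emits a constant amplitude
      ``sigmoid(logit(a))`` each step via the signal-output bias (exact for
      amplitudes within sigmoid([-2, 2])); amplitudes outside that band
      additionally recruit saturated hidden drive.
    """
    if behavior == "stationary":
        arch = RECEIVER_ARCH
        return Genome(genes=np.full(arch.genome_length, 0.5), role=RECEIVER)

    arch = SENDER_ARCH
    w_in = np.zeros((arch.n_inputs, arch.n_hidden))
    w_hh = np.zeros((arch.n_hidden, arch.n_hidden))
    w_out = np.zeros((arch.n_hidden, arch.n_outputs))
    bias = np.zeros(arch.n_neurons)
    tau = np.full(arch.n_neurons, 1.0)

    if behavior == "constant_full_speed_ccw":
        bias[arch.n_inputs : arch.n_inputs + arch.n_hidden] = 2.0  # saturate hidden
        w_out[:, 0] = 4.0
        w_out[:, 1] = -4.0
        bias[arch.n_inputs + arch.n_hidden + 0] = 2.0
        bias[arch.n_inputs + arch.n_hidden + 1] = -2.0
    elif behavior == "constant_amplitude":
        if amplitude is None or not 0.0 <= amplitude <= 1.0:
            raise ValueError("constant_amplitude requires an amplitude in [0, 1]")
        sig_neuron = arch.n_inputs + arch.n_hidden + 2
        with np.errstate(divide="ignore"):
            logit = np.log(amplitude / (1.0 - amplitude)) if 0 < amplitude < 1 else np.inf * np.sign(amplitude - 0.5)
        if np.isfinite(logit) and abs(logit) <= 2.0:
            bias[sig_neuron] = logit
        else:
            # recruit saturated hidden drive; steady-state hidden state is
            # alpha*tau*drive/(1+alpha*tau) so the reachable band is documented
            # as "near 0/near 1", not exact
            bias[arch.n_inputs : arch.n_inputs + arch.n_hidden] = 2.0
            w_out[:, 2] = 4.0 if amplitude > 0.5 else -4.0
            bias[sig_neuron] = 2.0 if amplitude > 0.5 else -2.0
    else:
        raise ValueError(f"unsupported fixture behavior {behavior!r}")

    return encode_params(
        NetworkParams(w_in=w_in, w_hh=w_hh, w_out=w_out, bias=bias, tau=tau),
        role=SENDER,
    )
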