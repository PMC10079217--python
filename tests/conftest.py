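"""Shared fixtures and the independent per-neuron CTRNN reference.

The reference implementation below is deliberately written as plain Python
loops over individual neurons, independent of the package's vectorized and
compiled paths, and serves as the oracle for equivalence tests.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from dispcomm import ctrnn
from dispcomm.world import default_world


@pytest.fixture
def world():
    return default_world()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def reference_ctrnn_step(params, s_prev, y_prev, x, integration):
    """Naive per-neuron CTRNN update (oracle).

    Mirrors the documented semantics: input neurons integrate the raw
    sensory value, hidden neurons the fresh input activations plus previous
    hidden activations, output neurons the fresh hidden activations.
    """

    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    def integ(s, drive, tau):
        if integration == "printed":
            return params.alpha * tau * (drive - s)
        return s + (params.alpha / tau) * (drive - s)

    ni, nh, no = params.n_inputs, params.n_hidden, params.n_outputs
    s = list(s_prev)
    y = list(y_prev)
    for i in range(ni):
        s[i] = integ(s_prev[i], x[i], params.tau[i])
        y[i] = sig(s[i] + params.bias[i])
    for j in range(nh):
        drive = 0.0
        for i in range(ni):
            drive += y[i] * params.w_in[i, j]
        for i in range(nh):
            drive += y_prev[ni + i] * params.w_hh[i, j]
        k = ni + j
        s[k] = integ(s_prev[k], drive, params.tau[k])
        y[k] = sig(s[k] + params.bias[k])
    for j in range(no):
        drive = 0.0
        for i in range(nh):
            drive += y[ni + i] * params.w_out[i, j]
        k = ni + nh + j
        s[k] = integ(s_prev[k], drive, params.tau[k])
        y[k] = sig(s[k] + params.bias[k])
    return np.array(s), np.array(y)


def random_genome(role: str, rng: np.random.Generator) -> ctrnn.Genome:
    arch = ctrnn.architecture_for(role)
    return ctrnn.Genome(genes=rng.random(arch.genome_length), role=role)
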