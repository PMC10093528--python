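"""Central finite-difference oracle for the backpropagation gradients.

Evaluates the training loss as a black-box function of every weight and
bias — it never touches :func:`fnnsweep.fnn.backward` — so it provides an
independent check of the analytic gradients.  A finite difference is only
a valid derivative estimate where the loss is differentiable in an
``h``-neighbourhood, so :func:`well_conditioned` screens check points for
proximity to the ReLU kinks, the hard-sigmoid ramp corners, the
cross-entropy probability clip, and (when an L1 penalty is active) weights
near zero where the subgradient is set-valued.
"""

from __future__ import annotations

import numpy as np

from .fnn import HyperParams, NetworkParams, forward, loss


def numerical_gradients(params: NetworkParams, X, y, hp: HyperParams, h: float = 1e-5):
    """Central differences (L(w+h)-L(w-h))/2h for every weight and bias."""
    def f():
        return loss(y, forward(params, X, hp, training=False)["p"], hp, params)

    grads_w, grads_b = [], []
    for arr_list, grads in ((params.weights, grads_w), (params.biases, grads_b)):
        for arr in arr_list:
            g = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ij = it.multi_index
                orig = arr[ij]
                arr[ij] = orig + h
                lp = f()
                arr[ij] = orig - h
                lm = f()
                arr[ij] = orig
                g[ij] = (lp - lm) / (2.0 * h)
            grads.append(g)
    return grads_w, grads_b


def well_conditioned(params: NetworkParams, X, y, hp: HyperParams,
                     margin: float = 1e-3) -> bool:
    """True when (params, X) sit away from every non-smooth locus of the loss."""
    cache = forward(params, X, hp, training=False)
    for z in cache["z"][:-1]:  # hidden pre-activations vs ReLU kink
        if np.min(np.abs(z)) < margin:
            return False
    p = cache["p"]
    if hp.output_activation == "hard_sigmoid":
        z_out = cache["z"][-1]
        if np.min(np.abs(np.abs(z_out) - 2.5)) < margin:  # ramp corners
            return False
    if np.min(p) < margin or np.max(p) > 1.0 - margin:  # clip region
        return False
    if hp.l1 > 0 and any(np.min(np.abs(w)) < margin for w in params.weights):
        return False
    return True


def random_small_configs(n_configs: int, seed: int = 0, n_cases: int = 8,
                         n_features: int = 4):
    """Yield (params, X, y, hp) for random small networks at generic points.

    Varies initializer, output activation, depth (1-3 layers) and L1/L2;
    candidate draws that land near a non-smooth locus of the loss are
    rejected, so every yielded configuration is a valid finite-difference
    check point.
    """
    from .fnn import INITIALIZERS, OUTPUT_ACTIVATIONS, init_params

    rng = np.random.default_rng(seed)
    produced = 0
    while produced < n_configs:
        hp = HyperParams(
            output_activation=OUTPUT_ACTIVATIONS[rng.integers(2)],
            weight_initializer=INITIALIZERS[rng.integers(len(INITIALIZERS))],
            n_hidden_layers=int(rng.integers(1, 4)),
            hidden_width=int(rng.integers(2, 6)),
            dropout_rate=0.0,
            l1=float(rng.choice([0.0, 0.01, 0.05])),
            l2=float(rng.choice([0.0, 0.01, 0.1])),
        )
        sizes = hp.layer_sizes(n_features)
        params = init_params(sizes, hp.weight_initializer, int(rng.integers(2**31)))
        X = rng.normal(size=(n_cases, n_features))
        y = rng.integers(0, 2, n_cases).astype(float)
        if not well_conditioned(params, X, y, hp):
            continue
        produced += 1
        yield params, X, y, hp


def max_relative_error(analytic_w, analytic_b, numeric_w, numeric_b,
                       floor: float = 1e-6) -> float:
    """max |a - n| / max(|a| + |n|, floor) over all parameters."""
    worst = 0.0
    for a_list, n_list in ((analytic_w, numeric_w), (analytic_b, numeric_b)):
        for a, n in zip(a_list, n_list):
            rel = np.abs(a - n) / np.maximum(np.abs(a) + np.abs(n), floor)
            worst = max(worst, float(rel.max()))
    return worst
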