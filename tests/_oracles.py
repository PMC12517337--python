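"""Independent oracles shared by the test modules.

These deliberately avoid the library code paths they check: the AUC oracle
counts concordant pairs with explicit loops, and the gradient oracle uses
central finite differences on the loss value alone.
"""

import numpy as np

from fedvar.params import unflatten_params


def brute_force_auc(scores, labels):
    """Pairwise concordance count over all (positive, negative) pairs."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def finite_difference_check(model, pv, X, y, eps=1e-5, n_coords=12, seed=0):
    """Max relative error between analytic and central-difference gradients.

    Coordinates where both gradients vanish (biases under batch norm, masked
    forest weights) are compared with an absolute floor of 1e-4 so roundoff
    in the difference quotient does not register as disagreement.
    """
    p = unflatten_params(pv)
    _, grads = model.loss_grad({k: v.copy() for k, v in p.items()}, X, y)
    rng = np.random.default_rng(seed)
    max_rel = 0.0
    for name in p:
        if name in model.non_trainable or name.startswith("bn_running"):
            continue
        flat = p[name].ravel()
        for i in rng.choice(flat.size, size=min(n_coords, flat.size), replace=False):
            def loss_at(v):
                q = {k: a.copy() for k, a in p.items()}
                q[name].ravel()[i] = v
                return model.loss_grad(q, X, y)[0]

            num = (loss_at(flat[i] + eps) - loss_at(flat[i] - eps)) / (2 * eps)
            ana = grads[name].ravel()[i]
            max_rel = max(max_rel, abs(num - ana) / max(abs(num), abs(ana), 1e-4))
    return max_rel
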