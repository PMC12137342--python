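"""Independent numerical oracles used by the tests.

These deliberately avoid the package's analytic (Bateman) path: the decay
system dN/dt = A·N is integrated as a stiff ODE (Radau, tight tolerances),
and time integrals use adaptive quadrature.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad, solve_ivp


def decay_matrix(chain):
    """Rate matrix A of dN/dt = A·N over the chain's radioactive members."""
    nucs = chain.radioactive_members
    idx = {n.name: i for i, n in enumerate(nucs)}
    A = np.zeros((len(nucs), len(nucs)))
    for n in nucs:
        A[idx[n.name], idx[n.name]] = -n.decay_constant
        for daughter, frac in n.branches:
            if daughter in idx:
                A[idx[daughter], idx[n.name]] += frac * n.decay_constant
    return A, idx


def ode_activities(chain, parent_activity_0, times, rtol=1e-12, atol=1e-22):
    """Chain activities at ``times`` (s) by stiff ODE integration.

    Returns {nuclide: array of activities aligned with times}.
    """
    times = np.atleast_1d(np.asarray(times, float))
    A, idx = decay_matrix(chain)
    n0 = np.zeros(len(idx))
    n0[idx[chain.root]] = parent_activity_0 / chain.parent.decay_constant
    sol = solve_ivp(
        lambda t, y: A @ y,
        (0.0, float(times[-1])),
        n0,
        method="Radau",
        jac=lambda t, y: A,
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    assert sol.success
    return {
        name: chain[name].decay_constant * sol.y[i]
        for name, i in idx.items()
    }


def quadrature_tia(conc_fn, t_max_s, **kwargs):
    """Adaptive-quadrature ∫₀^t_max conc(t) dt."""
    val, err = quad(conc_fn, 0.0, t_max_s, limit=400, **kwargs)
    return val
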