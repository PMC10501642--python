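"""Independent brute-force oracles for the reduced two-type chains.

These build the *full* one-step transition matrix of the reduced chain --
self-transitions included -- and solve the standard absorbing-chain linear
systems with dense numpy algebra.  They share no code path with the
package's conditional-jump-chain solvers, so agreement is a genuine
cross-check.
"""

from __future__ import annotations

import numpy as np

from evograph.chains import BDChain, StarChain


def _absorbing_solve(P: np.ndarray, transient: np.ndarray, fix_targets: np.ndarray):
    """phi, conditional fixation/extinction times from a full matrix.

    ``fix_targets``: indices of absorbing states counting as fixation.
    Returns arrays over the transient states (in the given order).
    """
    n_states = P.shape[0]
    Q = P[np.ix_(transient, transient)]
    R = P[np.ix_(transient, fix_targets)]
    I = np.eye(transient.size)
    phi = np.linalg.solve(I - Q, R.sum(axis=1))
    psi_fix = np.linalg.solve(I - Q, phi)
    ext = 1.0 - phi
    psi_ext = np.linalg.solve(I - Q, ext)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_fix = np.where(phi > 1e-300, psi_fix / phi, np.nan)
        tau_ext = np.where(ext > 1e-300, psi_ext / ext, np.nan)
    return phi, tau_fix, tau_ext


def star_dense_oracle(c: StarChain) -> dict[str, np.ndarray]:
    """Exact absorption quantities for the (2n+2)-state star chain.

    Returns dicts of arrays indexed by the leaf-mutant count i = 0..n for
    the mutant-center ('center') and wild-type-center ('leaf') states.
    """
    n = c.n
    b = lambda i: i  # (•, i)
    w = lambda i: n + 1 + i  # (∘, i)
    size = 2 * n + 2
    P = np.zeros((size, size))
    T_uc, T_dc = c.T_up_center(), c.T_down_center()
    T_ul, T_dl = c.T_up_leaf(), c.T_down_leaf()
    for i in range(n):
        P[b(i), b(i + 1)] = T_uc[i]
        P[b(i), w(i)] = T_dc[i]
        P[b(i), b(i)] = 1.0 - T_uc[i] - T_dc[i]
    P[b(n), b(n)] = 1.0
    for i in range(1, n + 1):
        P[w(i), b(i)] = T_ul[i - 1]
        P[w(i), w(i - 1)] = T_dl[i - 1]
        P[w(i), w(i)] = 1.0 - T_ul[i - 1] - T_dl[i - 1]
    P[w(0), w(0)] = 1.0

    transient = np.array([b(i) for i in range(n)] + [w(i) for i in range(1, n + 1)])
    phi_t, tau_fix_t, tau_ext_t = _absorbing_solve(P, transient, np.array([b(n)]))

    def unpack(vec, fill_b_n, fill_w_0):
        out_b = np.empty(n + 1)
        out_w = np.empty(n + 1)
        out_b[:n] = vec[:n]
        out_b[n] = fill_b_n
        out_w[1:] = vec[n:]
        out_w[0] = fill_w_0
        return out_b, out_w

    phi_b, phi_w = unpack(phi_t, 1.0, 0.0)
    tf_b, tf_w = unpack(tau_fix_t, 0.0, np.nan)
    te_b, te_w = unpack(tau_ext_t, np.nan, 0.0)
    return {
        "phi_center": phi_b,
        "phi_leaf": phi_w,
        "tau_fix_center": tf_b,
        "tau_fix_leaf": tf_w,
        "tau_ext_center": te_b,
        "tau_ext_leaf": te_w,
    }


def bd_dense_oracle(c: BDChain) -> dict[str, np.ndarray]:
    """Exact absorption quantities for a birth-death chain, states 0..N."""
    N = c.N
    P = np.zeros((N + 1, N + 1))
    for i in range(1, N):
        P[i, i + 1] = c.T_plus[i - 1]
        P[i, i - 1] = c.T_minus[i - 1]
        P[i, i] = 1.0 - c.T_plus[i - 1] - c.T_minus[i - 1]
    P[0, 0] = 1.0
    P[N, N] = 1.0
    transient = np.arange(1, N)
    phi_t, tau_fix_t, tau_ext_t = _absorbing_solve(P, transient, np.array([N]))
    pad = lambda v, lo, hi: np.concatenate([[lo], v, [hi]])
    return {
        "phi": pad(phi_t, 0.0, 1.0),
        "tau_fix": pad(tau_fix_t, np.nan, 0.0),
        "tau_ext": pad(tau_ext_t, 0.0, np.nan),
    }


def bd_tau1_nested_sum(c: BDChain) -> float:
    """Conditional single-mutant fixation time via the classical nested sum.

    ``tau_1 = sum_{k=1}^{N-1} sum_{l=1}^{k} (phi_l / T_l+)
    prod_{m=l+1}^{k} gamma_m`` evaluated with an O(N) inner recurrence --
    an implementation route independent of the package's tridiagonal solve.
    """
    N = c.N
    gamma = c.gamma()
    # phi_l via direct cumulative products (small-N oracle use only)
    cum = np.cumprod(gamma)
    denom = 1.0 + cum.sum()
    phi = np.array([(1.0 + cum[: l - 1].sum()) / denom for l in range(1, N)])
    tau = 0.0
    S = 0.0
    for k in range(1, N):
        S = gamma[k - 1] * S + phi[k - 1] / c.T_plus[k - 1]
        tau += S
    return tau
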