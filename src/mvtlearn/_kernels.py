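"""Numerical kernels for likelihood replay.

The per-second reward-rate recursion is sequential, so likelihood evaluation
is a tight loop over the seconds of a session.  The loops are jitted with
numba when available and fall back to pure Python otherwise; both paths apply
the identical delta-rule arithmetic ``rho += alpha * (r - rho)`` in the same
order, so results agree bit-for-bit with the simulator's trace path.

Trial encoding: ``choice`` is 0 = reject, 1 = accept, 2 = missed.  ``enc_upd``
and ``timeout_upd`` are the number of zero-reward updates applied per
encounter/timeout (0 when the update cadence is restricted to handling
seconds).  ``order_code`` selects the double-update order on the reward
second: 0 = delay update then reward update (default), 1 = reversed.
"""

from __future__ import annotations

import math

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def loglik_pertrial(
    choice, r_opt, t_opt, include, enc_upd, timeout_upd, handling_upd,
    ap, am, b0, b1, rho0, order_code, out_ll,
):
    """Total log-likelihood and per-trial terms (NaN where no term applies)."""
    rho = rho0
    ll = 0.0
    n = choice.shape[0]
    for i in range(n):
        for _ in range(enc_upd):
            rho = rho + am * (0.0 - rho)
        c = rho * t_opt[i]
        x = b1 * (r_opt[i] - c) - b0
        out_ll[i] = math.nan
        if include[i] and choice[i] != 2:
            if x >= 0.0:
                lse = math.log1p(math.exp(-x))  # -log sigmoid(x)
                log_p = -lse
                log_q = -x - lse
            else:
                lse = math.log1p(math.exp(x))
                log_p = x - lse
                log_q = -lse
            term = log_p if choice[i] == 1 else log_q
            out_ll[i] = term
            ll += term
        if choice[i] == 1:
            if handling_upd:
                for _ in range(t_opt[i] - 1):
                    rho = rho + am * (0.0 - rho)
            if order_code == 0:
                rho = rho + am * (0.0 - rho)
                rho = rho + ap * (r_opt[i] - rho)
            else:
                rho = rho + ap * (r_opt[i] - rho)
                rho = rho + am * (0.0 - rho)
        elif choice[i] == 2:
            for _ in range(timeout_upd):
                rho = rho + am * (0.0 - rho)
    return ll, rho


@njit(cache=True)
def loglik_grad(
    choice, r_opt, t_opt, include, enc_upd, timeout_upd, handling_upd,
    ap, am, b0, b1, rho0, order_code,
):
    """Log-likelihood and its gradient w.r.t. (ap, am, b0, b1) in natural space.

    Forward-mode accumulation: carry d(rho)/d(ap) and d(rho)/d(am) through the
    recursion.  Zero-reward updates use ``am``; reward updates use ``ap``.
    """
    rho = rho0
    g_ap = 0.0
    g_am = 0.0
    ll = 0.0
    G_ap = 0.0
    G_am = 0.0
    G_b0 = 0.0
    G_b1 = 0.0
    n = choice.shape[0]
    for i in range(n):
        for _ in range(enc_upd):
            g_ap = (1.0 - am) * g_ap
            g_am = (1.0 - am) * g_am - rho
            rho = rho + am * (0.0 - rho)
        c = rho * t_opt[i]
        x = b1 * (r_opt[i] - c) - b0
        if include[i] and choice[i] != 2:
            if x >= 0.0:
                ex = math.exp(-x)
                p = 1.0 / (1.0 + ex)
                lse = math.log1p(ex)
                log_p = -lse
                log_q = -x - lse
            else:
                ex = math.exp(x)
                p = ex / (1.0 + ex)
                lse = math.log1p(ex)
                log_p = x - lse
                log_q = -lse
            if choice[i] == 1:
                ll += log_p
                dldx = 1.0 - p
            else:
                ll += log_q
                dldx = -p
            drho = dldx * (-b1 * t_opt[i])
            G_ap += drho * g_ap
            G_am += drho * g_am
            G_b0 += -dldx
            G_b1 += dldx * (r_opt[i] - c)
        if choice[i] == 1:
            if handling_upd:
                for _ in range(t_opt[i] - 1):
                    g_ap = (1.0 - am) * g_ap
                    g_am = (1.0 - am) * g_am - rho
                    rho = rho + am * (0.0 - rho)
            if order_code == 0:
                g_ap = (1.0 - am) * g_ap
                g_am = (1.0 - am) * g_am - rho
                rho = rho + am * (0.0 - rho)
                g_ap = (1.0 - ap) * g_ap + (r_opt[i] - rho)
                g_am = (1.0 - ap) * g_am
                rho = rho + ap * (r_opt[i] - rho)
            else:
                g_ap = (1.0 - ap) * g_ap + (r_opt[i] - rho)
                g_am = (1.0 - ap) * g_am
                rho = rho + ap * (r_opt[i] - rho)
                g_ap = (1.0 - am) * g_ap
                g_am = (1.0 - am) * g_am - rho
                rho = rho + am * (0.0 - rho)
        elif choice[i] == 2:
            for _ in range(timeout_upd):
                g_ap = (1.0 - am) * g_ap
                g_am = (1.0 - am) * g_am - rho
                rho = rho + am * (0.0 - rho)
    return ll, G_ap, G_am, G_b0, G_b1, rho
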