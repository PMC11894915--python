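"""Independent brute-force oracles used to validate the Monte Carlo algorithms.

Each oracle computes an exact expectation by enumeration / closed form and
shares no code path with the estimators it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import betabinom, binom


def _nb_triplet(prev, sens, spec, omega):
    return (
        0.0,
        prev * sens - (1.0 - prev) * (1.0 - spec) * omega,
        prev - (1.0 - prev) * omega,
    )


def exact_evsi_beta_binomial(post, z: float, n_future: int) -> float:
    """Exact EVSI under independent beta posteriors by exhaustive enumeration.

    Future confusion counts are enumerated with their beta-binomial marginal
    probabilities; because the components stay independent given the data
    and the NB is linear in each component (products factorize), the inner
    expectation is the NB at the component-wise posterior means.
    """
    omega = z / (1.0 - z)
    (ap, bp), (ase, bse), (asp, bsp) = post.prev, post.sens, post.spec
    # ENB under current information: expectations factorize over components
    mp, mse, msp = ap / (ap + bp), ase / (ase + bse), asp / (asp + bsp)
    enb_current = max(_nb_triplet(mp, mse, msp, omega))

    enb_sample = 0.0
    for n_pos in range(n_future + 1):
        p_pos = betabinom(n_future, ap, bp).pmf(n_pos)
        n_neg = n_future - n_pos
        for n_tp in range(n_pos + 1):
            p_tp = betabinom(n_pos, ase, bse).pmf(n_tp) if n_pos else 1.0
            for n_tn in range(n_neg + 1):
                p_tn = betabinom(n_neg, asp, bsp).pmf(n_tn) if n_neg else 1.0
                prob = p_pos * p_tp * p_tn
                if prob == 0.0:
                    continue
                prev_u = (ap + n_pos) / (ap + bp + n_future)
                sens_u = (ase + n_tp) / (ase + bse + n_pos)
                spec_u = (asp + n_tn) / (asp + bsp + n_neg)
                nbs = _nb_triplet(prev_u, sens_u, spec_u, omega)
                l = int(np.argmax(nbs))
                # E[NB_l(theta*) | D] = NB_l at the posterior means given D
                enb_sample += prob * nbs[l]
    return enb_sample - enb_current


def exact_evpi_bernoulli_corners(q_prev, q_sens, q_spec, z: float) -> float:
    """Exact EVPI when each component is (approximately) Bernoulli.

    For betas Beta(eps*q, eps*(1-q)) with eps -> 0 the distribution puts
    mass q at 1 and 1-q at 0, so the expectation of the max enumerates the
    eight corners of the unit cube.
    """
    omega = z / (1.0 - z)
    enb_truth = 0.0
    for cp in (0, 1):
        for cse in (0, 1):
            for csp in (0, 1):
                prob = (
                    (q_prev if cp else 1 - q_prev)
                    * (q_sens if cse else 1 - q_sens)
                    * (q_spec if csp else 1 - q_spec)
                )
                enb_truth += prob * max(_nb_triplet(cp, cse, csp, omega))
    enb_current = max(_nb_triplet(q_prev, q_sens, q_spec, omega))
    return enb_truth - enb_current


def exact_evsi_general(draws: np.ndarray, z: float, n_future: int) -> float:
    """Exact EVSI of the likelihood-reweighting algorithm for tiny inputs.

    Enumerates every future confusion-count configuration; for each, the
    reweighted posterior over the M draws and the resulting decision are
    computed exactly, and the scored NB is averaged over truths j with the
    exact data probabilities P(D | theta_j).  Feasible only for small M and
    n_future.
    """
    omega = z / (1.0 - z)
    m = draws.shape[0]
    nbs = np.array([_nb_triplet(*row, omega) for row in draws])  # (M, 3)
    enb_current = max(nbs.mean(axis=0))

    configs = [
        (n_pos, n_tp, n_tn)
        for n_pos in range(n_future + 1)
        for n_tp in range(n_pos + 1)
        for n_tn in range(n_future - n_pos + 1)
    ]
    enb_sample = 0.0
    for j in range(m):
        p, se, sp = draws[j]
        for n_pos, n_tp, n_tn in configs:
            n_neg = n_future - n_pos
            prob = (
                binom.pmf(n_pos, n_future, p)
                * (binom.pmf(n_tp, n_pos, se) if n_pos else 1.0)
                * (binom.pmf(n_tn, n_neg, sp) if n_neg else 1.0)
            )
            if prob == 0.0:
                continue
            w = np.array(
                [
                    binom.pmf(n_pos, n_future, pk)
                    * (binom.pmf(n_tp, n_pos, sek) if n_pos else 1.0)
                    * (binom.pmf(n_tn, n_neg, spk) if n_neg else 1.0)
                    for pk, sek, spk in draws
                ]
            )
            if w.sum() == 0.0:
                continue
            w = w / w.sum()
            weighted = w @ nbs
            weighted[0] = 0.0
            l = int(np.argmax(weighted))
            enb_sample += prob * nbs[j, l] / m
    return enb_sample - enb_current
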