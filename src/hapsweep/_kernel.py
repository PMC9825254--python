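"""Sparse sexed Wright-Fisher kernel for selected-locus origin dynamics.

Tracks only the individuals carrying at least one copy of the focal allele
(each copy labelled by its mutational origin).  Because neutral linked sites
have no fitness effect, the marginal law of the selected-locus process is
identical to the full individual-based engine's; this kernel is an exact
marginalization, not an approximation, and is validated distributionally
against the full engine in the test suite.

Conventions
-----------
* ``sex`` 1 = female, 0 = male.
* ``a``/``b`` hold origin ids (> 0) or 0 for a wild-type copy; for X males
  ``b`` is -1 (no second X).
* Fitness: 1, 1+h*s, 1+s for 0/1/2 focal copies; hemizygous X males carrying
  the allele have fitness 1+s_m (dosage compensation).  Selection acts through
  parent-sampling weights (fecundity selection).
* Mothers are drawn proportional to female fitness, fathers to male fitness;
  fathers transmit their X to daughters only (unrecombined), sons receive no
  focal X from the father.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_CAP = 0
STATUS_FIXED = 1
STATUS_LOST = 2
STATUS_FREQ = 3
STATUS_OVERFLOW = 4
STATUS_SEX_EXTINCT = 5

MAX_ORG = 8192  # simultaneously segregating origins


@njit(cache=True)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def _shuffle(arr, n):
    for i in range(n - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        t = arr[i]
        arr[i] = arr[j]
        arr[j] = t


@njit(cache=True)
def _multinomial(n, p, k, out):
    """Sequential-binomial multinomial draw; returns the total drawn."""
    rem_n = n
    rem_p = 1.0
    total = 0
    for j in range(k):
        if rem_n <= 0 or rem_p <= 1e-15 or p[j] <= 0.0:
            out[j] = 0
            rem_p -= p[j]
            continue
        pj = p[j] / rem_p
        if pj >= 1.0:
            out[j] = rem_n
        else:
            out[j] = np.random.binomial(rem_n, pj)
        rem_n -= out[j]
        total += out[j]
        rem_p -= p[j]
    return total


@njit(cache=True)
def _expand(counts, org_ids, n_org, buf):
    """Expand per-origin counts into a flat origin-id list and shuffle it."""
    k = 0
    for t in range(n_org):
        for _ in range(counts[t]):
            buf[k] = org_ids[t]
            k += 1
    _shuffle(buf, k)
    return k


@njit(cache=True)
def run_phase(
    sex, a, b, n_carr, n_f, n_pop, is_x,
    s_f, h_f, s_m, h_m, mu,
    gen, max_gen,
    stop_on_fix, stop_on_loss, stop_freq,
    origin_gen, next_origin,
    org_ids, gpf, gpm,
    cnt_md, cnt_ms, cnt_pd, cnt_ps,
    buf_mat, buf_pat,
    sex2, a2, b2,
):
    """Advance one selection/mutation regime until a stop condition.

    Returns ``(status, gen, n_carr, n_f, next_origin)``; carrier arrays are
    updated in place (first ``n_carr`` entries valid).
    """
    status = STATUS_CAP
    while gen < max_gen:
        forced_mut = False
        if n_carr == 0:
            if stop_on_loss:
                return STATUS_LOST, gen, n_carr, n_f, next_origin
            if mu <= 0.0:
                gen = max_gen
                break
            copies_exp = 2 * n_pop if not is_x else n_pop + n_pop // 2
            p_any = 1.0 - (1.0 - mu) ** copies_exp
            skip = np.random.geometric(p_any)
            if gen + skip > max_gen:
                gen = max_gen
                break
            gen += skip - 1
            forced_mut = True

        # ---- collect active origins -----------------------------------
        n_org = 0
        for i in range(n_carr):
            ai = a[i]
            if ai > 0:
                found = False
                for t in range(n_org):
                    if org_ids[t] == ai:
                        found = True
                        break
                if not found:
                    org_ids[n_org] = ai
                    n_org += 1
            bi = b[i]
            if bi > 0:
                found = False
                for t in range(n_org):
                    if org_ids[t] == bi:
                        found = True
                        break
                if not found:
                    org_ids[n_org] = bi
                    n_org += 1
        if n_org > MAX_ORG - 8:
            return STATUS_OVERFLOW, gen, n_carr, n_f, next_origin

        # ---- fitness-weighted gamete distributions --------------------
        ncf = 0
        for i in range(n_carr):
            if sex[i] == 1:
                ncf += 1
        ncm = n_carr - ncf
        w_f_tot = float(n_f - ncf)
        w_m_tot = float(n_pop - n_f - ncm)
        for t in range(n_org):
            gpf[t] = 0.0
            gpm[t] = 0.0
        for i in range(n_carr):
            ai = a[i]
            bi = b[i]
            if sex[i] == 1:
                c = (1 if ai > 0 else 0) + (1 if bi > 0 else 0)
                if c == 1:
                    w = 1.0 + s_f * h_f
                elif c == 2:
                    w = 1.0 + s_f
                else:
                    w = 1.0
                if w < 0.0:
                    w = 0.0
                w_f_tot += w
                if ai > 0:
                    for t in range(n_org):
                        if org_ids[t] == ai:
                            gpf[t] += 0.5 * w
                            break
                if bi > 0:
                    for t in range(n_org):
                        if org_ids[t] == bi:
                            gpf[t] += 0.5 * w
                            break
            else:
                if is_x:
                    w = 1.0 + s_m if ai > 0 else 1.0
                    if w < 0.0:
                        w = 0.0
                    w_m_tot += w
                    if ai > 0:
                        for t in range(n_org):
                            if org_ids[t] == ai:
                                gpm[t] += w  # whole X to each daughter
                                break
                else:
                    c = (1 if ai > 0 else 0) + (1 if bi > 0 else 0)
                    if c == 1:
                        w = 1.0 + s_m * h_m
                    elif c == 2:
                        w = 1.0 + s_m
                    else:
                        w = 1.0
                    if w < 0.0:
                        w = 0.0
                    w_m_tot += w
                    if ai > 0:
                        for t in range(n_org):
                            if org_ids[t] == ai:
                                gpm[t] += 0.5 * w
                                break
                    if bi > 0:
                        for t in range(n_org):
                            if org_ids[t] == bi:
                                gpm[t] += 0.5 * w
                                break

        if w_f_tot <= 0.0 or w_m_tot <= 0.0:
            return STATUS_SEX_EXTINCT, gen, n_carr, n_f, next_origin

        # ---- next generation ------------------------------------------
        n_f2 = np.random.binomial(n_pop, 0.5)
        if n_f2 == 0 or n_f2 == n_pop:
            return STATUS_SEX_EXTINCT, gen, n_carr, n_f, next_origin
        n_m2 = n_pop - n_f2
        for t in range(n_org):
            gpf[t] /= w_f_tot
            gpm[t] /= w_m_tot
        k_md = _multinomial(n_f2, gpf, n_org, cnt_md)
        k_ms = _multinomial(n_m2, gpf, n_org, cnt_ms)
        k_pd = _multinomial(n_f2, gpm, n_org, cnt_pd)
        if is_x:
            k_ps = 0
        else:
            k_ps = _multinomial(n_m2, gpm, n_org, cnt_ps)

        n2 = 0
        ncf2 = 0
        # daughters: maternal gamete in a, paternal in b
        _expand(cnt_md, org_ids, n_org, buf_mat)
        _expand(cnt_pd, org_ids, n_org, buf_pat)
        if k_md > 0 and k_pd > 0:
            n_both = np.random.hypergeometric(k_pd, n_f2 - k_pd, k_md)
        else:
            n_both = 0
        for i in range(k_md):
            sex2[n2] = 1
            a2[n2] = buf_mat[i]
            b2[n2] = buf_pat[i] if i < n_both else 0
            n2 += 1
            ncf2 += 1
        for i in range(n_both, k_pd):
            sex2[n2] = 1
            a2[n2] = buf_pat[i]
            b2[n2] = 0
            n2 += 1
            ncf2 += 1
        # sons
        _expand(cnt_ms, org_ids, n_org, buf_mat)
        if is_x:
            for i in range(k_ms):
                sex2[n2] = 0
                a2[n2] = buf_mat[i]
                b2[n2] = -1
                n2 += 1
        else:
            _expand(cnt_ps, org_ids, n_org, buf_pat)
            if k_ms > 0 and k_ps > 0:
                n_both = np.random.hypergeometric(k_ps, n_m2 - k_ps, k_ms)
            else:
                n_both = 0
            for i in range(k_ms):
                sex2[n2] = 0
                a2[n2] = buf_mat[i]
                b2[n2] = buf_pat[i] if i < n_both else 0
                n2 += 1
            for i in range(n_both, k_ps):
                sex2[n2] = 0
                a2[n2] = buf_pat[i]
                b2[n2] = 0
                n2 += 1

        # ---- new mutations --------------------------------------------
        copies2 = 2 * n_pop if not is_x else 2 * n_f2 + n_m2
        if mu > 0.0:
            if forced_mut:
                n_mut = 1 + np.random.binomial(copies2 - 1, mu)
            else:
                n_mut = np.random.binomial(copies2, mu)
            for _ in range(n_mut):
                # carrier copy counts (recomputed: carriers may be appended)
                carr_copies = 0
                if is_x:
                    for i in range(n2):
                        carr_copies += 2 if sex2[i] == 1 else 1
                else:
                    carr_copies = 2 * n2
                r = np.random.randint(0, copies2)
                if r < carr_copies:
                    if is_x:
                        acc = 0
                        for i in range(n2):
                            c = 2 if sex2[i] == 1 else 1
                            if r < acc + c:
                                slot = r - acc
                                if slot == 0:
                                    if a2[i] == 0:
                                        origin_gen[next_origin] = gen
                                        a2[i] = next_origin
                                        next_origin += 1
                                else:
                                    if b2[i] == 0:
                                        origin_gen[next_origin] = gen
                                        b2[i] = next_origin
                                        next_origin += 1
                                break
                            acc += c
                    else:
                        i = r // 2
                        if r % 2 == 0:
                            if a2[i] == 0:
                                origin_gen[next_origin] = gen
                                a2[i] = next_origin
                                next_origin += 1
                        else:
                            if b2[i] == 0:
                                origin_gen[next_origin] = gen
                                b2[i] = next_origin
                                next_origin += 1
                else:
                    rr = r - carr_copies
                    ncm2 = n2 - ncf2
                    wtf_copies = 2 * (n_f2 - ncf2)
                    if rr < wtf_copies:
                        sex2[n2] = 1
                        a2[n2] = next_origin
                        b2[n2] = 0
                    else:
                        sex2[n2] = 0
                        a2[n2] = next_origin
                        b2[n2] = -1 if is_x else 0
                    origin_gen[next_origin] = gen
                    next_origin += 1
                    if sex2[n2] == 1:
                        ncf2 += 1
                    n2 += 1

        # ---- commit ----------------------------------------------------
        for i in range(n2):
            sex[i] = sex2[i]
            a[i] = a2[i]
            b[i] = b2[i]
        n_carr = n2
        n_f = n_f2
        gen += 1

        m_copies = 0
        for i in range(n_carr):
            if a[i] > 0:
                m_copies += 1
            if b[i] > 0:
                m_copies += 1
        if n_carr == 0 and stop_on_loss:
            return STATUS_LOST, gen, n_carr, n_f, next_origin
        if stop_on_fix and m_copies == copies2:
            return STATUS_FIXED, gen, n_carr, n_f, next_origin
        if stop_freq > 0.0 and m_copies >= stop_freq * copies2:
            return STATUS_FREQ, gen, n_carr, n_f, next_origin

    return status, gen, n_carr, n_f, next_origin
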