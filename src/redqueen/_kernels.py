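"""Compiled meiosis and generation-loop kernels (numba).

One fused kernel implements the whole meiosis attempt: chemical-equilibrium
binding on the four chromatids, DSB induction with p = min(1, d/k), the
symmetric-DSB scan, CO choice, conversion repair against the homolog, and
gamete materialization. Both the python-facing ``resolve_meiosis`` and the
generation loop call the same kernel.

Binding is drawn exactly but cheaply. The joint state of the four
independent Bernoulli(x) instances at one target column is sampled with a
single uniform: first the number bound (5-outcome CDF of Binomial(4, x)),
then which chromatids (uniform among the patterns with that popcount,
decoded from the remaining entropy of the same uniform), then chromatids
whose site copy is inactive are masked out (masking independent bits to
zero leaves the remaining bits with their correct marginal law). DSBs are
placed by drawing the Binomial(k, p) count (inversion) and then a uniform
subset of the k bound instances — the exact joint law of per-instance
Bernoulli(p) draws.

Columns are kept sorted by genomic position over a prefix of length
``sorted_prefix`` (newly born alleles append to an unsorted tail until the
next compaction), so the CO arm exchange is two slice copies plus a short
loop over the tail.

Chromatid indexing: bits/indices 0,1 are the sister chromatids of parent
haplotype A, 2,3 of haplotype B. Relative site index j in [0, 2h): j < h is
site j of allele A, else site j - h of allele B; homozygotes use j < h only.

Randomness comes from an explicit xoshiro256++ state (uint64[4]) owned by
the caller and seeded once per simulation via ``seed_state``; draws are
consumed in the fixed order written here, so runs are bit-for-bit
reproducible at a fixed seed, independent of the numpy/numba RNG.
"""

import math

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NO_BINDING = 1
STATUS_NO_SYMMETRIC_DSB = 2
STATUS_NO_DSB = 3  # control mode only: binding occurred but no DSB drawn

_POPCOUNT4 = np.array([0, 1, 1, 2, 1, 2, 2, 3, 1, 2, 2, 3, 2, 3, 3, 4],
                      dtype=np.int64)
# 4-bit patterns grouped by popcount (row = number bound, padded with 0)
_PATTERNS4 = np.array([
    [0, 0, 0, 0, 0, 0],
    [1, 2, 4, 8, 0, 0],
    [3, 5, 6, 9, 10, 12],
    [7, 11, 13, 14, 0, 0],
    [15, 0, 0, 0, 0, 0]], dtype=np.uint8)
_NPATTERNS4 = np.array([1, 4, 6, 4, 1], dtype=np.int64)

_U64 = np.uint64
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


def binding_cdf(x: np.ndarray) -> np.ndarray:
    """CDF of the number bound among 4 chromatids, per site.

    ``x``: occupancy per site, any shape; returns ``x.shape + (5,)`` with
    entry k = P(Binomial(4, x) <= k).
    """
    x = np.asarray(x, dtype=float)
    q = 1.0 - x
    x2 = x * x
    q2 = q * q
    out = np.empty(x.shape + (5,))
    out[..., 0] = q2 * q2
    out[..., 1] = out[..., 0] + 4.0 * x * q * q2
    out[..., 2] = out[..., 1] + 6.0 * x2 * q2
    out[..., 3] = out[..., 2] + 4.0 * x2 * x * q
    out[..., 4] = 1.0
    return out


def new_rng_state(seed: int) -> np.ndarray:
    """Fresh xoshiro256++ state from an integer seed (splitmix64 expansion)."""
    state = np.empty(4, dtype=np.uint64)
    z = _U64(seed & 0xFFFFFFFFFFFFFFFF)
    for i in range(4):
        z = _U64((int(z) + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF)
        t = int(z)
        t = ((t ^ (t >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
        t = ((t ^ (t >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
        state[i] = _U64(t ^ (t >> 31))
    if not state.any():
        state[0] = _U64(1)
    return state


@njit(cache=True, inline="always")
def _next64(rs):
    s0 = rs[0]
    s1 = rs[1]
    s2 = rs[2]
    s3 = rs[3]
    tmp = s0 + s3
    result = ((tmp << _U64(23)) | (tmp >> _U64(41))) + s0
    t = s1 << _U64(17)
    s2 ^= s0
    s3 ^= s1
    s1 ^= s2
    s0 ^= s3
    s2 ^= t
    s3 = (s3 << _U64(45)) | (s3 >> _U64(19))
    rs[0] = s0
    rs[1] = s1
    rs[2] = s2
    rs[3] = s3
    return result


@njit(cache=True, inline="always")
def _rand01(rs):
    return (_next64(rs) >> _U64(11)) * _INV53


@njit(cache=True, inline="always")
def _randint(rs, n):
    # 53-bit uniform scaled to [0, n); exact enough for n << 2^31
    v = int(_rand01(rs) * n)
    return v if v < n else n - 1


@njit(cache=True)
def _binomial(rs, n, p):
    """Binomial(n, p) by CDF inversion; n*p stays small in this model."""
    q = 1.0 - p
    r = _rand01(rs)
    pdf = math.exp(n * math.log(q))
    cdf = pdf
    x = 0
    ratio = p / q
    while r > cdf and x < n:
        x += 1
        pdf *= (n - x + 1) * ratio / x
        cdf += pdf
    return x


@njit(cache=True)
def attempt_meiosis(stateA, stateB, aA, aB, allele_cols, h,
                    cdf_hom, cdf_het, col_pos, sorted_prefix, prdm9_pos,
                    d, require_sym, rs,
                    out_gamete, buf_t, buf_j, buf_sym, bound_nib,
                    pc4, patt4, npatt4):
    """One meiosis attempt; on success writes the gamete into ``out_gamete``.

    ``allele_cols[a]`` lists the columns of live-allele row ``a``;
    ``cdf_hom``/``cdf_het`` are flattened ``binding_cdf`` tables of shape
    (n_rows * h, 5) at dosage c_hom / 1, row a*h+j = site j of allele row a.
    ``rs`` is the xoshiro256++ state; ``bound_nib`` (uint8[>=2h]) and the
    ``buf_*`` DSB buffers (>= 8h entries) are caller scratch. Returns
    (status, k, n_dsb, n_sym, co_buf_index, t_broken, t_partner, t_gamete,
    gamete_allele_row); on failure the last five fields are -1 except the
    allele row, which is aA.
    """
    hom = aA == aB
    n_rel = h if hom else 2 * h
    cdf = cdf_hom if hom else cdf_het

    # --- PRDM9 binding: one uniform per site, count+pattern decode, masking
    k = 0
    for j in range(n_rel):
        if j < h:
            a = aA
            jj = j
        else:
            a = aB
            jj = j - h
        g = allele_cols[a, jj]
        mask = 0
        if stateA[g] != 0:
            mask |= 3
        if stateB[g] != 0:
            mask |= 12
        if mask == 0:
            bound_nib[j] = np.uint8(0)
            continue
        rowf = a * h + jj
        r = _rand01(rs)
        if r < cdf[rowf, 0]:
            bound_nib[j] = np.uint8(0)
            continue
        if r >= cdf[rowf, 3]:
            nib = 15 & mask
        else:
            kk = 1
            while r >= cdf[rowf, kk]:
                kk += 1
            lo = cdf[rowf, kk - 1]
            span = cdf[rowf, kk] - lo
            idx = int((r - lo) / span * npatt4[kk])
            if idx >= npatt4[kk]:
                idx = npatt4[kk] - 1
            nib = patt4[kk, idx] & mask
        bound_nib[j] = np.uint8(nib)
        k += pc4[nib]
    if k == 0:
        return (STATUS_NO_BINDING, 0, 0, 0, -1, -1, -1, -1, aA)

    # --- DSB induction: Binomial(k, p) count + uniform subset of instances
    p = d / k
    nd = k if p >= 1.0 else _binomial(rs, k, p)
    if nd == 0:
        st = STATUS_NO_SYMMETRIC_DSB if require_sym else STATUS_NO_DSB
        return (st, k, 0, 0, -1, -1, -1, -1, aA)
    if nd >= k:
        for i in range(k):
            buf_t[i] = i  # ranks
        nr = k
    else:
        nr = 0
        while nr < nd:
            cand = _randint(rs, k)
            dup = False
            for i in range(nr):
                if buf_t[i] == cand:
                    dup = True
                    break
            if not dup:
                buf_t[nr] = cand
                nr += 1
        for i in range(1, nr):  # insertion sort; nd is small
            key = buf_t[i]
            m = i - 1
            while m >= 0 and buf_t[m] > key:
                buf_t[m + 1] = buf_t[m]
                m -= 1
            buf_t[m + 1] = key
    # single scan locating the ranks -> (chromatid, site, symmetric)
    ns = 0
    idx = 0
    rank = 0
    for j in range(n_rel):
        nib = bound_nib[j]
        if nib == 0:
            continue
        cnt = pc4[nib]
        while idx < nr and buf_t[idx] < rank + cnt:
            off = buf_t[idx] - rank
            t = 0
            seen = -1
            for b in range(4):
                if nib & (1 << b):
                    seen += 1
                    if seen == off:
                        t = b
                        break
            omask = 12 if t < 2 else 3
            sym = 1 if (nib & omask) != 0 else 0
            buf_j[idx] = j
            buf_sym[idx] = np.uint8((t << 1) | sym)
            if sym:
                ns += 1
            idx += 1
        rank += cnt
        if idx == nr:
            break
    for i in range(nr):  # unpack chromatid / symmetry flags
        buf_t[i] = buf_sym[i] >> 1
        buf_sym[i] = buf_sym[i] & 1

    # --- failure tests and CO choice
    if require_sym:
        if ns == 0:
            return (STATUS_NO_SYMMETRIC_DSB, k, nr, 0, -1, -1, -1, -1, aA)
        r_i = _randint(rs, ns)
        co_i = -1
        c = 0
        for i in range(nr):
            if buf_sym[i] != 0:
                if c == r_i:
                    co_i = i
                    break
                c += 1
    else:
        co_i = _randint(rs, nr)

    t_co = buf_t[co_i]
    j_co = buf_j[co_i]
    if j_co < h:
        g_co = allele_cols[aA, j_co]
    else:
        g_co = allele_cols[aB, j_co - h]
    co_pos = col_pos[g_co]

    # CO partner: uniform among the homolog chromatids bound at the CO locus
    nib_co = bound_nib[j_co]
    o = 2 if t_co < 2 else 0
    b1 = (nib_co & (1 << o)) != 0
    b2 = (nib_co & (2 << o)) != 0
    if b1 and b2:
        partner = o + _randint(rs, 2)
    elif b1:
        partner = o
    elif b2:
        partner = o + 1
    else:
        # control mode can pick a CO at an asymmetric DSB
        partner = o + _randint(rs, 2)

    # --- gamete: one of the 4 chromatids uniformly
    gchrom = _randint(rs, 4)
    n_cols = stateA.shape[0]
    base = stateA if gchrom < 2 else stateB
    templ = stateB if gchrom < 2 else stateA
    for g in range(n_cols):  # plain loop: vectorizes to memcpy
        out_gamete[g] = base[g]
    # conversion repair: every DSB copies the homolog haplotype's site state
    for i in range(nr):
        if buf_t[i] == gchrom:
            jx = buf_j[i]
            gg = allele_cols[aA, jx] if jx < h else allele_cols[aB, jx - h]
            out_gamete[gg] = templ[gg]
    gam_allele = aA if gchrom < 2 else aB
    # CO: exchange the arms beyond the CO locus between broken and partner
    if gchrom == t_co or gchrom == partner:
        mate = partner if gchrom == t_co else t_co
        mate_base = stateA if mate < 2 else stateB
        mate_templ = stateB if mate < 2 else stateA
        b = np.searchsorted(col_pos[:sorted_prefix], co_pos, side='right')
        for g in range(b, sorted_prefix):
            out_gamete[g] = mate_base[g]
        for g in range(sorted_prefix, n_cols):
            if col_pos[g] > co_pos:
                out_gamete[g] = mate_base[g]
        for i in range(nr):
            if buf_t[i] == mate:
                jx = buf_j[i]
                gg = allele_cols[aA, jx] if jx < h else allele_cols[aB, jx - h]
                if col_pos[gg] > co_pos:
                    out_gamete[gg] = mate_templ[gg]
        if prdm9_pos > co_pos:
            gam_allele = aA if mate < 2 else aB
    return (STATUS_OK, k, nr, ns, co_i, t_co, partner, gchrom, gam_allele)


@njit(cache=True)
def fill_next_generation(hap_state, hap_allele, next_state, next_allele,
                         n_cols, h, allele_cols, cdf_hom, cdf_het, col_pos,
                         sorted_prefix, prdm9_pos, d, require_sym, n_mei,
                         max_parent_draws, rs):
    """Produce ``next_state.shape[0]`` gametes (independent parent draws).

    A drawn parent gets up to ``n_mei`` meiosis attempts; on failure of all,
    a new parent is drawn. Returns 0, or -1 if ``max_parent_draws``
    consecutive parent draws failed (population effectively sterile).
    """
    N = hap_state.shape[0] // 2
    bound_nib = np.empty(2 * h, np.uint8)
    cap = 8 * h  # strict upper bound on k, hence on the DSB count
    buf_t = np.empty(cap, np.int64)
    buf_j = np.empty(cap, np.int64)
    buf_sym = np.empty(cap, np.uint8)
    pc4 = _POPCOUNT4
    patt4 = _PATTERNS4
    npatt4 = _NPATTERNS4
    for i in range(next_state.shape[0]):
        draws = 0
        done = False
        while not done:
            pidx = _randint(rs, N)
            draws += 1
            for _a in range(n_mei):
                res = attempt_meiosis(
                    hap_state[2 * pidx, :n_cols], hap_state[2 * pidx + 1, :n_cols],
                    hap_allele[2 * pidx], hap_allele[2 * pidx + 1], allele_cols,
                    h, cdf_hom, cdf_het, col_pos, sorted_prefix, prdm9_pos,
                    d, require_sym, rs,
                    next_state[i, :n_cols], buf_t, buf_j, buf_sym, bound_nib,
                    pc4, patt4, npatt4)
                if res[0] == STATUS_OK:
                    next_allele[i] = res[8]
                    done = True
                    break
            if not done and draws >= max_parent_draws:
                return -1
    return 0


@njit(cache=True)
def gather_cols(old_state, src, out_state):
    """Column gather: out[:, t] = old[:, src[t]] (used at compaction)."""
    n = old_state.shape[0]
    m = src.shape[0]
    for i in range(n):
        row = old_state[i]
        orow = out_state[i]
        for t in range(m):
            orow[t] = row[src[t]]


@njit(cache=True)
def hap_theta(hap_state, hap_allele, allele_cols, h):
    """Fraction of active own-allele sites per haplotype."""
    n = hap_state.shape[0]
    out = np.empty(n)
    for i in range(n):
        a = hap_allele[i]
        cnt = 0
        for j in range(h):
            cnt += hap_state[i, allele_cols[a, j]]
        out[i] = cnt / h
    return out


@njit(cache=True)
def hap_block_stats(hap_state, hap_allele, allele_cols, h,
                    x1, x2, x3, xh1, xh2, xh3, col_aff):
    """Per-haplotype realized statistics of the own-allele site block.

    Returns float64[(2N, 9)]: theta, <x>,<x^2>,<x^3> at c=1, the same at
    c=c_hom, mean affinity of active sites, count of active sites.
    Moments are normalized by h (inactive sites contribute zero).
    """
    n = hap_state.shape[0]
    out = np.zeros((n, 9))
    for i in range(n):
        a = hap_allele[i]
        na = 0
        m1 = 0.0
        m2 = 0.0
        m3 = 0.0
        n1 = 0.0
        n2 = 0.0
        n3 = 0.0
        asum = 0.0
        for j in range(h):
            g = allele_cols[a, j]
            if hap_state[i, g] != 0:
                na += 1
                m1 += x1[g]
                m2 += x2[g]
                m3 += x3[g]
                n1 += xh1[g]
                n2 += xh2[g]
                n3 += xh3[g]
                asum += col_aff[g]
        out[i, 0] = na / h
        out[i, 1] = m1 / h
        out[i, 2] = m2 / h
        out[i, 3] = m3 / h
        out[i, 4] = n1 / h
        out[i, 5] = n2 / h
        out[i, 6] = n3 / h
        out[i, 7] = asum / na if na > 0 else 0.0
        out[i, 8] = na
    return out
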