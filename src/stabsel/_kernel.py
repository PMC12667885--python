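"""Numba generation loop for the Wright-Fisher simulator.

This is a fused fast path over the per-step operations in
:mod:`stabsel.simulate`: fitness-weighted parent sampling, independent
Mendelian transmission per segregating site (free recombination),
infinite-sites mutation, and folding of fixed mutations into a phenotype
offset.

Genotypes are held sparsely: each individual owns a list of packed
``(site slot << 2) | genotype`` entries for the sites it carries. At
mutation-selection-drift balance most sites are rare, so the entry count
is an order of magnitude below the dense individual-by-site matrix and
per-generation work scales with the number of allele copies rather than
N x sites. Site slots are recycled through a free list when mutations
are lost or fix, and each offspring's genetic value is accumulated while
its entries are emitted, so no separate dense pass over genotypes is
needed. The Mendelian coin flips consume batched bits from 62-bit
integer draws and the transmission inner loop is branch-free, which
matters: the flips are unpredictable by construction.

The kernel uses numba's internal RNG seeded once per replicate, so a
given (config, seed) is bit-reproducible.
"""

import numpy as np
from numba import njit

__all__ = ["wf_kernel"]


@njit(cache=True)
def wf_kernel(
    N,
    U,
    VM,
    VS,
    VE,
    opt,
    burn_in,
    record_every,
    n_samples,
    seed,
    neutral,
):
    """Run one replicate; return (mean_fitness, vg, pbar) sample series.

    ``neutral`` disables selection (all fitnesses one, uniform parent
    choice) while keeping mutation and drift; used for the drift-limit
    check of the simulator.
    """
    np.random.seed(seed)

    two_n = 2 * N
    lam = 2.0 * N * U
    sd_m = np.sqrt(VM)
    sd_e = np.sqrt(VE) if VE > 0.0 else 0.0
    two_vs = 2.0 * VS

    # site slots
    cap = 256
    eff = np.zeros(cap, dtype=np.float64)
    cnt = np.zeros(cap, dtype=np.int32)
    gbuf = np.zeros(cap, dtype=np.int32)  # per-offspring merge scratch
    free = np.empty(cap, dtype=np.int32)
    for j in range(cap):
        free[j] = cap - 1 - j
    n_free = cap
    active = np.empty(cap, dtype=np.int32)
    n_active = 0

    # packed CSR genotype entries: individual i owns [ptr[i], ptr[i+1])
    max_e = 4096
    ptr = np.zeros(N + 1, dtype=np.int64)
    ent = np.empty(max_e, dtype=np.int32)
    ptr2 = np.zeros(N + 1, dtype=np.int64)
    ent2 = np.empty(max_e, dtype=np.int32)

    touched = np.empty(cap, dtype=np.int32)
    cand = np.empty(cap, dtype=np.int32)

    offset = 0.0
    z = np.zeros(N, dtype=np.float64)  # genetic values, current generation
    z2 = np.empty(N, dtype=np.float64)
    w = np.empty(N, dtype=np.float64)
    cum = np.empty(N, dtype=np.float64)

    mf = np.empty(n_samples, dtype=np.float64)
    vg_out = np.empty(n_samples, dtype=np.float64)
    pb = np.empty(n_samples, dtype=np.float64)

    # batched fair-coin bits
    bit_buf = np.int64(0)
    bits_left = 0

    mut_slot = np.empty(64, dtype=np.int32)
    mut_carrier = np.empty(64, dtype=np.int64)

    total_gens = burn_in + (n_samples - 1) * record_every + 1
    sample_i = 0

    for gen in range(total_gens):
        # phenotypes and fitness from stored genetic values
        wsum = 0.0
        psum = 0.0
        if neutral:
            for i in range(N):
                w[i] = 1.0
                psum += z[i] + (np.random.normal(0.0, sd_e) if sd_e > 0.0 else 0.0)
            wsum = float(N)
        else:
            for i in range(N):
                p = z[i]
                if sd_e > 0.0:
                    p += np.random.normal(0.0, sd_e)
                d = p - opt
                wi = np.exp(-d * d / two_vs)
                w[i] = wi
                wsum += wi
                psum += p
        if wsum <= 0.0 or not np.isfinite(wsum):
            raise ValueError(
                "all fitnesses underflowed to zero; increase vs or reduce vm"
            )

        if gen >= burn_in and (gen - burn_in) % record_every == 0:
            zbar = 0.0
            for i in range(N):
                zbar += z[i]
            zbar /= N
            ss = 0.0
            for i in range(N):
                d = z[i] - zbar
                ss += d * d
            mf[sample_i] = wsum / N
            vg_out[sample_i] = ss / N
            pb[sample_i] = psum / N
            sample_i += 1
            if sample_i == n_samples:
                break

        if not neutral:
            acc = 0.0
            for i in range(N):
                acc += w[i]
                cum[i] = acc

        # draw this generation's new mutations up front
        n_new = np.random.poisson(lam) if lam > 0.0 else 0
        if n_new > mut_slot.shape[0]:
            mut_slot = np.empty(2 * n_new, dtype=np.int32)
            mut_carrier = np.empty(2 * n_new, dtype=np.int64)
        for m in range(n_new):
            if n_free == 0:
                cap2 = cap * 2
                effn = np.zeros(cap2, dtype=np.float64)
                cntn = np.zeros(cap2, dtype=np.int32)
                gbufn = np.zeros(cap2, dtype=np.int32)
                freen = np.empty(cap2, dtype=np.int32)
                activen = np.empty(cap2, dtype=np.int32)
                touchedn = np.empty(cap2, dtype=np.int32)
                candn = np.empty(cap2, dtype=np.int32)
                effn[:cap] = eff
                cntn[:cap] = cnt
                gbufn[:cap] = gbuf
                activen[:n_active] = active[:n_active]
                for j in range(cap, cap2):
                    freen[n_free] = cap2 - 1 - (j - cap)
                    n_free += 1
                eff, cnt, gbuf, free, active = effn, cntn, gbufn, freen, activen
                touched, cand = touchedn, candn
                cap = cap2
            n_free -= 1
            s = free[n_free]
            mut_slot[m] = s
            mut_carrier[m] = np.random.randint(0, N)
            eff[s] = np.random.normal(0.0, sd_m)
        # visit mutations in carrier order during the offspring loop
        morder = np.argsort(mut_carrier[:n_new])

        # zero counts of candidate slots before re-accumulating
        n_cand = 0
        for jj in range(n_active):
            s = active[jj]
            cnt[s] = 0
            cand[n_cand] = s
            n_cand += 1
        for m in range(n_new):
            s = mut_slot[m]
            cnt[s] = 0
            cand[n_cand] = s
            n_cand += 1

        # reproduction: two fitness-weighted parents per offspring,
        # Mendelian transmission per carried site, plus new mutations
        pos = 0
        mptr = 0
        for i in range(N):
            ptr2[i] = pos
            if neutral:
                p1 = np.random.randint(0, N)
                p2 = np.random.randint(0, N)
            else:
                r = np.random.random() * wsum
                lo = 0
                hi = N - 1
                while lo < hi:
                    mid = (lo + hi) >> 1
                    if cum[mid] > r:
                        hi = mid
                    else:
                        lo = mid + 1
                p1 = lo
                r = np.random.random() * wsum
                lo = 0
                hi = N - 1
                while lo < hi:
                    mid = (lo + hi) >> 1
                    if cum[mid] > r:
                        hi = mid
                    else:
                        lo = mid + 1
                p2 = lo
            nt = 0
            for par in range(2):
                pp = p1 if par == 0 else p2
                for e in range(ptr[pp], ptr[pp + 1]):
                    # branch-free Mendelian transmission of one entry:
                    # genotype 2 always passes a copy, genotype 1 passes
                    # one with probability 1/2 (a batched random bit)
                    if bits_left == 0:
                        bit_buf = np.random.randint(0, np.int64(1) << 62)
                        bits_left = 62
                    take = np.int32(bit_buf & 1)
                    bit_buf >>= 1
                    bits_left -= 1
                    v = ent[e]
                    g = v & 3
                    inc = (g >> 1) | (take & g)
                    s = v >> 2
                    old = gbuf[s]
                    gbuf[s] = old + inc
                    touched[nt] = s
                    nt += np.int32(inc != 0) & np.int32(old == 0)
            while mptr < n_new and mut_carrier[morder[mptr]] == i:
                s = mut_slot[morder[mptr]]
                if gbuf[s] == 0:
                    touched[nt] = s
                    nt += 1
                gbuf[s] += 1
                mptr += 1
            # emit offspring entries, accumulating its genetic value
            if pos + nt > max_e:
                max_e2 = 2 * max_e + 2 * nt
                en = np.empty(max_e2, dtype=np.int32)
                en[:pos] = ent2[:pos]
                ent2 = en
                en = np.empty(max_e2, dtype=np.int32)
                en[: ptr[N]] = ent[: ptr[N]]
                ent = en
                max_e = max_e2
            zi = offset
            for t in range(nt):
                s = touched[t]
                g = gbuf[s]
                gbuf[s] = 0
                ent2[pos] = (s << 2) | g
                pos += 1
                cnt[s] += g
                zi += g * eff[s]
            z2[i] = zi
        ptr2[N] = pos

        # prune: free lost slots, fold fixed slots into the offset
        n_active = 0
        any_fixed = False
        for jj in range(n_cand):
            s = cand[jj]
            c = cnt[s]
            if c == 0:
                free[n_free] = s
                n_free += 1
            elif c == two_n:
                offset += 2.0 * eff[s]
                cnt[s] = -1  # mark fixed for entry compaction
                any_fixed = True
            else:
                active[n_active] = s
                n_active += 1
        if any_fixed:
            newpos = 0
            for i in range(N):
                start = ptr2[i]
                ptr2[i] = newpos
                stop = pos if i == N - 1 else ptr2[i + 1]
                for e in range(start, stop):
                    v = ent2[e]
                    if cnt[v >> 2] != -1:
                        ent2[newpos] = v
                        newpos += 1
            ptr2[N] = newpos
            for jj in range(n_cand):
                s = cand[jj]
                if cnt[s] == -1:
                    cnt[s] = 0
                    free[n_free] = s
                    n_free += 1

        # swap generations
        ptr, ptr2 = ptr2, ptr
        ent, ent2 = ent2, ent
        z, z2 = z2, z

    return mf, vg_out, pb
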