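"""Compiled inner loop of the overdamped filament simulation.

Integration scheme: backward Euler per filament for the stiff linear terms
(bending via the discrete biharmonic operator, inextensibility via stiff
axial springs in an isotropic split), with all couplings to other bodies
(cross-linkers, tethers, steric contacts, confinement) treated by a
lagged-anchor diagonally-implicit split: each such spring contributes its
stiffness to the diagonal of the filament system and its anchor (evaluated
at the previous positions) to the right-hand side.  This keeps one shared
symmetric pentadiagonal matrix per filament for the x, y and z components
and is stable at the working time step of 1 ms despite spring constants of
order 10^3–10^5 pN/μm.

Units: μm, pN, s throughout (the engine sits behind the nm→μm boundary).
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DIVERGED = 1


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _band_cholesky(ab, n):
    """In-place Cholesky of a symmetric pentadiagonal SPD matrix.

    ab is (3, n) lower-band storage: ab[0] diagonal, ab[1] first
    sub-diagonal, ab[2] second sub-diagonal.
    """
    for j in range(n):
        s = ab[0, j]
        k0 = j - 2 if j >= 2 else 0
        for k in range(k0, j):
            s -= ab[j - k, k] * ab[j - k, k]
        d = np.sqrt(s)
        ab[0, j] = d
        imax = j + 3 if j + 3 <= n else n
        for i in range(j + 1, imax):
            v = ab[i - j, j]
            kk0 = i - 2 if i >= 2 else 0
            for k in range(kk0, j):
                v -= ab[i - k, k] * ab[j - k, k]
            ab[i - j, j] = v / d


@njit(cache=True)
def _band_solve3(ab, b, n):
    """Solve L L^T x = b for 3 right-hand sides; b is (n, 3), overwritten."""
    for i in range(n):
        k0 = i - 2 if i >= 2 else 0
        for c in range(3):
            v = b[i, c]
            for k in range(k0, i):
                v -= ab[i - k, k] * b[k, c]
            b[i, c] = v / ab[0, i]
    for i in range(n - 1, -1, -1):
        imax = i + 3 if i + 3 <= n else n
        for c in range(3):
            v = b[i, c]
            for k in range(i + 1, imax):
                v -= ab[k - i, i] * b[k, c]
            b[i, c] = v / ab[0, i]


@njit(cache=True)
def advance(
    pos,            # (n, 3) bead positions, modified in place
    fil_ptr,        # (nf+1,) filament bead ranges
    fil_dir,        # (nf,) +1 pole-A filament, -1 pole-B
    fil_of_bead,    # (n,)
    ds,             # (nf,) segment length per filament
    gamma_bead,     # (nf,) drag per bead
    teth_bead, teth_spb, teth_dx, teth_dy, teth_dz,  # tether definitions
    teth_k,
    spb_x,          # (2,) SPB positions on the x-axis, modified in place
    gamma_spb,
    lk_a, lk_b,     # (n_linkers_max,) linker bead indices
    bead_link_count,  # (n,)
    n_lk_start,
    lk_rest, lk_k,
    n_steps, dt, kT,
    ei, k_stretch,
    steric_range, steric_k,
    alpha, centring,
    pole_k0, pole_k_rate, pole_k_max, pole_rest,
    bind_linkers_flag, bind_every, bind_batch,
    capture, midzone_half, max_links_per_bead,
    record_every, forces_out,
):
    """Run n_steps of overdamped dynamics; returns (status, n_lk, n_recorded)."""
    n = pos.shape[0]
    nf = fil_ptr.shape[0] - 1
    n_teth = teth_bead.shape[0]
    n_lk = n_lk_start
    n_rec = 0

    force = np.zeros((n, 3))
    kdiag = np.zeros(n)
    noise_amp = np.empty(nf)
    for f in range(nf):
        noise_amp[f] = np.sqrt(2.0 * kT * gamma_bead[f] / dt) if kT > 0 else 0.0
    spb_noise = np.sqrt(2.0 * kT * gamma_spb / dt) if kT > 0 else 0.0

    for istep in range(n_steps):
        t = istep * dt
        pole_k = pole_k0 + pole_k_rate * t
        if pole_k > pole_k_max:
            pole_k = pole_k_max

        for i in range(n):
            kdiag[i] = 0.0
            force[i, 0] = 0.0
            force[i, 1] = 0.0
            force[i, 2] = 0.0

        # --- cross-linker springs (Hookean, rest length lk_rest) ---
        for l in range(n_lk):
            a = lk_a[l]
            b = lk_b[l]
            dx = pos[b, 0] - pos[a, 0]
            dy = pos[b, 1] - pos[a, 1]
            dz = pos[b, 2] - pos[a, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > 1e-12:
                fmag = lk_k * (r - lk_rest) / r
                force[a, 0] += fmag * dx
                force[a, 1] += fmag * dy
                force[a, 2] += fmag * dz
                force[b, 0] -= fmag * dx
                force[b, 1] -= fmag * dy
                force[b, 2] -= fmag * dz
            kdiag[a] += lk_k
            kdiag[b] += lk_k

        # --- steric repulsion between different filaments (x-binning) ---
        if steric_k > 0.0 and nf > 1:
            xmin = pos[0, 0]
            xmax = pos[0, 0]
            for i in range(1, n):
                if pos[i, 0] < xmin:
                    xmin = pos[i, 0]
                if pos[i, 0] > xmax:
                    xmax = pos[i, 0]
            nbins = int((xmax - xmin) / steric_range) + 1
            counts = np.zeros(nbins + 1, dtype=np.int64)
            binidx = np.empty(n, dtype=np.int64)
            for i in range(n):
                b_i = int((pos[i, 0] - xmin) / steric_range)
                if b_i >= nbins:
                    b_i = nbins - 1
                binidx[i] = b_i
                counts[b_i + 1] += 1
            for b_i in range(nbins):
                counts[b_i + 1] += counts[b_i]
            order = np.empty(n, dtype=np.int64)
            fill = counts[:nbins].copy()
            for i in range(n):
                order[fill[binidx[i]]] = i
                fill[binidx[i]] += 1
            r2cut = steric_range * steric_range
            for i in range(n):
                bi = binidx[i]
                fi = fil_of_bead[i]
                for bb in range(bi, min(bi + 2, nbins)):
                    for jj in range(counts[bb], counts[bb + 1]):
                        j = order[jj]
                        if j <= i and bb == bi:
                            continue
                        if fil_of_bead[j] == fi:
                            continue
                        dx = pos[j, 0] - pos[i, 0]
                        dy = pos[j, 1] - pos[i, 1]
                        dz = pos[j, 2] - pos[i, 2]
                        d2 = dx * dx + dy * dy + dz * dz
                        if d2 >= r2cut or d2 < 1e-18:
                            continue
                        r = np.sqrt(d2)
                        fmag = steric_k * (steric_range - r) / r
                        force[i, 0] -= fmag * dx
                        force[i, 1] -= fmag * dy
                        force[i, 2] -= fmag * dz
                        force[j, 0] += fmag * dx
                        force[j, 1] += fmag * dy
                        force[j, 2] += fmag * dz
                        kdiag[i] += steric_k
                        kdiag[j] += steric_k

        # --- tethers to SPB face points ---
        spb_force = np.zeros(2)
        spb_kdiag = np.zeros(2)
        for tt in range(n_teth):
            b = teth_bead[tt]
            s = teth_spb[tt]
            ax = spb_x[s] + teth_dx[tt]
            force[b, 0] += teth_k * (ax - pos[b, 0])
            force[b, 1] += teth_k * (teth_dy[tt] - pos[b, 1])
            force[b, 2] += teth_k * (teth_dz[tt] - pos[b, 2])
            kdiag[b] += teth_k
            spb_force[s] += teth_k * (pos[b, 0] - ax)
            spb_kdiag[s] += teth_k

        # --- lateral confinement / centring toward the x-axis ---
        for f in range(nf):
            k_lat = (alpha + centring) * ds[f]
            if k_lat > 0.0:
                for i in range(fil_ptr[f], fil_ptr[f + 1]):
                    force[i, 1] -= k_lat * pos[i, 1]
                    force[i, 2] -= k_lat * pos[i, 2]
                    kdiag[i] += k_lat

        # --- thermal noise ---
        if kT > 0.0:
            for f in range(nf):
                amp = noise_amp[f]
                for i in range(fil_ptr[f], fil_ptr[f + 1]):
                    force[i, 0] += amp * np.random.standard_normal()
                    force[i, 1] += amp * np.random.standard_normal()
                    force[i, 2] += amp * np.random.standard_normal()

        # --- per-filament implicit solve ---
        for f in range(nf):
            i0 = fil_ptr[f]
            nb = fil_ptr[f + 1] - i0
            dsf = ds[f]
            kb = ei / (dsf * dsf * dsf)
            gdt = gamma_bead[f] / dt
            ab = np.zeros((3, nb))
            rhs = np.empty((nb, 3))
            # stretch: isotropic chain Laplacian + lagged rest-length force
            for i in range(nb):
                lap = 2.0 if 0 < i < nb - 1 else 1.0
                ab[0, i] = gdt + kdiag[i0 + i] + k_stretch * lap
            for i in range(nb - 1):
                ab[1, i] = -k_stretch
            # bending: free-free biharmonic band
            if nb >= 3:
                for i in range(nb):
                    if i == 0 or i == nb - 1:
                        d4 = 1.0
                    elif i == 1 or i == nb - 2:
                        d4 = 5.0 if nb >= 4 else 4.0
                    else:
                        d4 = 6.0
                    ab[0, i] += kb * d4
                for i in range(nb - 1):
                    o1 = -2.0 if (i == 0 or i == nb - 2) else -4.0
                    ab[1, i] += kb * o1
                for i in range(nb - 2):
                    ab[2, i] += kb * 1.0
            # rhs: (gamma/dt + kdiag)*x_old + external force + rest-length term
            for i in range(nb):
                gi = gdt + kdiag[i0 + i]
                rhs[i, 0] = gi * pos[i0 + i, 0] + force[i0 + i, 0]
                rhs[i, 1] = gi * pos[i0 + i, 1] + force[i0 + i, 1]
                rhs[i, 2] = gi * pos[i0 + i, 2] + force[i0 + i, 2]
            for i in range(nb - 1):
                ux = pos[i0 + i + 1, 0] - pos[i0 + i, 0]
                uy = pos[i0 + i + 1, 1] - pos[i0 + i, 1]
                uz = pos[i0 + i + 1, 2] - pos[i0 + i, 2]
                r = np.sqrt(ux * ux + uy * uy + uz * uz)
                if r > 1e-12:
                    c = k_stretch * dsf / r
                    rhs[i, 0] += -c * ux
                    rhs[i, 1] += -c * uy
                    rhs[i, 2] += -c * uz
                    rhs[i + 1, 0] += c * ux
                    rhs[i + 1, 1] += c * uy
                    rhs[i + 1, 2] += c * uz
            _band_cholesky(ab, nb)
            _band_solve3(ab, rhs, nb)
            for i in range(nb):
                pos[i0 + i, 0] = rhs[i, 0]
                pos[i0 + i, 1] = rhs[i, 1]
                pos[i0 + i, 2] = rhs[i, 2]

        # --- SPBs: semi-implicit scalar update on the x-axis ---
        sep = spb_x[1] - spb_x[0]
        ext = sep - pole_rest
        fsp = pole_k * ext
        for s in range(2):
            ftot = spb_force[s] + (fsp if s == 0 else -fsp)
            if spb_noise > 0.0:
                ftot += spb_noise * np.random.standard_normal()
            spb_x[s] += ftot / (gamma_spb / dt + spb_kdiag[s] + pole_k)

        # --- cross-linker binding (initialisation phase only) ---
        if bind_linkers_flag and (istep % bind_every == 0) and n_lk < lk_a.shape[0]:
            centre = 0.5 * (spb_x[0] + spb_x[1])
            cand_a = np.empty(4096, dtype=np.int64)
            cand_b = np.empty(4096, dtype=np.int64)
            n_cand = 0
            for f1 in range(nf):
                if fil_dir[f1] != 1:
                    continue
                for f2 in range(nf):
                    if fil_dir[f2] != -1:
                        continue
                    for i in range(fil_ptr[f1], fil_ptr[f1 + 1]):
                        if abs(pos[i, 0] - centre) > midzone_half:
                            continue
                        if bead_link_count[i] >= max_links_per_bead:
                            continue
                        for j in range(fil_ptr[f2], fil_ptr[f2 + 1]):
                            if abs(pos[j, 0] - pos[i, 0]) > ds[f1]:
                                continue
                            if abs(pos[j, 0] - centre) > midzone_half:
                                continue
                            if bead_link_count[j] >= max_links_per_bead:
                                continue
                            dx = pos[j, 0] - pos[i, 0]
                            dy = pos[j, 1] - pos[i, 1]
                            dz = pos[j, 2] - pos[i, 2]
                            if dx * dx + dy * dy + dz * dz > capture * capture:
                                continue
                            dup = False
                            for l in range(n_lk):
                                if lk_a[l] == i and lk_b[l] == j:
                                    dup = True
                                    break
                            if not dup and n_cand < 4096:
                                cand_a[n_cand] = i
                                cand_b[n_cand] = j
                                n_cand += 1
            bound_now = 0
            while bound_now < bind_batch and n_cand > 0 and n_lk < lk_a.shape[0]:
                pick = np.random.randint(0, n_cand)
                i = cand_a[pick]
                j = cand_b[pick]
                cand_a[pick] = cand_a[n_cand - 1]
                cand_b[pick] = cand_b[n_cand - 1]
                n_cand -= 1
                if (bead_link_count[i] >= max_links_per_bead
                        or bead_link_count[j] >= max_links_per_bead):
                    continue
                lk_a[n_lk] = i
                lk_b[n_lk] = j
                n_lk += 1
                bead_link_count[i] += 1
                bead_link_count[j] += 1
                bound_now += 1

        # --- recording and divergence check ---
        if record_every > 0 and istep % record_every == 0:
            sep = spb_x[1] - spb_x[0]
            forces_out[n_rec] = pole_k * (sep - pole_rest)
            n_rec += 1
            if not (np.isfinite(pos[0, 0]) and np.isfinite(spb_x[0])):
                return STATUS_DIVERGED, n_lk, n_rec
        elif istep % 200 == 0:
            if not (np.isfinite(pos[0, 0]) and np.isfinite(spb_x[0])):
                return STATUS_DIVERGED, n_lk, n_rec

    return STATUS_OK, n_lk, n_rec
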