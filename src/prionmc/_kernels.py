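"""Numba kernels for the four-term interaction potential.

All kernels accept a boolean ``mask``/``use_mask`` pair: with ``use_mask``
set, only pair terms involving at least one masked (moved) atom are summed,
which is what makes move-local energy differences cheap.

Periodic systems use the minimum-image convention for *inter-chain* pairs
only; a chain is never wrapped through the box internally.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EV_CUTOFF = 4.3  # Angstrom, pair cutoff of the excluded-volume term
HB_CUTOFF = 4.5  # Angstrom, H...O cutoff of the hydrogen-bond term
SC_CONTACT = 4.5  # Angstrom, sidechain heavy-atom contact distance


@njit(cache=True)
def _mimg(d, box):
    if box > 0.0:
        d -= box * np.rint(d / box)
    return d


@njit(cache=True)
def ev_energy(coords, sigma, chain_id, local_id, bondsep, lam_bonded, kappa,
              box, mask, use_mask):
    """Excluded volume: kappa * sum [lam (si+sj)/r]^12, shifted to zero at the
    cutoff. Pairs fixed by the covalent geometry (<= 2 bonds) are skipped;
    3-bond pairs are softened by ``lam_bonded``. Returns (energy, min_r2)."""
    n = coords.shape[0]
    e = 0.0
    rc2 = EV_CUTOFF * EV_CUTOFF
    minr2 = 1.0e30
    if kappa == 0.0:
        return 0.0, minr2
    for i in range(n):
        for j in range(i + 1, n):
            if use_mask and not (mask[i] or mask[j]):
                continue
            same = chain_id[i] == chain_id[j]
            lam = 1.0
            if same:
                sep = bondsep[local_id[i], local_id[j]]
                if sep <= 2:
                    continue
                if sep == 3:
                    lam = lam_bonded
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            if not same:
                dx = _mimg(dx, box)
                dy = _mimg(dy, box)
                dz = _mimg(dz, box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < minr2:
                minr2 = r2
            if r2 >= rc2 or r2 < 1e-12:
                continue
            s = lam * (sigma[i] + sigma[j])
            sr12 = (s * s / r2) ** 6
            shift = (s / EV_CUTOFF) ** 12
            e += sr12 - shift
    return kappa * e, minr2


@njit(cache=True)
def loc_energy(coords, li, lj, qq, kappa, mask, use_mask):
    """Local electrostatics between adjacent backbone peptide units."""
    e = 0.0
    for k in range(li.shape[0]):
        i = li[k]
        j = lj[k]
        if use_mask and not (mask[i] or mask[j]):
            continue
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        e += qq[k] / r
    return kappa * e


@njit(cache=True)
def hb_energy(coords, dn, dh, dres, dchain, ac, ao, ares, achain,
              eps, sig, box, mask, use_mask):
    """Backbone NH...O=C hydrogen bonding.

    10-12 radial well (minimum -eps at r = sig) times cos^2(alpha)cos^2(beta),
    alpha = deviation of N-H...O from linearity, beta = deviation of N...O=C
    from linearity; the term gates off when either angle reaches 90 deg or
    r > 4.5 A. Same-chain pairs closer than two residues apart are excluded.
    """
    e = 0.0
    if eps == 0.0:
        return 0.0
    for a in range(dn.shape[0]):
        na = dn[a]
        ha = dh[a]
        for b in range(ac.shape[0]):
            ca = ac[b]
            oa = ao[b]
            same = dchain[a] == achain[b]
            if same:
                dr = dres[a] - ares[b]
                if -2 < dr < 2:
                    continue
            if use_mask and not (mask[na] or mask[ha] or mask[ca] or mask[oa]):
                continue
            # v = O - H (minimum image across chains)
            vx = coords[oa, 0] - coords[ha, 0]
            vy = coords[oa, 1] - coords[ha, 1]
            vz = coords[oa, 2] - coords[ha, 2]
            if not same:
                vx = _mimg(vx, box)
                vy = _mimg(vy, box)
                vz = _mimg(vz, box)
            r2 = vx * vx + vy * vy + vz * vz
            if r2 > HB_CUTOFF * HB_CUTOFF:
                continue
            r = np.sqrt(r2)
            # u = H - N
            ux = coords[ha, 0] - coords[na, 0]
            uy = coords[ha, 1] - coords[na, 1]
            uz = coords[ha, 2] - coords[na, 2]
            un = np.sqrt(ux * ux + uy * uy + uz * uz)
            cosa = (ux * vx + uy * vy + uz * vz) / (un * r)
            if cosa <= 0.0:
                continue
            # p = N - O_img = u_HN - v; q = C - O (acceptor-internal)
            px = -ux - vx + 0.0
            py = -uy - vy + 0.0
            pz = -uz - vz + 0.0
            # N - O = (N - H) - (O - H) = -u - v
            qx = coords[ca, 0] - coords[oa, 0]
            qy = coords[ca, 1] - coords[oa, 1]
            qz = coords[ca, 2] - coords[oa, 2]
            pn = np.sqrt(px * px + py * py + pz * pz)
            qn = np.sqrt(qx * qx + qy * qy + qz * qz)
            cosb = -(px * qx + py * qy + pz * qz) / (pn * qn)
            if cosb <= 0.0:
                continue
            x2 = (sig * sig) / r2
            x10 = x2 ** 5
            x12 = x10 * x2
            e += (5.0 * x12 - 6.0 * x10) * cosa * cosa * cosb * cosb
    return eps * e


@njit(cache=True)
def sc_energy(coords, grp_atom, grp_start, grp_len, grp_cat, grp_res, grp_chain,
              m_table, box, mask, use_mask):
    """Sidechain contact potential: -sum M[cat_i, cat_j] * C_ij with C_ij the
    fraction of heavy-atom pairs within the contact distance."""
    ng = grp_start.shape[0]
    e = 0.0
    c2 = SC_CONTACT * SC_CONTACT
    for gi in range(ng):
        for gj in range(gi + 1, ng):
            m = m_table[grp_cat[gi], grp_cat[gj]]
            if m == 0.0:
                continue
            same = grp_chain[gi] == grp_chain[gj]
            if same:
                dr = grp_res[gi] - grp_res[gj]
                if -2 < dr < 2:
                    continue
            if use_mask:
                any_moved = False
                for a in range(grp_len[gi]):
                    if mask[grp_atom[grp_start[gi] + a]]:
                        any_moved = True
                        break
                if not any_moved:
                    for b in range(grp_len[gj]):
                        if mask[grp_atom[grp_start[gj] + b]]:
                            any_moved = True
                            break
                if not any_moved:
                    continue
            cnt = 0
            for a in range(grp_len[gi]):
                ia = grp_atom[grp_start[gi] + a]
                for b in range(grp_len[gj]):
                    ib = grp_atom[grp_start[gj] + b]
                    dx = coords[ia, 0] - coords[ib, 0]
                    dy = coords[ia, 1] - coords[ib, 1]
                    dz = coords[ia, 2] - coords[ib, 2]
                    if not same:
                        dx = _mimg(dx, box)
                        dy = _mimg(dy, box)
                        dz = _mimg(dz, box)
                    if dx * dx + dy * dy + dz * dz < c2:
                        cnt += 1
            if cnt > 0:
                e -= m * cnt / (grp_len[gi] * grp_len[gj])
    return e
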