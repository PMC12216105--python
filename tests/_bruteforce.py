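"""Independent brute-force reference implementations of the statistics.

Everything here is written by direct enumeration (pairwise loops, exhaustive
subsets, per-site scans) with no code shared with the package, so it can
serve as the oracle in equivalence tests on tiny matrices.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def seg_columns(hap):
    n = len(hap)
    out = []
    for j in range(hap.shape[1]):
        c = sum(hap[i][j] for i in range(n))
        if 0 < c < n:
            out.append(j)
    return out


def bf_classic(hap, positions, L):
    hap = np.asarray(hap)
    n = hap.shape[0]
    segs = seg_columns(hap)
    S = len(segs) / L
    if not segs:
        return {"S": S, "D": np.nan, "PI_mean": np.nan, "PI_sd": np.nan}
    hs = []
    for j in segs:
        diff = sum(
            1 for a, b in itertools.combinations(range(n), 2) if hap[a, j] != hap[b, j]
        )
        hs.append(diff / math.comb(n, 2))
    hs = np.array(hs)
    pi = hs.sum()  # mean pairwise differences across the matrix
    s_count = len(segs)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s_count + e2 * s_count * (s_count - 1)
    D = (pi - s_count / a1) / math.sqrt(var) if var > 0 else np.nan
    return {"S": S, "D": D, "PI_mean": hs.mean(), "PI_sd": hs.std(ddof=0)}


def bf_window_het(hap, positions, L, w):
    hap = np.asarray(hap)
    n = hap.shape[0]
    n_win = max(1, math.ceil(L / w - 1e-9))
    hets = []
    for k in range(n_win):
        cols = [j for j, p in enumerate(positions) if k * w <= p < (k + 1) * w]
        strings = ["".join(str(hap[i, j]) for j in cols) for i in range(n)]
        freqs = {}
        for s in strings:
            freqs[s] = freqs.get(s, 0) + 1
        hets.append(1 - sum((c / n) ** 2 for c in freqs.values()))
    hets = np.array(hets)
    return {"WinH_mean": hets.mean(), "WinH_sd": hets.std(ddof=0)}


def bf_sfs(hap, positions, freqs):
    hap = np.asarray(hap)
    counts = [int(hap[:, j].sum()) for j in range(hap.shape[1])]
    total = sum(1 for c in counts if c in list(freqs))
    out = {}
    for i in freqs:
        sites = [j for j, c in enumerate(counts) if c == i]
        out[f"SFS_{i}"] = 100 * len(sites) / total if total else np.nan
        if len(sites) >= 2:
            gaps = [positions[b] - positions[a] for a, b in zip(sites, sites[1:])]
            out[f"SFS_gapsd_{i}"] = float(np.std(gaps, ddof=0))
        else:
            out[f"SFS_gapsd_{i}"] = np.nan
    return out


def bf_ld(hap, positions, edges):
    hap = np.asarray(hap, dtype=float)
    n = hap.shape[0]
    segs = seg_columns(hap)
    out = {}
    for b in range(len(edges) - 1):
        r2s = []
        for a, c in itertools.combinations(segs, 2):
            d = abs(positions[c] - positions[a])
            if not edges[b] <= d < edges[b + 1]:
                continue
            pa = hap[:, a].mean()
            pc = hap[:, c].mean()
            pac = (hap[:, a] * hap[:, c]).mean()
            r2s.append((pac - pa * pc) ** 2 / (pa * (1 - pa) * pc * (1 - pc)))
        if len(r2s) < 1:
            out[f"LD_{b + 1}_mean"] = np.nan
            out[f"LD_{b + 1}_sd"] = np.nan
        else:
            out[f"LD_{b + 1}_mean"] = float(np.mean(r2s))
            out[f"LD_{b + 1}_sd"] = (
                float(np.std(r2s, ddof=0)) if len(r2s) >= 2 else np.nan
            )
    return out


def bf_ibs(hap, positions, L, m_list, n_deciles=9):
    """Exhaustive-subset IBS deciles (valid when C(n, m) is small)."""
    hap = np.asarray(hap)
    n = hap.shape[0]
    qs = [(k + 1) / (n_deciles + 1) for k in range(n_deciles)]
    out = {}
    for m in m_list:
        lengths = []
        for rows in itertools.combinations(range(n), m):
            cuts = []
            for j in range(hap.shape[1]):
                c = sum(hap[i, j] for i in rows)
                if 0 < c < m:
                    cuts.append(positions[j])
            bounds = [0.0] + cuts + [L]
            lengths.extend(bounds[k + 1] - bounds[k] for k in range(len(bounds) - 1))
        dec = np.quantile(np.array(lengths), qs, method="linear")
        for k in range(n_deciles):
            out[f"IBS_m{m}_d{k + 1}"] = float(dec[k])
    return out


def bf_afibs(hap, positions, L, freqs):
    hap = np.asarray(hap)
    counts = [int(hap[:, j].sum()) for j in range(hap.shape[1])]
    out = {}
    for i in freqs:
        lengths = []
        for j, c in enumerate(counts):
            if c != i:
                continue
            carriers = [r for r in range(hap.shape[0]) if hap[r, j] == 1]
            left = 0.0
            for k in range(j - 1, -1, -1):
                sub = {hap[r, k] for r in carriers}
                if len(sub) > 1:
                    left = positions[k]
                    break
            right = L
            for k in range(j + 1, hap.shape[1]):
                sub = {hap[r, k] for r in carriers}
                if len(sub) > 1:
                    right = positions[k]
                    break
            lengths.append(right - left)
        out[f"AFIBS_{i}_mean"] = float(np.mean(lengths)) if len(lengths) >= 1 else np.nan
        out[f"AFIBS_{i}_sd"] = float(np.std(lengths, ddof=0)) if len(lengths) >= 2 else np.nan
    return out


def bf_cross(hap1, hap2, positions, L, full_grid=True):
    hap1 = np.asarray(hap1)
    hap2 = np.asarray(hap2)
    n1, n2 = hap1.shape[0], hap2.shape[0]
    s = hap1.shape[1]
    out = {}
    cells = [
        (i, j)
        for i in range(n1 + 1)
        for j in range(n2 + 1)
        if full_grid or (i, j) not in ((0, 0), (n1, n2))
    ]
    if s == 0:
        out.update({"Fst": np.nan, "Dxy": np.nan})
        for i, j in cells:
            out[f"JSFS_{i}_{j}"] = np.nan
        return out
    hw_sum = hb_sum = dxy = 0.0
    for j in range(s):
        within = []
        for hap in (hap1, hap2):
            n = hap.shape[0]
            pairs = list(itertools.combinations(range(n), 2))
            diff = sum(1 for a, b in pairs if hap[a, j] != hap[b, j])
            within.append(diff / len(pairs))
        hw_sum += (within[0] + within[1]) / 2
        between = sum(
            1 for a in range(n1) for b in range(n2) if hap1[a, j] != hap2[b, j]
        )
        hb_sum += between / (n1 * n2)
        p1 = hap1[:, j].mean()
        p2 = hap2[:, j].mean()
        dxy += p1 * (1 - p2) + p2 * (1 - p1)
    out["Fst"] = 1 - hw_sum / hb_sum if hb_sum > 0 else np.nan
    out["Dxy"] = dxy / L
    for i, j in cells:
        k = sum(
            1
            for col in range(s)
            if hap1[:, col].sum() == i and hap2[:, col].sum() == j
        )
        out[f"JSFS_{i}_{j}"] = 100 * k / s
    return out
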