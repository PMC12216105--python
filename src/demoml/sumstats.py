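"""Summary-statistics engine: eleven classes of per-locus statistics.

Within-population classes (computed for each population sample and for the
pooled sample): proportion of segregating sites (S), Tajima's D (D),
per-site expected heterozygosity mean/sd (PI), 50 kb-window haplotypic
heterozygosity (WinH), derived-allele site frequency spectrum percentages
and adjacent-SNP gap dispersions (SFS), r^2 linkage disequilibrium in 19
geometric distance bins (LD), identical-by-state segment length deciles for
subsets of m haplotypes (IBS), and allele-frequency-conditioned IBS segment
lengths around focal SNPs (AFIBS).  Among-population classes: Hudson's Fst,
raw divergence Dxy, and the joint site frequency spectrum (JSFS).

All per-locus values are aggregated across loci with mean, median and
sample variance into a fixed, named feature schema.  For the default study
design (10 diploids per population, segregating-site input) the schema
enumerates exactly 3024 features.

Coordinates are 0-based half-open throughout.  Statistics that are
undefined on a locus (e.g. Tajima's D with no segregating site) are masked
with NaN per locus and, if masked on every locus, imputed with 0 after
aggregation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .demography import SampleDesign
from .simulate import LocusData

__all__ = [
    "StatConfig",
    "FeatureSchema",
    "FeatureVector",
    "CLASS_NAMES",
    "classic_stats",
    "window_haplo_het",
    "sfs_features",
    "ld_features",
    "ld_bin_edges",
    "ibs_features",
    "ibs_m_values",
    "afibs_features",
    "cross_pop_features",
    "locus_stat_vector",
    "aggregate_features",
    "build_schema",
    "simulation_features",
]

CLASS_NAMES = ("S", "D", "PI", "WinH", "SFS", "LD", "IBS", "AFIBS", "Fst", "Dxy", "JSFS")
SCOPES = ("p1", "p2", "all")
AGGREGATORS = ("mu", "med", "var")


@dataclass(frozen=True)
class StatConfig:
    """Configuration of the statistics engine.

    Defaults reproduce the study design.  ``sampling_seed`` controls the
    seeded LD pair subsampling and IBS haplotype-subset draws, which are
    identical across loci so that per-locus values stay comparable.
    """

    window_size: float = 50_000.0
    n_ld_bins: int = 19
    ld_mean_min: float = 282.0
    ld_mean_max: float = 1.4e6
    ld_pair_cap: int = 10_000
    ibs_n_subsets: int = 20
    n_deciles: int = 9
    sampling_seed: int = 2027
    # schema-composition switches (reconciled defaults give 3024 features
    # under the 10-diploids-per-population design)
    include_pop_fixed_sfs: bool = True  # per-pop SFS/AFIBS range 1..n_hap
    jsfs_full_grid: bool = True  # keep the structurally-zero corner cells
    include_pooled_ibs: bool = True
    include_pooled_afibs: bool = True


def ld_bin_edges(cfg: StatConfig) -> np.ndarray:
    """Geometric distance-bin edges whose per-bin geometric means run from
    ``ld_mean_min`` (282 bp) to ``ld_mean_max`` (1.4 Mb)."""
    k = cfg.n_ld_bins
    ratio = (cfg.ld_mean_max / cfg.ld_mean_min) ** (1.0 / (k - 1))
    means = cfg.ld_mean_min * ratio ** np.arange(k)
    edges = np.empty(k + 1)
    edges[:-1] = means / np.sqrt(ratio)
    edges[-1] = means[-1] * np.sqrt(ratio)
    return edges


def ibs_m_values(n_hap: int) -> tuple[int, ...]:
    """Subset sizes m for IBS segments: powers of two in [2, n_hap]."""
    out = []
    m = 2
    while m <= n_hap:
        out.append(m)
        m *= 2
    return tuple(out)


def _sfs_range(n_hap: int, pooled: bool, cfg: StatConfig) -> range:
    if pooled or not cfg.include_pop_fixed_sfs:
        return range(1, n_hap)
    return range(1, n_hap + 1)


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------


def _segregating(hap: np.ndarray) -> np.ndarray:
    n = hap.shape[0]
    counts = hap.sum(axis=0)
    return (counts > 0) & (counts < n)


def classic_stats(hap: np.ndarray, positions: np.ndarray, locus_length: float) -> dict:
    """S (segregating-site proportion), Tajima's D, and per-site expected
    heterozygosity mean/sd, on sites segregating within this sample."""
    hap = np.asarray(hap)
    n = hap.shape[0]
    if n < 2:
        raise ValueError("need at least two haplotypes")
    seg = _segregating(hap)
    s_count = int(seg.sum())
    out = {"S": s_count / locus_length, "D": np.nan, "PI_mean": np.nan, "PI_sd": np.nan}
    if s_count == 0:
        return out
    c = hap[:, seg].sum(axis=0).astype(float)
    p = c / n
    h = (n / (n - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2)
    out["PI_mean"] = float(h.mean())
    out["PI_sd"] = float(h.std(ddof=0))
    # Tajima (1989)
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = float(h.sum())  # mean pairwise differences
    var = e1 * s_count + e2 * s_count * (s_count - 1.0)
    if var > 0:
        out["D"] = (pi - s_count / a1) / np.sqrt(var)
    return out


def window_haplo_het(
    hap: np.ndarray, positions: np.ndarray, locus_length: float, window_size: float = 50_000.0
) -> dict:
    """Mean and sd of haplotypic heterozygosity 1 - sum f_h^2 over
    non-overlapping windows tiling the locus."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    hap = np.asarray(hap)
    n = hap.shape[0]
    n_win = max(1, int(np.ceil(locus_length / window_size - 1e-9)))
    hets = np.empty(n_win)
    for k in range(n_win):
        lo, hi = k * window_size, (k + 1) * window_size
        cols = (positions >= lo) & (positions < hi)
        sub = hap[:, cols]
        if sub.shape[1] == 0:
            hets[k] = 0.0
            continue
        _, counts = np.unique(sub, axis=0, return_counts=True)
        f = counts / n
        hets[k] = 1.0 - (f**2).sum()
    return {"WinH_mean": float(hets.mean()), "WinH_sd": float(hets.std(ddof=0))}


def sfs_features(
    hap: np.ndarray, positions: np.ndarray, freqs: Iterable[int] | None = None
) -> dict:
    """Derived-allele SFS percentages and adjacent-SNP gap dispersion.

    ``pct_i`` = 100 x (#sites with derived count i) / (#sites with count in
    the scope's range); ``gapsd_i`` = sd of gaps between consecutive
    positions of sites with count i (masked below two qualifying sites).
    """
    hap = np.asarray(hap)
    n = hap.shape[0]
    if freqs is None:
        freqs = range(1, n)
    freqs = list(freqs)
    counts = hap.sum(axis=0)
    in_range = np.isin(counts, freqs)
    total = int(in_range.sum())
    out = {}
    for i in freqs:
        sel = counts == i
        k = int(sel.sum())
        out[f"SFS_{i}"] = 100.0 * k / total if total else np.nan
        if k >= 2:
            gaps = np.diff(positions[sel])
            out[f"SFS_gapsd_{i}"] = float(np.std(gaps, ddof=0))
        else:
            out[f"SFS_gapsd_{i}"] = np.nan
    return out


def _sample_bin_pairs(
    positions: np.ndarray, lo: float, hi: float, cap: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (a, b), a < b, with hi > positions[b]-positions[a] >= lo;
    exhaustive when their number is <= cap, else a seeded uniform subsample."""
    s = positions.shape[0]
    start = np.searchsorted(positions, positions + lo, side="left")
    stop = np.searchsorted(positions, positions + hi, side="left")
    start = np.maximum(start, np.arange(s) + 1)
    counts = np.maximum(stop - start, 0)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    cum = np.concatenate([[0], np.cumsum(counts)])
    if total <= cap:
        a = np.repeat(np.arange(s), counts)
        b = np.repeat(start, counts) + (np.arange(total) - np.repeat(cum[:-1], counts))
        return a, b
    picks = np.sort(rng.choice(total, size=cap, replace=False))
    a = np.searchsorted(cum, picks, side="right") - 1
    b = start[a] + (picks - cum[a])
    return a, b


def ld_features(
    hap: np.ndarray,
    positions: np.ndarray,
    edges: np.ndarray,
    pair_cap: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Mean and sd of r^2 for SNP pairs in each distance bin.

    r^2 is computed from phased two-locus haplotype frequencies; bins with
    fewer than two pairs are masked.  Pair counts per bin are capped by
    seeded subsampling.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    hap = np.asarray(hap)
    seg = _segregating(hap)
    subT = np.ascontiguousarray(hap[:, seg].T, dtype=np.float64)  # (sites, n)
    pos = positions[seg]
    n_bins = len(edges) - 1
    pair_a, pair_b, bin_id = [], [], []
    for b in range(n_bins):
        a_idx, b_idx = _sample_bin_pairs(pos, edges[b], edges[b + 1], pair_cap, rng)
        pair_a.append(a_idx)
        pair_b.append(b_idx)
        bin_id.append(np.full(a_idx.shape[0], b))
    n_per_bin = np.array([a.shape[0] for a in pair_a])
    out = {}
    if n_per_bin.sum() == 0:
        for b in range(n_bins):
            out[f"LD_{b + 1}_mean"] = np.nan
            out[f"LD_{b + 1}_sd"] = np.nan
        return out
    a_all = np.concatenate(pair_a)
    b_all = np.concatenate(pair_b)
    bins = np.concatenate(bin_id)
    freq = subT.mean(axis=1)
    pa, pb = freq[a_all], freq[b_all]
    pab = np.einsum("ij,ij->i", subT[a_all], subT[b_all]) / subT.shape[1]
    r2 = (pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb))
    sums = np.bincount(bins, weights=r2, minlength=n_bins)
    means = sums / np.maximum(n_per_bin, 1)
    # two-pass dispersion (centred) to avoid catastrophic cancellation
    sqs = np.bincount(bins, weights=(r2 - means[bins]) ** 2, minlength=n_bins)
    for b in range(n_bins):
        k = n_per_bin[b]
        if k < 1:
            out[f"LD_{b + 1}_mean"] = np.nan
            out[f"LD_{b + 1}_sd"] = np.nan
            continue
        out[f"LD_{b + 1}_mean"] = float(means[b])
        # the dispersion needs at least two pairs
        out[f"LD_{b + 1}_sd"] = float(np.sqrt(sqs[b] / k)) if k >= 2 else np.nan
    return out


def ibs_features(
    hap: np.ndarray,
    positions: np.ndarray,
    locus_length: float,
    m_list: Sequence[int],
    n_subsets: int = 20,
    n_deciles: int = 9,
    rng: np.random.Generator | None = None,
) -> dict:
    """Deciles of the pooled IBS segment-length distribution for random
    subsets of m haplotypes (sites polymorphic within the subset partition
    [0, locus_length], flanking segments included)."""
    if rng is None:
        rng = np.random.default_rng(0)
    hap = np.asarray(hap)
    n = hap.shape[0]
    # canonical (lexicographic) row order so subset draws are invariant to
    # the haplotype ordering of the input matrix
    if hap.shape[1]:
        hap = hap[np.lexsort(hap.T[::-1])]
    qs = np.arange(1, n_deciles + 1) / (n_deciles + 1.0)
    out = {}
    for m in m_list:
        if m > n:
            raise ValueError(f"subset size m={m} exceeds {n} haplotypes")
        from math import comb

        if comb(n, m) <= n_subsets:  # exhaustive when feasible
            subsets = [np.array(c) for c in itertools.combinations(range(n), m)]
        else:
            subsets = [rng.choice(n, size=m, replace=False) for _ in range(n_subsets)]
        lengths = []
        for rows in subsets:
            c = hap[rows].sum(axis=0)
            poly = (c > 0) & (c < m)
            cut = positions[poly]
            lengths.append(np.diff(np.concatenate([[0.0], cut, [locus_length]])))
        pooled = np.concatenate(lengths)
        dec = np.quantile(pooled, qs, method="linear")
        for k in range(n_deciles):
            out[f"IBS_m{m}_d{k + 1}"] = float(dec[k])
    return out


def afibs_features(
    hap: np.ndarray,
    positions: np.ndarray,
    locus_length: float,
    freqs: Iterable[int] | None = None,
) -> dict:
    """Allele-frequency-conditioned IBS segment lengths.

    For each site with derived count i, the segment extends from the nearest
    flanking site at which the i carrier haplotypes are not all identical
    (exclusive), truncated at the locus boundaries; per-frequency mean and sd
    over qualifying sites (sd masked below two sites).
    """
    hap = np.asarray(hap, dtype=np.int32)
    n = hap.shape[0]
    s = hap.shape[1]
    if freqs is None:
        freqs = range(2, n)
    freqs = list(freqs)
    counts = hap.sum(axis=0)
    col_idx = np.arange(s)
    out = {}
    for i in freqs:
        js = np.flatnonzero(counts == i)
        if js.size == 0:
            out[f"AFIBS_{i}_mean"] = np.nan
            out[f"AFIBS_{i}_sd"] = np.nan
            continue
        # derived counts within each focal site's carrier set, all columns at once
        carrier_counts = hap[:, js].T @ hap  # (n_focal, s)
        broken = (carrier_counts > 0) & (carrier_counts < i)
        broken[np.arange(js.size), js] = False
        # nearest breaking site on each side of the focal column
        last_left = np.maximum.accumulate(np.where(broken, col_idx, -1), axis=1)
        li = np.where(js > 0, last_left[np.arange(js.size), np.maximum(js - 1, 0)], -1)
        first_right = np.minimum.accumulate(
            np.where(broken, col_idx, s)[:, ::-1], axis=1
        )[:, ::-1]
        ri = np.where(js < s - 1, first_right[np.arange(js.size), np.minimum(js + 1, s - 1)], s)
        left = np.where(li >= 0, positions[np.maximum(li, 0)], 0.0)
        right = np.where(ri < s, positions[np.minimum(ri, s - 1)], locus_length)
        vals = right - left
        out[f"AFIBS_{i}_mean"] = float(vals.mean())
        out[f"AFIBS_{i}_sd"] = float(vals.std(ddof=0)) if vals.size >= 2 else np.nan
    return out


def cross_pop_features(
    hap1: np.ndarray, hap2: np.ndarray, positions: np.ndarray, locus_length: float,
    jsfs_full_grid: bool = True,
) -> dict:
    """Hudson's Fst (ratio of sums), raw divergence Dxy, and the JSFS.

    JSFS cell (i, j) is the percentage of sites with derived count i in
    population 1 and j in population 2 among all sites segregating in the
    pooled sample; the structurally-zero corner cells (0,0) and (n1,n2) are
    kept under the full-grid convention (configurable).
    """
    hap1 = np.asarray(hap1, dtype=float)
    hap2 = np.asarray(hap2, dtype=float)
    n1, n2 = hap1.shape[0], hap2.shape[0]
    c1 = hap1.sum(axis=0)
    c2 = hap2.sum(axis=0)
    s = c1.shape[0]
    out: dict[str, float] = {}
    cells = [
        (i, j)
        for i in range(n1 + 1)
        for j in range(n2 + 1)
        if jsfs_full_grid or (i, j) not in ((0, 0), (n1, n2))
    ]
    if s == 0:
        out["Fst"] = np.nan
        out["Dxy"] = np.nan
        for i, j in cells:
            out[f"JSFS_{i}_{j}"] = np.nan
        return out
    p1 = c1 / n1
    p2 = c2 / n2
    hw = np.zeros(s)
    if n1 > 1:
        hw += 2.0 * c1 * (n1 - c1) / (n1 * (n1 - 1.0))
    if n2 > 1:
        hw += 2.0 * c2 * (n2 - c2) / (n2 * (n2 - 1.0))
    hw /= 2.0
    hb = (c1 * (n2 - c2) + c2 * (n1 - c1)) / (n1 * n2)
    out["Fst"] = 1.0 - hw.sum() / hb.sum() if hb.sum() > 0 else np.nan
    out["Dxy"] = float((p1 * (1 - p2) + p2 * (1 - p1)).sum() / locus_length)
    grid = np.zeros((n1 + 1, n2 + 1))
    np.add.at(grid, (c1.astype(int), c2.astype(int)), 1.0)
    grid *= 100.0 / s
    for i, j in cells:
        out[f"JSFS_{i}_{j}"] = float(grid[i, j])
    return out


# ---------------------------------------------------------------------------
# schema and aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, named feature manifest.

    Each aggregated feature name is ``<base>_<scope>-<agg>`` with scope in
    {p1, p2, all, xpop} and agg in {mu, med, var}; ``base_names`` lists the
    per-locus statistics in the same order (one per 3 aggregated features).
    """

    names: tuple[str, ...]
    base_names: tuple[str, ...]
    classes: tuple[str, ...]  # per aggregated feature
    scopes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.names)

    def class_of(self, name: str) -> str:
        try:
            return self.classes[self.names.index(name)]
        except ValueError:
            raise KeyError(f"feature {name!r} not in schema") from None

    def to_manifest(self) -> dict:
        return {
            "n_features": len(self.names),
            "features": [
                {"name": n, "class": c, "scope": s}
                for n, c, s in zip(self.names, self.classes, self.scopes)
            ],
        }


@dataclass
class FeatureVector:
    """Aggregated feature values aligned to a schema."""

    schema: FeatureSchema
    values: np.ndarray
    n_missing: np.ndarray  # per aggregated feature: loci masked during aggregation
    simulation_id: int | None = None


def _class_of_base(base: str) -> str:
    for cls in ("WinH", "SFS", "LD", "IBS", "AFIBS", "JSFS", "Fst", "Dxy", "PI"):
        if base.startswith(cls):
            return cls
    if base == "S":
        return "S"
    if base == "D":
        return "D"
    raise ValueError(f"cannot classify base statistic {base!r}")


def _scope_base_names(n_hap: int, pooled: bool, cfg: StatConfig) -> list[str]:
    names = ["S", "D", "PI_mean", "PI_sd", "WinH_mean", "WinH_sd"]
    for i in _sfs_range(n_hap, pooled, cfg):
        names.append(f"SFS_{i}")
    for i in _sfs_range(n_hap, pooled, cfg):
        names.append(f"SFS_gapsd_{i}")
    for b in range(cfg.n_ld_bins):
        names.append(f"LD_{b + 1}_mean")
        names.append(f"LD_{b + 1}_sd")
    if not pooled or cfg.include_pooled_ibs:
        for m in ibs_m_values(n_hap):
            for k in range(cfg.n_deciles):
                names.append(f"IBS_m{m}_d{k + 1}")
    if not pooled or cfg.include_pooled_afibs:
        for i in _sfs_range(n_hap, pooled, cfg):
            names.append(f"AFIBS_{i}_mean")
            names.append(f"AFIBS_{i}_sd")
    return names


def _cross_base_names(n1: int, n2: int, cfg: StatConfig) -> list[str]:
    names = ["Fst", "Dxy"]
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if cfg.jsfs_full_grid or (i, j) not in ((0, 0), (n1, n2)):
                names.append(f"JSFS_{i}_{j}")
    return names


def build_schema(design: SampleDesign, cfg: StatConfig | None = None) -> FeatureSchema:
    """Deterministically enumerate the aggregated feature schema for a design."""
    cfg = cfg or StatConfig()
    h = design.n_hap_per_pop
    bases: list[tuple[str, str]] = []  # (base name with scope suffix, scope)
    for scope, pooled, n_hap in (("p1", False, h), ("p2", False, h), ("all", True, 2 * h)):
        for base in _scope_base_names(n_hap, pooled, cfg):
            bases.append((f"{base}_{scope}", scope))
    for base in _cross_base_names(h, h, cfg):
        bases.append((f"{base}_xpop", "xpop"))
    names, base_names, classes, scopes = [], [], [], []
    for base, scope in bases:
        raw = base[: -(len(scope) + 1)]
        cls = _class_of_base(raw)
        for agg in AGGREGATORS:
            names.append(f"{base}-{agg}")
            base_names.append(base)
            classes.append(cls)
            scopes.append(scope)
    return FeatureSchema(
        names=tuple(names),
        base_names=tuple(base_names),
        classes=tuple(classes),
        scopes=tuple(scopes),
    )


def locus_stat_vector(
    locus: LocusData, design: SampleDesign, cfg: StatConfig | None = None
) -> dict[str, float]:
    """All per-locus base statistics keyed by ``<base>_<scope>`` (NaN = masked)."""
    cfg = cfg or StatConfig()
    edges = ld_bin_edges(cfg)
    out: dict[str, float] = {}
    pools = {
        "p1": (locus.pop_matrix(0), False),
        "p2": (locus.pop_matrix(1), False),
        "all": (locus.haplotypes, True),
    }
    for scope_id, (scope, (full, pooled)) in enumerate(pools.items()):
        present = full.sum(axis=0) > 0 if full.shape[1] else np.zeros(0, dtype=bool)
        hap = full[:, present]
        pos = locus.positions[present]
        n_hap = hap.shape[0]
        rng = np.random.default_rng([cfg.sampling_seed, scope_id])
        stats: dict[str, float] = {}
        stats.update(classic_stats(hap, pos, locus.locus_length))
        stats.update(window_haplo_het(hap, pos, locus.locus_length, cfg.window_size))
        freqs = _sfs_range(n_hap, pooled, cfg)
        stats.update(sfs_features(hap, pos, freqs))
        stats.update(ld_features(hap, pos, edges, cfg.ld_pair_cap, rng))
        if not pooled or cfg.include_pooled_ibs:
            stats.update(
                ibs_features(
                    hap, pos, locus.locus_length, ibs_m_values(n_hap),
                    cfg.ibs_n_subsets, cfg.n_deciles, rng,
                )
            )
        if not pooled or cfg.include_pooled_afibs:
            stats.update(afibs_features(hap, pos, locus.locus_length, freqs))
        for key, val in stats.items():
            out[f"{key}_{scope}"] = val
    cross = cross_pop_features(
        locus.pop_matrix(0), locus.pop_matrix(1), locus.positions,
        locus.locus_length, cfg.jsfs_full_grid,
    )
    for key, val in cross.items():
        out[f"{key}_xpop"] = val
    return out


def aggregate_features(
    per_locus: Sequence[dict[str, float]],
    schema: FeatureSchema,
    simulation_id: int | None = None,
) -> FeatureVector:
    """Mean / median / sample variance across loci, masked entries ignored.

    A feature whose base statistic is masked on every locus (or, for the
    variance, defined on fewer than two loci) is imputed with 0; the count
    of masked loci per feature is reported alongside.
    """
    if not per_locus:
        raise ValueError("need at least one locus")
    n_loci = len(per_locus)
    values = np.empty(len(schema))
    n_missing = np.zeros(len(schema), dtype=int)
    base_cache: dict[str, np.ndarray] = {}
    for idx in range(0, len(schema), 3):
        base = schema.base_names[idx]
        if base not in base_cache:
            base_cache[base] = np.array([d[base] for d in per_locus], dtype=float)
        vals = base_cache[base]
        ok = np.isfinite(vals)
        k = int(ok.sum())
        sub = vals[ok]
        for off, agg in enumerate(AGGREGATORS):
            miss = n_loci - k
            if agg == "mu":
                v = sub.mean() if k >= 1 else 0.0
            elif agg == "med":
                v = float(np.median(sub)) if k >= 1 else 0.0
            else:
                v = sub.var(ddof=1) if k >= 2 else 0.0
            values[idx + off] = v
            n_missing[idx + off] = miss
    return FeatureVector(schema=schema, values=values, n_missing=n_missing,
                         simulation_id=simulation_id)


def simulation_features(
    loci: Sequence[LocusData],
    design: SampleDesign,
    cfg: StatConfig | None = None,
    schema: FeatureSchema | None = None,
    simulation_id: int | None = None,
) -> FeatureVector:
    """Per-locus statistics plus cross-locus aggregation for one simulation."""
    cfg = cfg or StatConfig()
    schema = schema or build_schema(design, cfg)
    per_locus = [locus_stat_vector(loc, design, cfg) for loc in loci]
    return aggregate_features(per_locus, schema, simulation_id)
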